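"""Iterative extraction of over-represented phosphorylation motifs.

Works on aligned 13-mer sequence windows (phosphorylated residue at the
centre, six flanking positions each side).  The extractor follows the
motif-x scheme: at each step, for every unconstrained (offset, residue)
pair, compute the binomial tail probability of seeing the foreground count
given the residue's frequency at that offset in the background; accept the
most significant pair if it clears the p cutoff and the minimum occurrence
count; reduce both window sets to the matching windows and repeat.  When a
motif is complete its foreground matches are removed and extraction
restarts, so several motifs can be reported per direction.  The motif score
is the sum of −log10 step p values, and the fold change compares foreground
and background match rates against the original set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, FormatError
from .io import PHOSPHO_RESIDUES, WINDOW_FLANK, WINDOW_LENGTH, PhosphoSite

__all__ = [
    "MotifPattern",
    "MotifResult",
    "extract_windows",
    "motif_x",
    "position_heatmap",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# flanking offsets −6..−1, +1..+6 (the centre is fixed by construction)
FLANK_OFFSETS = tuple(o for o in range(-WINDOW_FLANK, WINDOW_FLANK + 1) if o != 0)


@dataclass(frozen=True)
class MotifPattern:
    """A set of fixed residues at flanking offsets around a central S/T/Y."""

    central: str
    constraints: tuple[tuple[int, str], ...]  # ordered (offset, residue)

    def __post_init__(self) -> None:
        if self.central not in PHOSPHO_RESIDUES:
            raise FormatError(f"central residue must be S/T/Y, got {self.central!r}")
        offsets = [o for o, _ in self.constraints]
        if len(set(offsets)) != len(offsets):
            raise FormatError("two constraints share an offset")
        for o, r in self.constraints:
            if o == 0 or not -WINDOW_FLANK <= o <= WINDOW_FLANK:
                raise FormatError(f"offset {o} outside the flanking range")

    def render(self) -> str:
        """Deterministic text form, e.g. ``xxxxxx_S_DxExxx``."""
        cells = ["x"] * WINDOW_LENGTH
        for offset, residue in self.constraints:
            cells[offset + WINDOW_FLANK] = residue
        left = "".join(cells[:WINDOW_FLANK])
        right = "".join(cells[WINDOW_FLANK + 1 :])
        return f"{left}_{self.central}_{right}"

    def matches(self, window: str) -> bool:
        return all(window[o + WINDOW_FLANK] == r for o, r in self.constraints)


@dataclass(frozen=True)
class MotifResult:
    pattern: MotifPattern
    motif_score: float  # Σ −log10 p over extraction steps
    fold_change: float  # (fg matches/fg size₀) / (bg matches/bg size₀)
    fg_matches: int
    bg_matches: int
    step_p_values: tuple[float, ...]


def extract_windows(
    sites: list[PhosphoSite],
    regulated_ids: set[str],
    split_central: bool = True,
) -> dict[str, tuple[list[str], list[str]]]:
    """Foreground (regulated) and background (all) windows per centre class.

    With ``split_central`` S, T and Y centres are analysed independently;
    otherwise every class shares one pooled pair.  Classes without any
    foreground window are omitted; an entirely empty foreground is an error.
    """
    if not regulated_ids <= {s.site_id for s in sites}:
        raise FormatError("regulated ids must be a subset of the site table")
    classes = sorted(PHOSPHO_RESIDUES) if split_central else ["STY"]
    out: dict[str, tuple[list[str], list[str]]] = {}
    for cls in classes:
        fg = [s.window for s in sites if s.residue in cls and s.site_id in regulated_ids]
        bg = [s.window for s in sites if s.residue in cls]
        if fg:
            out[cls] = (fg, bg)
    if not out:
        raise FormatError("no regulated site yields a foreground window")
    return out


def _counts(windows: list[str]) -> np.ndarray:
    """Residue × flank-offset occurrence counts (20 × 12)."""
    counts = np.zeros((len(AMINO_ACIDS), len(FLANK_OFFSETS)), dtype=np.int64)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for window in windows:
        for j, offset in enumerate(FLANK_OFFSETS):
            aa = window[offset + WINDOW_FLANK]
            if aa in index:  # padding '_' does not count
                counts[index[aa], j] += 1
    return counts


def binomial_tail(k: int, n: int, q: float) -> float:
    """P(X ≥ k) for X ~ Binomial(n, q)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, q))


def motif_x(
    foreground: list[str],
    background: list[str],
    central: str,
    p_cutoff: float = 1e-6,
    min_occurrences: int = 20,
) -> list[MotifResult]:
    """Greedy motif extraction from aligned 13-mer windows.

    At each step the (offset, residue) with the smallest binomial tail
    probability is accepted if p < ``p_cutoff`` and the foreground count is
    at least ``min_occurrences``; ties prefer the larger count, then the
    smaller offset, then the alphabetically first residue.  Matching windows
    replace both sets and the search repeats; a completed motif's foreground
    matches are removed before looking for the next motif.  Returns possibly
    several motifs; an empty list means nothing cleared the cutoff.
    """
    for w in foreground + background:
        if len(w) != WINDOW_LENGTH:
            raise FormatError("all windows must have length 13")
    fg0, bg0 = len(foreground), len(background)
    results: list[MotifResult] = []
    remaining_fg = list(foreground)
    while True:
        constraints: list[tuple[int, str]] = []
        step_ps: list[float] = []
        fg = list(remaining_fg)
        bg = list(background)
        while True:
            if not fg or not bg:
                break
            fg_counts = _counts(fg)
            bg_counts = _counts(bg)
            bg_freq = bg_counts / len(bg)
            taken = {o for o, _ in constraints}
            best: tuple | None = None
            for j, offset in enumerate(FLANK_OFFSETS):
                if offset in taken:
                    continue
                for i, residue in enumerate(AMINO_ACIDS):
                    k = int(fg_counts[i, j])
                    if k < min_occurrences:
                        continue
                    q = float(bg_freq[i, j])
                    p = binomial_tail(k, len(fg), q)
                    key = (p, -k, offset, residue)
                    if best is None or key < best[0]:
                        best = (key, offset, residue, p)
            if best is None or best[3] >= p_cutoff:
                break
            _, offset, residue, p = best
            constraints.append((offset, residue))
            step_ps.append(p)
            pos = offset + WINDOW_FLANK
            fg = [w for w in fg if w[pos] == residue]
            bg = [w for w in bg if w[pos] == residue]
        if not constraints:
            break
        pattern = MotifPattern(central=central, constraints=tuple(constraints))
        fg_matches = sum(pattern.matches(w) for w in remaining_fg)
        bg_matches = sum(pattern.matches(w) for w in background)
        fold = (fg_matches / fg0) / (bg_matches / bg0) if bg_matches else np.inf
        results.append(
            MotifResult(
                pattern=pattern,
                motif_score=float(-np.log10(step_ps).sum()),
                fold_change=float(fold),
                fg_matches=fg_matches,
                bg_matches=bg_matches,
                step_p_values=tuple(step_ps),
            )
        )
        remaining_fg = [w for w in remaining_fg if not pattern.matches(w)]
        if not remaining_fg:
            break
    return results


def position_heatmap(
    foreground: list[str],
    background: list[str],
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residue × offset enrichment map with significance marks.

    Each cell is log2 of the pseudocounted foreground/background frequency
    ratio for that residue at that flanking offset; the companion boolean
    frame marks cells whose two-sided binomial test survives BH correction
    at ``alpha``.
    """
    if not foreground or not background:
        raise FormatError("foreground and background must be non-empty")
    fg_counts = _counts(foreground)
    bg_counts = _counts(background)
    n_fg, n_bg = len(foreground), len(background)
    fg_freq = (fg_counts + pseudocount) / (n_fg + 2 * pseudocount)
    bg_freq = (bg_counts + pseudocount) / (n_bg + 2 * pseudocount)
    ratio = np.log2(fg_freq / bg_freq)

    raw_bg_freq = np.clip(bg_counts / n_bg, 1e-12, 1 - 1e-12)
    pvals = np.array(
        [
            [
                stats.binomtest(int(fg_counts[i, j]), n_fg, raw_bg_freq[i, j]).pvalue
                for j in range(len(FLANK_OFFSETS))
            ]
            for i in range(len(AMINO_ACIDS))
        ]
    )
    significant = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")[0].reshape(pvals.shape)
    index = pd.Index(list(AMINO_ACIDS), name="residue")
    cols = pd.Index(FLANK_OFFSETS, name="offset")
    return (
        pd.DataFrame(ratio, index=index, columns=cols),
        pd.DataFrame(significant, index=index, columns=cols),
    )
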