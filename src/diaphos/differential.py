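"""Stage-contrast statistics, regulation classes and over-representation.

For a contrast B/A (e.g. PD/D) every feature gets the ratio of linear-scale
group means, a two-sided t-test p value on log2 values (pooled-variance by default),
a Benjamini–Hochberg q value across the contrast, and a regulation class:
``up`` when ratio > 1.3 and p < 0.05, ``down`` when ratio < 0.77 and
p < 0.05, ``unchanged`` otherwise.  Classification uses the raw p value;
the q value is reported alongside and a strict-FDR mode can classify on q
instead.  The >5-fold "extreme" lists and a generic hypergeometric
over-representation test for annotated feature sets live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DesignError, FormatError
from .io import FeatureSetCollection, QuantMatrix

__all__ = [
    "Thresholds",
    "classify",
    "compare_groups",
    "all_contrasts",
    "extreme_features",
    "ora",
]


@dataclass(frozen=True)
class Thresholds:
    """Regulation-calling thresholds.

    Defaults follow the common practice for 3-replicate TMT designs:
    ratio > 1.3 or < 0.77 at raw p < 0.05, and a 5-fold cut for the
    extreme lists.
    """

    up_threshold: float = 1.3
    down_threshold: float = 0.77
    alpha: float = 0.05
    extreme_fold: float = 5.0

    def __post_init__(self) -> None:
        if not self.down_threshold < 1.0 < self.up_threshold:
            raise ConfigError("need down_threshold < 1 < up_threshold")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.extreme_fold <= 1.0:
            raise ConfigError("extreme_fold must exceed 1")


def classify(ratio: float, p: float, thresholds: Thresholds, use_q: bool = False, q: float = np.nan) -> str:
    """Regulation class as a pure function of (ratio, p, thresholds)."""
    crit = q if use_q else p
    if ratio > thresholds.up_threshold and crit < thresholds.alpha:
        return "up"
    if ratio < thresholds.down_threshold and crit < thresholds.alpha:
        return "down"
    return "unchanged"


def compare_groups(
    matrix: QuantMatrix,
    contrast: tuple[str, str],
    thresholds: Thresholds = Thresholds(),
    test: str = "student",
    strict_fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature statistics for the contrast ``B/A``.

    Parameters
    ----------
    matrix
        Linear-scale quantification matrix.
    contrast
        ``(A, B)`` stage labels; the reported ratio is mean(B)/mean(A) on
        linear scale and the test compares log2 values between the groups.
    test
        ``"student"`` (pooled variance, default — the groups share a noise
        model and at n=3 the pooled estimate buys real power) or
        ``"welch"`` (unequal variances).
    strict_fdr
        Classify on BH q instead of raw p.

    Returns
    -------
    DataFrame indexed by feature with columns ``contrast``, ``ratio``,
    ``log2_ratio``, ``p``, ``q`` and ``class``.
    """
    if matrix.scale != "linear":
        raise FormatError("compare_groups expects a linear-scale matrix")
    group_a, group_b = contrast
    cols_a = matrix.samples_for_stage(group_a)
    cols_b = matrix.samples_for_stage(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError(f"contrast {group_b}/{group_a}: each group needs ≥2 replicates")
    if test not in ("welch", "student"):
        raise ConfigError(f"unknown test {test!r}")

    a = matrix.values[cols_a].to_numpy(float)
    b = matrix.values[cols_b].to_numpy(float)
    ratio = b.mean(axis=1) / a.mean(axis=1)
    log_a, log_b = np.log2(a), np.log2(b)
    p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=(test == "student")).pvalue
    # a feature constant in both groups compares equal: no evidence of change
    p = np.where(np.isnan(p) & np.isclose(ratio, 1.0), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    label = f"{group_b}/{group_a}"
    records = pd.DataFrame(
        {
            "contrast": label,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "p": p,
            "q": q,
        },
        index=matrix.values.index.rename("feature"),
    )
    crit = records["q"] if strict_fdr else records["p"]
    records["class"] = np.select(
        [
            (records["ratio"] > thresholds.up_threshold) & (crit < thresholds.alpha),
            (records["ratio"] < thresholds.down_threshold) & (crit < thresholds.alpha),
        ],
        ["up", "down"],
        default="unchanged",
    )
    return records


def all_contrasts(stages: list[str]) -> list[tuple[str, str]]:
    """Successive-stage contrasts plus the endpoints: for stages
    (D, PD, FPD) this yields PD/D, FPD/PD and FPD/D."""
    pairs = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) > 2:
        pairs.append((stages[0], stages[-1]))
    return pairs


def extreme_features(
    records: pd.DataFrame,
    extreme_fold: float = 5.0,
    require_alpha: bool = False,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one contrast's records into >fold up and <1/fold down lists.

    With ``require_alpha`` the raw p value must also fall below ``alpha``.
    Both lists are sorted by descending absolute log2 ratio.
    """
    if records["contrast"].nunique() > 1:
        raise DesignError("extreme_features expects records from a single contrast")
    keep = records["p"] < alpha if require_alpha else pd.Series(True, index=records.index)
    up = records[(records["ratio"] > extreme_fold) & keep]
    down = records[(records["ratio"] < 1.0 / extreme_fold) & keep]
    order = lambda df: df.reindex(df["log2_ratio"].abs().sort_values(ascending=False).index)
    return order(up), order(down)


def ora(
    selected: set[str],
    universe: set[str],
    annotation_sets: FeatureSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each set.

    Every annotation set is first intersected with the universe.  For a set
    of size K in a universe of size N with n features selected and k of them
    in the set, p = P(X ≥ k) for X ~ Hypergeom(N, K, n); q is BH-adjusted
    across sets.
    """
    if not universe:
        raise DesignError("empty universe")
    if not set(selected) <= set(universe):
        raise DesignError("selected features must be a subset of the universe")
    n_universe, n_selected = len(universe), len(selected)
    rows = []
    for name in annotation_sets:
        members = annotation_sets[name] & universe
        if not members:
            continue
        k = len(members & selected)
        expected = len(members) * n_selected / n_universe
        p = stats.hypergeom.sf(k - 1, n_universe, len(members), n_selected)
        rows.append((name, len(members), k, expected, p))
    result = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "expected", "p"]).set_index("set")
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        result["q"] = pd.Series(dtype=float)
    return result.sort_values("p")
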