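"""Readers, writers and in-memory containers for the pipeline's file formats.

The quantitative tables are plain TSV: a header row of sample ids and a first
column of feature ids.  Kinase–substrate maps and functional annotation sets
use the GMT convention (set name, free-text description, then tab-separated
members).  Phosphosite tables carry, per site, the parent protein, the
phosphorylated residue, its 1-based position and a 13-mer sequence window
centred on the residue (six flanking residues each side, terminal overhang
padded with ``_``).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

WINDOW_LENGTH = 13
WINDOW_FLANK = 6
PHOSPHO_RESIDUES = frozenset("STY")

__all__ = [
    "QuantMatrix",
    "PhosphoSite",
    "FeatureSetCollection",
    "read_design",
    "write_design",
    "read_quant_table",
    "write_quant_table",
    "read_gmt",
    "write_gmt",
    "read_site_table",
    "write_site_table",
    "read_edge_list",
    "write_edge_list",
    "make_window",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class QuantMatrix:
    """Feature × sample abundance table with its stage/replicate design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    design
        DataFrame indexed by sample id with columns ``stage`` and
        ``replicate``; every sample column of ``values`` must appear here.
    scale
        ``"linear"`` (strictly positive abundances) or ``"log2"``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate feature id(s): {', '.join(map(str, dupes[:5]))}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise DesignError(f"sample(s) missing from design: {', '.join(map(str, missing))}")
        if not {"stage", "replicate"}.issubset(self.design.columns):
            raise DesignError("design needs 'stage' and 'replicate' columns")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("abundance values must be numeric")
        if not np.isfinite(vals).all():
            raise FormatError("abundance values must be finite")
        if self.scale == "linear" and not (vals > 0).all():
            r, c = np.argwhere(~(vals > 0))[0]
            raise FormatError(
                f"non-positive abundance for feature {self.values.index[r]!r} "
                f"in sample {self.values.columns[c]!r} (linear scale requires values > 0)"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in design order, deduplicated."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.design.loc[s, "stage"], None)
        return list(seen)

    def samples_for_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.design.loc[s, "stage"] == stage]

    def log2(self) -> "QuantMatrix":
        """Return the matrix on log2 scale (no-op if already log2)."""
        if self.scale == "log2":
            return self
        return QuantMatrix(np.log2(self.values), self.design, scale="log2")

    def linear(self) -> "QuantMatrix":
        if self.scale == "linear":
            return self
        return QuantMatrix(2.0 ** self.values, self.design, scale="linear")

    def with_values(self, values: pd.DataFrame) -> "QuantMatrix":
        return QuantMatrix(values, self.design, scale=self.scale)


@dataclass(frozen=True)
class PhosphoSite:
    """One phosphorylated residue with its local sequence context."""

    site_id: str
    protein_id: str
    residue: str
    position: int  # 1-based index into the parent protein
    window: str  # 13-mer, centre = phosphorylated residue, '_'-padded

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise FormatError(
                f"site {self.site_id!r}: residue must be S, T or Y, got {self.residue!r}"
            )
        if self.position < 1:
            raise FormatError(f"site {self.site_id!r}: position must be ≥ 1")
        if len(self.window) != WINDOW_LENGTH:
            raise FormatError(
                f"site {self.site_id!r}: window must have length {WINDOW_LENGTH}, "
                f"got {len(self.window)}"
            )
        if self.window[WINDOW_FLANK] != self.residue:
            raise FormatError(
                f"site {self.site_id!r}: window centre {self.window[WINDOW_FLANK]!r} "
                f"does not match residue {self.residue!r}"
            )


class FeatureSetCollection(Mapping[str, frozenset]):
    """Named feature sets (kinase → substrate sites, term → proteins, ...)."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, frozenset] = {}
        for name, members in sets.items():
            if name in self._sets:
                raise FormatError(f"duplicate set name {name!r}")
            members = frozenset(members)
            if not members:
                raise FormatError(f"set {name!r} has no members")
            self._sets[name] = members
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def restricted_to(self, universe: Iterable[str], min_size: int = 1) -> "FeatureSetCollection":
        """Intersect every set with ``universe``; drop sets below ``min_size``."""
        universe = frozenset(universe)
        kept = {
            name: members & universe
            for name, members in self._sets.items()
            if len(members & universe) >= min_size
        }
        return FeatureSetCollection(kept, {k: self.descriptions.get(k, "") for k in kept})


# ---------------------------------------------------------------------------
# design tables


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design TSV with columns sample, stage, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "stage": str})
    for col in ("sample", "stage", "replicate"):
        if col not in df.columns:
            raise FormatError(f"design file {path}: missing column {col!r}")
    if df["sample"].duplicated().any():
        raise FormatError(f"design file {path}: duplicate sample ids")
    return df.set_index("sample")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quantification matrices


def read_quant_table(path: str | Path, design: pd.DataFrame, scale: str = "linear") -> QuantMatrix:
    """Parse a feature × sample TSV into a validated :class:`QuantMatrix`.

    The first column holds feature ids, the header row sample ids.  Row order
    is preserved.  Duplicate feature ids, non-numeric cells and samples absent
    from the design are reported with their coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise FormatError(f"{path}: duplicate feature id(s): {', '.join(dupes[:5])}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}")
    return QuantMatrix(numeric.astype(float), design, scale=scale)


def write_quant_table(matrix: QuantMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("feature").to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT feature sets


def read_gmt(path: str | Path) -> FeatureSetCollection:
    """Read a GMT file: per line, set name, description, then members.

    Duplicate members within a line are collapsed; member order is not
    significant.  Lines with fewer than three fields are rejected with their
    line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs ≥3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return FeatureSetCollection(sets, descriptions)


def write_gmt(collection: FeatureSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# phosphosite tables


def make_window(sequence: str, position: int) -> str:
    """Cut the 13-mer window centred on 1-based ``position`` of ``sequence``.

    Overhang beyond either protein terminus is padded with ``_`` so the
    phosphorylated residue always sits at offset 0 (string index 6).
    """
    i = position - 1
    if not 0 <= i < len(sequence):
        raise FormatError(f"position {position} outside sequence of length {len(sequence)}")
    left = sequence[max(0, i - WINDOW_FLANK) : i]
    right = sequence[i + 1 : i + 1 + WINDOW_FLANK]
    return "_" * (WINDOW_FLANK - len(left)) + left + sequence[i] + right + "_" * (WINDOW_FLANK - len(right))


SITE_COLUMNS = ["site", "protein", "residue", "position", "window"]


def read_site_table(path: str | Path) -> list[PhosphoSite]:
    """Read a phosphosite TSV (site, protein, residue, position, window)."""
    df = pd.read_csv(path, sep="\t", dtype={"site": str, "protein": str, "residue": str, "window": str})
    for col in SITE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sites = [
        PhosphoSite(row.site, row.protein, row.residue, int(row.position), row.window)
        for row in df.itertuples(index=False)
    ]
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate site ids")
    return sites


def write_site_table(sites: Iterable[PhosphoSite], path: str | Path) -> None:
    rows = [(s.site_id, s.protein_id, s.residue, s.position, s.window) for s in sites]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PPI edge lists


EDGE_COLUMNS = ["node_a", "node_b", "confidence"]


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an undirected PPI edge list TSV (node_a, node_b, confidence)."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    if conf.isna().any() or (conf < 0).any() or (conf > 1).any():
        raise FormatError(f"{path}: confidence scores must be numeric and in [0, 1]")
    df = df.assign(confidence=conf.astype(float))
    if (df["node_a"] == df["node_b"]).any():
        raise FormatError(f"{path}: self-loop edge present")
    key = df.apply(lambda r: tuple(sorted((r.node_a, r.node_b))), axis=1)
    if key.duplicated().any():
        raise FormatError(f"{path}: duplicate undirected edge present")
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
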