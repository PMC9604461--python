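"""Bundled example data.

Two small curated tables from a published TMT proteome/phosphoproteome
study of *Bombus terrestris* queen diapause (stages D → PD → FPD): the
proteins and the phosphosites reported as candidate >5-fold changers in the
PD/D and FPD/PD contrasts, with their printed ratios and p values.  They
serve as real-data fixtures for the extreme-fold filtering logic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_extreme_deps", "load_extreme_depps", "as_comparison_records"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("diaphos.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_extreme_deps() -> pd.DataFrame:
    """Candidate >5-fold differentially expressed proteins (both contrasts)."""
    return _load("bterrestris_extreme_deps.tsv")


def load_extreme_depps() -> pd.DataFrame:
    """Candidate >5-fold differentially phosphorylated sites (both contrasts)."""
    return _load("bterrestris_extreme_depps.tsv")


def as_comparison_records(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Reshape one contrast of a bundled table into comparison-record form.

    The result has the columns :func:`diaphos.differential.extreme_features`
    expects (contrast, ratio, log2_ratio, p) indexed by a unique feature id.
    """
    rows = table[table["group"] == group].copy()
    if "position" in rows.columns:
        feature = rows["accession"] + "_" + rows["residue"] + rows["position"].astype(str)
    else:
        feature = rows["accession"]
    rows.index = pd.Index(feature, name="feature")
    return pd.DataFrame(
        {
            "contrast": group,
            "ratio": rows["ratio"].astype(float),
            "log2_ratio": np.log2(rows["ratio"].astype(float)),
            "p": rows["p"].astype(float),
        }
    )
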