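"""Two-level normalization of quantitative phosphoproteomics data.

Abundance tables are first brought onto a common total (each sample column is
rescaled so its sum equals the mean column sum), which removes loading and
labelling differences between samples.  Phosphosite abundances are then
divided, per sample, by the abundance of the parent protein, so that a change
in site stoichiometry can be separated from a change in protein amount.
Sites whose parent protein was not quantified pass through unchanged and are
counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError
from .io import PhosphoSite, QuantMatrix

__all__ = ["NormalizationReport", "total_normalize", "protein_normalize"]


@dataclass(frozen=True)
class NormalizationReport:
    scale_factors: pd.Series  # per-sample multiplier applied by total_normalize
    n_adjusted: int  # sites divided by their parent protein
    n_unadjusted: int  # sites whose parent was not quantified

    @property
    def n_sites(self) -> int:
        return self.n_adjusted + self.n_unadjusted


def total_normalize(matrix: QuantMatrix) -> tuple[QuantMatrix, pd.Series]:
    """Scale each sample column so all column sums equal the mean column sum.

    Returns the normalized matrix together with the per-sample scale factors.
    The transformation preserves within-column structure and is idempotent;
    multiplying any input column by a constant leaves the output unchanged.
    """
    if matrix.scale != "linear":
        raise FormatError("total_normalize expects a linear-scale matrix")
    sums = matrix.values.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise FormatError(f"sample {bad!r} has non-positive column sum")
    target = sums.mean()
    factors = target / sums
    return matrix.with_values(matrix.values * factors), factors


def protein_normalize(
    phospho: QuantMatrix,
    protein: QuantMatrix,
    sites: list[PhosphoSite],
) -> tuple[QuantMatrix, NormalizationReport]:
    """Divide each phosphosite by its parent protein's abundance, per sample.

    Both matrices must be on linear scale and share the same sample set.
    Sites without a quantified parent are passed through unadjusted; the
    report records how many sites fell in each class.
    """
    if phospho.scale != "linear" or protein.scale != "linear":
        raise FormatError("protein_normalize expects linear-scale matrices")
    if set(phospho.sample_ids) != set(protein.sample_ids):
        raise DesignError("phospho and protein matrices have different sample sets")

    parent = {s.site_id: s.protein_id for s in sites}
    missing = [f for f in phospho.feature_ids if f not in parent]
    if missing:
        raise FormatError(f"phospho feature(s) absent from site table: {missing[:5]}")

    prot = protein.values[phospho.sample_ids]
    parents = pd.Series({f: parent[f] for f in phospho.feature_ids})
    has_parent = parents.isin(prot.index)
    out = phospho.values.copy()
    if has_parent.any():
        divisor = prot.loc[parents[has_parent].to_numpy()]
        divisor.index = parents[has_parent].index
        out.loc[has_parent] = phospho.values.loc[has_parent] / divisor
    report = NormalizationReport(
        scale_factors=pd.Series(np.ones(len(phospho.sample_ids)), index=phospho.sample_ids),
        n_adjusted=int(has_parent.sum()),
        n_unadjusted=int((~has_parent).sum()),
    )
    return phospho.with_values(out), report
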