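"""Soft trajectory clustering of stage expression profiles.

Features are reduced to per-stage means of log2 abundance, filtered on the
standard deviation of that profile (low-SD features carry no trajectory
signal), z-scored across stages, and clustered with fuzzy c-means: each
feature receives a graded membership in every cluster, controlled by the
fuzzifier ``m`` (m → 1 approaches hard k-means, larger m softens the
partition).  The defaults — six clusters, m = 2, SD filter 0.4 — suit a
three-stage design whose features follow a small set of monotone or
single-step trajectory archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyProfileError, FormatError
from .io import QuantMatrix

__all__ = ["ProfileSet", "ClusterModel", "prepare_profiles", "fuzzy_cmeans", "assign_clusters"]


@dataclass(frozen=True)
class ProfileSet:
    """Standardized per-stage profiles of the features that survived the SD filter."""

    profiles: pd.DataFrame  # features × stages, z-scored across stages
    min_sd: float  # SD threshold applied before standardization
    raw_sd: pd.Series  # pre-standardization SD of the retained features


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model."""

    centers: pd.DataFrame  # clusters × stages
    memberships: pd.DataFrame  # features × clusters, rows sum to 1
    m: float
    n_iter: int
    objective: list[float] = field(default_factory=list)  # per-iteration Σ u^m d²

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def prepare_profiles(matrix: QuantMatrix, min_sd: float = 0.4) -> ProfileSet:
    """Stage-mean log2 profiles, SD-filtered and z-scored across stages.

    The SD is the sample standard deviation (ddof=1) of the per-stage log2
    means; features with SD ≤ ``min_sd`` are removed.  Survivors are
    standardized so each profile has mean 0 and SD 1 across stages.
    """
    stages = matrix.stages
    if len(stages) < 2:
        raise ConfigError("need at least two stages")
    log = matrix.log2().values
    means = pd.DataFrame(
        {stage: log[matrix.samples_for_stage(stage)].mean(axis=1) for stage in stages}
    )
    sd = means.std(axis=1, ddof=1)
    keep = sd > min_sd
    if not keep.any():
        raise EmptyProfileError(f"no feature has profile SD > {min_sd}")
    means = means[keep]
    z = means.sub(means.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ProfileSet(profiles=z, min_sd=min_sd, raw_sd=sd[keep])


def fuzzy_cmeans(
    profiles: ProfileSet | pd.DataFrame,
    c: int = 6,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterModel:
    """Fuzzy c-means with Euclidean distance.

    Alternates the two closed-form updates until the largest membership
    change falls below ``tol``:

    - centers: v_j = Σ_i u_ij^m x_i / Σ_i u_ij^m
    - memberships: u_ij = 1 / Σ_k (d_ij / d_ik)^(2/(m−1))

    A feature exactly on a center gets membership 1 for that center (lowest
    index on ties).  The objective Σ u_ij^m d_ij² is recorded per iteration
    and is non-increasing.  Initial memberships are drawn from a symmetric
    Dirichlet with the given seed, so the fit is reproducible.
    """
    x = profiles.profiles if isinstance(profiles, ProfileSet) else profiles
    if c < 2:
        raise ConfigError("need at least two clusters")
    if m <= 1.0:
        raise ConfigError("fuzzifier m must exceed 1")
    data = x.to_numpy(float)
    n = len(data)
    if n < c:
        raise ConfigError(f"cannot fit {c} clusters to {n} profiles")
    if len(np.unique(data, axis=0)) < c:
        raise ConfigError(f"need at least {c} distinct profiles")

    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)
    exponent = 2.0 / (m - 1.0)
    objective: list[float] = []
    for iteration in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ data) / um.sum(axis=0)[:, None]
        # squared Euclidean distances features × clusters
        d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_u = np.zeros_like(u)
        zero = d2 <= 1e-300
        on_center = zero.any(axis=1)
        if on_center.any():
            first = zero[on_center].argmax(axis=1)
            new_u[np.flatnonzero(on_center), first] = 1.0
        rest = ~on_center
        if rest.any():
            inv = d2[rest] ** (-exponent / 2.0) if exponent != 2.0 else 1.0 / d2[rest]
            new_u[rest] = inv / inv.sum(axis=1, keepdims=True)
        objective.append(float((new_u**m * d2).sum()))
        shift = np.abs(new_u - u).max()
        u = new_u
        if shift < tol:
            break
    stage_names = list(x.columns)
    return ClusterModel(
        centers=pd.DataFrame(centers, index=range(1, c + 1), columns=stage_names),
        memberships=pd.DataFrame(u, index=x.index, columns=range(1, c + 1)),
        m=m,
        n_iter=iteration,
        objective=objective,
    )


def assign_clusters(model: ClusterModel, min_membership: float = 0.5) -> pd.Series:
    """Hard assignment: argmax membership if it reaches ``min_membership``.

    Features below the threshold get the sentinel 0 ("unassigned"); ties go
    to the lowest cluster index.
    """
    u = model.memberships
    best = u.idxmax(axis=1)  # idxmax takes the first (lowest) label on ties
    top = u.max(axis=1)
    assigned = best.where(top >= min_membership, other=0)
    if min_membership <= 0:
        assigned = best
    return assigned.astype(int).rename("cluster")
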