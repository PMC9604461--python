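"""Kinase activity inference from substrate phosphorylation changes (KSEA).

Phosphosites are ranked by their contrast log2 ratio and each kinase's
substrate set is scored with the weighted Kolmogorov–Smirnov running-sum
statistic familiar from gene-set enrichment analysis: walking down the
ranked list, hits increment the sum by |metric|^p normalised over the hits,
misses decrement by 1/(N − N_hits), and the enrichment score (ES) is the
signed extremum.  Because three replicates preclude sample permutation, the
null is built from random same-size site sets; the normalised score (NES)
divides ES by the mean magnitude of same-sign null scores, and the
permutation p value counts same-sign nulls at least as extreme.  The NES is
read as a kinase activity score: positive when the predominant substrate
change is increased phosphorylation, negative otherwise.  Kinases passing
the significance filter and their differential substrate sites form the
kinase–substrate regulatory network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .io import FeatureSetCollection

__all__ = [
    "SiteRanking",
    "KinaseActivity",
    "build_site_ranks",
    "enrichment_score",
    "kinase_activity_scores",
    "build_ks_network",
]


@dataclass(frozen=True)
class SiteRanking:
    """Sites ordered by a contrast metric, largest first."""

    contrast: str
    site_ids: tuple[str, ...]
    metrics: np.ndarray  # aligned with site_ids, descending

    def __post_init__(self) -> None:
        if len(self.site_ids) != len(self.metrics):
            raise ConfigError("site ids and metrics differ in length")
        if not np.isfinite(self.metrics).all():
            raise ConfigError("rank metrics must be finite")

    def __len__(self) -> int:
        return len(self.site_ids)


@dataclass(frozen=True)
class KinaseActivity:
    kinase: str
    es: float
    nes: float
    p: float
    sign: int  # +1 activated, −1 inhibited
    n_substrates: int
    substrates: tuple[str, ...]


def build_site_ranks(records: pd.DataFrame, contrast: str | None = None) -> SiteRanking:
    """Rank sites by log2 ratio, descending; ties break on site id.

    ``records`` is a ``compare_groups`` result for one contrast (optionally
    checked against ``contrast``).
    """
    if records.empty:
        raise DesignError("cannot rank an empty contrast")
    labels = records["contrast"].unique()
    if len(labels) > 1:
        raise DesignError("records span multiple contrasts")
    if contrast is not None and labels[0] != contrast:
        raise DesignError(f"records are for contrast {labels[0]!r}, expected {contrast!r}")
    if records.index.has_duplicates:
        dupes = records.index[records.index.duplicated()].unique()
        raise DesignError(f"duplicate site(s) in contrast: {list(dupes[:5])}")
    # two-key sort: metric descending, then id ascending (deterministic ties)
    metric = records["log2_ratio"].to_numpy(float)
    ids = records.index.to_numpy(object)
    order = sorted(range(len(records)), key=lambda i: (-metric[i], str(ids[i])))
    ordered = records.iloc[order]
    return SiteRanking(
        contrast=str(labels[0]),
        site_ids=tuple(ordered.index),
        metrics=ordered["log2_ratio"].to_numpy(float),
    )


def _es_from_positions(abs_metric: np.ndarray, positions: np.ndarray) -> float:
    """ES for hit ``positions`` (sorted, 0-based) in a list of N sites.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit, immediately before a hit, or at the ends.
    """
    n = len(abs_metric)
    nh = len(positions)
    if nh == 0 or nh > n:
        raise ConfigError("hit set must be non-empty and no larger than the ranking")
    weights = abs_metric[positions]
    total = weights.sum()
    if total <= 0:  # all-zero metrics degenerate to unweighted steps
        weights = np.ones(nh)
        total = float(nh)
    gain = np.cumsum(weights) / total
    if nh == n:  # no misses: the sum climbs monotonically to 1
        return 1.0
    miss_step = 1.0 / (n - nh)
    misses_before = positions - np.arange(nh)  # misses strictly before each hit
    after = gain - misses_before * miss_step
    before = np.concatenate(([0.0], gain[:-1])) - misses_before * miss_step
    top, bottom = after.max(), before.min()
    return float(top if top >= -bottom else bottom)


def enrichment_score(
    ranking: SiteRanking,
    substrate_set: set[str],
    weight: float = 1.0,
) -> tuple[float, int]:
    """Weighted KS enrichment score of a substrate set in the ranking.

    Returns the ES together with the 0-based position where the running sum
    attains its signed extremum.
    """
    index = {s: i for i, s in enumerate(ranking.site_ids)}
    positions = np.array(sorted(index[s] for s in substrate_set if s in index))
    if len(positions) == 0:
        raise ConfigError("substrate set is disjoint from the ranking")
    abs_metric = np.abs(ranking.metrics) ** weight
    es = _es_from_positions(abs_metric, positions)
    # locate the extremum by a full pass (cheap, done once per reported set)
    n = len(ranking)
    running = np.full(n, -1.0 / (n - len(positions)) if n > len(positions) else 0.0)
    weights = abs_metric[positions]
    total = weights.sum()
    running[positions] = (weights / total) if total > 0 else 1.0 / len(positions)
    cumulative = np.cumsum(running)
    argmax = int(np.argmax(np.abs(cumulative)))
    return es, argmax


def kinase_activity_scores(
    ranking: SiteRanking,
    kinase_sets: FeatureSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 3,
    weight: float = 1.0,
) -> list[KinaseActivity]:
    """Score every kinase set against the ranking with a permutation null.

    The null draws ``n_perm`` random site sets of the same size (seeded).
    NES = ES / mean(|null ES| of the same sign); p = (1 + #same-sign nulls
    as or more extreme) / (1 + #same-sign nulls).  Sets smaller than
    ``min_set_size`` after restriction to the ranking are skipped.
    """
    if n_perm < 100:
        raise ConfigError("need at least 100 permutations")
    n = len(ranking)
    abs_metric = np.abs(ranking.metrics) ** weight
    site_index = {s: i for i, s in enumerate(ranking.site_ids)}
    rng = np.random.default_rng(seed)
    results: list[KinaseActivity] = []
    null_cache: dict[int, np.ndarray] = {}
    for kinase in kinase_sets:
        members = sorted(m for m in kinase_sets[kinase] if m in site_index)
        if len(members) < min_set_size:
            if not members:
                warnings.warn(f"kinase {kinase!r}: substrate set disjoint from ranking; skipped")
            continue
        positions = np.array(sorted(site_index[m] for m in members))
        es = _es_from_positions(abs_metric, positions)
        size = len(positions)
        if size not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                perm = np.sort(rng.choice(n, size=size, replace=False))
                null[i] = _es_from_positions(abs_metric, perm)
            null_cache[size] = null
        null = null_cache[size]
        same_sign = null * np.sign(es) > 0
        n_same = int(same_sign.sum())
        denom = np.abs(null[same_sign]).mean() if n_same else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_same)
        results.append(
            KinaseActivity(
                kinase=kinase,
                es=float(es),
                nes=float(nes),
                p=float(p),
                sign=int(np.sign(nes)) or 1,
                n_substrates=size,
                substrates=tuple(members),
            )
        )
    if not results and len(kinase_sets):
        warnings.warn("no kinase set reached min_set_size; empty result")
    return results


def activities_frame(activities: list[KinaseActivity]) -> pd.DataFrame:
    """Tabular view of :func:`kinase_activity_scores` output."""
    return pd.DataFrame(
        [
            {
                "kinase": a.kinase,
                "es": a.es,
                "nes": a.nes,
                "p": a.p,
                "sign": a.sign,
                "n_substrates": a.n_substrates,
            }
            for a in activities
        ]
    ).set_index("kinase") if activities else pd.DataFrame(
        columns=["es", "nes", "p", "sign", "n_substrates"]
    )


def build_ks_network(
    activities: list[KinaseActivity],
    records: pd.DataFrame,
    alpha: float = 0.05,
) -> "nx.DiGraph":
    """Directed kinase→site network of significant kinases and regulated sites.

    Kinases with permutation p ≥ ``alpha`` are dropped; edges only reach
    sites classed up or down in the contrast.  Node attributes carry the
    kinase activation state ("activated"/"inhibited") and the site
    regulation class; edges carry both.
    """
    import networkx as nx

    graph = nx.DiGraph()
    site_class = records["class"]
    for activity in activities:
        if activity.p >= alpha:
            continue
        state = "activated" if activity.sign > 0 else "inhibited"
        edges = [
            (s, site_class.loc[s])
            for s in activity.substrates
            if s in site_class.index and site_class.loc[s] in ("up", "down")
        ]
        if not edges:
            continue
        graph.add_node(activity.kinase, kind="kinase", state=state, nes=activity.nes, p=activity.p)
        for site, cls in edges:
            graph.add_node(site, kind="site", regulation=cls)
            graph.add_edge(activity.kinase, site, kinase_state=state, site_regulation=cls)
    return graph
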