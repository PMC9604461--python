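import numpy as np
import pandas as pd
import pytest

from diaphos.errors import ConfigError, DesignError
from diaphos.io import FeatureSetCollection
from diaphos.kinase import (
    KinaseActivity,
    build_ks_network,
    build_site_ranks,
    enrichment_score,
    kinase_activity_scores,
)


def brute_force_es(metrics: np.ndarray, hits: set[int], weight: float = 1.0) -> float:
    """Independent oracle: walk the full running sum and take the signed extremum."""
    n = len(metrics)
    hit_weights = np.abs(metrics) ** weight
    total = sum(hit_weights[i] for i in hits)
    n_miss = n - len(hits)
    running, best = 0.0, 0.0
    for i in range(n):
        if i in hits:
            running += hit_weights[i] / total if total > 0 else 1.0 / len(hits)
        else:
            running -= 1.0 / n_miss
        # signed extremum; an exact |max| == |min| tie resolves to the
        # positive deviation, matching the documented convention
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def _records(ratios, ids=None, contrast="PD/D", classes=None, p=0.01):
    ids = ids or [f"s{i}" for i in range(len(ratios))]
    frame = pd.DataFrame(
        {
            "contrast": contrast,
            "ratio": ratios,
            "log2_ratio": np.log2(ratios),
            "p": p,
            "class": classes if classes is not None else "unchanged",
        },
        index=pd.Index(ids, name="feature"),
    )
    return frame


class TestSiteRanks:
    def test_log2_metrics_descending(self):
        ranking = build_site_ranks(_records([4.0, 1.0, 0.25]))
        assert list(ranking.site_ids) == ["s0", "s1", "s2"]
        assert np.allclose(ranking.metrics, [2.0, 0.0, -2.0])

    def test_ties_break_on_id(self):
        ranking = build_site_ranks(_records([2.0, 2.0], ids=["zeta", "alpha"]))
        assert list(ranking.site_ids) == ["alpha", "zeta"]

    def test_empty_contrast_rejected(self):
        with pytest.raises(DesignError):
            build_site_ranks(_records([]))

    def test_duplicate_site_rejected(self):
        with pytest.raises(DesignError):
            build_site_ranks(_records([2.0, 3.0], ids=["a", "a"]))


class TestEnrichmentScore:
    def test_single_member_at_top_is_one(self):
        ranking = build_site_ranks(_records([8.0, 2.0, 1.0, 0.5]))
        es, _ = enrichment_score(ranking, {"s0"})
        assert es == pytest.approx(1.0)

    def test_single_member_at_bottom_equal_metrics(self):
        # all-equal |metric|: the sum drifts to −(N−1)/(N−1) just before the hit
        records = _records([2.0] * 5 + [0.5], ids=[f"s{i}" for i in range(6)])
        ranking = build_site_ranks(records)
        es, _ = enrichment_score(ranking, {"s5"})
        oracle = brute_force_es(ranking.metrics, {5})
        assert es == pytest.approx(oracle)
        assert es == pytest.approx(-1.0)

    def test_full_set_is_one(self):
        ranking = build_site_ranks(_records([4.0, 2.0, 0.5]))
        es, _ = enrichment_score(ranking, {"s0", "s1", "s2"})
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_lists(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        ratios = 2.0 ** rng.normal(0, 1, n)
        ranking = build_site_ranks(_records(list(ratios), ids=[f"s{i:02d}" for i in range(n)]))
        size = int(rng.integers(1, n))
        hit_ids = set(rng.choice(ranking.site_ids, size, replace=False))
        hits = {i for i, s in enumerate(ranking.site_ids) if s in hit_ids}
        es, _ = enrichment_score(ranking, hit_ids)
        assert es == pytest.approx(brute_force_es(ranking.metrics, hits), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_and_antisymmetric_under_reversal(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 30
        ratios = 2.0 ** rng.normal(0, 1, n)
        ids = [f"s{i:02d}" for i in range(n)]
        fwd = build_site_ranks(_records(list(ratios), ids=ids))
        rev = build_site_ranks(_records(list(1.0 / np.array(ratios)), ids=ids))
        hit_ids = set(rng.choice(ids, 7, replace=False))
        es_fwd, _ = enrichment_score(fwd, hit_ids)
        es_rev, _ = enrichment_score(rev, hit_ids)
        assert -1.0 <= es_fwd <= 1.0
        assert es_rev == pytest.approx(-es_fwd, abs=1e-9)

    def test_disjoint_set_rejected(self):
        ranking = build_site_ranks(_records([2.0, 0.5]))
        with pytest.raises(ConfigError):
            enrichment_score(ranking, {"absent"})


class TestActivityScores:
    def _ranking(self, rng, n=120):
        ratios = 2.0 ** rng.normal(0, 1, n)
        return build_site_ranks(_records(list(ratios), ids=[f"s{i:03d}" for i in range(n)]))

    def test_top_heavy_regulon_is_positive_and_significant(self, rng):
        ranking = self._ranking(rng)
        top = set(ranking.site_ids[:5])  # top 4% of ranks
        sets = FeatureSetCollection({"K": top})
        (activity,) = kinase_activity_scores(ranking, sets, n_perm=1000, seed=1)
        assert activity.nes > 0
        assert activity.sign == 1
        assert activity.p <= 0.01

    def test_same_seed_reproducible(self, rng):
        ranking = self._ranking(rng)
        sets = FeatureSetCollection({"K": set(ranking.site_ids[10:18])})
        a1 = kinase_activity_scores(ranking, sets, n_perm=200, seed=5)
        a2 = kinase_activity_scores(ranking, sets, n_perm=200, seed=5)
        assert a1 == a2

    def test_p_invariant_to_metric_rescaling(self, rng):
        ratios = 2.0 ** rng.normal(0, 1, 60)
        ids = [f"s{i:02d}" for i in range(60)]
        r1 = build_site_ranks(_records(list(ratios), ids=ids))
        r2 = build_site_ranks(_records(list(ratios**3.0), ids=ids))  # ×3 on log2 scale
        sets = FeatureSetCollection({"K": set(ids[:6])})
        (a1,) = kinase_activity_scores(r1, sets, n_perm=300, seed=2)
        (a2,) = kinase_activity_scores(r2, sets, n_perm=300, seed=2)
        assert a1.p == a2.p

    def test_small_sets_skipped_with_warning(self, rng):
        ranking = self._ranking(rng)
        sets = FeatureSetCollection({"K": set(ranking.site_ids[:2])})
        with pytest.warns(UserWarning, match="min_set_size"):
            result = kinase_activity_scores(ranking, sets, n_perm=100, seed=0, min_set_size=3)
        assert result == []

    def test_too_few_permutations_rejected(self, rng):
        ranking = self._ranking(rng)
        with pytest.raises(ConfigError):
            kinase_activity_scores(
                ranking, FeatureSetCollection({"K": set(ranking.site_ids[:5])}), n_perm=10
            )


class TestKsNetwork:
    def _activity(self, kinase, p, sign, substrates):
        return KinaseActivity(
            kinase=kinase, es=0.8 * sign, nes=2.0 * sign, p=p, sign=sign,
            n_substrates=len(substrates), substrates=tuple(substrates),
        )

    def test_insignificant_kinase_excluded(self):
        records = _records([4.0, 0.2], classes=["up", "down"])
        graph = build_ks_network([self._activity("K1", 0.2, 1, ["s0"])], records)
        assert graph.number_of_nodes() == 0

    def test_edges_only_to_regulated_sites(self):
        records = _records([4.0, 1.0, 0.2, 3.0], classes=["up", "unchanged", "down", "up"])
        activity = self._activity("K1", 0.001, 1, ["s0", "s1", "s2"])
        graph = build_ks_network([activity], records)
        assert set(graph.successors("K1")) == {"s0", "s2"}
        assert graph.nodes["K1"]["state"] == "activated"
        assert graph.nodes["s2"]["regulation"] == "down"

    def test_inhibited_kinase_state(self):
        records = _records([0.2], classes=["down"])
        graph = build_ks_network([self._activity("K1", 0.001, -1, ["s0"])], records)
        assert graph.nodes["K1"]["state"] == "inhibited"
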