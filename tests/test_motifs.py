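import math
from fractions import Fraction

import numpy as np
import pytest

from diaphos.errors import FormatError
from diaphos.io import PhosphoSite, make_window
from diaphos.motifs import (
    AMINO_ACIDS,
    MotifPattern,
    binomial_tail,
    extract_windows,
    motif_x,
    position_heatmap,
)
from diaphos.synthetic import BACKGROUND_AA_FREQ, SimulationConfig, generate_dataset


def exact_binomial_tail(k: int, n: int, q: float) -> float:
    """Independent oracle: P(X ≥ k) by exact summation with rational binomials."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        total += float(Fraction(math.comb(n, i))) * (q**i) * ((1 - q) ** (n - i))
    return total


def _window_with(residues: dict[int, str], central: str = "S") -> str:
    cells = ["A"] * 13
    cells[6] = central
    for offset, aa in residues.items():
        cells[offset + 6] = aa
    return "".join(cells)


class TestPattern:
    def test_render_matches_convention(self):
        pattern = MotifPattern("S", ((1, "D"), (3, "E")))
        assert pattern.render() == "xxxxxx_S_DxExxx"

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(FormatError):
            MotifPattern("S", ((1, "D"), (1, "E")))

    def test_matching(self):
        pattern = MotifPattern("S", ((1, "D"),))
        assert pattern.matches(_window_with({1: "D"}))
        assert not pattern.matches(_window_with({1: "E"}))


class TestExtractWindows:
    def _sites(self):
        return [
            PhosphoSite("a", "P1", "S", 7, _window_with({1: "D"})),
            PhosphoSite("b", "P1", "S", 9, _window_with({2: "E"})),
            PhosphoSite("c", "P2", "Y", 7, _window_with({}, central="Y")),
        ]

    def test_all_regulated_equals_background(self):
        pairs = extract_windows(self._sites(), {"a", "b", "c"})
        assert pairs["S"][0] == pairs["S"][1]
        assert pairs["Y"][0] == pairs["Y"][1]

    def test_single_regulated_site(self):
        pairs = extract_windows(self._sites(), {"a"})
        assert len(pairs["S"][0]) == 1 and len(pairs["S"][1]) == 2
        assert "Y" not in pairs  # no regulated Y site → no Y class

    def test_central_split_is_partition(self):
        pairs = extract_windows(self._sites(), {"a", "c"})
        assert set(pairs) == {"S", "Y"}

    def test_pooled_central(self):
        pairs = extract_windows(self._sites(), {"a", "c"}, split_central=False)
        assert len(pairs["STY"][1]) == 3

    def test_unknown_regulated_id_rejected(self):
        with pytest.raises(FormatError):
            extract_windows(self._sites(), {"nope"})


class TestBinomialOracle:
    @pytest.mark.parametrize(
        "k,n,q",
        [(3, 10, 0.2), (0, 10, 0.2), (10, 10, 0.05), (25, 100, 0.1), (1, 1, 0.5), (60, 80, 0.7)],
    )
    def test_matches_exact_tail(self, k, n, q):
        expected = exact_binomial_tail(k, n, q)
        assert binomial_tail(k, n, q) == pytest.approx(expected, rel=1e-12)


class TestMotifX:
    def test_forced_first_step_exact_p(self):
        """All 100 foreground windows carry D at +1 while the background
        frequency is exactly 5% → the step p value is 0.05^100."""
        fg = [_window_with({1: "D"}) for _ in range(100)]
        bg = [_window_with({1: "D"}) for _ in range(5)] + [
            _window_with({1: "A"}) for _ in range(95)
        ]
        results = motif_x(fg, bg, central="S", p_cutoff=1e-6, min_occurrences=20)
        assert results
        first = results[0]
        assert first.pattern.constraints[0] == (1, "D")
        assert first.step_p_values[0] == pytest.approx(0.05**100, rel=1e-9)

    def test_null_foreground_yields_no_motif(self, rng):
        aa = np.array(list(BACKGROUND_AA_FREQ))
        probs = np.array(list(BACKGROUND_AA_FREQ.values()))
        probs = probs / probs.sum()
        empty = 0
        for _ in range(10):
            bg = ["".join(w[:6]) + "S" + "".join(w[6:]) for w in
                  (rng.choice(aa, 12, p=probs) for _ in range(400))]
            fg = list(rng.choice(bg, 80, replace=False))
            if not motif_x(fg, bg, central="S", p_cutoff=1e-6, min_occurrences=20):
                empty += 1
        assert empty >= 9

    def test_planted_motif_recovered_from_ground_truth(self):
        config = SimulationConfig(
            seed=13, n_proteins=400, n_kinases=4, regulon_size=15,
            kinase_stages=(1,), kinase_signs=(1,),
        )
        data = generate_dataset(config)
        regulated = {
            s for info in data.truth.kinase_truth.values() for s in info["substrates"]
        }
        fg, bg = extract_windows(data.sites, regulated)["S"]
        results = motif_x(fg, bg, central="S")
        assert results
        assert set(results[0].pattern.constraints) == set(config.motif_spec)

    def test_score_is_sum_of_step_scores(self):
        fg = [_window_with({1: "D", 3: "E"}) for _ in range(50)]
        bg = fg + [_window_with({}) for _ in range(450)]
        results = motif_x(fg, bg, central="S", min_occurrences=10)
        for res in results:
            assert res.motif_score == pytest.approx(
                sum(-math.log10(p) for p in res.step_p_values)
            )
            assert all(p < 1e-6 for p in res.step_p_values)

    def test_fold_change_uses_original_sizes(self):
        fg = [_window_with({1: "D"}) for _ in range(30)] + [_window_with({}) for _ in range(30)]
        bg = fg + [_window_with({}) for _ in range(240)]
        results = motif_x(fg, bg, central="S", min_occurrences=10)
        assert results
        res = results[0]
        assert res.fold_change == pytest.approx(
            (res.fg_matches / 60) / (res.bg_matches / 300)
        )


class TestPositionHeatmap:
    def test_identity_when_fg_equals_bg(self):
        windows = [_window_with({1: "D"}), _window_with({2: "E"})]
        heat, _ = position_heatmap(windows, windows)
        assert np.allclose(heat.to_numpy(), 0.0)

    def test_depletion_is_negative_and_finite(self):
        fg = [_window_with({1: "A"}) for _ in range(30)]
        bg = [_window_with({1: "W"}) for _ in range(30)]
        heat, _ = position_heatmap(fg, bg)
        assert heat.loc["W", 1] < 0
        assert np.isfinite(heat.to_numpy()).all()

    def test_planted_enrichment_is_positive_and_significant(self):
        fg = [_window_with({1: "D"}) for _ in range(100)]
        bg = fg + [_window_with({1: "A"}) for _ in range(900)]
        heat, significant = position_heatmap(fg, bg)
        assert heat.loc["D", 1] > 0
        assert significant.loc["D", 1]
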