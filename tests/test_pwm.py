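"""Motif model: construction invariants, exact p-values, significant positions."""

import numpy as np
import pytest

from conftest import enumerate_score_distribution, random_toy_pwm
from prmpred import (
    build_pwm,
    position_information_content,
    pvalue_of_score,
    score_distribution,
    score_window,
    significant_positions,
    threshold_for_pvalue,
)
from prmpred.errors import (
    AlphabetError,
    EmptySignificantSet,
    InsufficientData,
    LengthMismatch,
    UnattainableThreshold,
)
from prmpred.pwm import LOG_ODDS_FLOOR, proteome_background, pwm_from_text, pwm_to_text


class TestBuildPwm:
    def test_single_letter_column_uniform_background(self):
        pwm = build_pwm(["PP", "PP"], "uniform", pseudocount=0.0)
        p = pwm.row("P")
        assert pwm.weights[p, 0] == pytest.approx(np.log2(20))
        assert pwm.weights[p, 1] == pytest.approx(np.log2(20))
        others = np.delete(pwm.weights, p, axis=0)
        assert np.all(others == LOG_ODDS_FLOOR)

    def test_background_matching_column_has_zero_weights(self):
        # every residue equally frequent -> frequencies equal the uniform
        # background -> all log-odds zero
        pwm = build_pwm(["A", "B", "C"], "uniform", pseudocount=0.0, alphabet="ABC")
        assert np.allclose(pwm.weights, 0.0)

    def test_hand_computed_toy_table(self, toy_pwm):
        # counts: col0 A=3,B=1,C=0; col1 B=2,C=2; plus pseudocount 1/cell
        raw = np.array([[3, 0], [1, 2], [0, 2]], dtype=float)
        expected_counts = raw + 1.0
        assert np.allclose(toy_pwm.counts, expected_counts)
        colsum = 4 + 3 * 1.0
        expected_weights = np.log2((expected_counts / colsum) / (1 / 3))
        assert np.allclose(toy_pwm.weights, expected_weights)

    def test_column_sums_and_background_invariants(self, toy_pwm):
        assert np.allclose(toy_pwm.counts.sum(axis=0), 4 + 3 * 1.0)
        assert toy_pwm.background.sum() == pytest.approx(1.0)

    def test_scaling_invariance_of_weights(self):
        peps = ["AB", "AC", "BC", "AB"]
        pwm1 = build_pwm(peps, "uniform", pseudocount=0.0, alphabet="ABC")
        pwm3 = build_pwm(peps * 3, "uniform", pseudocount=0.0, alphabet="ABC")
        assert np.allclose(pwm1.weights, pwm3.weights)

    @pytest.mark.parametrize(
        "peptides,err",
        [
            (["AB"], InsufficientData),
            (["AB", "ABC"], LengthMismatch),
            (["AB", "AZ"], AlphabetError),
        ],
    )
    def test_input_validation(self, peptides, err):
        with pytest.raises(err):
            build_pwm(peptides, "uniform", alphabet="ABC")

    def test_proteome_background_sums_to_one(self):
        bg = proteome_background(["ACDE", "AAAA"])
        assert bg.sum() == pytest.approx(1.0)
        assert np.all(bg > 0)
        assert bg[0] > bg[5]  # A much more frequent than G


class TestScoring:
    def test_consensus_window_achieves_max_score(self, toy_pwm):
        assert score_window(toy_pwm, toy_pwm.consensus) == pytest.approx(
            toy_pwm.max_score
        )

    def test_score_is_direct_sum(self, toy_pwm):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = "".join("ABC"[i] for i in rng.integers(0, 3, toy_pwm.n))
            direct = sum(
                toy_pwm.weights[toy_pwm.row(c), j] for j, c in enumerate(w)
            )
            assert score_window(toy_pwm, w) == pytest.approx(direct)

    def test_window_length_checked(self, toy_pwm):
        with pytest.raises(LengthMismatch):
            score_window(toy_pwm, "ABC")


class TestScoreDistribution:
    def test_total_mass_and_monotonicity(self, toy_pwm):
        dist = score_distribution(toy_pwm)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.support) > 0)
        assert np.all(np.diff(dist.tail_prob) <= 1e-15)
        assert dist.tail_prob[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_column_closed_form(self):
        pwm = build_pwm(["A", "A", "B"], "uniform", pseudocount=0.0, alphabet="ABC")
        dist = score_distribution(pwm)
        # tail at score s = sum of background mass of letters with weight >= s
        for s in np.unique(pwm.weights[:, 0]):
            expected = pwm.background[pwm.weights[:, 0] >= s - 1e-12].sum()
            assert pvalue_of_score(dist, float(s)) == pytest.approx(expected)

    def test_two_letter_hand_enumeration(self):
        pwm = build_pwm(["AA", "AB"], "uniform", pseudocount=0.0, alphabet="AB")
        # col frequencies: col0 A=1; col1 A=.5, B=.5
        # weights: col0 A=1, B=floor; col1 both 0
        dist = score_distribution(pwm)
        # four windows: AA,AB score 1 (p each .25), BA,BB score floor+0
        assert pvalue_of_score(dist, 1.0) == pytest.approx(0.5)
        assert pvalue_of_score(dist, LOG_ODDS_FLOOR) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        g = 1e-3
        for _ in range(5):
            pwm = random_toy_pwm(rng)
            dist = score_distribution(pwm, g)
            support, probs, tail = enumerate_score_distribution(pwm, g)
            assert np.allclose(dist.support, support, atol=g / 2)
            assert np.allclose(dist.probs, probs, atol=1e-12)
            assert np.allclose(dist.tail_prob, tail, atol=1e-12)


class TestPvalueThreshold:
    def test_extreme_scores(self, toy_pwm):
        dist = score_distribution(toy_pwm)
        assert pvalue_of_score(dist, -1e9) == 1.0
        assert pvalue_of_score(dist, 1e9) == 0.0

    def test_pvalue_monotone_in_score(self, toy_pwm):
        dist = score_distribution(toy_pwm)
        scores = np.linspace(-5, 5, 50)
        pvals = [pvalue_of_score(dist, s) for s in scores]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_threshold_round_trip(self, toy_pwm):
        dist = score_distribution(toy_pwm)
        # smallest attainable tail of this 3-letter toy is 2/9
        for p in (1.0, 0.5, 0.3):
            thr = threshold_for_pvalue(dist, p)
            assert pvalue_of_score(dist, thr) <= p

    def test_pvalue_one_gives_minimum_support(self, toy_pwm):
        dist = score_distribution(toy_pwm)
        assert threshold_for_pvalue(dist, 1.0) == pytest.approx(dist.support[0])

    def test_unattainable_pvalue(self, toy_pwm):
        dist = score_distribution(toy_pwm)
        with pytest.raises(UnattainableThreshold):
            threshold_for_pvalue(dist, 1e-30)

    def test_quantile_matches_enumeration(self):
        rng = np.random.default_rng(7)
        pwm = random_toy_pwm(rng, n=3)
        g = 1e-3
        dist = score_distribution(pwm, g)
        support, _, tail = enumerate_score_distribution(pwm, g)
        for p in (0.05, 0.01):
            thr = threshold_for_pvalue(dist, p)
            expected = support[np.argmax(tail <= p)]
            assert thr == pytest.approx(expected, abs=g / 2)


class TestInformationContent:
    def test_background_column_zero(self):
        pwm = build_pwm(["A", "B", "C"], "uniform", pseudocount=0.0, alphabet="ABC")
        assert position_information_content(pwm)[0] == pytest.approx(0.0)

    def test_point_mass_column(self):
        pwm = build_pwm(["PP", "PP"], "uniform", pseudocount=0.0)
        ic = position_information_content(pwm)
        assert np.allclose(ic, np.log2(20))

    def test_mixed_column_direct_formula(self, toy_pwm):
        f = toy_pwm.frequencies
        bg = toy_pwm.background
        expected = (f * np.log2(f / bg[:, None])).sum(axis=0)
        assert np.allclose(position_information_content(toy_pwm), expected)

    def test_significant_positions_cutoffs(self, toy_pwm):
        assert significant_positions(toy_pwm, 0.0) == [0, 1]
        with pytest.raises(EmptySignificantSet):
            significant_positions(toy_pwm, np.log2(3) + 0.1)

    def test_conserved_vs_background_column(self):
        pwm = build_pwm(
            ["AA", "AB", "AC"], "uniform", pseudocount=0.0, alphabet="ABC"
        )
        # column 0 is a point mass (IC log2 3), column 1 matches background
        assert significant_positions(pwm, 1.0) == [0]


def test_serialization_round_trip(toy_pwm):
    text = pwm_to_text(toy_pwm)
    back = pwm_from_text(text)
    assert back.id == toy_pwm.id
    assert back.alphabet == toy_pwm.alphabet
    assert np.allclose(back.counts, toy_pwm.counts)
    assert np.allclose(back.weights, toy_pwm.weights)
    assert np.allclose(back.background, toy_pwm.background)
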