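"""Peptide-level evidence: closed-form scores, alignment oracle, contact transfer."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from prmpred import (
    accessibility_score,
    align_global,
    conservation_from_msa,
    conservation_score,
    contact_model_from_map,
    disorder_score,
    structural_contact_score,
)
from prmpred.errors import (
    DegenerateModel,
    EmptyInput,
    EmptySignificantSet,
    MissingReference,
    TrackMismatch,
)
from prmpred.peptide_features import ContactModel, ResidueTrack
from prmpred.scan import PeptideHit

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def make_hit(start=3, end=6, sig=(3, 4, 5, 6), protein="p1"):
    return PeptideHit(
        protein_id=protein, pwm_id="m", domain_id="d", start=start, end=end,
        window_seq="A" * (end - start + 1), score=0.0, pvalue=1.0,
        significant_protein_positions=tuple(sig),
    )


def track(kind, values, protein="p1"):
    return ResidueTrack(protein_id=protein, kind=kind, values=tuple(values))


class TestTrackScores:
    def test_disorder_all_and_none(self):
        hit = make_hit()
        ten = [1.0] * 10
        assert disorder_score(hit, track("disorder", ten)) == 1.0
        assert disorder_score(hit, track("disorder", [0.0] * 10)) == 0.0

    def test_disorder_fraction(self):
        hit = make_hit(sig=(3, 4, 5, 6))
        values = [0.0] * 10
        for pos in (3, 4, 5):  # 3 of 4 significant residues disordered
            values[pos - 1] = 1.0
        assert disorder_score(hit, track("disorder", values)) == 0.75

    def test_disorder_binarization_threshold(self):
        hit = make_hit(sig=(3, 4))
        values = [0.0, 0.0, 0.5, 0.49, 0.0, 0.0]
        assert disorder_score(hit, track("disorder", values)) == 0.5

    def test_accessibility_boundary_inclusive(self):
        hit = make_hit(sig=(3, 4))
        values = [0.0, 0.0, 0.25, 0.24, 0.0, 0.0]
        assert accessibility_score(hit, track("rsa", values)) == 0.5

    def test_accessibility_all_exposed_or_buried(self):
        hit = make_hit()
        assert accessibility_score(hit, track("rsa", [0.30] * 10)) == 1.0
        assert accessibility_score(hit, track("rsa", [0.10] * 10)) == 0.0

    def test_conservation_is_plain_mean(self):
        hit = make_hit(sig=(3, 4))
        assert conservation_score(hit, track("conservation", [9, 9, 1.0, 0.0, 9, 9])) == 0.5
        assert conservation_score(hit, track("conservation", [0.7] * 6)) == pytest.approx(0.7)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=12)
        hit2 = make_hit(start=2, end=9, sig=(2, 5, 9))
        expected = np.mean([vals[1], vals[4], vals[8]])
        assert conservation_score(hit2, track("conservation", vals)) == pytest.approx(expected)

    def test_scores_depend_only_on_significant_positions(self):
        hit = make_hit(sig=(4, 5))
        base = [0.8] * 10
        perturbed = list(base)
        perturbed[0] = perturbed[9] = 0.01  # outside the significant set
        for kind, func in (("disorder", disorder_score), ("rsa", accessibility_score),
                           ("conservation", conservation_score)):
            assert func(hit, track(kind, base)) == func(hit, track(kind, perturbed))

    def test_empty_significant_set_rejected(self):
        hit = make_hit(sig=())
        with pytest.raises(EmptySignificantSet):
            disorder_score(hit, track("disorder", [1.0] * 10))

    def test_short_track_rejected(self):
        hit = make_hit(start=3, end=9, sig=(3,))
        with pytest.raises(TrackMismatch):
            conservation_score(hit, track("conservation", [1.0] * 5))


class TestConservationFromMsa:
    def test_identical_rows_score_one_prenormalization(self):
        rows = [("r1", "ACD"), ("r2", "ACD"), ("r3", "ACD")]
        t = conservation_from_msa(rows, "r1", normalize=False)
        assert t.values == (1.0, 1.0, 1.0)

    def test_pair_count_oracle(self):
        # column 0: letters A,A,B,B -> agreeing pairs: (r1,r2),(r3,r4) = 2 of 6
        rows = [("r1", "A"), ("r2", "A"), ("r3", "B"), ("r4", "B")]
        t = conservation_from_msa(rows, "r1", normalize=False)
        assert t.values[0] == pytest.approx(2 / 6)

    def test_two_rows_single_pair_with_matrix(self):
        rows = [("a", "PG"), ("b", "PA")]
        t = conservation_from_msa(rows, "a", BLOSUM62, normalize=False)
        assert t.values == (float(BLOSUM62["P", "P"]), float(BLOSUM62["G", "A"]))

    def test_reference_gap_columns_dropped_and_gap_pairs_zero(self):
        rows = [("a", "A-C"), ("b", "AB-")]
        t = conservation_from_msa(rows, "a", normalize=False)
        # column 1 (ref gap) dropped; column 2 pair has a gap -> 0
        assert len(t.values) == 2
        assert t.values == (1.0, 0.0)

    def test_missing_reference(self):
        with pytest.raises(MissingReference):
            conservation_from_msa([("a", "A"), ("b", "A")], "zz")

    def test_znormalized_track_is_centered(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACDG"), 30)) for _ in range(4)]
        rows = [(f"r{i}", s) for i, s in enumerate(seqs)]
        t = conservation_from_msa(rows, "r0")
        assert np.mean(t.values) == pytest.approx(0.0, abs=1e-9)
        assert np.std(t.values) == pytest.approx(1.0, abs=1e-9)


def brute_force_global_score(a, b, matrix, gap_open, gap_extend):
    """Exhaustive affine-gap global alignment score via recursion over the
    last emitted column (match, gap-in-a, gap-in-b)."""
    from functools import lru_cache

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 start/after match, 1 in gap on a side, 2 in gap on b side
        if i == len(a) and j == len(b):
            return 0.0
        options = [NEG]
        if i < len(a) and j < len(b):
            options.append(float(matrix[a[i], b[j]]) + best(i + 1, j + 1, 0))
        if j < len(b):  # gap in a (consume b)
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i, j + 1, 1))
        if i < len(a):  # gap in b (consume a)
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i + 1, j, 2))
        return max(options)

    return best(0, 0, 0)


class TestGlobalAlignment:
    def test_identity_alignment(self):
        aln = align_global("PPP", "PPP")
        assert aln.score == 3 * float(BLOSUM62["P", "P"])
        assert aln.mapping == ((0, 0), (1, 1), (2, 2))
        assert aln.aligned_a == aln.aligned_b == "PPP"

    def test_self_alignment_scores_diagonal_sum(self):
        seq = "MKWVTFIS"
        aln = align_global(seq, seq)
        assert aln.score == sum(float(BLOSUM62[c, c]) for c in seq)
        assert aln.mapping == tuple((i, i) for i in range(len(seq)))

    def test_degapping_recovers_inputs(self):
        aln = align_global("MKWVTF", "MKTF")
        assert aln.aligned_a.replace("-", "") == "MKWVTF"
        assert aln.aligned_b.replace("-", "") == "MKTF"
        assert all(a < c or b < d for (a, b), (c, d) in
                   zip(aln.mapping, aln.mapping[1:]))

    def test_empty_sequence_rejected(self):
        with pytest.raises(EmptyInput):
            align_global("", "PPP")

    def test_matches_exhaustive_search_short_pairs(self):
        rng = np.random.default_rng(3)
        alphabet = "ACGT"  # 4-letter toy alphabet (valid BLOSUM62 letters)
        for _ in range(30):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list(alphabet), la))
            b = "".join(rng.choice(list(alphabet), lb))
            expected = brute_force_global_score(a, b, BLOSUM62, -10.0, -1.0)
            assert align_global(a, b).score == pytest.approx(expected), (a, b)


class TestContactModel:
    def test_max_normalization(self):
        m = contact_model_from_map([(0, 0, 50.0), (1, 1, 25.0)], "AC", "GT")
        areas = sorted(c for _, _, c in m.contacts)
        assert areas == [0.5, 1.0]

    def test_single_pair_is_one(self):
        m = contact_model_from_map([(0, 1, 7.3)], "AC", "GT")
        assert m.contacts[0][2] == 1.0

    def test_order_invariance(self):
        pairs = [(0, 0, 50.0), (1, 1, 25.0), (1, 0, 10.0)]
        m1 = contact_model_from_map(pairs, "AC", "GT")
        m2 = contact_model_from_map(pairs[::-1], "AC", "GT")
        assert m1.contacts == m2.contacts

    def test_all_zero_areas_rejected(self):
        with pytest.raises(DegenerateModel):
            contact_model_from_map([(0, 0, 0.0)], "AC", "GT")


class TestStructuralContact:
    DOMAIN = "MKWVTFISLLFLFSSAYS"
    PEPTIDE = "RPLPPLP"

    def _model(self, contacts):
        return ContactModel(model_id="toy", domain_seq=self.DOMAIN,
                            peptide_seq=self.PEPTIDE, contacts=tuple(contacts))

    def test_identity_query_scores_mean_area(self):
        model = self._model([(0, 0, 0.8), (5, 3, 0.4)])
        sc, best = structural_contact_score(self.DOMAIN, self.PEPTIDE, [model])
        assert sc == pytest.approx((0.8 + 0.4) / 2)
        assert best == "toy"

    def test_gap_at_contact_residue_penalizes_average(self):
        model = self._model([(0, 0, 0.8), (5, 3, 0.4)])
        # delete peptide residue 3 (0-based) -> the 0.4 contact is unalignable
        query_pep = self.PEPTIDE[:3] + self.PEPTIDE[4:]
        sc, _ = structural_contact_score(self.DOMAIN, query_pep, [model])
        assert sc == pytest.approx(0.8 / 2)

    def test_repairing_a_gap_never_decreases_score(self):
        model = self._model([(0, 0, 0.8), (5, 3, 0.4)])
        gapped = structural_contact_score(self.DOMAIN, self.PEPTIDE[:3] + self.PEPTIDE[4:], [model])[0]
        full = structural_contact_score(self.DOMAIN, self.PEPTIDE, [model])[0]
        assert full >= gapped

    def test_best_model_is_argmax(self):
        weak = ContactModel(model_id="weak", domain_seq=self.DOMAIN,
                            peptide_seq=self.PEPTIDE,
                            contacts=((0, 0, 0.1), (1, 1, 0.1)))
        strong = self._model([(0, 0, 1.0), (5, 3, 1.0)])
        sc, best = structural_contact_score(self.DOMAIN, self.PEPTIDE, [weak, strong])
        assert best == "strong" if strong.model_id == "strong" else "toy"
        assert sc == pytest.approx(1.0)

    def test_score_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        model = self._model(
            [(int(rng.integers(0, 18)), int(rng.integers(0, 7)),
              float(rng.uniform(0.1, 1))) for _ in range(5)]
        )
        sc, _ = structural_contact_score("MKWVTF", "RPLP", [model])
        assert 0.0 <= sc <= 1.0

    def test_no_models_rejected(self):
        with pytest.raises(EmptyInput):
            structural_contact_score("MKWVTF", "RPLP", [])
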