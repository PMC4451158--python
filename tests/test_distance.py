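import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from its2barcode import (
    DistanceMatrix,
    MultipleAlignment,
    PairwiseSiteCounts,
    SaturatedDistanceError,
    ValidationError,
    count_site_patterns,
    distance_matrix,
    k2p_distance,
    species_summaries,
)
from its2barcode.errors import NoOverlapError


class TestSiteCounts:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (4, 0, 0)),
            ("AAAA", "GAAA", (4, 1, 0)),  # A<->G is a transition
            ("AC-T", "ACGT", (3, 0, 0)),  # gap column pairwise-deleted
            ("ACGT", "ACGA", (4, 0, 1)),  # T<->A is a transversion
            ("ANGT", "ACGT", (3, 0, 0)),  # ambiguity pairwise-deleted
        ],
    )
    def test_hand_counted_columns(self, a, b, expected):
        c = count_site_patterns(a, b)
        assert (c.n, c.s, c.v) == expected

    def test_no_overlap_is_an_error(self):
        with pytest.raises(NoOverlapError):
            count_site_patterns("A---", "-CGT")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            count_site_patterns("ACG", "AC")


class TestK2P:
    def test_zero_divergence(self):
        assert k2p_distance(PairwiseSiteCounts(n=100, s=0, v=0)) == 0.0

    def test_transitions_only_closed_form(self):
        # P=0.1, Q=0 -> -1/2 ln(0.8)
        d = k2p_distance(PairwiseSiteCounts(n=100, s=10, v=0))
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-15)

    def test_saturation_boundary(self):
        # P=0.3, Q=0.4 -> 1 - 2P - Q = 0
        with pytest.raises(SaturatedDistanceError):
            k2p_distance(PairwiseSiteCounts(n=10, s=3, v=4))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(1, 400), st.integers(0, 400), st.integers(0, 400))
    def test_k2p_dominates_p_distance(self, n, s, v):
        # multiple-hit correction can only increase the raw proportion
        if s + v > n or 1 - 2 * s / n - v / n <= 0 or 1 - 2 * v / n <= 0:
            return
        c = PairwiseSiteCounts(n=n, s=s, v=v)
        d = k2p_distance(c)
        assert d >= c.P + c.Q - 1e-12
        if s == v == 0:
            assert d == 0.0


class TestDistanceMatrix:
    def test_identical_rows_give_zero_matrix(self):
        msa = MultipleAlignment(
            {"a": "ACGT", "b": "ACGT"}, {"a": "Sp_x", "b": "Sp_x"}
        )
        dm = distance_matrix(msa)
        assert np.array_equal(dm.d, np.zeros((2, 2)))

    def test_three_rows_match_per_pair_closed_form(self):
        rows = {"a": "AAAAAAAAAA", "b": "GAAAAAAAAA", "c": "GAAAAAAAAT"}
        msa = MultipleAlignment(rows, {k: "Sp_x" for k in rows})
        dm = distance_matrix(msa)
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            expected = k2p_distance(count_site_patterns(rows[x], rows[y]))
            assert dm.get(x, y) == pytest.approx(expected, abs=1e-15)

    def test_row_permutation_invariance(self, default_msa):
        ids = list(default_msa.rows)
        dm1 = distance_matrix(default_msa)
        rev = {i: default_msa.rows[i] for i in reversed(ids)}
        dm2 = distance_matrix(MultipleAlignment(rev, default_msa.labels))
        for a in ids[::7]:
            for b in ids[::5]:
                assert dm1.get(a, b) == dm2.get(a, b)

    def test_saturated_pair_flagged_as_inf_when_configured(self):
        rows = {"a": "ACACACACAC", "b": "GTGTGTGTGT", "c": "ACACACACAC"}
        msa = MultipleAlignment(rows, {k: "Sp_x" for k in rows})
        from its2barcode.distance import SaturatedPairsError

        with pytest.raises(SaturatedPairsError):
            distance_matrix(msa)
        dm = distance_matrix(msa, on_saturation="inf")
        assert math.isinf(dm.get("a", "b"))
        assert dm.get("a", "c") == 0.0

    def test_k2p_estimate_converges_to_simulated_divergence(self):
        # two sequences evolved apart by expected divergence t under the
        # K2P process: the corrected estimate should be nearly unbiased
        rng = np.random.default_rng(42)
        t, L, kappa, reps = 0.1, 10_000, 4.0, 50
        ti_frac = kappa / (kappa + 2.0)
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        bases = "ACGT"
        estimates = []
        for _ in range(reps):
            anc = rng.choice(list(bases), size=L)
            pair = []
            for _side in range(2):
                seq = anc.copy()
                hits = rng.poisson(t / 2, size=L)
                for site in np.nonzero(hits)[0]:
                    for _h in range(hits[site]):
                        old = seq[site]
                        if rng.random() < ti_frac:
                            seq[site] = transition[old]
                        else:
                            seq[site] = [b for b in bases if b not in (old, transition[old])][
                                rng.integers(0, 2)
                            ]
                pair.append("".join(seq))
            estimates.append(k2p_distance(count_site_patterns(*pair)))
        assert abs(np.mean(estimates) - t) / t < 0.10


class TestSpeciesSummaries:
    def test_two_singleton_species(self):
        dm = DistanceMatrix(("x", "y"), np.array([[0.0, 0.1], [0.1, 0.0]]))
        out = species_summaries(dm, {"x": "Sp_x", "y": "Sp_y"})
        for s in out:
            assert s.intra is None  # a single sample has no within-species pair
            assert (s.inter.min, s.inter.max, s.inter.mean) == (0.1, 0.1, 0.1)

    def test_shared_haplotype_species_has_zero_intra(self, default_msa):
        dm = distance_matrix(default_msa)
        for s in species_summaries(dm, default_msa.labels):
            assert s.intra is not None
            assert s.intra.min == s.intra.max == s.intra.mean == 0.0

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(7)
        ids = tuple(f"s{i}" for i in range(9))
        labels = {f"s{i}": f"Sp_{i % 3}" for i in range(9)}
        m = np.round(rng.uniform(0.01, 0.2, size=(9, 9)), 4)
        d = np.triu(m, 1)
        d = d + d.T
        dm = DistanceMatrix(ids, d)
        for s in species_summaries(dm, labels):
            own = [i for i, x in enumerate(ids) if labels[x] == s.species]
            intra = [d[a, b] for ai, a in enumerate(own) for b in own[ai + 1 :]]
            inter = [d[a, b] for a in own for b in range(9) if b not in own]
            assert s.intra.mean == pytest.approx(np.mean(intra))
            assert s.inter.min == pytest.approx(np.min(inter))
            assert s.inter.max == pytest.approx(np.max(inter))
            assert s.inter.mean == pytest.approx(np.mean(inter))

    def test_unlabeled_id_rejected(self):
        dm = DistanceMatrix(("x", "y"), np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            species_summaries(dm, {"x": "Sp_x"})
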