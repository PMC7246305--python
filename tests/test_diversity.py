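import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from msapdiv import (
    MarkerType,
    build_diversity_table,
    drop_monomorphic,
    ppol,
    pprivate,
    rarity_index,
    shannon_index,
    species_diversity_records,
)

from conftest import build_matrix

# ---------------------------------------------------------------------------
# brute-force reimplementation (naive loops, no shared code with the package)
# ---------------------------------------------------------------------------


def naive_ppol(values, pops, focal):
    rows = [i for i, p in enumerate(pops) if p == focal]
    n_poly = 0
    for j in range(values.shape[1]):
        col = {values[i][j] for i in rows}
        n_poly += col == {0, 1}
    return n_poly / values.shape[1]


def naive_shannon(values, pops, focal):
    rows = [i for i, p in enumerate(pops) if p == focal]
    total = 0.0
    for j in range(values.shape[1]):
        p = sum(values[i][j] for i in rows) / len(rows)
        for q in (p, 1 - p):
            if q > 0:
                total -= q * math.log(q)
    return total / values.shape[1]


def naive_ppriv(values, pops, focal):
    present = privat = 0
    for j in range(values.shape[1]):
        in_focal = any(values[i][j] for i, p in enumerate(pops) if p == focal)
        in_other = any(values[i][j] for i, p in enumerate(pops) if p != focal)
        present += in_focal
        privat += in_focal and not in_other
    return privat / present


def naive_rarity(values, pops, focal):
    k, n = values.shape
    occ = [sum(values[i][j] for i in range(k)) for j in range(n)]
    ri = []
    for i in range(k):
        if pops[i] != focal:
            continue
        ri.append(sum(values[i][j] / occ[j] for j in range(n) if occ[j] > 0))
    return ri, sum(ri) / len(ri)


# ---------------------------------------------------------------------------


class TestPpol:
    def test_constant_columns_give_zero(self):
        m = build_matrix([[1, 0], [1, 0], [1, 0]])
        assert ppol(m, "pop1") == 0.0

    def test_one_of_three_mixed(self):
        m = build_matrix(np.array([[1, 1, 0], [0, 1, 0], [1, 1, 0]]))
        assert ppol(m, "pop1") == pytest.approx(1 / 3)

    def test_all_columns_mixed_give_one(self):
        m = build_matrix([[1, 0, 1], [0, 1, 0]])
        assert ppol(m, "pop1") == 1.0


class TestShannon:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([1, 1, 0, 0], math.log(2)),     # p = 1/2: two-state maximum
            ([1, 1, 1, 1], 0.0),             # fixed band
            ([1, 0, 0, 0], 0.562335),        # p = 1/4
        ],
    )
    def test_single_locus_entropies(self, column, expected):
        m = build_matrix(np.array(column)[:, None])
        assert shannon_index(m, "pop1") == pytest.approx(expected, abs=1e-6)

    def test_never_exceeds_ln2(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            m = build_matrix(rng.integers(0, 2, (6, 15)))
            assert shannon_index(m, "pop1") <= math.log(2) + 1e-12


class TestPPrivate:
    def test_quarter_private(self):
        # focal pop presents 4 loci, one absent elsewhere
        vals = np.array(
            [
                [1, 1, 1, 1, 0],
                [1, 1, 1, 1, 0],
                [1, 1, 1, 0, 1],
                [1, 1, 1, 0, 1],
            ]
        )
        m = build_matrix(vals, populations=["a", "a", "b", "b"])
        assert pprivate(m, "a") == pytest.approx(0.25)

    def test_shared_everywhere_gives_zero(self):
        m = build_matrix(np.ones((4, 3)), populations=["a", "a", "b", "b"])
        assert pprivate(m, "a") == 0.0

    def test_single_copy_band_counts_as_private(self):
        vals = np.array([[1, 1], [0, 1], [0, 1], [0, 1]])
        m = build_matrix(vals, populations=["a", "a", "b", "b"])
        assert pprivate(m, "a") == pytest.approx(0.5)

    def test_empty_focal_population_rejected(self):
        vals = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        m = build_matrix(vals, populations=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="no present bands"):
            pprivate(m, "a")


class TestRarity:
    def test_all_ones_two_individuals(self):
        m = build_matrix(np.ones((2, 4)))
        ri_x, ri = rarity_index(m, "pop1")
        assert np.allclose(ri_x, 2.0)
        assert ri == pytest.approx(2.0)

    def test_unique_band_contributes_one(self):
        vals = np.zeros((3, 1), dtype=int)
        vals[0, 0] = 1
        ri_x, _ = rarity_index(build_matrix(vals), "pop1")
        assert ri_x[0] == pytest.approx(1.0)

    def test_conservation_identity_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            vals = rng.integers(0, 2, (10, 20))
            m = build_matrix(vals, populations=["a"] * 5 + ["b"] * 5)
            total = sum(rarity_index(m, pop)[0].sum() for pop in ("a", "b"))
            n_present = (vals.sum(axis=0) > 0).sum()
            assert total == pytest.approx(n_present, abs=1e-10)


class TestAgainstBruteForce:
    def test_random_matrices_agree_with_naive_loops(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            vals = rng.integers(0, 2, (8, 12))
            pops = ["a"] * 4 + ["b"] * 4
            m = build_matrix(vals, populations=pops)
            for focal in ("a", "b"):
                assert ppol(m, focal) == pytest.approx(naive_ppol(vals, pops, focal))
                assert shannon_index(m, focal) == pytest.approx(
                    naive_shannon(vals, pops, focal)
                )
                in_focal = vals[[i for i, p in enumerate(pops) if p == focal]].any()
                if in_focal:
                    assert pprivate(m, focal) == pytest.approx(
                        naive_ppriv(vals, pops, focal)
                    )
                ri_x, ri = rarity_index(m, focal)
                nri_x, nri = naive_rarity(vals, pops, focal)
                assert np.allclose(ri_x, nri_x)
                assert ri == pytest.approx(nri)

    def test_indices_invariant_to_locus_and_individual_order(self):
        rng = np.random.default_rng(21)
        vals = rng.integers(0, 2, (9, 14))
        pops = ["a"] * 5 + ["b"] * 4
        m = build_matrix(vals, populations=pops)
        lperm = rng.permutation(14)
        # permute individuals within populations so labels stay aligned
        iperm = np.concatenate([rng.permutation(5), 5 + rng.permutation(4)])
        m2 = build_matrix(vals[np.ix_(iperm, lperm)], populations=[pops[i] for i in iperm])
        for focal in ("a", "b"):
            assert ppol(m2, focal) == pytest.approx(ppol(m, focal))
            assert shannon_index(m2, focal) == pytest.approx(shannon_index(m, focal))
            assert pprivate(m2, focal) == pytest.approx(pprivate(m, focal))
            assert rarity_index(m2, focal)[1] == pytest.approx(rarity_index(m, focal)[1])


class TestPropertyBased:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(hnp.arrays(np.uint8, (6, 10), elements=st.integers(0, 1)))
    def test_rarity_conservation_and_si_bound(self, vals):
        m = build_matrix(vals, populations=["a"] * 3 + ["b"] * 3)
        total = rarity_index(m, "a")[0].sum() + rarity_index(m, "b")[0].sum()
        assert total == pytest.approx((vals.sum(axis=0) > 0).sum(), abs=1e-10)
        for pop in ("a", "b"):
            assert 0.0 <= shannon_index(m, pop) <= math.log(2) + 1e-12
            assert 0.0 <= ppol(m, pop) <= 1.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        hnp.arrays(np.uint8, (5, 8), elements=st.integers(0, 1)),
        st.permutations(range(8)),
    )
    def test_locus_order_invariance(self, vals, perm):
        pops = ["a"] * 3 + ["b"] * 2
        m = build_matrix(vals, populations=pops)
        m2 = build_matrix(vals[:, list(perm)], populations=pops)
        assert shannon_index(m2, "a") == pytest.approx(shannon_index(m, "a"))
        assert ppol(m2, "a") == pytest.approx(ppol(m, "a"))
        assert rarity_index(m2, "a")[1] == pytest.approx(rarity_index(m, "a")[1])


class TestDiversityTable:
    def test_record_counts_and_consistency(self, desk_table):
        assert len(desk_table) == 42 * 3
        assert (desk_table.groupby("marker_type").size() == 42).all()
        assert desk_table["SI"].max() <= math.log(2)
        assert desk_table[["PPOL", "PPRIV"]].max().max() <= 1.0
        assert desk_table[["PPOL", "PPRIV"]].min().min() >= 0.0

    def test_single_species_three_populations(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 2, (12, 30))
        pops = ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4
        m = drop_monomorphic(build_matrix(vals, populations=pops))
        table = build_diversity_table({"sp1": {"AFLP": m}})
        assert len(table) == 3
        rec = table[table["population"] == "p2"].iloc[0]
        assert rec["PPOL"] == pytest.approx(ppol(m, "p2"))
        assert rec["SI"] == pytest.approx(shannon_index(m, "p2"))
        assert rec["PPRIV"] == pytest.approx(pprivate(m, "p2"))
        assert rec["RI"] == pytest.approx(rarity_index(m, "p2")[1])

    def test_missing_population_rejected(self):
        rng = np.random.default_rng(6)
        m = build_matrix(rng.integers(0, 2, (4, 10)), populations=["p1"] * 2 + ["p2"] * 2)
        with pytest.raises(ValueError, match="p3"):
            build_diversity_table(
                {"sp1": {"AFLP": m}},
                expected_populations={"sp1": ["p1", "p2", "p3"]},
            )
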