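import itertools
import math

import numpy as np
import pandas as pd
import pytest

from delimetrics.core_io import DistanceMatrix
from delimetrics.morph import (
    MorphError,
    congruence_tests,
    encode_traits,
    holm_adjust,
    jaccard_matrix,
    mantel,
    mantel_per_trait,
    pcoa,
    upgma,
)
from tests.conftest import random_distance_matrix


def naive_upgma_cophenetic(dm: DistanceMatrix) -> dict[frozenset, float]:
    """O(n^3) average-linkage oracle tracking cophenetic distances."""
    clusters = [[i] for i in range(dm.n)]
    coph: dict[frozenset, float] = {}

    def cdist(a, b):
        return float(np.mean([dm.values[i, j] for i in a for j in b]))

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = cdist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        for i in clusters[x]:
            for j in clusters[y]:
                coph[frozenset((dm.ids[i], dm.ids[j]))] = d
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return coph


@pytest.fixture
def trait_table():
    return pd.DataFrame(
        {
            "shape": ["ellipsoidal", "spherical", "ellipsoidal, ovoid", "spherical"],
            "pyrenoid": ["present", "absent", "present", np.nan],
            "chloroplast": ["band", "cup", "band", "cup"],
        },
        index=["s1", "s2", "s3", "s4"],
    )


class TestEncodeTraits:
    def test_indicator_expansion_three_states(self):
        df = pd.DataFrame({"t": ["b"]}, index=["s1"])
        bm = encode_traits(df, vocabulary={"t": ["a", "b", "c"]})
        assert list(bm.data.loc["s1"]) == [0.0, 1.0, 0.0]

    def test_multi_valued_cell_sets_both(self, trait_table):
        bm = encode_traits(trait_table)
        row = bm.data.loc["s3"]
        assert row["shape=ellipsoidal"] == 1.0 and row["shape=ovoid"] == 1.0

    def test_completeness_filter_drops_70pct(self):
        cols = {f"t{i}": ["a"] * 2 for i in range(10)}
        df = pd.DataFrame(cols, index=["keep", "drop"])
        for i in range(3):  # 7/10 known -> below the 80% bar
            df.loc["drop", f"t{i}"] = np.nan
        bm = encode_traits(df)
        assert list(bm.strains) == ["keep"]

    def test_exactly_80pct_kept(self):
        cols = {f"t{i}": ["a"] * 1 for i in range(10)}
        df = pd.DataFrame(cols, index=["s"])
        for i in range(2):
            df.loc["s", f"t{i}"] = np.nan
        assert list(encode_traits(df).strains) == ["s"]

    def test_empty_after_filter_errors(self):
        df = pd.DataFrame({"t1": [np.nan], "t2": ["a"]}, index=["s"])
        with pytest.raises(MorphError):
            encode_traits(df)

    def test_missing_trait_all_nan_indicators(self, trait_table):
        bm = encode_traits(trait_table, min_completeness=0.6)
        assert bm.data.loc["s4", bm.trait_columns("pyrenoid")].isna().all()


class TestJaccard:
    def test_hand_count(self):
        df = pd.DataFrame({"t": ["a, c", "b, c"]}, index=["x", "y"])
        dm = jaccard_matrix(encode_traits(df))
        assert dm.get("x", "y") == pytest.approx(1 - 1 / 3)

    def test_identical_vectors_zero(self, trait_table):
        # s4 has 2/3 traits determined; relax the filter to keep it
        dm = jaccard_matrix(encode_traits(trait_table, min_completeness=0.6))
        assert dm.get("s2", "s4") == 0.0  # agree on every shared determined trait

    def test_no_shared_determined_traits_masked(self):
        df = pd.DataFrame(
            {"t1": ["a", np.nan, "a"], "t2": [np.nan, "b", "b"]},
            index=["x", "y", "z"],
        )
        dm = jaccard_matrix(encode_traits(df, min_completeness=0.0))
        assert math.isnan(dm.get("x", "y")) and not math.isnan(dm.get("x", "z"))

    def test_bounds_symmetry_diagonal(self, trait_table):
        dm = jaccard_matrix(encode_traits(trait_table))
        vals = dm.values[~np.isnan(dm.values)]
        assert ((vals >= 0) & (vals <= 1)).all()
        assert np.allclose(np.diagonal(dm.values), 0)


class TestMantel:
    def test_identical_matrices_r_one(self):
        dm = random_distance_matrix(6, np.random.default_rng(1))
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_four_strain_exact_enumeration(self):
        rng = np.random.default_rng(2)
        dm1 = random_distance_matrix(4, rng)
        dm2 = random_distance_matrix(4, rng)
        x = dm1.values[np.triu_indices(4, 1)]
        r_obs = np.corrcoef(x, dm2.values[np.triu_indices(4, 1)])[0, 1]
        count = 0
        for p in itertools.permutations(range(4)):
            perm = dm2.values[np.ix_(p, p)][np.triu_indices(4, 1)]
            if np.corrcoef(x, perm)[0, 1] >= r_obs - 1e-12:
                count += 1
        p_exact = count / 24
        res = mantel(dm1, dm2, n_perm=10000, seed=3)
        assert abs(res.p - p_exact) < 0.02

    def test_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(4)
        dm1 = random_distance_matrix(6, rng)
        dm2 = random_distance_matrix(6, rng)
        p = rng.permutation(6)
        ids = tuple(dm1.ids[i] for i in p)
        dm1p = DistanceMatrix(ids, dm1.values[np.ix_(p, p)])
        dm2p = DistanceMatrix(ids, dm2.values[np.ix_(p, p)])
        assert mantel(dm1, dm2, 10, seed=0).r == pytest.approx(
            mantel(dm1p, dm2p, 10, seed=0).r
        )

    def test_degenerate_trait_errors(self):
        dm1 = random_distance_matrix(4, np.random.default_rng(5))
        flat = DistanceMatrix(dm1.ids, np.where(np.eye(4), 0.0, 0.5))
        with pytest.raises(MorphError, match="degenerate"):
            mantel(dm1, flat, n_perm=9, seed=0)

    def test_per_trait_self_correlation(self):
        # one trait only: single-trait matrix IS the overall matrix
        df = pd.DataFrame({"t": ["a", "b", "a", "b", "c"]},
                          index=[f"s{i}" for i in range(5)])
        bm = encode_traits(df)
        res = mantel_per_trait(bm, "t", n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1.0], [1.0, 0]]))
        tree = upgma(dm)
        assert tree.height == pytest.approx(0.5)
        assert sorted(tree.leaf_names()) == ["A", "B"]

    def test_three_leaf_hand_arithmetic(self):
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(DistanceMatrix(("A", "B", "C"), D))
        coph = tree.cophenetic()
        assert coph[frozenset(("A", "B"))] == pytest.approx(0.2)
        assert coph[frozenset(("A", "C"))] == pytest.approx(0.6)
        assert tree.height == pytest.approx(0.3)

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            dm = random_distance_matrix(8, rng)
            coph = upgma(dm).cophenetic()
            oracle = naive_upgma_cophenetic(dm)
            for key in oracle:
                assert coph[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_ultrametric_three_point_condition(self):
        rng = np.random.default_rng(11)
        dm = random_distance_matrix(7, rng)
        coph = upgma(dm).cophenetic()
        for a, b, c in itertools.combinations(dm.ids, 3):
            ds = sorted(
                [coph[frozenset((a, b))], coph[frozenset((a, c))], coph[frozenset((b, c))]]
            )
            assert ds[2] - ds[1] < 1e-9

    def test_masked_matrix_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(MorphError, match="complete"):
            upgma(DistanceMatrix(("A", "B"), D))


class TestPcoa:
    def test_equidistant_triangle(self):
        D = np.where(np.eye(3), 0.0, 1.0)
        ordn = pcoa(DistanceMatrix(("a", "b", "c"), D), k=2)
        c = ordn.coordinates
        d01 = np.linalg.norm(c[0] - c[1])
        d02 = np.linalg.norm(c[0] - c[2])
        d12 = np.linalg.norm(c[1] - c[2])
        assert d01 == pytest.approx(d02) == pytest.approx(d12)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(6)), D)
        ordn = pcoa(dm, k=3)
        rec = np.linalg.norm(
            ordn.coordinates[:, None] - ordn.coordinates[None, :], axis=2
        )
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_eigenvalues_non_increasing(self):
        dm = random_distance_matrix(8, np.random.default_rng(14))
        ordn = pcoa(dm, k=3)
        assert np.all(np.diff(ordn.eigenvalues) <= 1e-12)

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(15)
        pts = rng.normal(size=(7, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = tuple(f"s{i}" for i in range(7))
        ours = pcoa(DistanceMatrix(ids, D), k=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D, ids))
        np.testing.assert_allclose(
            ours.eigenvalues[:3], ref.eigvals.to_numpy()[:3], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates), np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-6
        )


class TestCongruence:
    def test_identical_matrices(self):
        dm = random_distance_matrix(6, np.random.default_rng(16))
        res = congruence_tests(dm, dm, n_perm=99, seed=0)
        assert res.W == pytest.approx(1.0)
        assert res.t0 == pytest.approx(1.0, abs=1e-6)
        assert res.p_cadm == pytest.approx(1 / 100)
        assert res.p_protest == pytest.approx(1 / 100)

    def test_independent_matrices_w_near_half(self):
        rng = np.random.default_rng(17)
        ws = []
        for _ in range(10):
            dm1 = random_distance_matrix(8, rng)
            dm2 = random_distance_matrix(8, rng)
            ws.append(congruence_tests(dm1, dm2, n_perm=19, seed=0).W)
        assert 0.3 < float(np.mean(ws)) < 0.7

    def test_published_holm_example(self):
        adj = holm_adjust([0.871, 0.594])
        assert adj[0] == pytest.approx(1.0) and adj[1] == pytest.approx(1.0)

    def test_holm_properties(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            raw = list(rng.uniform(0, 1, rng.integers(2, 6)))
            adj = holm_adjust(raw)
            assert all(a >= r - 1e-12 for a, r in zip(adj, raw))
            assert all(a <= 1.0 for a in adj)
            order = np.argsort(raw)
            assert all(
                adj[order[i]] <= adj[order[i + 1]] + 1e-12
                for i in range(len(raw) - 1)
            )
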