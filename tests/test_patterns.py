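import itertools

import numpy as np
import pytest
from scipy import sparse

import igan
from igan.association import AssociationNetworkSet, NetworkBlock
from igan.patterns import (
    CommMatrix,
    PatternDecomposition,
    benchmark,
    build_comm_matrix,
    nmf_patterns,
    rank_scan,
    shuffle_rows,
    simple_microenvironments,
    weighted_kl,
)


def nets_with_rowsums(A, B, ligand_rowsums):
    """One block whose per-pair ligand row sums are given (one ligand, T=5)."""
    n = len(ligand_rowsums)
    T = 5
    H = np.zeros((n, 1, T), dtype=np.uint8)
    for k, s in enumerate(ligand_rowsums):
        H[k, 0, :s] = 1
    block = NetworkBlock(source_type=A, target_type=B, a=np.arange(n), b=np.arange(n),
                         H=sparse.csr_matrix(H.reshape(n, T)), n_source=1, n_target=T)
    return AssociationNetworkSet(source_genes=["L"], target_genes=[f"t{i}" for i in range(T)],
                                 blocks={(A, B): block})


def random_decomp(rng, m, k, n_cols):
    return PatternDecomposition(W=rng.random((m, k)) + 1e-3, Hb=rng.random((k, n_cols)),
                                rank=k, seed=0, reconstruction_error=0.0,
                                row_names=[f"T{i}" for i in range(m)])


class TestBuildCommMatrix:
    def test_hand_worked_mean_load(self):
        nets = nets_with_rowsums("X", "Y", [2, 0, 1])
        ct = np.array(["X", "Y"], dtype=object)
        C = build_comm_matrix(nets, ct, ["L"], "sending")
        assert C.to_frame().loc["X", "L"] == pytest.approx(1.0)
        assert C.to_frame().loc["Y", "L"] == 0.0

    def test_receiving_uses_target_type_row(self):
        nets = nets_with_rowsums("X", "Y", [2, 0, 1])
        ct = np.array(["X", "Y"], dtype=object)
        C = build_comm_matrix(nets, ct, ["L"], "receiving")
        assert C.to_frame().loc["Y", "L"] == pytest.approx(1.0)
        assert C.to_frame().loc["X", "L"] == 0.0

    def test_all_zero_networks(self):
        nets = nets_with_rowsums("X", "Y", [0, 0])
        C = build_comm_matrix(nets, np.array(["X", "Y"], dtype=object), ["L"], "sending")
        assert not C.C.any()

    def test_intra_type_blocks_ignored(self):
        nets = nets_with_rowsums("X", "X", [3, 3])
        C = build_comm_matrix(nets, np.array(["X", "Y"], dtype=object), ["L"], "sending")
        assert not C.C.any()

    def test_symmetric_two_type_fixture(self, rng):
        # couplings symmetric by construction: sending of X == receiving of X
        loads = list(rng.integers(0, 5, size=6))
        blocks = {}
        for (A, B) in (("X", "Y"), ("Y", "X")):
            n = len(loads)
            H = np.zeros((n, 1, 5), dtype=np.uint8)
            for k, s in enumerate(loads):
                H[k, 0, :s] = 1
            blocks[(A, B)] = NetworkBlock(source_type=A, target_type=B,
                                          a=np.arange(n), b=np.arange(n),
                                          H=sparse.csr_matrix(H.reshape(n, 5)),
                                          n_source=1, n_target=5)
        nets = AssociationNetworkSet(source_genes=["L"],
                                     target_genes=[f"t{i}" for i in range(5)],
                                     blocks=blocks)
        ct = np.array(["X", "Y"], dtype=object)
        send = build_comm_matrix(nets, ct, ["L"], "sending").C
        recv = build_comm_matrix(nets, ct, ["L"], "receiving").C
        np.testing.assert_allclose(send[0], recv[0])


class TestSimpleMicroenvironments:
    def test_segregated_zones_recovered(self):
        cfg = igan.SimConfig(layout="boundary", shape=(8, 8), types=("A", "B"),
                             n_genes=4, couplings=(), seed=0)
        ds, truth = igan.simulate(cfg)
        graph = igan.build_neighbor_graph(ds)
        me = simple_microenvironments(graph, ds.cell_type, n_env=2, seed=0)
        E = me.to_frame()
        # each type concentrates in one environment (boundary cells aside)
        assert (E.max(axis=1) / E.sum(axis=1)).min() > 0.8

    def test_row_sums_equal_type_counts(self, small_grid_dataset):
        ds = small_grid_dataset
        graph = igan.build_neighbor_graph(ds)
        me = simple_microenvironments(graph, ds.cell_type, n_env=3, seed=1)
        for i, t in enumerate(me.cell_types):
            assert me.E[i].sum() == (ds.cell_type == t).sum()

    def test_single_type_collapses(self):
        coords = np.column_stack([np.arange(6.0), np.zeros(6)])
        graph = igan.build_neighbor_graph(coords, threshold=1.0)
        ct = np.array(["A"] * 6, dtype=object)
        me = simple_microenvironments(graph, ct, n_env=2, seed=0)
        assert (me.E.sum(axis=0) > 0).sum() == 1  # identical compositions, one env

    def test_too_many_environments_fatal(self):
        coords = np.column_stack([np.arange(3.0), np.zeros(3)])
        graph = igan.build_neighbor_graph(coords, threshold=1.0)
        with pytest.raises(ValueError, match="n_env"):
            simple_microenvironments(graph, np.array(["A"] * 3, dtype=object), n_env=5)


class TestNMFPatterns:
    def test_exact_rank_one_recovery(self):
        M = np.outer([1.0, 2.0, 3.0], [4.0, 0.5, 2.0, 1.0])
        d = nmf_patterns(M, k=1, seed=0)
        assert d.reconstruction_error < 1e-6

    def test_error_nests_with_rank(self, rng):
        M = rng.random((6, 5))
        errs = rank_scan(M, ks=[1, 2, 3, 4, 5], seed=0)["reconstruction_error"]
        assert (np.diff(errs) <= 1e-8).all()

    def test_seed_determinism(self, rng):
        M = rng.random((6, 5))
        d1, d2 = nmf_patterns(M, k=3, seed=42), nmf_patterns(M, k=3, seed=42)
        np.testing.assert_array_equal(d1.W, d2.W)
        np.testing.assert_array_equal(d1.Hb, d2.Hb)

    def test_zero_matrix_fatal(self):
        with pytest.raises(ValueError, match="zero"):
            nmf_patterns(np.zeros((3, 3)), k=1)

    def test_rank_above_dims_fatal(self, rng):
        with pytest.raises(ValueError, match="rank"):
            nmf_patterns(rng.random((3, 4)), k=4)


class TestWeightedKL:
    def test_identical_decompositions_score_zero(self, rng):
        d = random_decomp(rng, 5, 3, 7)
        score = weighted_kl(d, d, cell_counts=np.arange(1, 6))
        assert score.value == pytest.approx(0.0, abs=1e-9)

    def test_pattern_permutation_absorbed_by_alignment(self, rng):
        dE = random_decomp(rng, 5, 3, 7)
        perm = [2, 0, 1]
        dC = PatternDecomposition(W=dE.W[:, perm], Hb=dE.Hb[perm], rank=3, seed=0,
                                  reconstruction_error=0.0, row_names=dE.row_names)
        score = weighted_kl(dE, dC, cell_counts=np.ones(5))
        assert score.value == pytest.approx(0.0, abs=1e-9)

    def test_two_pattern_swap_example(self):
        Ea = np.array([[0.9, 0.1], [0.1, 0.9]])
        Ca = Ea[:, ::-1]
        dE = PatternDecomposition(W=Ea, Hb=np.ones((2, 3)) / 3, rank=2, seed=0,
                                  reconstruction_error=0.0, row_names=["a", "b"])
        dC = PatternDecomposition(W=Ca, Hb=np.ones((2, 3)), rank=2, seed=0,
                                  reconstruction_error=0.0, row_names=["a", "b"])
        score = weighted_kl(dE, dC, cell_counts=np.ones(2))
        assert score.value == pytest.approx(0.0, abs=1e-9)
        assert score.permutation == (1, 0)

    def test_single_type_direct_arithmetic(self):
        # one cell type: KL_w = sum_j wp_j * p_j log(p_j / q_j) with wp = (1,1)
        dE = PatternDecomposition(W=np.array([[0.9, 0.1]]), Hb=np.eye(2), rank=2,
                                  seed=0, reconstruction_error=0.0, row_names=["a"])
        dC = PatternDecomposition(W=np.array([[0.5, 0.5]]), Hb=np.eye(2), rank=2,
                                  seed=0, reconstruction_error=0.0, row_names=["a"])
        expected = 0.9 * np.log(0.9 / 0.5) + 0.1 * np.log(0.1 / 0.5)
        score = weighted_kl(dE, dC, cell_counts=np.array([10.0]))
        assert score.value == pytest.approx(expected, rel=1e-9)

    def test_assignment_alignment_matches_exhaustive(self, rng):
        from igan.patterns import _alignment_costs, _normalize_rows
        for _ in range(20):
            dE = random_decomp(rng, 6, 4, 5)
            dC = random_decomp(rng, 6, 4, 5)
            wc = rng.random(6); wc /= wc.sum()
            wp = dE.Hb.sum(axis=1)
            cost = _alignment_costs(_normalize_rows(dE.W), _normalize_rows(dC.W), wc, wp)
            best = min(cost[np.arange(4), list(p)].sum()
                       for p in itertools.permutations(range(4)))
            got = weighted_kl(dE, dC, cell_counts=wc)
            assert got.value == pytest.approx(best, rel=1e-9)

    def test_rank_mismatch_fatal(self, rng):
        with pytest.raises(ValueError, match="rank"):
            weighted_kl(random_decomp(rng, 4, 2, 5), random_decomp(rng, 4, 3, 5),
                        np.ones(4))


class TestBenchmark:
    def test_planted_method_beats_shuffled(self, rng):
        # overlapping staircase type profiles: identifiable against any row
        # permutation (pure block-diagonal profiles would not be, since the
        # pattern-alignment step can absorb a row shuffle there)
        P = np.array([[4, 2, 1, 0], [1, 4, 2, 0], [0, 1, 4, 2], [0, 0, 1, 4]], float)
        envs, counts, true_d, shuf_d = [], [], [], []
        for d in range(6):
            E = P * rng.integers(20, 40) + rng.random((4, 4))
            C = P * 0.3 + 0.05 * rng.random((4, 4))
            perm = rng.permutation(4)
            while (perm == np.arange(4)).all():
                perm = rng.permutation(4)
            envs.append(nmf_patterns(E, k=2, seed=d))
            counts.append(E.sum(axis=1))
            true_d.append(nmf_patterns(C, k=2, seed=d))
            shuf_d.append(nmf_patterns(C[perm], k=2, seed=d))
        scores, tests = benchmark(envs, counts, {"true": true_d, "shuffled": shuf_d})
        piv = scores.pivot(index="dataset", columns="method", values="kl_w")
        assert (piv["true"] < piv["shuffled"]).all()
        assert tests.loc[0, "wilcoxon_p"] < 0.05

    def test_identical_scores_give_p_one(self, rng):
        envs = [random_decomp(rng, 3, 2, 4) for _ in range(5)]
        counts = [np.ones(3)] * 5
        method = [random_decomp(rng, 3, 2, 4) for _ in range(5)]
        scores, tests = benchmark(envs, counts, {"m1": method, "m2": method})
        assert tests.loc[0, "wilcoxon_p"] == 1.0

    def test_too_few_scores_skips_test(self, rng):
        envs = [random_decomp(rng, 3, 2, 4) for _ in range(3)]
        counts = [np.ones(3)] * 3
        scores, tests = benchmark(envs, counts,
                                  {"m1": [random_decomp(rng, 3, 2, 4) for _ in range(3)],
                                   "m2": [random_decomp(rng, 3, 2, 4) for _ in range(3)]})
        assert np.isnan(tests.loc[0, "wilcoxon_p"])
        assert len(scores) == 6


def test_shuffle_rows_never_identity(rng):
    C = CommMatrix(C=rng.random((4, 3)), cell_types=list("abcd"), ligands=list("xyz"),
                   direction="sending")
    for seed in range(10):
        shuf = shuffle_rows(C, seed=seed)
        assert not np.allclose(shuf.C, C.C)
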