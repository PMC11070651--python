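import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import igan
from igan.association import (
    NeighborhoodCounts,
    PairScatter,
    TooFewPairsError,
    association_statistic,
    critical_joint_count,
    window_counts,
)
from igan.association import test_gene_pair as run_pair_test


def brute_force_counts(x, y, k, b):
    """Independent O(n^2) oracle: w nearest by |value - value_k|, index ties,
    focal forced in."""
    n = len(x)
    w = math.ceil(b * n)

    def window(v):
        order = sorted(range(n), key=lambda j: (abs(v[j] - v[k]), j))
        sel = order[:w]
        if k not in sel:
            sel = sel[:-1] + [k]
        return set(sel)

    wx, wy = window(x), window(y)
    return len(wx), len(wy), len(wx & wy)


class TestWindowCounts:
    def test_symmetric_scatter(self):
        sc = PairScatter(x=[1, 2, 3, 4, 5], y=[1, 2, 3, 4, 5])
        c = window_counts(sc, k=2, b=0.4)
        assert (c.n_x, c.n_y, c.n_xy) == (2, 2, 2)

    def test_anticorrelated_extremes_still_colocalize(self):
        sc = PairScatter(x=[1, 2, 3, 4, 5], y=[5, 4, 3, 2, 1])
        c = window_counts(sc, k=0, b=0.4)
        assert (c.n_x, c.n_y, c.n_xy) == (2, 2, 2)

    def test_full_window(self):
        sc = PairScatter(x=[3, 1, 4, 1, 5], y=[9, 2, 6, 5, 3])
        c = window_counts(sc, k=1, b=0.999)
        assert (c.n_x, c.n_y, c.n_xy) == (5, 5, 5)

    def test_too_few_pairs(self):
        with pytest.raises(TooFewPairsError):
            window_counts(PairScatter(x=[1, 2], y=[1, 2]), k=0, b=0.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=3, max_value=60),
           st.sampled_from([0.05, 0.1, 0.3, 0.7]))
    def test_matches_brute_force_oracle(self, seed, n, b):
        rng = np.random.default_rng(seed)
        # integer values provoke heavy ties; floats the generic path
        x = rng.integers(0, 4, size=n).astype(float) if seed % 2 else rng.random(n)
        y = rng.integers(0, 4, size=n).astype(float) if seed % 3 else rng.random(n)
        sc = PairScatter(x=x, y=y)
        for k in range(0, n, max(1, n // 5)):
            c = window_counts(sc, k=k, b=b)
            assert (c.n_x, c.n_y, c.n_xy) == brute_force_counts(x, y, k, b)


class TestAssociationStatistic:
    def test_known_value(self):
        rho = association_statistic(NeighborhoodCounts(0, 10, 10, 10), n=100)
        assert rho == pytest.approx(9.9499, abs=1e-4)
        direct = (10 / 100 - 0.01) / math.sqrt(10 * 10 * 90 * 90 / (100 ** 4 * 99))
        assert rho == pytest.approx(direct, abs=1e-12)

    def test_independence_point_is_zero(self):
        # n_xy = n_x n_y / n exactly
        rho = association_statistic(NeighborhoodCounts(0, 20, 10, 4), n=50)
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_depleted_joint_count_is_negative(self):
        assert association_statistic(NeighborhoodCounts(0, 5, 5, 0), n=50) < 0

    def test_degenerate_windows_are_nan(self):
        assert math.isnan(association_statistic(NeighborhoodCounts(0, 50, 5, 5), n=50))
        assert math.isnan(association_statistic(NeighborhoodCounts(0, 0, 5, 0), n=50))


class TestCriticalCount:
    def test_normal_rule_equals_rho_threshold(self):
        n, w, alpha = 200, 20, 0.01
        crit = critical_joint_count(n, w, w, alpha, null="normal")
        z = norm.ppf(1 - alpha)
        for nxy in range(w + 1):
            rho = association_statistic(NeighborhoodCounts(0, w, w, nxy), n)
            assert (nxy >= crit) == (rho > z)

    def test_exact_rule_controls_level(self):
        from scipy.stats import hypergeom
        n, w = 500, 50
        crit = critical_joint_count(n, w, w, 0.01, null="exact")
        size = hypergeom.sf(crit - 1 - 1, n - 1, w - 1, w - 1)
        assert size <= 0.01
        assert hypergeom.sf(crit - 2 - 1, n - 1, w - 1, w - 1) > 0.01  # smallest such

    def test_unattainable_threshold(self):
        assert critical_joint_count(10, 2, 2, 1e-6) == 11


class TestTestGenePair:
    def test_rank_correlated_signal_detected(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = x + 0.1 * rng.standard_normal(n)  # near-perfect rank correlation
        h = run_pair_test(PairScatter(x, y), b=0.1, alpha=0.01)
        assert h.mean() > 10 * 0.01

    def test_constant_marginal_gives_all_zeros(self, rng):
        n = 50
        h = run_pair_test(PairScatter(np.full(n, 3.0), rng.random(n)))
        assert not h.any()

    def test_permutation_equivariance(self, rng):
        n = 80
        x, y = rng.random(n), rng.random(n)
        h = run_pair_test(PairScatter(x, y), b=0.2, alpha=0.05)
        perm = rng.permutation(n)
        h_perm = run_pair_test(PairScatter(x[perm], y[perm]), b=0.2, alpha=0.05)
        np.testing.assert_array_equal(h[perm], h_perm)

    def test_null_rate_within_monte_carlo_band(self, rng):
        n, alpha, reps = 500, 0.01, 10
        rates = [
            run_pair_test(PairScatter(rng.random(n), rng.random(n)), 0.1, alpha).mean()
            for _ in range(reps)
        ]
        rate = float(np.mean(rates))
        assert rate == pytest.approx(alpha, abs=3 * math.sqrt(alpha * (1 - alpha) / n))

    def test_monotone_negative_association_also_colocalizes(self, rng):
        # windows measure local co-occupancy, so any monotone relation -- with
        # either sign -- concentrates both windows on the same pairs
        n = 300
        x = rng.standard_normal(n)
        y = -x + 0.1 * rng.standard_normal(n)
        one = run_pair_test(PairScatter(x, y), alternative="greater")
        two = run_pair_test(PairScatter(x, y), alternative="two-sided")
        assert one.mean() > 0.5
        assert two.sum() <= one.sum()  # two-sided splits alpha


class TestBuildNetworks:
    def test_matches_standalone_gene_pair_tests(self, boundary_run):
        ds, nets = boundary_run["ds"], boundary_run["nets"]
        block = nets.blocks[("A", "B")]
        dsn = igan.normalize(ds)
        X = dsn.expr_dense()
        gi = {g: i for i, g in enumerate(ds.gene_ids)}
        counts = block.edge_count_matrix()
        for si, src in enumerate(nets.source_genes):
            for tj, tgt in enumerate([nets.target_genes[0], nets.target_genes[5]]):
                sc = PairScatter(X[gi[src], block.a], X[gi[tgt], block.b])
                h = run_pair_test(sc, b=0.1, alpha=0.001)
                j = nets.target_genes.index(tgt)
                assert counts[si, j] == h.sum()

    def test_planted_coupling_dominates(self, boundary_run):
        nets = boundary_run["nets"]
        counts = nets.blocks[("A", "B")].edge_count_matrix()
        i = nets.source_genes.index("g000")
        j = nets.target_genes.index("g005")
        planted = counts[i, j]
        rest = np.delete(counts.ravel(), i * len(nets.target_genes) + j)
        assert planted > 0.01 * nets.blocks[("A", "B")].n
        assert planted > rest.max()

    def test_directionality(self, boundary_run):
        nets = boundary_run["nets"]
        fwd = nets.blocks[("A", "B")].edge_count_matrix()
        rev = nets.blocks[("B", "A")].edge_count_matrix()
        assert not np.array_equal(fwd, rev)

    def test_constant_gene_yields_empty_row(self, small_grid_dataset):
        ds = small_grid_dataset
        X = ds.expr_dense()
        X[0] = 7.0  # constant source gene
        ds2 = igan.SpatialDataset(expr=X, gene_ids=ds.gene_ids, cell_ids=ds.cell_ids,
                                  coords=ds.coords, cell_type=ds.cell_type)
        graph = igan.build_neighbor_graph(ds2)
        pairs = igan.collect_cell_pairs(graph, ds2.cell_type, "X", "Y")
        nets = igan.build_networks(ds2, pairs, [ds.gene_ids[0]], list(ds.gene_ids),
                                   alpha=0.05)
        assert nets.blocks[("X", "Y")].H.sum() == 0

    def test_min_pairs_skips_small_blocks(self, small_grid_dataset, caplog):
        ds = small_grid_dataset
        graph = igan.build_neighbor_graph(ds)
        pairs = igan.collect_cell_pairs(graph, ds.cell_type, "X", "Y")
        with caplog.at_level("WARNING"):
            nets = igan.build_networks(ds, pairs, [ds.gene_ids[0]], [ds.gene_ids[1]],
                                       min_pairs=10 ** 6)
        assert not nets.blocks and nets.skipped[("X", "Y")] == pairs.n

    def test_round_trip_through_csv(self, boundary_run, tmp_path):
        from igan.association import read_networks, write_networks
        nets = boundary_run["nets"]
        write_networks(nets, tmp_path / "net.csv")
        back = read_networks(tmp_path / "net.csv")
        assert back.source_genes == nets.source_genes
        assert back.target_genes == nets.target_genes
        for key, block in nets.blocks.items():
            np.testing.assert_array_equal(back.blocks[key].a, block.a)
            assert (back.blocks[key].H != block.H).nnz == 0
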