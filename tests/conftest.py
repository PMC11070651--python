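import numpy as np
import pytest

import igan


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def boundary_run():
    """Boundary fixture with one planted coupling, fully processed once."""
    cfg = igan.preset_config("boundary", seed=5)
    ds, truth = igan.simulate(cfg)
    graph = igan.build_neighbor_graph(ds)
    pair_sets = igan.all_cell_pair_sets(graph, ds.cell_type)
    nets = igan.build_networks(
        ds, pair_sets, source_genes=["g000", "g001", "g002"],
        target_genes=list(ds.gene_ids), b=0.1, alpha=0.001,
    )
    return dict(cfg=cfg, ds=ds, truth=truth, graph=graph, pair_sets=pair_sets, nets=nets)


@pytest.fixture()
def small_grid_dataset(rng):
    """6x6 unit grid, two interleaved types, random NB counts, 8 genes."""
    cfg = igan.SimConfig(layout="checkerboard", shape=(6, 6), types=("X", "Y"),
                         n_genes=8, couplings=(), seed=123)
    ds, _ = igan.simulate(cfg)
    return ds
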