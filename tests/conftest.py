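import numpy as np
import pandas as pd
import pytest

from gipni import datagen, io as gio, perturbation


@pytest.fixture(scope="session")
def default_sim():
    """The default-condition bulk simulation (seed 17); treat as read-only."""
    cfg = datagen.SimulationConfig()
    net = datagen.make_toy_network(cfg.n_genes, cfg.n_edges, cfg.seed)
    cohorts, surv, truth = datagen.simulate_bulk(cfg, net)
    return cfg, net, cohorts, surv, truth


@pytest.fixture(scope="session")
def default_epm(default_sim):
    """Edge perturbation matrix of cohort 1 against the normal reference."""
    _cfg, net, cohorts, _surv, _truth = default_sim
    return perturbation.perturbation_matrix(cohorts[1], cohorts[0], net)


@pytest.fixture(scope="session")
def sc_sim():
    """Toy single-cell experiment with 500 cells per epithelial cluster."""
    return datagen.simulate_single_cell(n_cells_per_cluster=500, seed=17)


@pytest.fixture(scope="session")
def prognostic_sim():
    """Two cohorts whose hazard depends linearly on 5 planted genes."""
    cohorts, surv, betas = datagen.simulate_prognostic(seed=17)
    ems = {c.cohort_id: gio.zscore(c) for c in cohorts}
    svs = {cid: surv.subset(em.sample_ids) for cid, em in ems.items()}
    return ems, svs, betas


@pytest.fixture()
def small_expression():
    rng = np.random.default_rng(3)
    vals = pd.DataFrame(
        rng.normal(size=(50, 20)),
        index=[f"g{i:02d}" for i in range(50)],
        columns=[f"s{j:02d}" for j in range(20)],
    )
    return gio.ExpressionMatrix(values=vals, cohort_id="toy")
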