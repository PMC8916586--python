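import numpy as np
import pandas as pd
import pytest

import lncpairs as lp


@pytest.fixture
def tiny_cohort():
    """Six genes (3 lncRNA / 3 mRNA), four tumor + three normal samples."""
    genes = ["LNC_A", "LNC_B", "LNC_C", "MR_X", "MR_Y", "MR_Z"]
    samples = [f"T{i}" for i in range(4)] + [f"N{i}" for i in range(3)]
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(6, 7)), index=genes, columns=samples
    )
    gene_type = pd.Series(["lncRNA"] * 3 + ["mRNA"] * 3, index=genes)
    group = pd.Series(["tumor"] * 4 + ["normal"] * 3, index=samples)
    return lp.ExpressionCohort("tiny", values, gene_type, group)


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down study conditions for fast unit tests."""
    return lp.SimulationConfig(
        n_lncrna=40,
        n_mrna=120,
        n_pathway_genes=20,
        n_true_pdls=8,
        n_planted_pairs=3,
        n_tumor=[150, 130, 110],
        n_normal=[30, 25, 20],
    )


@pytest.fixture(scope="session")
def small_sim(small_sim_config):
    return lp.simulate_cohorts(small_sim_config, seed=2024)


@pytest.fixture(scope="session")
def small_pipeline(small_sim, small_sim_config):
    cohorts, survs, truth = small_sim
    cfg = lp.PipelineConfig(n_permutations=199, n_bootstrap=200, rng_seed=5)
    result = lp.run_full_pipeline(
        cohorts, survs, lp.pathway_gene_set(small_sim_config), cfg
    )
    return result, truth, cfg


def random_monotone_transform(rng, lo, hi, n_knots=12):
    """A random strictly increasing piecewise-linear map on [lo, hi]."""
    knots = np.linspace(lo - 1e-9, hi + 1e-9, n_knots)
    incr = rng.uniform(0.05, 2.0, size=n_knots - 1)
    vals = np.concatenate([[rng.uniform(-3, 3)], incr]).cumsum()

    def fn(x):
        return np.interp(x, knots, vals)

    return fn
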