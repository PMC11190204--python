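import numpy as np
import pandas as pd
import pytest

import chronospec as cs


@pytest.fixture(scope="session")
def grid_times():
    """The standard 6-timepoint x 4-replicate circadian sampling grid."""
    return np.repeat(np.arange(0, 24, 4.0), 4)


@pytest.fixture()
def small_experiment():
    """3 genes x 4 samples, one tissue, two timepoints x two replicates."""
    values = pd.DataFrame(
        [[10.0, 12.0, 9.0, 11.0], [0.0, 5.0, 4.0, 6.0], [100.0, 90.0, 110.0, 95.0]],
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    samples = pd.DataFrame(
        {
            "tissue": ["liver"] * 4,
            "ct": [0.0, 0.0, 12.0, 12.0],
            "replicate": [1, 2, 1, 2],
            "condition": ["control"] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return cs.ExpressionExperiment(values, samples)


@pytest.fixture(scope="session")
def standard_sim():
    """The default planted simulation (2 tissues x 6 CT x 4 reps)."""
    cfg = cs.SimulationConfig(n_genes=1000, seed=3, nb_dispersion=0.05)
    exp, truth = cs.simulate_experiment(cfg)
    return exp, truth


@pytest.fixture(scope="session")
def standard_tpm(standard_sim):
    exp, truth = standard_sim
    lengths = {g: 1000 for g in exp.gene_ids}
    return cs.filter_expressed(cs.counts_to_tpm(exp, lengths)), truth
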