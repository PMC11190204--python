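"""Shared paths and the study configuration for the analysis scripts."""

from pathlib import Path

import chronospec as cs

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

SEED = 1
GENE_LENGTH_BP = 1000

# the emulated study design: 2 organs x 6 circadian times x 4 replicates
STUDY_CONFIG = cs.SimulationConfig(
    n_genes=2000,
    seed=SEED,
    nb_dispersion=0.05,
)


def load_experiment():
    exp = cs.read_experiment(DATA / "counts.tsv", DATA / "samples.tsv")
    import pandas as pd

    truth = pd.read_csv(DATA / "truth.tsv", sep="\t", index_col=0)
    return exp, truth


def load_tpm():
    exp, truth = load_experiment()
    lengths = {g: GENE_LENGTH_BP for g in exp.gene_ids}
    tpm = cs.filter_expressed(cs.counts_to_tpm(exp, lengths))
    return exp, tpm, truth
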