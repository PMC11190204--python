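"""Fisher-exact enrichment of the DEG classes against gene sets.

Builds a planted "aging-like" set biased toward circadian-affected DEGs
(emulating an aging/longevity collection) and a size-matched random
set, then tests every class x set pair over the expressed background.
Writes enrichment.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, RESULTS, SEED, load_tpm

import chronospec as cs


def main():
    exp, tpm, truth = load_tpm()
    cls = pd.read_csv(RESULTS / "classification.tsv", sep="\t", index_col=0)
    background = list(tpm.gene_ids)
    queries = cs.GeneSetCollection.from_dict(
        {c: cls.index[cls["class"] == c] for c in cs.DEG_CLASSES}
    )

    rng = np.random.default_rng(SEED)
    circ = cls.index[cls["class"] == "circadian_affected"].to_numpy()
    rest = cls.index[cls["class"] != "circadian_affected"].to_numpy()
    n_from_circ = min(90, len(circ))
    aging_like = np.concatenate(
        [
            rng.choice(circ, n_from_circ, replace=False),
            rng.choice(rest, 30, replace=False),
        ]
    )
    random_set = rng.choice(np.array(background), len(aging_like), replace=False)
    targets = cs.GeneSetCollection.from_dict(
        {"aging_like": aging_like, "random": random_set}
    ).restrict(background)

    table = cs.enrich_matrix(queries, targets, background)
    table.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    for _, r in table.iterrows():
        print(f"{r['query']:>18} x {r['target']:<10} OR {r['odds_ratio']:6.2f} "
              f"q {r['q']:.2g} -> {r['direction']}")


if __name__ == "__main__":
    main()
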