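"""The DEG trichotomy: circadian-affected, constitutive, temporal.

A differentially expressed gene (DEG: significant at >= 1 timepoint) is

* **circadian_affected** if it is rhythmic (q < 0.05) in either tissue,
  or is a target of a core clock transcription factor (BMAL1, CLOCK,
  PERs, CRYs — supplied as a gene-set collection);
* otherwise **constitutive** if it is significant at every timepoint;
* otherwise **temporal**.

Non-DEGs are labelled ``non_deg``. The three DEG classes are pairwise
disjoint and exhaust the DEG set by construction; this partition is
re-asserted on every run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DEResult
from .experiment import GeneSetCollection

__all__ = ["classify_degs", "class_summary", "DEG_CLASSES"]

DEG_CLASSES = ("circadian_affected", "constitutive", "temporal")


def classify_degs(
    de: DEResult,
    rhythm_a: pd.DataFrame,
    rhythm_b: pd.DataFrame,
    tf_targets: GeneSetCollection | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assign every gene to a class with its evidence record.

    All inputs must cover the same gene universe (the expressed set); a
    gene in the DE table missing from a rhythm table is fatal.
    Returns a per-gene table with columns ``class, rhythmic_in_a,
    rhythmic_in_b, is_tf_target, n_de_timepoints, is_deg``.
    """
    genes = de.summary.index
    for name, tab in (("A", rhythm_a), ("B", rhythm_b)):
        missing = genes.difference(tab.index)
        if len(missing):
            raise ValueError(
                f"genes missing from rhythm table {name}: {list(missing[:10])}"
            )
    rhy_a = (rhythm_a.loc[genes, "q"] < q_threshold).to_numpy()
    rhy_b = (rhythm_b.loc[genes, "q"] < q_threshold).to_numpy()
    targets = tf_targets.union() if tf_targets is not None else frozenset()
    is_target = genes.isin(targets)
    is_deg = de.summary["is_deg"].to_numpy()
    de_all = de.summary["de_at_all_timepoints"].to_numpy()

    circadian = is_deg & (rhy_a | rhy_b | is_target)
    constitutive = is_deg & ~circadian & de_all
    temporal = is_deg & ~circadian & ~de_all
    cls = np.where(circadian, "circadian_affected",
          np.where(constitutive, "constitutive",
          np.where(temporal, "temporal", "non_deg")))

    out = pd.DataFrame(
        {
            "class": cls,
            "rhythmic_in_a": rhy_a,
            "rhythmic_in_b": rhy_b,
            "is_tf_target": is_target,
            "n_de_timepoints": de.summary["n_de_timepoints"].to_numpy(),
            "is_deg": is_deg,
        },
        index=genes,
    )
    _assert_partition(out)
    return out


def _assert_partition(cls: pd.DataFrame) -> None:
    """The three DEG classes must partition the DEG set exactly."""
    is_deg = cls["is_deg"]
    in_classes = cls["class"].isin(DEG_CLASSES)
    if not (in_classes == is_deg).all():
        raise AssertionError("DEG classes do not partition the DEG set")


def class_summary(cls: pd.DataFrame, exp) -> dict:
    """Per-class counts/proportions and expression-level comparison.

    Expression level is the per-gene median TPM across samples; classes
    are compared pairwise by two-sided Wilcoxon rank-sum. Classes with
    fewer than 2 genes are skipped with a warning.
    """
    counts = cls.loc[cls["is_deg"], "class"].value_counts().reindex(DEG_CLASSES, fill_value=0)
    props = counts / counts.sum() if counts.sum() else counts.astype(float)

    med_tpm = exp.values.median(axis=1)
    levels = {c: med_tpm.loc[cls.index[cls["class"] == c]] for c in DEG_CLASSES}
    medians = {c: float(np.median(v)) if len(v) else np.nan for c, v in levels.items()}
    tests = {}
    names = list(DEG_CLASSES)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(levels[a]) < 2 or len(levels[b]) < 2:
                warnings.warn(f"class comparison {a} vs {b} skipped: too few genes")
                continue
            stat = stats.mannwhitneyu(levels[a], levels[b], alternative="two-sided")
            tests[(a, b)] = float(stat.pvalue)
    return {
        "counts": counts,
        "proportions": props,
        "median_tpm": medians,
        "wilcoxon_p": tests,
    }
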