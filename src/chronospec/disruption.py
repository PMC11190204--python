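"""Amplitude-change effect sizes between control and disrupted conditions.

Circadian disruption (sleep deprivation, inverted feeding) is quantified
per gene as the change in fitted cosinor amplitude between the control
and disrupted arms; gene sets (aging/longevity collections, DEG classes)
are compared to their complement by a two-sided Wilcoxon rank-sum on the
absolute amplitude change, optionally with downsampling to equalize
group sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import GeneSetCollection

__all__ = ["amplitude_change", "compare_sets"]


def amplitude_change(
    rhythm_ctrl: pd.DataFrame,
    rhythm_dis: pd.DataFrame,
    relative: bool = False,
) -> pd.DataFrame:
    """Per-gene amplitude change between two rhythm tables.

    ``delta = amp_control - amp_disrupted``; ``relative=True`` divides
    each amplitude by its mesor first (scale-free option). The two
    tables must cover the same gene universe.
    """
    if not rhythm_ctrl.index.equals(rhythm_dis.index):
        only_c = rhythm_ctrl.index.difference(rhythm_dis.index)
        only_d = rhythm_dis.index.difference(rhythm_ctrl.index)
        raise ValueError(
            f"gene universes differ: control-only={list(only_c[:5])}, "
            f"disrupted-only={list(only_d[:5])}"
        )
    amp_c = rhythm_ctrl["amp"].to_numpy(dtype=float)
    amp_d = rhythm_dis["amp"].to_numpy(dtype=float)
    if relative:
        amp_c = amp_c / np.maximum(rhythm_ctrl["mesor"].to_numpy(dtype=float), 1e-12)
        amp_d = amp_d / np.maximum(rhythm_dis["mesor"].to_numpy(dtype=float), 1e-12)
    delta = amp_c - amp_d
    return pd.DataFrame(
        {
            "amp_control": amp_c,
            "amp_disrupted": amp_d,
            "delta": delta,
            "abs_delta": np.abs(delta),
        },
        index=rhythm_ctrl.index,
    )


def compare_sets(
    ac: pd.DataFrame,
    sets: GeneSetCollection,
    downsample: bool = False,
    seed: int = 0,
    rounds: int = 25,
    rhythmic_only: pd.Index | None = None,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Wilcoxon rank-sum of |amplitude change|, set vs complement.

    With ``downsample`` the larger group is randomly subsampled (seeded)
    to the smaller's size and the test repeated over ``rounds`` rounds;
    the median p is reported. ``rhythmic_only`` optionally restricts the
    universe to a gene index (e.g. rhythm-significant genes). Sets
    smaller than ``min_set_size`` are skipped with a warning.
    """
    universe = ac.index if rhythmic_only is None else ac.index.intersection(rhythmic_only)
    vals = ac.loc[universe, "abs_delta"]
    rng = np.random.default_rng(seed)
    rows = []
    for name in sets:
        members = universe.intersection(sets[name])
        if len(members) < min_set_size:
            warnings.warn(f"set {name!r} has {len(members)} genes in universe; skipped")
            continue
        in_set = vals.loc[members].to_numpy()
        out_set = vals.drop(members).to_numpy()
        if downsample:
            k = min(len(in_set), len(out_set))
            ps = []
            for _ in range(rounds):
                a = rng.choice(in_set, size=k, replace=False) if len(in_set) > k else in_set
                b = rng.choice(out_set, size=k, replace=False) if len(out_set) > k else out_set
                ps.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            p = float(np.median(ps))
        else:
            p = float(stats.mannwhitneyu(in_set, out_set, alternative="two-sided").pvalue)
        rows.append(
            {
                "set": name,
                "n_set": len(in_set),
                "n_complement": len(out_set),
                "median_abs_delta_set": float(np.median(in_set)),
                "mean_abs_delta_set": float(np.mean(in_set)),
                "median_abs_delta_complement": float(np.median(out_set)),
                "mean_abs_delta_complement": float(np.mean(out_set)),
                "wilcoxon_p": p,
                "downsampled": downsample,
            }
        )
    return pd.DataFrame(rows)
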