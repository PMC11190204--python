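"""Ground-truthed synthetic multi-tissue circadian count experiments.

The generator emulates the design of a two-organ circadian profiling
study: 2 tissues x 6 circadian timepoints (every 4 h in constant
darkness) x 4 replicates, negative-binomial counts. Planted structure:

* a rhythmic fraction per tissue with 24 h period — mean
  ``mu = B * (1 + A cos(2*pi*(ct - phase)/24))`` with relative amplitude
  A < 1 (raised cosine);
* tissue-specific genes whose baseline ``B`` is multiplied by a fold
  factor in their tissue at every timepoint (constitutive DE);
* temporal-DE genes whose fold factor applies only at a random subset of
  timepoints;
* clock-TF target labels correlated with rhythmicity;
* coding/lncRNA biotypes with genomic coordinates, a fraction of lncRNAs
  placed within 50 kb of a rhythmic coding partner whose phase they
  inherit (to exercise the neighbor-phase statistic).

Everything is deterministic given the seed; the disrupted arm of a
paired simulation uses an RNG stream keyed by (seed, arm) so the two
arms share baselines, phases and labels and differ only in the planted
amplitude scaling plus sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .experiment import ExpressionExperiment, GeneSetCollection

__all__ = ["SimulationConfig", "simulate_experiment", "simulate_disruption_pair"]


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    tissues: tuple[str, ...] = ("liver", "kidney")
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_replicates: int = 4
    condition: str = "control"
    # planted fractions
    frac_rhythmic: float = 0.20          # per tissue
    frac_tissue_specific: float = 0.15   # constitutive DE candidates
    frac_temporal: float = 0.15          # DE at a timepoint subset
    rel_amplitude: float = 0.5           # A, fraction of baseline mean
    tissue_fold: float = 8.0
    temporal_fold: float = 8.0
    # baseline counts: B ~ LogNormal(mu, sigma) (natural log)
    baseline_logmean_mu: float = 4.0
    baseline_logmean_sigma: float = 1.0
    nb_dispersion: float = 0.1           # var = mu + alpha*mu^2
    # labels
    frac_tf_target_given_rhythmic: float = 0.5
    frac_tf_target_given_nonrhythmic: float = 0.05
    lncRNA_fraction: float = 0.15
    lnc_near_coding_frac: float = 0.6    # lncRNAs placed <50 kb from a coding partner
    lnc_phase_jitter_h: float = 1.0      # sd of inherited-phase jitter, hours
    # phase structure: None = phases uniform on [0,24); an integer k draws
    # phases from k evenly spaced cluster centers with Gaussian jitter,
    # emulating the dawn/dusk phase waves of real circadian transcriptomes
    # (needed for discrete co-expression modules to exist at all)
    phase_clusters: int | None = None
    phase_cluster_jitter_h: float = 1.0
    # coordinates
    gene_length_bp: int = 1000           # fixed so counts ~ TPM up to scale
    cluster_spacing_bp: int = 200_000
    neighbor_offset_bp: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_rhythmic", "frac_tissue_specific", "frac_temporal",
                     "frac_tf_target_given_rhythmic", "frac_tf_target_given_nonrhythmic",
                     "lncRNA_fraction", "lnc_near_coding_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rel_amplitude >= 1.0:
            raise ValueError("rel_amplitude must be < 1 (mean would go negative)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(tp) <= 0) or tp[0] < 0 or tp[-1] >= 24:
            raise ValueError("timepoints must be strictly increasing within [0, 24)")


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plant per-gene ground truth: baselines, rhythm flags, DE structure,
    biotypes, TF-target labels and genomic coordinates."""
    G = cfg.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(G)])
    n_tis = len(cfg.tissues)

    baseline = np.exp(rng.normal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sigma, G))
    rhythmic = rng.random((G, n_tis)) < cfg.frac_rhythmic  # per tissue
    if cfg.phase_clusters:
        centers = np.linspace(0, 24, cfg.phase_clusters, endpoint=False)
        phase = (
            rng.choice(centers, G) + rng.normal(0, cfg.phase_cluster_jitter_h, G)
        ) % 24
    else:
        phase = rng.uniform(0, 24, G)
    amp = np.where(rhythmic.any(axis=1), cfg.rel_amplitude, 0.0)

    # disjoint DE groups: tissue-specific (all timepoints) vs temporal
    u = rng.random(G)
    is_specific = u < cfg.frac_tissue_specific
    is_temporal = (u >= cfg.frac_tissue_specific) & (
        u < cfg.frac_tissue_specific + cfg.frac_temporal
    )
    de_tissue = rng.integers(0, n_tis, G)  # tissue with the elevated baseline
    n_tp = len(cfg.timepoints)
    temporal_mask = np.zeros((G, n_tp), dtype=bool)
    for g in np.flatnonzero(is_temporal):
        k = rng.integers(1, max(2, n_tp // 2))  # 1..2 of 6 timepoints
        temporal_mask[g, rng.choice(n_tp, size=k, replace=False)] = True

    is_tf_target = np.where(
        rhythmic.any(axis=1),
        rng.random(G) < cfg.frac_tf_target_given_rhythmic,
        rng.random(G) < cfg.frac_tf_target_given_nonrhythmic,
    )

    biotype = np.where(rng.random(G) < cfg.lncRNA_fraction, "lncRNA", "coding")

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline": baseline,
            "true_phase": phase,
            "true_rel_amplitude": amp,
            "is_tf_target": is_tf_target,
            "biotype": biotype,
            "is_specific": is_specific,
            "is_temporal": is_temporal,
            "de_tissue": [cfg.tissues[i] for i in de_tissue],
        }
    ).set_index("gene_id", drop=False)
    for j, tis in enumerate(cfg.tissues):
        truth[f"is_rhythmic_{tis}"] = rhythmic[:, j]
    for j, ct in enumerate(cfg.timepoints):
        truth[f"temporal_de_CT{int(ct)}"] = temporal_mask[:, j]

    _place_coordinates(cfg, rng, truth)
    _assign_true_class(cfg, truth)
    return truth


def _place_coordinates(cfg: SimulationConfig, rng: np.random.Generator, truth: pd.DataFrame) -> None:
    """Lay genes on one chromosome; a fraction of lncRNAs sit within 50 kb
    of a coding partner and, when that partner is rhythmic, inherit its
    phase up to jitter."""
    G = len(truth)
    start = np.arange(G, dtype=int) * cfg.cluster_spacing_bp + 10_000
    end = start + cfg.gene_length_bp
    strand = np.where(rng.random(G) < 0.5, "+", "-")
    truth["chrom"] = "chr1"
    truth["start"] = start
    truth["end"] = end
    truth["strand"] = strand

    lnc_idx = np.flatnonzero((truth["biotype"] == "lncRNA").to_numpy())
    cod_idx = np.flatnonzero((truth["biotype"] == "coding").to_numpy())
    if len(lnc_idx) == 0 or len(cod_idx) == 0:
        return
    rhythmic_any = truth[[f"is_rhythmic_{t}" for t in cfg.tissues]].any(axis=1).to_numpy()
    rhythmic_cod = cod_idx[rhythmic_any[cod_idx]]
    starts = truth["start"].to_numpy().copy()
    ends = truth["end"].to_numpy().copy()
    phases = truth["true_phase"].to_numpy().copy()
    for g in lnc_idx:
        if rng.random() >= cfg.lnc_near_coding_frac:
            continue
        pool = rhythmic_cod if rhythmic_any[g] and len(rhythmic_cod) else cod_idx
        partner = int(rng.choice(pool))
        offset = int(rng.integers(2_000, cfg.neighbor_offset_bp))
        starts[g] = starts[partner] + offset
        ends[g] = starts[g] + cfg.gene_length_bp
        if rhythmic_any[g] and rhythmic_any[partner]:
            phases[g] = (phases[partner] + rng.normal(0, cfg.lnc_phase_jitter_h)) % 24
    truth["start"] = starts
    truth["end"] = ends
    truth["true_phase"] = phases


def _assign_true_class(cfg: SimulationConfig, truth: pd.DataFrame) -> None:
    rhythmic_any = truth[[f"is_rhythmic_{t}" for t in cfg.tissues]].any(axis=1)
    is_deg = truth["is_specific"] | truth["is_temporal"]
    circ = is_deg & (rhythmic_any | truth["is_tf_target"])
    const = is_deg & ~circ & truth["is_specific"]
    temp = is_deg & ~circ & ~const
    cls = np.where(circ, "circadian_affected",
          np.where(const, "constitutive",
          np.where(temp, "temporal", "non_deg")))
    truth["true_class"] = cls


def _mean_matrix(cfg: SimulationConfig, truth: pd.DataFrame, amp_scale: np.ndarray | None = None):
    """Expected counts per gene x sample plus the sample sheet."""
    G = len(truth)
    records = []
    for tis in cfg.tissues:
        for ct in cfg.timepoints:
            for rep in range(1, cfg.n_replicates + 1):
                records.append(
                    {
                        "sample_id": f"{tis}_CT{int(ct):02d}_R{rep}",
                        "tissue": tis,
                        "ct": float(ct),
                        "replicate": rep,
                        "condition": cfg.condition,
                    }
                )
    sheet = pd.DataFrame(records).set_index("sample_id")

    B = truth["baseline"].to_numpy()
    phase = truth["true_phase"].to_numpy()
    amp = truth["true_rel_amplitude"].to_numpy().copy()
    if amp_scale is not None:
        amp = amp * amp_scale
        if np.any(amp >= 1.0):
            raise ValueError("scaled relative amplitude >= 1 gives negative means")
    tp_index = {float(ct): j for j, ct in enumerate(cfg.timepoints)}
    temporal_cols = truth[[f"temporal_de_CT{int(ct)}" for ct in cfg.timepoints]].to_numpy()

    mu = np.empty((G, len(sheet)))
    for s, (sid, row) in enumerate(sheet.iterrows()):
        tis, ct = row["tissue"], float(row["ct"])
        base = B.copy()
        spec = truth["is_specific"].to_numpy() & (truth["de_tissue"] == tis).to_numpy()
        base = np.where(spec, base * cfg.tissue_fold, base)
        temp_here = (
            truth["is_temporal"].to_numpy()
            & (truth["de_tissue"] == tis).to_numpy()
            & temporal_cols[:, tp_index[ct]]
        )
        base = np.where(temp_here, base * cfg.temporal_fold, base)
        rhythmic_here = truth[f"is_rhythmic_{tis}"].to_numpy()
        a = np.where(rhythmic_here, amp, 0.0)
        mu[:, s] = base * (1.0 + a * np.cos(2 * np.pi * (ct - phase) / 24.0))
    return mu, sheet


def _draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def simulate_experiment(cfg: SimulationConfig):
    """Generate one count experiment plus its ground truth.

    Returns ``(ExpressionExperiment in counts, truth DataFrame)``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_truth(cfg, rng)
    mu, sheet = _mean_matrix(cfg, truth)
    counts = _draw_counts(mu, cfg.nb_dispersion, rng)
    values = pd.DataFrame(counts, index=pd.Index(truth.index, name="gene_id"), columns=sheet.index)
    exp = ExpressionExperiment(values, sheet, unit="counts")
    return exp, truth


def simulate_disruption_pair(
    cfg: SimulationConfig,
    sets: GeneSetCollection,
    factors: dict[str, float],
):
    """Paired control/disrupted experiments sharing all planted structure.

    The disrupted arm's relative amplitudes are scaled, per gene, by the
    factor of the gene set it belongs to (phases and baselines are
    preserved). Each arm draws counts from its own RNG stream keyed by
    (seed, arm). Returns ``(control, disrupted, truth)``.
    """
    for name, f in factors.items():
        if name not in sets:
            raise KeyError(f"unknown gene set {name!r}")
        if f < 0:
            raise ValueError("amplitude factors must be >= 0")
    rng_truth = np.random.default_rng(cfg.seed)
    truth = _draw_truth(cfg, rng_truth)
    unknown = sets.union(list(factors)) - set(truth.index)
    if unknown:
        raise KeyError(f"genes in sets absent from simulation: {sorted(unknown)[:10]}")

    scale = np.ones(len(truth))
    for name, f in factors.items():
        scale[truth.index.isin(sets[name])] = f

    mu_ctrl, sheet = _mean_matrix(cfg, truth)
    mu_dis, _ = _mean_matrix(cfg, truth, amp_scale=scale)
    arms = []
    for arm_id, mu in ((0, mu_ctrl), (1, mu_dis)):
        rng = np.random.default_rng([cfg.seed, arm_id])
        counts = _draw_counts(mu, cfg.nb_dispersion, rng)
        sh = sheet.copy()
        sh["condition"] = "control" if arm_id == 0 else "disrupted"
        sh.index = [f"{sid}_{sh['condition'].iloc[0]}" for sid in sheet.index]
        sh.index.name = "sample_id"
        values = pd.DataFrame(counts, index=pd.Index(truth.index, name="gene_id"), columns=sh.index)
        arms.append(ExpressionExperiment(values, sh, unit="counts"))
    truth = truth.assign(amp_factor=scale)
    return arms[0], arms[1], truth


def truth_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """Extract a BED-style annotation table from the truth frame."""
    ann = truth[["gene_id", "chrom", "start", "end", "strand", "biotype"]].copy()
    ann["score"] = 0
    return ann


def truth_tf_targets(truth: pd.DataFrame) -> GeneSetCollection:
    """The planted clock-TF target collection (one pooled set)."""
    members = truth.index[truth["is_tf_target"]]
    return GeneSetCollection.from_dict({"clock_tf_targets": list(members)})
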