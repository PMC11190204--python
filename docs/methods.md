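# Methods

## The model

Expression of gene g in sample s of tissue τ at circadian time t is
modelled as negative binomial,

    c_gs ~ NB(mean μ_gs, dispersion α),   Var = μ + α μ²,

with a raised-cosine mean

    μ_gs = B_gτ · (1 + A_g cos(2π (t − φ_g) / 24)),   0 ≤ A_g < 1.

B_gτ is the tissue baseline, A_g the relative amplitude, φ_g the peak
time. Differential structure enters through the baseline: a
tissue-specific gene has B multiplied by a fold factor in its tissue at
every timepoint; a temporal-DE gene only at a planted subset of
timepoints. The waveform is a cosine because the detector is a
waveform-agnostic rank correlation against a cosine reference family;
any monotone-equivalent shape gives identical p-values.

## Rhythm detection

For each lag ℓ in {0, 2, …, 22} h the reference r_i = cos(2π(t_i−ℓ)/24)
is built and Kendall's S between data and reference computed. Under the
null (exchangeable data), the distribution of S against a fixed
reference with tie groups (from replicates and from the cosine's
symmetry, e.g. sizes (4,8,8,4) on a 6×4 grid) factorizes into a
convolution of Mann–Whitney U distributions; we compute each U pmf as
the coefficients of the Gaussian binomial via exact
multiply-and-divide recurrences, so the null is exact, not simulated.
One-sided upper p-values are minimized over lags and multiplied by the
lag count (the classic JTK Bonferroni convention), capped at 1; BH runs
across genes per scan. Beyond 50 observations a flagged normal
approximation with continuity correction takes over.

Two consequences of this convention are worth stating plainly:

* **Conservatism.** The 12 lag references are strongly correlated, so
  the Bonferroni-corrected p is conservative: on a null NB simulation
  the raw p < 0.05 fraction is ≈ 0.02, not 0.05 (single-lag p-values
  are exactly calibrated; verified against 20,000 Gaussian nulls).
  Power pays for this: with 20% planted rhythmic genes at A = 0.5 and
  dispersion 0.1, sensitivity at q < 0.05 is ≈ 0.83–0.86 with empirical
  FDR ≈ 0.08–0.11 across seeds.
* **Attainability floors.** p-values are discrete. On a 6-point
  single-replicate series the best achievable lag-corrected p is
  12/180 ≈ 0.067 — *no* 6-point series can reach q < 0.05. Any test of
  a replicate-averaged series (module eigengenes, per-timepoint
  specificity indices) is therefore structurally unable to produce
  calls; these tests run on sample-level series (n = 24) instead, with
  replicate-averaged modes available but off by default.

Ties in the data contribute zero to S and are not re-conditioned in the
null (they slightly deepen the conservatism); the reported tau uses the
tau-b tie correction. Amplitude and peak time come from the cosinor
least-squares fit on the input (TPM) scale, since the rank statistic
carries no amplitude; this quantity is what "AMP" means throughout.

## Specificity indices

Tau is implemented in its canonical form Σ(1 − x̂_i)/(n − 1). A variant
with denominator Σx_i² circulates in print but is dimensionally
inconsistent (it is not bounded by [0,1] and changes under rescaling);
we implement the canonical form and note the discrepancy rather than
silently matching it. SPM and EE follow their standard definitions.
Index input is per-tissue mean TPM — across all timepoints for the
static profile, per timepoint for the time course.

A subtlety found while validating the time-resolved index: for a gene
rhythmic in one tissue with *equal* baselines, Tau responds to the
absolute deviation between tissues, so its series oscillates at ~12 h
(peak and trough both raise it) and a 24 h test rightly ignores it. A
clean 24 h Tau oscillation requires rhythmicity on top of a baseline
shift; the simulation recovers those genes at ≈ 0.8 sensitivity with
≈ 0.02 false-positive rate at low noise.

## Differential expression

Median-of-ratios size factors; per-gene NB dispersion by method of
moments pooled across the two groups (floored at 1e-8); Wald test on
the log fold change with Var(log μ̂) ≈ (1/μ + α)/n per group. Because
the dispersion is estimated from 4+4 replicates, the Wald statistic is
t-like rather than normal; we use a t reference with n_A + n_B − 2
degrees of freedom, which calibrates the null to 0.054 at nominal 0.05
(normal reference is anticonservative at this sample size). DE calls
require BH q < 0.05 within the timepoint AND |log2 FC| ≥ 1; an optional
consensus mode adds an NB score test, mirroring two-engine intersection
practice, and external (log2_fc, p) tables can be substituted. The
engine is cross-checked against DESeq2 (pydeseq2) in the test suite for
ranking agreement, never used as the implementation.

The permutation baseline shuffles circadian-time labels within each
tissue at the individual-sample level and recomputes the fraction of
DEGs significant at all timepoints. Block-wise permutation (whole
replicate groups swapping labels) is also available but leaves the
statistic nearly invariant — a relabelled timepoint spike is still a
spike — so it serves only as a negative control.

## Classification and its limits on synthetic data

The class rule is a pure function of the evidence record: rhythmic in
either tissue (per-tissue BH q < 0.05) OR clock-TF target ⇒
circadian-affected; else DE at all timepoints ⇒ constitutive; else
temporal. The partition property (three disjoint classes exhausting the
DEG set) is asserted on every run.

On the low-noise standard simulation, recovered classes match planted
truth for ≈ 91–94% of DEGs. The shortfall is concentrated in one cell
of the confusion matrix: planted *temporal* genes whose 8-fold spike at
1–2 timepoints is, objectively, an oscillation — the rank test detects
a fraction of them, promoting them to circadian-affected. This is a
property of the generative definition (spiky temporal genes), not an
implementation defect; constitutive and circadian-affected genes are
recovered essentially perfectly. On real data the analogous genes are
borderline-fold genes, which do not look rhythmic.

## Enrichment

Two-sided Fisher exact tests ("sum of all tables with probability ≤
observed") over the expressed-gene universe; target sets are
intersected with the background first. Odds ratios use Haldane's 0.5
correction only when a cell is zero, flagged. BH runs within each query
across targets; direction is enriched/depleted/ns at q < 0.05.

## Co-expression modules

Counts are stabilized as log2(1 + c/sf) (the documented stand-in for
rlog), filtered at raw MAD > 0.1, and correlated by biweight
midcorrelation (9-MAD outlier weighting, per-vector Pearson fallback at
MAD = 0, flagged). The unsigned adjacency |bicor|^softpower (default
14) feeds the topological overlap matrix; genes are clustered by
average linkage on 1 − TOM with a *static* cut — the deliberate
simplification of dynamic tree cut. The cut default is 0.95 (the
cutreeStatic convention): TOM dissimilarities concentrate near 1, so
cutting at 0.25 — a value that belongs to eigengene-merging, not the
gene dendrogram — shatters everything into singletons. Static cutting
resolves only tightly coherent modules (within-module |r| ≳ 0.9 at
softpower 14); diffuse phase continua, as produced by uniformly
distributed circadian phases, are honestly reported as unassigned.
Eigengenes are first-principal-component sample scores of the
standardized module submatrix, unit norm, sign-oriented to the module
mean; cycling calls rhythm-test eigengene and mean series with BH
across modules.

## Disruption

Per-gene amplitude change Δ = AMP_control − AMP_disrupted from the two
cosinor fits; |Δ| compared set-vs-complement by two-sided Wilcoxon
rank-sum, with optional seeded downsampling of the larger group
(median p over 25 rounds) and a relative-amplitude (AMP/mesor) option.
Both median and mean |Δ| are reported per set, since aggregation
conventions differ.

## Synthetic world: defaults and what green tests establish

Defaults: 2 tissues × 6 timepoints (every 4 h) × 4 replicates; 20%
rhythmic per tissue, A = 0.5; 15% tissue-specific (8-fold), 15%
temporal (8-fold at 1–2 of 6 timepoints); NB dispersion 0.1 (0.05 in
the scripted study for a mid-noise regime); baselines LogNormal(4, 1)
on the natural log, i.e. a median of ≈ 55 counts spanning roughly an
order of magnitude each way, a realistic expressed-gene depth profile;
P(TF target) = 0.5 given rhythmic, 0.05 otherwise; 15% lncRNA, 60% of
them placed within 50 kb of a coding partner, inheriting its phase ± 1 h
when both are rhythmic. Phases are uniform over the day by default; an
optional phase_clusters knob concentrates them into k waves, without
which discrete co-expression modules do not exist (and the module
detector says so). Gene lengths are fixed at 1 kb so counts are
proportional to TPM.

The generator emulates design structure, not data pathology: no batch
effects, no library-size gradients beyond sampled NB totals, no
cell-type mixtures, no non-sinusoidal waveforms, no missing samples. A
green recovery test therefore establishes that each estimator inverts
its own generative model at realistic noise — not that the pipeline is
robust to the artefacts of a real sequencing study.

## Numerical choices

Exact nulls are cached per tie pattern; Gaussian-binomial recurrences
are exact in float64 up to n = 50 (coefficients < 2^53). Cosine
references are rounded to 9 decimals before tie grouping. Degenerate
cases: constant series ⇒ p = 1, amplitude 0; all-zero specificity
profiles ⇒ NaN with a count; all-zero genes in DE ⇒ p = 1, fc = 0;
empty expressed set, missing timepoints, or mismatched gene universes
are fatal. Decile ties in specific-gene calling break by gene id.
Seeds: one RNG per simulation; disruption pairs use streams keyed
(seed, arm) so arms share all planted structure.
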