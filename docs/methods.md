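# Methods

## Turnover model

A single pulse of heavy Lys/Arg followed by an endogenous chase makes a
peptide's heavy fractional abundance `F = H/(H+L)` rise and then relax. We
model both phases with one observed rate constant,

    F(t) = k · t · e^(−k·t),        t½ = ln 2 / k,

which assumes (i) the precursor pool's enrichment decays with the same rate
`k` that governs protein replacement (a one-pool approximation — see
limitations), (ii) the protein pool is at steady state over the labeling
window, and (iii) replicates are exchangeable, so all time points and
replicates of a peptide enter a single unweighted least-squares objective.
`F` can never exceed `e⁻¹ ≈ 0.368`; observations above that bound are
geometrically unreachable by the model and simply leave large residuals.

**Fitting.** Derivative-based nonlinear least squares
(`scipy.optimize.least_squares`) with the analytic gradient
`∂F/∂k = t·e^(−kt)(1−kt)`, a positivity bound on `k`, a cap of 100
function evaluations, and step tolerance 1e-10. The starting value comes
from the model's linearization: `ln(F/t) = ln k − k·t`, so the OLS slope of
`ln(F/t)` on `t` over the positive points is `−k`; if that slope is
non-negative or degenerate we fall back to `k₀ = 1/mean(t)`. A fit needs at
least 3 observations spanning 2 distinct positive times.

**Inference and filtering.** With one fitted parameter we use `df = n − 1`:
the residual variance is `RSS/(n−1)`, the standard error of `k` is
`sqrt(RSS/(n−1) / Σ(∂F/∂k)²)` from the linearized covariance at the
optimum, and the p-value is two-sided from the t distribution on `k/se`.
Fits are kept when `converged AND p < 0.05 AND se < 0.025 hour⁻¹` (the SE
threshold is interpreted in rate units). Non-convergent fits and fits
pinned at the positivity boundary are flagged and excluded downstream.
Protein-level summaries are the median and MAD of passing peptide rates per
protein per tissue.

## Precursor-pool kinetics (MIDA)

Peptides with exactly two labelable residues of the same kind (KK or RR —
mixed K/R pairs are excluded because the two labels draw on chemically
distinct precursor pools) occur in three isotopomer states. Assuming
independent labeling of the two sites with pool heavy fraction `p`, the
LL:HL:HH channels are `(1−p)² : 2p(1−p) : p²`, inverted by
`p = (2·HH/HL)/(1+2·HH/HL)` (undefined and skipped when HL = 0). Per-sample
medians of `p` over qualifying peptides are fitted, per tissue, to
`p(t) = p0·e^(−k_p·t)` by least squares, initialized from a log-linear
regression. `p0` is free by default — the injected bolus mixes with the
endogenous pool, so initial enrichment is below 1 — with an optional
constrained mode (`fix_p0`). A fit is flagged degenerate when the fitted
decay over the sampled time span is negligible (`k_p·span < 1e-4`), in
which case no half-life is reported.

## Quantification and harmonization

Heavy fractional abundance sums every channel with ≥ 1 heavy site into `H`;
records with zero total intensity are skipped and counted. Fractions are
ratios within a run and are therefore computed before any batch
correction. Replicate CVs (sd/mean) are computed per peptide per channel
class (light vs heavy) within replicate groups and summarized by their
median.

Batch harmonization is a single-point calibration against the pooled
reference sample each batch carries: per feature — a (peptide, channel)
pair, since light and heavy forms behave as distinct analytes — the offset
is the feature's log2 reference intensity in the batch minus the mean of
its log2 reference intensities across batches. Subtracting the offset makes
reference measurements identical across batches; features missing from a
batch's reference are left uncorrected and flagged. Per-sample median
centering follows (mean centering is a switchable option; median was chosen
as the more robust default). The two steps are jointly idempotent. PCA is a
column-centered SVD on complete-case features (peptides missing in any
sample are dropped; imputation is out of scope).

## Between-group statistics

Spearman rank correlation compares turnover rates of shared peptides
between tissues (≥ 3 required). Per-protein tissue differences use a
two-sided Mann-Whitney U on peptide-level rates — the exact null when the
combined sample is ≤ 12 without ties, the tie-corrected normal
approximation otherwise — with a minimum of 3 passing peptides per tissue
per protein (the analysis is underpowered below that), followed by
Benjamini-Hochberg adjustment across proteins. Compartment analysis runs
one-way ANOVA on log10 rates, each compartment against all other rates or
against a named reference compartment (cytosol, mitochondria) as two-group
contrasts, BH-adjusted within each contrast scheme. Constant, perfectly
separated groups are reported with p = 0 and a `separated` flag rather than
an infinite F failing silently. Comparisons use filter-passing fits only by
default.

## Synthetic data generator

The generator emulates the statistical structure of the experiment, not
the instrument: no spectra, chromatography or identification are simulated.

* **Rates**: log-normal across proteins, default `ln k ~ N(−3.9, 1.4²)`
  (median ≈ 0.02 hour⁻¹, ±3σ covering roughly 3e-4…1 and the tails of the
  observed 3.8e-5…0.42 hour⁻¹ range). All peptides of a protein share its
  rate.
* **Abundances**: log-normal, default σ = 2.3 on the natural log (~4
  decades across peptides). An optional knob correlates log-abundance with
  log-rate (negative values emulate the observed anticorrelation between
  abundance and turnover); default off.
* **Fractions**: single-site peptides place `F(t) = k·t·e^(−k·t)` of their
  abundance in the heavy channel — the fitted model is exactly recoverable
  by construction, which is what makes noise-free recovery a meaningful
  end-to-end check. Two-site (KK/RR) peptides split binomially across
  LL/HL/HH driven by the decaying pool `p(t) = p0·e^(−ln2·t/h)` (defaults
  p0 = 0.8, h = 6 h, matching a pool half-life of a few hours). The
  simulator can thus express either view of the pool/protein coupling; the
  one-parameter protein model is the default analysis surface.
* **Noise**: multiplicative log-normal with unit mean, parameterized by the
  channel-class CV — defaults 14% (light) and 22% (heavy), the replicate
  variability scale of the experiment the generator emulates. Intensities
  are positive by construction.
* **Design**: tissues × time points (default 1/2/4/6 h) × replicates
  (default 3), one batch per tissue with a log2 offset applied
  multiplicatively, and one pooled reference sample per batch re-measuring
  the across-sample mean mixture under the batch offset. Missingness is
  uniform row dropout (default 5%).
* **Determinism**: one integer seed drives a single `numpy` generator;
  identical config + seed reproduces byte-identical tables.

What passing tests on synthetic data do **not** show: robustness to
non-multiplicative noise (interference, co-elution), intensity-dependent
missingness, misidentified peptides, natural-isotope effects, or
peptide-level rate heterogeneity within a protein. Real-data behavior on
those axes is untested by design.

## Problem sizes and numerical choices

The default demo (200 proteins × 2 tissues × 4 times × 3 replicates,
~4,700 measurements, ~1,200 peptide fits) runs in a few seconds on one
CPU; the test suite's recovery grids use 50 rates log-spaced over
1e-4…0.42 hour⁻¹ and noisy cohorts of ~30 repeats per rate, sizes chosen
to make Monte-Carlo checks stable at fixed seeds. Ties in medians follow
pandas defaults (mean of the middle pair). TSV floats are written with 12
significant digits so that tables round-trip losslessly.

## Known limitations

* The one-parameter model conflates precursor-pool decay with protein
  replacement; proteins much faster or slower than the pool are biased
  toward the pool's timescale. A delayed-precursor (two-parameter) model is
  deliberately out of scope.
* Heavy-arginine to proline conversion is not corrected.
* The labeling window overlaps cell division, so `k` mixes degradation and
  dilution by growth; no correction is attempted.
* Peptides with more than two labelable sites are excluded from MIDA, and
  natural isotope abundance is assumed handled upstream by the
  quantification engine.
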