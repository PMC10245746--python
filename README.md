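# pulsekin

Peptide-level protein turnover kinetics from **in utero pulse-chase
proteomics**. A bolus of heavy lysine (Lys8) and arginine (Arg10) injected
into a developing mouse fetus acts as a brief pulse that is chased by
unlabeled amino acids from the maternal diet; harvesting tissues at a few
labeling times and quantifying each tryptic peptide's light (pre-existing)
and heavy (nascent) channels by LC-MS lets one infer how fast each protein
is replaced. `pulsekin` turns long-format peptide intensity tables into
turnover rates, half-lives, precursor-pool kinetics, batch-harmonized
abundances and tissue-comparison statistics — and ships a synthetic-data
generator with known ground truth so the whole pipeline is testable without
any raw mass-spectrometry data.

## The model

Each peptide's heavy fractional abundance `F = H/(H+L)` follows the
one-parameter pulse-chase model

```
F(t) = k · t · e^(−k·t)
```

where `k` (hour⁻¹) is the observed turnover rate constant and `t` the time
in hours between pulse injection and harvest. The curve rises as label is
incorporated, peaks at `F = e⁻¹` when `t = 1/k`, and decays as the heavy
precursor washes out; `t½ = ln 2 / k` converts rates to half-lives. Every
peptide time course (all time points and replicates jointly) is fitted by
nonlinear least squares with an analytic gradient, initialized from the
linearization `ln(F/t) = ln k − k·t`, capped at 100 iterations, and
filtered on the model p-value (< 0.05) and the standard error of `k`
(< 0.025 hour⁻¹).

The free amino-acid precursor pool is monitored independently via **mass
isotopomer distribution analysis (MIDA)**: peptides carrying two lysines or
two arginines occur as fully light (LL), singly heavy (HL) and fully heavy
(HH) forms in proportions `(1−p)² : 2p(1−p) : p²`, so the pool's heavy
fraction is `p = (2·HH/HL)/(1 + 2·HH/HL)`. Per-sample medians of `p` fitted
to `p(t) = p0·e^(−k_p·t)` give the pool's decay half-life.

Datasets acquired in batches are harmonized by **single-point calibration**
against a pooled reference sample run in every batch: per feature, the
batch's log2 reference deviation from the across-batch mean is subtracted,
followed by per-sample median centering.

## Worked example

Simulate a two-tissue experiment (200 proteins, chase times 1/2/4/6 h,
three replicates) and run the full pipeline:

```
$ cat demo.toml
n_proteins = 200
tissues = ["liver", "brain"]
timepoints_hours = [1.0, 2.0, 4.0, 6.0]
replicates_per_timepoint = 3
frac_double_residue = 0.15
seed = 42

$ turnover run --config demo.toml --out-dir demo_out
Spearman rho(liver, brain) = 0.9617 (n=98)
pipeline complete: mean incorporation 0.2308, 450/1226 turnover fits pass the filter -> demo_out

$ turnover mida --quant demo_out/quant.tsv --metadata demo_out/metadata.tsv --out pool.tsv
brain: pool half-life 6.00 h (p0 = 0.801, n = 12)
liver: pool half-life 6.12 h (p0 = 0.799, n = 12)
```

The mean incorporation (0.2308) is the average heavy fractional abundance
over all peptide-sample records; 450 of 1226 peptide fits survive the
p/SE filter at this noise level (CVs of 14% light / 22% heavy); and the
MIDA fits recover the generator's precursor-pool half-life (6 h, initial
enrichment 0.8) from the simulated KK/RR peptide channels. Outputs land in
`demo_out/`: `turnover_fits.tsv` (rate, SE, p-value, half-life and filter
flag per peptide), `pool_fits.tsv`, `protein_rollup.tsv`,
`tissue_comparison.tsv` (per-protein Mann-Whitney with BH q-values) and a
`manifest.json` recording the config hash and row counts.

The same stages are available as library functions
(`pulsekin.fit_turnover`, `pulsekin.mida.fit_pool_decay`,
`pulsekin.quantify.harmonize`, `pulsekin.compare.mannwhitney_per_protein`,
…) and as individual subcommands `turnover
simulate|quantify|mida|fit|compare`.

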