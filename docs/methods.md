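# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and
the design decisions that were genuinely open.

## Rate models

All mutation-rate quantities come from Poisson models with a log link
and a log-exposure offset. The single-rate model is

    y_i ~ Poisson(λ),  log λ = α + log E_i,  α ~ N(0, 10),

with `y_i` the count in MA line `i`. Because the intercept-only
likelihood depends on the data only through the total count and total
exposure, printed totals can be split evenly across lines without loss
(`workflow.split_evenly`; a property test confirms insensitivity to the
split). Rates convert as `μ = exp(α)/(N·t·m)` per bp or `exp(α)/(t·m)`
per genome, with `N` callable bases, `t` transfers, `m` mitoses per
transfer.

Window-level variation is a Poisson regression over fixed-width windows
(200 bp by default, matching the diversity windows; the fitting
granularity was an open choice) with offset
`log(callable_bp · n_lines · t · m)` and predictors: standardized
GC-fraction, H3K9me3 / H3K27me3 indicators, a centromere overlay flag,
and a GC×H3K9me3 interaction. Priors are N(0, 10) on the intercept and
N(0, 5) on coefficients (weakly regularizing on the log scale). `m`
enters window offsets as its posterior median — its coefficient of
variation is below 2%, so this changes nothing detectable — while
`to_rate` keeps full draw-wise propagation for headline rates.

Two numerical points matter when interpreting coefficients:

- With bimodal GC that separates domains almost perfectly, the H3K9me3
  indicator and the GC×H3K9me3 interaction trade off; the *realized*
  fold between domains is therefore reported as a posterior contrast of
  mean linear predictors over each domain's own windows
  (`FittedRateModel.stratum_contrast`), not as a single coefficient.
- Windows straddling a domain boundary carry a majority label but mixed
  true rates. Calibration studies use `genome_context.window_purity` to
  drop them (≈1–3% of windows); leaving them in biases the euchromatic
  baseline upward by a few percent.

Model comparison uses WAIC computed from pointwise log-likelihoods over
thinned posterior draws, converted to pseudo-BMA (exponentiated,
renormalized elpd) weights. The choice of criterion behind "model
weights" was open; WAIC-based pseudo-BMA is the simplest member of that
family and is labelled as such in outputs.

## Posterior sampling

pymc-style samplers are not used; the models here are log-concave
Poisson GLMs, for which an independence Metropolis–Hastings chain with a
multivariate Student-t proposal (df 8, scale 1.3× the inverse Hessian)
centred on the posterior mode is exact and mixes nearly i.i.d. The mode
and Hessian come from a damped Newton iteration on the convex negative
log posterior. Defaults are 4 chains × (1000 warmup + 3000 retained)
iterations; split-R-hat above 1.01 and acceptance below 5% emit
warnings. Cross-checks: a dense-grid integration oracle for
intercept-only fits (agreement within 2% on the rate scale) and an
adaptive random-walk sampler for small non-GLM targets (flanking
regression, nuclei model); both routes agree on shared test problems.
In high dimensions with many zero counts (the 35-parameter
trinucleotide model) acceptance drops to ~0.2–0.3 and R-hat can sit
near 1.01; estimates remain stable across proposal settings and agree
with the independent random-walk route.

HPD intervals are the shortest window of ⌈0.95 n⌉ consecutive order
statistics. At small draw counts this estimator is biased slightly
narrow; calibration-sensitive analyses use ≥6000 pooled draws.

## Mitoses per transfer

Nuclei are counted in replicate at the start and end of each phase of a
transfer. Each phase contributes `d_p = log2(final/initial)` doublings;
observed ratios carry lognormal count noise, so
`x_r ~ N(d_p, √2·σ)` with a half-normal(0.25) prior on the per-count
log2 noise scale and a positive-truncated N(10, 10) prior on `d_p`. The
exact count-noise model was an open design point; this one reproduces
the reported scale (≈25 mitoses/transfer, ≈1015 for 40 transfers) and
propagates uncertainty as required. The 2-D (d, σ) posterior is
evaluated on a dense grid per phase — phases are independent — and
`m = Σ_p d_p`.

## Spectra and context

Substitutions are collapsed to 6 base-pair classes (strand unknown);
trinucleotides to 32 classes, canonicalized as the lexicographic minimum
of the strand pair and displayed `MIN:REVCOMP`. Relative rates are
Poisson posteriors with source-census × exposure offsets, renormalized
draw-wise to sum to 1, so equal mutability is 1/6 (or 1/32); whether to
normalize to sum 1 or mean 1 was open — the two differ by a constant
factor, and the choice is recorded in output metadata. Domain spectrum
ratios compare these normalized shapes, so the overall domain rate fold
cancels; the trinucleotide correction weights each domain's census by
genome-wide per-class mutability before summing.

The flanking-base model regresses each class's mean log relative rate
on focal-pair and 5'/3'-flank indicators (flanks defined in the
pyrimidine-centred orientation, the only strand-consistent choice) with
the class's posterior sd as known measurement error plus an estimated
residual scale (half-normal(0.5) prior). Degenerate measurement sds are
floored at 1e-3 with a log entry.

## Indels and repeats

Each indel gets exactly one category with precedence homopolymer >
microsatellite > other_repeat > nonrepeat. A deletion is
homopolymer-class when the deleted bases lie inside a catalogued run
(≥5 bp); an insertion when its insertion point is strictly inside a run
and the inserted sequence is the run base. Microsatellites — criteria
were unspecified upstream — are defined as ≥3 contiguous copies of a
2–6-bp motif covering the site, with the indel length a motif multiple.
The homopolymer rate model is a per-locus Poisson regression with a
type indicator (A:T vs C:G) and a single shared length slope (no
interaction), offset `log(n_loci · n_lines · t · m)`; length strata
above 15 are pooled at their census-weighted mean length to avoid empty
cells.

## Diversity

θ_W uses the per-site missing-data form: a site with `n_i` called
alleles contributes `1/a_{n_i}` if it segregates among the called
alleles (any multiallelic pattern counts as segregating — the upstream
convention was unstated), and window θ is the sum over sites divided by
callable bp. Windows under 50% callable are flagged missing
(configurable). Haploid genotypes are assumed. The θ–rate regression is
a conjugate Bayesian linear fit of window θ on log10 predicted μ with
the reference prior; Bayesian R² is the draw-wise fitted-variance
share. The zero-window robustness variant is a two-part (hurdle) model
— logistic for P(θ>0), linear on the positive part — one member of the
possible zero-model family, and labelled as such.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 39 lines, 40
transfers, 25.375 mitoses/transfer; euchromatic SNM rate 2.46e-10 and
H3K9me3 rate 2.43e-9 /bp/mitosis; H3K27me3 fold 1.4; an additional
centromere fold (1.5, a choice — only "an additional increase" is
established); 6-class spectra tuned to euchromatic Ts/Tv 1.49 (with the
A:T→G:C / C:G→T:A ratio 1.23) and H3K9me3 Ts/Tv 0.93 with C:G→G:C
doubled; homopolymer per-locus rates 1.79e-8 (A:T) and 8.15e-9 (C:G)
with a shared length slope of 0.25 per base (the magnitude was open;
the sign and sharedness are the established features); θ–μ slope
0.0096 per decade. The default genome is 2 Mb over 4 contigs, and
per-bp rates are multiplied by (41.1 Mb / simulated length) so expected
counts per line (~30) — and hence posterior widths — match the real
experiment; per-genome rates (translocations, non-repeat indels) are
not scaled. Tests run on a 250-kb version, where the same scaling keeps
total counts at study scale.

Deliberately not emulated: read-level errors and mapping bias (mutation
calls are taken as true), per-line rate heterogeneity (the outlier-line
phenomenon), within-domain GC dependence of the SNM rate (mutations are
placed by domain and source pair only, so the generating GC slope is
≈0), RIP, selection/demography in the population sample (sites are
i.i.d. with a neutral 1/k frequency spectrum), and linkage. Passing
recovery tests therefore demonstrates that each inference stage is
calibrated for the data-generating process it assumes — not that the
real data satisfy those assumptions.

Determinism: one seed fixes every output byte; generating parameters are
recorded in a JSON sidecar, and recovery tests read their truths from
that sidecar (e.g. the K9/euchromatin fold is 2.43e-9 / 2.46e-10 =
9.878).

## Calibration suite sizes

The test suite runs recovery studies at sizes chosen to finish a full
run in a couple of minutes while keeping ≥50 effective checks per
quantity: 100 full-pipeline replicates for the window model (250-kb
genomes), 100 count-level replicates for the 6-class spectrum, 100
response-level replicates for the flanking model, 150 for the
homopolymer model, 60 for the θ–μ slope, with a ≥90% HPDI-coverage bar
throughout. Reduced per-fit draw counts (2 chains × 700–1500) are used
inside loops except where HPD-estimator bias matters (homopolymer
model: 4 × 1500).

## Known limitations

- The independence sampler is tailored to log-concave targets; it is not
  a general MCMC engine.
- The trinucleotide model assumes class effects shared across domains
  (no interactions); with strongly domain-specific spectra the shared
  effects are a compromise average.
- Microsatellite and "other repeat" definitions are simple scans, not a
  full tandem-repeat annotation.
- The hurdle diversity model treats windows independently; spatial
  autocorrelation of θ is ignored.
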