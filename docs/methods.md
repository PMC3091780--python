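# Methods

## The benchmark

`spikeqc` treats a gene-expression platform as a measurement instrument and
a spike-in panel as its calibrant. Every RNA standard is dosed at a known
copy number per ng of total RNA, so any measurement of the panel can be
scored against exact truth. Two designs drive the benchmark:

* **Dilution pools.** Eight standards and eight abundance levels
  (0, 1, 10, …, 10⁶ copies/ng) arranged as a cyclic Latin square: standard
  *i* (row order 13, 42, 81, 84, 95, 99, 113, 171) receives, in sample *j*,
  the level at index (j − i + 1) mod 8 of the ascending ladder. Each
  standard visits every level once, each pool carries every level once, and
  all pool totals equal 1,111,111 copies/ng, so dosing is balanced. The zero
  level provides negative controls. The rotation phase is fixed so the
  default export reproduces the canonical published pool table cell for
  cell.
* **Condition panels.** Two single-sample panels, A ("normal") and B
  ("disease"), of the same eight standards. Four standards change between
  panels (B/A ratios 0.5, 1.5, 5.0, 10.0), four do not (ratio 1.0), spanning
  10–10⁵ copies/ng. The truth label for classification is "differentially
  expressed" iff the ratio differs from 1.

Dosing arithmetic: 26 pg total RNA per mammalian cell converts copies/ng to
copies/cell as `copies_per_ng × 0.026` (100 copies/ng = 2.6 copies/cell; the
conversion is exact, not rounded to an order of magnitude). At the default
1 ng of RNA per qPCR reaction, 1 copy/ng is exactly one expected template
molecule per reaction. The spike mass check
`Σ copies × length × 330 g/mol / N_A` against 2% mRNA content confirms the
default panels never add more than ~4% to the sample's mRNA mass. The
per-standard transcript lengths in the default library are synthetic
stand-ins spanning the real library's 481–1324 nt range; only dosing-mass
arithmetic uses them.

## Generative models

No public generative model exists for either platform, so the simulators
are explicit, minimal stochastic models of the behaviours the analyses
assume. Both are deterministic given (design, parameters, seed); per-stage
seeds are derived from one top-level seed via `SeedSequence` so stages can
be rerun in isolation.

### Microarray

Per probe of standard *s* at abundance *c* (copies/ng), on the array for
run *k* with labelling *l*:

    I = gain_s · c / (1 + c/K) · exp(ε) · exp(r_k) · exp(λ_l)
    ε ~ N(0, σ(c)²),   σ(c)² = σ_tech² + σ_low² / (1 + c/c₀)

* `gain_s` — probe affinity (a.u. per copy/ng), drawn once per standard
  from a lognormal (median 50, log-SD 0.5). All 100 replicate probes of a
  standard share one gain because they are the same sequence; probe-level
  variation enters only through noise.
* Saturation is hyperbolic with K = 5×10⁵ copies/ng, placing the linear
  range at roughly 10–10⁵ with visible compression at 10⁶. `K = inf`
  disables it (the noise-free ideal-response limit).
* Noise is multiplicative lognormal, matching CV-style reporting; the
  log-scale SD rises from σ_tech = 0.12 at high abundance to
  √(σ_tech² + σ_low²) ≈ 1.2 near zero (σ_low = 1.2, c₀ = 5 copies/ng), so
  the CV of raw intensities falls from ~30%+ at 1–10 copies/ng to <10%
  above 10³ — the abundance-dependent precision structure the QC metrics
  must detect.
* Run and labelling effects are shared lognormal factors (log-SD 0.05
  each). The split between them is a free modelling choice; only their sum
  is identified by the analyses.
* Blank features draw from N(150, 30²) truncated at 0. Intensities are
  emitted as background-corrected values: blanks represent residual
  background features, not an additive term on signal probes. Standards
  dosed at zero draw from the blank distribution.
* Each array also carries 600 generic background features standing in for
  the whole-genome probe content of a real array: each gets a fixed
  expression level (lognormal, median 2000 a.u., log-SD 2.0), identical in
  every sample because all samples share the same background RNA. They
  anchor the per-array 75th-percentile scaling so normalisation does not
  depend on the spike composition of the panel — without them,
  quantile scaling of spike-only arrays introduces panel-dependent
  fold-change bias.

Calibration: gain median 50 against background mean 150 puts the detection
crossover between 1 and 10 copies/ng — at 1 copy/ng the median spike signal
(~50 a.u.) sits well below the blank-derived LOD, at 10 copies/ng
(~500 a.u.) well above, with ~100% detection from 100 copies/ng. These are
modelling choices fixed once in the parameter defaults, not measured
constants.

### RT-qPCR

Per reaction at abundance *c*:

    m ~ Poisson(c · input_ng · rt_yield)
    m = 0            → UNDETERMINED
    otherwise  Ct = Ct₁ − ln(m)/ln(1+E) + s_k + N(0, σ_ct²)
    Ct > 45 cycles   → UNDETERMINED

* `rt_yield = 0.25` models a reverse-transcription step far below 100%
  efficiency: at one expected copy per reaction only 1 − e^(−0.25) ≈ 22% of
  reactions fire, ~92% at 10 copies and ~100% at 100 — the dropout regime
  that places the qPCR LOD at 10 copies/ng.
* `E` is the per-assay PCR efficiency (default 0.9; E = 1 is perfect
  doubling), `Ct₁ = 38` the single-molecule Ct, `σ_ct = 0.25` cycles the
  replicate noise, and run shifts `s_k ~ N(0, 0.3²)` cycles model
  plate-to-plate threshold differences. There is deliberately no saturation
  term: linearity extends to 10⁶ copies/ng.
* `poisson=False` replaces `m` by its expectation — the noise-free limit
  used for closed-form checks (e.g. exact efficiency round-trips).
* UNDETERMINED is an explicit state (a flag column in memory, the literal
  token in files), never a sentinel Ct value, and undetermined reactions
  are excluded from means, CVs and fits rather than imputed; their rate is
  reported separately as the positive-reaction fraction.

## Analysis procedures and numerical choices

* **Normalisation.** `v = log2(raw + pseudocount)` (pseudocount 1.0 a.u. so
  degenerate zeros stay finite); per array subtract the array's 75th
  percentile of `v`; per feature subtract the median across arrays. The
  underlying platform convention is per-array quantile scaling followed by
  per-feature baselining; a literal per-feature 75th percentile is
  incoherent for single measurements per array, so that reading was
  rejected.
* **Probe summaries.** Median of the 100 replicate probes per standard per
  array (robust to outlier probes); mean available as an option.
* **LOD.** `mean(blanks) + t₀.₉₇₅,ₙ₋₁ · SD(blanks)/√n` on raw intensities —
  the two-sided 95% upper confidence limit of the mean blank signal.
  Computed on the raw scale over all blank observations (features × arrays);
  the distributional scale and the choice of n are analysis conventions
  documented here, with coverage verified by simulation (the true blank
  mean exceeds the estimate in ≈2.5% of repeated draws). Detection uses
  strict ">": a summary exactly at the LOD counts as not detected.
* **LOD level call.** The platform LOD level is the lowest nonzero
  abundance whose detection fraction (array) or positive-reaction fraction
  (qPCR) reaches 0.5; the joint call takes the lowest level meeting the
  rule on both platforms.
* **Linear range.** OLS of log2 signal (array) or log2 mean Q (qPCR) on
  log2 copies/ng. Automatic range selection enumerates every contiguous
  window of ≥4 distinct nonzero levels and keeps the window maximising R²
  (ties within 1e-9 go to the wider window, then the lower start) —
  a deterministic surrogate for visual inspection.
* **ΔCt and quantities.** ΔCt is referenced to the mean determined Ct of
  the 10⁶ copies/ng calibrator within the same assay and run, so per-run
  additive shifts cancel exactly; Q = (1+E)^(−ΔCt). The mean (not median)
  reference follows the platform convention. Efficiency from a dilution
  series: OLS slope of mean Ct on log10 input, E = 10^(−1/slope) − 1;
  estimates above 1 are flagged, above 1.2 rejected as pathological.
* **Precision.** CV% = 100·SD/mean (sample SD). Normalised-scale variation
  maps log2 SD to a linear percentage as 100·(2^SD − 1). Between-run
  metrics use one summary per run; within-run metrics average the
  replicate-level CV across runs. Groups with fewer than two determined
  observations report the metric as absent rather than 0.
* **Fold changes.** Arrays are paired within run by labelling index
  (2 pairs × 3 runs = 6 comparisons in the canonical layout; any explicit
  pairing list is accepted, but cross-run pairs are rejected under the
  default policy). Per-feature log2 ratios combine across comparisons by
  arithmetic mean (geometric mean on the linear scale). Accuracy counts
  features with |observed/expected − 1| ≤ 0.10, boundary inclusive.
* **Volcano classification.** Welch two-sample t-test on log2 values, two
  sided, no multiple-testing correction (matching raw-p volcano practice);
  degenerate zero-variance features take p = 1 at equal means, p → 0
  otherwise. DEG iff |mean log2 FC| ≥ log2(cutoff) (inclusive) and
  p < 0.05 (exclusive). Confusion is tallied overall and per standard.
* **Concordance.** OLS slope and Pearson R of qPCR on array log2 fold
  changes per standard (the axis scale is a package convention).
* **PCA.** SVD of the mean-centred, unit-variance-scaled matrix (sample SD,
  n − 1); zero-variance variables are dropped with a warning. Conditions
  mode: observations = arrays. Entities mode: the matrix is transposed so
  observations = features and scaling applies across arrays. Component
  signs are fixed by making each component's largest-magnitude loading
  positive, so results are exactly reproducible. Separation is the mean
  silhouette width on the first two components (singleton groups score 0).

## Problem sizes

Default analyses use 3 runs, 100 replicate probes and 100 blanks per array
(24 arrays for the pools; 12 for the panels) and triplicate qPCR reactions
(576 reactions for the pools); Monte-Carlo checks in the test suite use
10⁴–10⁵ draws. These sizes make every stochastic check stable across seeds
while keeping a full run under a few seconds.

## What the simulations do and do not show

Passing the benchmark on simulated data demonstrates that the analysis
pipeline is correct and well calibrated against a known generative truth:
exact recovery in noise-free limits, correct dropout statistics, correct
CV/abundance ordering, unbiased fold changes once quantile scaling is
anchored. It does not certify any physical platform: real arrays add
probe-sequence effects, spatial artifacts, dye chemistry and scanner
nonlinearity; real qPCR adds inhibition, primer-dimer artifacts and
amplification-curve pathologies — none of which are modelled. Real-platform
headline figures (e.g. detection percentages at 1 copy/ng, PCA variance
splits) therefore appear here only as regimes the simulation reproduces
qualitatively, not as quantities the package claims to re-measure.

## Known limitations

* The labelling/run variance split is unidentifiable from the emitted
  tables; only their combined effect is tested.
* The qPCR model emits Ct values only — no fluorescence curves, baselines
  or threshold selection.
* Between-run array normalisation relies on the background feature set
  being truly constant across samples; differential background (e.g.
  sample-specific RNA quality) is not modelled.
* The automatic linear-range rule maximises R² and can keep a low level
  that sits on the regression line by chance where visual inspection might
  exclude it; fixed ranges can be supplied where that matters.
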