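# Methods

## Statistical model and procedures

### Delta-CT stability

For each unordered gene pair (g, k) the per-sample difference
`dCT_s = CT_g,s - CT_k,s` eliminates everything a sample contributes to
both genes (template amount, RT yield, pipetting), leaving relative
regulation plus technical noise. The pair's variability is the population
standard deviation (divisor N) of `dCT` across samples; a gene's statistic
is the mean of its pair SDs against every other candidate. Population
rather than sample SD is used throughout (both engines), treating the
sample set as the frame of inference rather than a draw from a larger
population; the choice also keeps the delta-CT and geNorm statistics
exactly interchangeable (below). Pairs are computed over pairwise-complete
samples; any pair sharing fewer than 3 observed samples is a hard error.
Within a condition subset, all samples — control and treated, every
timepoint and replicate, and both tissues in combined analyses — enter as
independent samples. Rank ties are broken lexicographically by gene id and
flagged in the result.

### geNorm

Relative quantities `Q = E**(minCT - CT)` anchor each gene at its minimum
CT (max Q = 1). M is the mean over partners of the population SD of
`log2(Q_g/Q_k)`; the highest-M gene is excluded each round (ties exclude
the lexicographically last gene) until two remain, which are reported as an
unordered final pair — the statistic cannot rank them against each other.
V_{n/n+1} is the population SD over samples of `log2(NF_n/NF_{n+1})`, with
NF_n the geometric mean of the top-n ranked genes' quantities.

With every efficiency at 2.0, `log2(Q_g/Q_k)` equals `-dCT` plus a
constant, so geNorm's pairwise variation equals the delta-CT pair SD
exactly and the full-panel M equals the delta-CT statistic. This identity
is asserted elementwise at 1e-9 in the tests and pins the two engines to
each other. Efficiency-corrected quantities are used whenever per-amplicon
efficiencies are supplied; `default_e = 2.0` otherwise.

### Curve processing

The model is constant background plus exponential growth clamped at a
plateau. Choices, all of which are configurable or asserted in tests:

- **Baseline**: a constant, grid-searched on [0, min signal) and refined by
  staged grid zooming (bracket shrinks 8x per stage to ~1e-13), maximising
  the R^2 of the best log-linear sliding window on the corrected signal.
  The window search during baseline fitting is confined to the early
  exponential phase — windows whose raw signal stays within ~100x the
  noise floor (smallest positive signal) — because a mis-set baseline only
  bends the log curve where signal and background are comparable;
  high-signal windows carry no baseline information and would make the
  objective flat.
- **Efficiency**: window of linearity, default length 5 (4-7 allowed),
  `E = 10**slope` of the max-R^2 window, ties to the earliest window.
  Windows whose corrected signal dips below 3x the estimated background are
  skipped when a clean (R^2 >= 0.99) window exists above that floor:
  residual baseline error biases the slope low in the lowest-signal
  windows. Monte-Carlo calibration (200 synthetic curves, E = 1.85, 2%
  multiplicative noise) gives mean error -0.004, SD 0.016, 98% of fits
  within 0.05 of truth; the frozen test band (>= 90% within 0.05, |mean
  bias| < 0.02 over 100 seeds) reflects that run.
- **Quality gate**: fits with R^2 < 0.99 are flagged low-quality, retained
  for CT extraction but excluded from group efficiency averaging.
- **Threshold and CT**: per amplicon, the threshold is the geometric mean
  over wells of the corrected signal at each well's window midpoint; CT is
  the log-linearly interpolated fractional cycle at that threshold. Group
  efficiency is the arithmetic mean of non-flagged per-well efficiencies
  (per-amplicon mean rather than per-well efficiency is used downstream).

"Exact" curve identities (noiseless recovery, the -1 cycle shift per
template doubling) are asserted at 1e-6 or better: the baseline is found by
numerical search, so equalities hold to solver precision, not bitwise.

### Quantification

Per replicate r, `ratio_r = E_t**(CT_t,cal - CT_t,r) / NF_r`, where the
calibrator CT is the mean over calibrator replicates (per tissue) and NF_r
is the geometric mean over scheme references of `E_ref**(CT_ref,cal -
CT_ref,r)`. The fold change is the geometric mean of ratios; its
uncertainty `se_log2 = SD(log2 ratio_r)/sqrt(n)` (sample SD) is reported on
the log2 scale because ratios are log-normal under CT-scale Gaussian noise.
Calibrator rows are emitted as exactly 1 (the estimator is identically 1
there; emitting the constant avoids spurious last-ulp noise) while their
replicate scatter still appears in `se_log2`. The efficiency-corrected
ratio was chosen over plain `2**-ddCT` because per-amplicon efficiencies
are first-class inputs; the two coincide when all E = 2.

### Recommendation rule

The recommended pair for a condition is the top two genes by the delta-CT
statistic; the geNorm trace is attached as context with a concordance note
(whether both genes sit in geNorm's top five). geNorm is not given a vote
because it scores co-regulated genes as jointly stable; the delta-CT
ranking is the primary criterion and reproduces all 15 published
condition-stratum pairs of the bundled soybean screen. The overall
single-gene recommendation is the delta-CT winner of the all-treatments,
tissues-combined stratum.

## Synthetic data

`CT_g,s = mu_g + shift_s + beta_g(condition) + eps_g,s` with per-sample
loading shift `shift ~ N(0, delta^2)`, condition effects beta (cycles), and
replicate noise `eps ~ N(0, sigma^2)`. Defaults emulate a realistic
screen: 13 genes with baselines uniform on 17-26 CT, 2 tissues x (control
at 0/2/10 h + 4 treatments at 2/10 h) x 3 replicates (66 samples), loading
shifts delta = 0.5 cycles, replicate noise sigma = 0.2 cycles, all beta = 0.
The analytic truth for a gene is `sqrt(popvar(beta over design) + sigma^2)`,
the noise-floor-adjusted spread of its condition effects; loading shifts do
not enter because every statistic in the package cancels them.

Numerical choice: all draws (mu, shift, beta, eps) are snapped to a dyadic
grid of 2^-16 cycles (~1.5e-5, far below instrument resolution). Sums of
such values are exact in float64, so per-sample shifts cancel *exactly*
when a delta-CT is formed and the all-stable/noise-free case yields
statistics that are exactly zero rather than ~1e-15.

Amplification curves: `signal_c = baseline + min(n0*E**c, plateau)*(1 +
eta_c)`, multiplicative Gaussian reporter noise, clipped at zero. The truth
object carries the analytic CT for any threshold.

What the generator does *not* emulate: PCR inhibition and efficiency drift
across the plate, primer-dimer artifacts, missing-well structure that
correlates with condition, co-regulated gene groups (each gene's beta is
independent), and heavier-than-Gaussian CT outliers. Tests passing on this
generator therefore validate the statistics and their implementations, not
robustness to those real-data pathologies.

## Problem sizes in the test suite

Property and recovery tests use 100-seed Monte Carlo at the default design
(13 x 66), 100 random 13 x 30 matrices for the cross-engine identity, 100
random 5-gene instances against the brute-force geNorm oracle, and 100-200
synthetic curves for efficiency-recovery calibration. These sizes give
stable pass/fail behaviour at fixed seeds while keeping the full suite
around ten seconds.

## Known limitations

- The raw per-sample CT data behind the bundled published statistics is not
  redistributable; the corresponding reproduction test requires the user to
  supply the converted spreadsheet (see README) and fails with instructions
  otherwise.
- Legacy binary `.xls` workbooks are not read; convert to `.xlsx` or CSV.
- The curve engine fits a constant (not sloped) baseline and does not
  attempt whole-curve sigmoid fits or melt-curve analysis.
- `fold_change` aligns replicates by position within a condition; designs
  with unequal replicate counts across genes are rejected rather than
  matched.
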