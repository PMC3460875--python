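# refstab

Reference-gene stability ranking and efficiency-corrected quantification
for qRT-PCR experiments.

Relative quantification by qRT-PCR stands or falls with the reference
(housekeeping) gene used to normalise away sample-to-sample differences in
template loading and reverse-transcription yield. Under abiotic stress
(dehydration, salt, cold, hormone treatments) many classic housekeepers are
themselves regulated, so the reference must be chosen per tissue and per
stress. `refstab` implements the two standard screening statistics used for
that choice, the curve-level preprocessing that produces the CT values they
consume, the downstream fold-change validation that shows why the choice
matters, and a ground-truth simulator for testing all of it. It ships with
the printed per-gene stability statistics of a published 13-gene soybean
screen (root and shoot tissue under dehydration, salt, cold and ABA), so the
recommendation logic can be exercised end to end without raw data.

## Methods

**Pairwise delta-CT.** For genes *g, k* and sample *s*,
ΔCT<sub>gk,s</sub> = CT<sub>g,s</sub> − CT<sub>k,s</sub>. Per-sample
loading effects cancel in the difference, so the population SD (STDEVP,
divisor *N*) of ΔCT<sub>gk</sub> across samples measures how much the two
genes move against each other. A gene's statistic is the mean of its pair
SDs over all other candidates; lower = more stable. The recommended pair
for a condition is the top two genes of this ranking.

**geNorm.** CTs are converted to relative quantities
Q = E<sup>(minCT − CT)</sup> with per-amplicon efficiency E. A gene's
M value is the mean over partners of the population SD of
log₂(Q<sub>g</sub>/Q<sub>k</sub>); the gene with the highest M is excluded
and M recomputed until two genes remain. Pairwise variation
V<sub>n/n+1</sub> of normalization factors (geometric means of the top-*n*
quantities) indicates how many references suffice. With all E = 2 the
geNorm pairwise variation V<sub>gk</sub> is *identical* to the delta-CT
pair SD — the package asserts this equivalence to 1e-9.

**Curve engine.** Raw fluorescence curves are baseline-corrected by the
constant that maximises the R² of the best log-linear sliding window,
efficiency is 10^slope of that window (window of linearity), an
amplicon-wide threshold is set at the geometric mean of window-midpoint
signals, and CTs are read off by log-linear interpolation.

**Quantification.** Efficiency-corrected (Pfaffl-type) ratios
E<sub>t</sub><sup>ΔCT(target)</sup> / NF with NF the geometric mean of the
reference quantities; with E = 2 and a stable reference this reduces to the
classic 2<sup>−ΔΔCT</sup>. `reference_consistency` flags condition cells
where a fold-change detection call (default threshold 2.0) flips depending
on the reference scheme.

## Worked example

```
$ python examples/published_recommendations.py
condition              recommended    statistics (cycles)  published
ABA/both               60s/ELF1b      0.3996, 0.4073      60s/ELF1b OK
...
dehydration/roots      Fbox/ABC       0.2026, 0.2145      Fbox/ABC OK
...
15/15 published pairs reproduced by the top-2-by-delta-CT rule.
```

Each line ranks the 13 candidates of one condition stratum by the printed
delta-CT statistic (cycles); e.g. for dehydrated roots *Fbox* (0.2026) and
*ABC* (0.2145) are the two most stable candidates and form the recommended
normalisation pair. The other examples simulate a full screen
(`rank_reference_genes.py`), fit efficiencies and CTs from raw curves
(`curve_efficiency.py`), and show how an unstable reference masks a true
2.5-fold induction (`fold_change_validation.py`).

A thin CLI mirrors the library: `refstab run|stability|genorm|quantify|simulate|curves --help`.

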