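# cdksize

Single-cell CDK-activity quantification and size-resolved division analysis
for fission-yeast translocation-biosensor experiments.

## The problem

In *Schizosaccharomyces pombe*, mitosis is triggered by cyclin–CDK
(here a monomeric cyclin B–Cdc2 fusion, "C-CDK"), and smaller cells must be
prevented from dividing for the population to hold its size. In vivo CDK
activity can be read out per cell as the nuclear/cytoplasmic (N/C)
fluorescence ratio of a translocation biosensor (Cut3 or synCut3): CDK
phosphorylation drives the reporter into the nucleus, so N/C ≈ 1 means
inactive CDK and N/C ≫ 1 means active CDK. Combining that readout with the
C-CDK level (its fluorescence concentration) and cell geometry, imaged
either by wide-field time lapse or imaging flow cytometry, lets one ask how
cell size, inhibitory tyrosine phosphorylation (removed in the CDK^AF
mutant), the phosphatase PP2A (removed in *ppa2*Δ), and DNA-per-volume
(ploidy) each shape the CDK activity dose–response.

`cdksize` implements that analysis chain as a tested library:

| module | what it does |
| --- | --- |
| `cdksize.synthetic` | ground-truth generator: populations, time-lapse lineages, rendered multi-channel cell images |
| `cdksize.quantify` | image → record: brightfield-pair segmentation, brightest-9-pixel C-CDK level, midline-profile N/C ratio, gradient-RMS focus gating |
| `cdksize.dose_response` | Hill fit (signed coefficient) for inhibitor titrations, rising sigmoid fit (EC50) for activity vs level, binned responses, DMSO normalisation |
| `cdksize.division` | P(Div) hazard curves, size-binned activation-threshold curves, synergy decomposition of genotype threshold curves |
| `cdksize.bistability` | mean activity-vs-level curves, spline maximum gradients, linear-regression residual nonlinearity |
| `cdksize.lineage` | degradation/division event detection, skipped-division classification, peak alignment, mitotic-entry calls |
| `cdksize.io`, `cdksize.pipeline`, `cdksize.cli` | CSV/Parquet/TIFF I/O, YAML pipeline runner with hashed manifests, `cdksize` command line |

## Core quantities

* **CDK activity** `activity_nc` — ratio of the most prominent central
  extremum of a 3-px-wide midline intensity profile to the cytoplasmic
  baseline (flat flanking segments). A dip (< 1) marks nuclear exclusion,
  a peak (> 1) nuclear accumulation.
* **C-CDK level** `cdk_level_au` — mean of the brightest contiguous 3×3
  pixel block inside the cell mask (a concentration, not a total).
* **Hill / sigmoid models** —
  `r(d) = bottom + (top − bottom) / (1 + (d/IC50)^(−h))` for inhibitor dose
  *d* (h < 0 for a falling response), and
  `a(L) = bottom + (top − bottom) / (1 + (EC50/L)^s)` for activity vs
  C-CDK level *L*.
* **P(Div)** — per minute: the fraction of cell-timepoints followed by
  mitotic C-CDK degradation within one frame, divided by the frame
  interval, binned by size or level.
* **Threshold curve** — per cell-size bin, the C-CDK level at which 50% of
  cells exceed CDK activity 5; bins where that fraction is never reached
  are explicitly flagged undefined (capped at 1000 AU only inside the
  synergy algebra, with per-bin flags).
* **Synergy** — `WT − [AF_PP2AΔ + (WT_PP2AΔ − AF_PP2AΔ) + (AF − AF_PP2AΔ)]`:
  zero when tyrosine phosphorylation and PP2A contribute additively,
  positive when they cooperate.

## Worked example

```python
import numpy as np
from cdksize import synthetic as syn
from cdksize.dose_response import fit_hill, hill_model
from cdksize.quantify import quantify_image
from cdksize.lineage import classify_skipped_divisions

# 1. refit a noiseless inhibitor titration
doses = np.array([0.0, 31.25, 62.5, 125.0, 250.0, 500.0, 1000.0])
activity = hill_model(doses, 115.4, -1.71, top=1.0, bottom=0.0)
fit = fit_hill(doses, activity)
print(f"IC50 = {fit.ic50:.1f} nM 1NM-PP1, Hill coefficient = {fit.hill_coef:.2f}")

# 2. render one synthetic cell and quantify it back
cfg = syn.SimConfig(seed=0, n_cells=1)
_, truth = syn.simulate_population(cfg)
cell = truth.iloc[0].copy()
cell["true_nc"], cell["true_level_au"] = 2.4, 520.0
img = syn.render_cell_image(cell, cfg, rng=np.random.default_rng(0))
rec = quantify_image(img)
print(f"true N/C 2.40 -> measured {rec['activity_nc']:.2f}; "
      f"true level 520 AU -> measured {rec['cdk_level_au']:.0f} AU")

# 3. skipped divisions in simulated AF-mutant lineages
traces = syn.simulate_lineages(cfg, 400, 450.0, genotype="AF",
                               rng=np.random.default_rng(1))
out = classify_skipped_divisions(traces)
print(f"degradation without division: {100*out.fraction:.1f}% "
      f"(95% CI {100*out.ci_low:.1f}-{100*out.ci_high:.1f}%)")
```

prints

```
IC50 = 115.4 nM 1NM-PP1, Hill coefficient = -1.71
true N/C 2.40 -> measured 2.40; true level 520 AU -> measured 522 AU
degradation without division: 4.8% (95% CI 3.9-6.0%)
```

The first line shows the fitter recovering the generating inhibitor
response exactly from seven noiseless points. The second shows the full
image round trip: a rendered cell is segmented from its brightfield pair
and its N/C ratio and C-CDK concentration are recovered within a few
percent. The third runs the event detectors over simulated AF-mutant
lineages, in which 5% of C-CDK degradation events occur without a paired
division by construction; the estimate's confidence interval covers that
rate.

The same stages are scriptable from the shell (`cdksize simulate`,
`cdksize quantify`, `cdksize gate`, `cdksize doseresponse`,
`cdksize thresholds`, `cdksize lineage`, `cdksize run pipeline.yaml`).

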