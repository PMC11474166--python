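# contrapet

Analysis of **remote (contralateral) neuroinflammation in glioma** from
TSPO-PET imaging. Gliomas — glioblastoma in particular — provoke a myeloid
immune response far beyond the lesion; the 18 kDa translocator protein
(TSPO), upregulated in activated myeloid cells, makes that response
measurable by PET in the tumor-free hemisphere. `contrapet` implements the
full quantification chain for such a study, for imaging scientists and
neuro-oncology researchers:

* **volumes** — SUV (= C_tissue / (ID/BW)) and pons-referenced SUVr
  normalization, spherical VOIs, exact lateral flipping in a symmetric
  atlas grid, NIfTI I/O with JSON provenance sidecars.
* **kinetics** — one-tissue-compartment simulation
  (C_T = K1·∫C_p e^{−k2(t−s)}ds), image-derived input functions, and Logan
  graphical analysis with flexible t* producing VT = K1/k2 and
  pons-scaled VTr maps.
* **segmentation** — TBR and rCE background-normalized maps and
  iso-contour region growing from seed points (thresholds 1.6 / 1.3,
  subject-specific TSPO threshold) inside a confining mask.
* **regional** — mirrored atlas parcellation (123 regions per hemisphere),
  15 anatomo-functional groups, z-scores vs controls, equal-variance t
  tests with Benjamini–Hochberg FDR and Cohen's d.
* **connectivity** — tumor-seed correlations, pooled matched-region
  interhemispheric correlation, interregional synchronicity matrices,
  voxel-wise seed regression (slope and t maps).
* **outcome** — partial correlation, multiple regression, Cox
  proportional-hazards (per-SD hazard ratios, Efron ties), log-rank after
  median split, covariate-adjusted group comparisons.
* **scradiotracing** — per-cell radiotracer uptake from sorted-cell
  pellets: decay correction, Bq/cell, %ID×BW, group fold changes.
* **synthetic** — a seeded cohort generator (volumes, atlas, kinetics,
  survival, pellets) providing ground truth for every stage.
* **pipeline / CLI** — `contrapet run-all` orchestrates everything with a
  checksummed provenance manifest and cached, bit-reproducible re-runs.

## Worked example

Run the full pipeline on a synthetic cohort (41 glioblastoma, 7 IDH-mutant
astrocytoma WHO 2, 20 healthy controls; fast 32³ profile):

```bash
contrapet run-all --out runs/demo --seed 1 --profile fast
# completed: 9 stages (9 computed)
python -c "import json; print(json.load(open('runs/demo/regional_stats/summary.json')))"
```

which prints (seed 1):

```
{'alpha_fdr': 0.05,
 'contralateral_elevation_pct': {'GBM': 9.32, 'IDHmut-A2': -3.45},
 'n_regions': 123, 'n_significant': 120}
```

Reading: the glioblastoma group's contralateral hemisphere SUVr is ~9%
above the healthy-control reference (the generator injected +9%), the
IDH-mutant group (n = 7, so noisy) shows no systematic elevation, and at
FDR q ≤ 0.05 120 of the 123 contralateral regions are individually
significant for this draw. `runs/demo/outcome/outcome.json` holds the Cox
models — for seed 1 the univariate hazard ratio per SD of contralateral
signal is 2.42 (generator truth 2.18) with log-rank χ² = 8.97 and
median survival 7.1 vs 31.8 months across the median split —
`segment/tumor_volumes.tsv` the per-modality tumor volumes, and
`scrt/scrt.json` the myeloid vs non-myeloid per-cell uptake fold changes.
Re-running the same command reports every stage as `cached`,
byte-identical.

The same machinery is available as a library:

```python
from contrapet.synthetic import CohortConfig
from contrapet.pipeline import analyze_cohort_regional

res = analyze_cohort_regional(CohortConfig.fast(seed=1))
print(res["elevation_pct"], res["n_significant"])
```

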