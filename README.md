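# petpair

Paired quantification of dedicated-breast PET (dbPET) versus whole-body
PET (wbPET) images of the same breast tumor: PERCIST-style uptake
metrics, metabolic volumes, 20 radiomic features, and exact paired
nonparametric statistics — together with a digital phantom simulator
that generates matched dbPET-like (1 mm voxel, narrow PSF) and
wbPET-like (4 mm voxel, wide PSF) acquisitions of one ground-truth
lesion, so the entire chain is testable without patient data.

It is written for quantitative-imaging researchers who want a
transparent, dependency-light reference implementation of this analysis
rather than a clinical tool.

## What it computes

For a tumor volume of interest (VOI) segmented as the seeded
26-connected component of {SUV ≥ T} (T = 3.0 db / 2.5 wb):

* **SUL = SUV · LBM/W** — uptake normalized by Janmahasatian lean body
  mass; SUL_max, SUL_mean, and **SUL_peak** = max over the tumor of the
  mean in a 1.2 cm spherical kernel (~1 mL, per PERCIST);
* **MTV** = Σ voxel volumes with SUV ≥ 0.4 · SUV_mean(VOI), and
  **TLG** = MTV · SUV_mean over the MTV sub-region;
* tumor-background ratios against 1.2 cm liver / contralateral-breast
  VOIs;
* **20 radiomic features** (mesh volume, surface area, sphericity, max
  3D diameter; entropy, uniformity, skewness, kurtosis, SD; six GLCM
  and five NGTDM texture features) after 2 mm isotropic resampling and
  fixed-bin-width (w = 0.5) discretization, implemented from first
  principles along IBSI definitions and verified against brute-force
  oracles;
* paired db − wb comparison per metric/feature: **exact Wilcoxon
  signed-rank p-values** and **Hodges–Lehmann median differences with
  distribution-free 95% CIs**, plus a size-stratified summary (d_MRI
  ≤ / > 2.5 cm) with fold changes of stratum medians.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import pandas as pd
from petpair import generate_cohort
from petpair.pipeline import RunConfig, quantify_case
from petpair.stats import compare_modalities

cases = generate_cohort(4, seed=11)          # 4 paired simulated patients
cfg = RunConfig(n_cases=4, seed=11)
rows = [quantify_case(c, m, cfg) for c in cases for m in ("db", "wb")]
df = pd.DataFrame(rows)
print(df[["case_id", "modality", "SUL_max", "SUL_peak",
          "MTV_mL", "TLG", "d_MRI_cm"]].round(2).to_string(index=False))
```

```
case_id modality  SUL_max  SUL_peak  MTV_mL    TLG  d_MRI_cm
case-00       db     9.15      7.67   18.95 198.22      3.21
case-00       wb     7.43      6.95   27.65 201.38      3.21
case-01       db     5.85      5.15   54.27 350.09      4.63
case-01       wb     5.08      4.79   65.66 349.66      4.63
case-02       db    10.12      8.43   95.77 992.19      5.58
case-02       wb     8.38      7.88  116.86 996.80      5.58
case-03       db     6.40      4.62    4.90  28.82      2.04
case-03       wb     4.32      3.75    7.04  28.31      2.04
```

Each case is one ground-truth lesion imaged under both configurations.
The partial-volume effect is visible directly: the high-resolution db
images recover higher SUL_max/SUL_peak (least attenuated for the large
5.6 cm lesion, strongest for the 2 cm one), while blur inflates the
threshold-segmented metabolic volume on wb — the same directions the
paired statistics then quantify:

```python
cmp = compare_modalities(df[df.modality == "db"], df[df.modality == "wb"],
                         ["SUL_max", "SUL_peak"])
```

```
 feature  db_median  wb_median  median_difference  ci_low  ci_high  p_value
 SUL_max      7.775      6.259              1.725   0.765    2.077    0.125
SUL_peak      6.413      5.873              0.628   0.360    0.877    0.125
```

(p = 0.125 is the smallest attainable two-sided exact p at n = 4; the
CI is flagged as the widest attainable at this n.)

The same analysis is available from the shell:

```bash
petpair run-all --n 10 --seed 1 --out run1      # full pipeline + reports
petpair simulate --n 10 --seed 1 --out cohort   # or stage by stage
petpair quantify cohort --out metrics.csv
petpair compare --metrics metrics.csv --out-dir reports
```

`run-all` writes NIfTI volumes with JSON sidecars, `metrics.csv`,
`features.csv`, paired-comparison and stratified-summary tables,
50-bin tumor SUL histograms, a YAML provenance config and a manifest.

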