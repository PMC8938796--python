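# spectromics

Spectral photon-counting micro-CT material decomposition and radiomic
classification of nanoparticle contrast-enhanced tumors.

Photon-counting detectors (PCD) bin X-ray photons into energy channels; with
thresholds at 25, 34, 50 and 60 keV, the middle bins bracket the iodine
K-edge (33.2 keV), so an iodinated nanoparticle contrast agent retained in a
tumor (EPR effect) can be quantified per voxel. This package is for
preclinical imaging groups who want to ask whether such spectral data — and
the radiomic texture signatures computed from it — can separate tumor
phenotypes (here: lymphocyte-present vs lymphocyte-deficient hosts) better
than a conventional energy-integrating detector (EID) scan.

The pipeline implements:

* **Material decomposition** — per voxel, solve `b = A x` where `b` holds
  the four bin intensities, `A` is a 4×3 sensitivity matrix calibrated from
  vials of known composition, and `x = (c_I, c_PE, c_CS)` are the iodine /
  photoelectric / Compton basis concentrations; the overdetermined system is
  solved by least squares.
* **Semantic metrics** — tumor volume, iodine-enhanced volume and percent,
  accumulated iodine mass, mean iodine concentration (voxels < 1 mg/mL
  discarded as sub-detection noise).
* **Agnostic radiomics** — 851 features per volume: 14 shape + 93
  first-order/GLCM/GLRLM/GLSZM/NGTDM/GLDM features on the original image and
  8 wavelet sub-bands; grouped into EID (851), PCD (3404) and material-map
  (2553) feature spaces.
* **Statistics & classification** — Wilcoxon–Mann–Whitney screening with
  Benjamini–Hochberg control; MRMR feature ranking (mutual-information
  relevance minus redundancy); 50×5 stratified Monte Carlo cross-validation
  with in-fold selection and an L2 logistic model; pooled ROC/AUC, metrics at
  the precision–recall intersection threshold, and pairwise signed-rank
  comparison of feature spaces.
* **Synthetic cohorts** — a phantom generator producing co-registered PCD,
  EID and ground-truth material volumes for two classes, so the whole
  analysis is testable without animal data.

## Worked example

```python
from spectromics import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=0))

sem = result.semantic.groupby("class")["mean_iodine_mgml"].mean()
print(f"mean iodine (mg/mL): deficient {sem[0]:.2f} vs present {sem[1]:.2f}")
for group, rep in result.reports.items():
    print(f"{group:13s} AUC {rep.auc:.3f} +/- {rep.auc_sd:.3f}   accuracy {rep.accuracy:.3f}")
print(f"signed-rank p (PCD vs EID): {result.comparisons['PCD_vs_EID']:.2e}")
```

prints (about a minute on one core):

```
mean iodine (mg/mL): deficient 3.20 vs present 5.11
EID           AUC 0.847 +/- 0.052   accuracy 0.738
PCD           AUC 0.962 +/- 0.028   accuracy 0.886
MaterialMaps  AUC 0.957 +/- 0.028   accuracy 0.874
signed-rank p (PCD vs EID): 7.98e-10
```

Reading this: the default cohort simulates 13 lymphocyte-present and 12
lymphocyte-deficient subjects. The decomposed iodine maps show the positive
class retaining more contrast agent (5.11 vs 3.20 mg/mL — the
leakier-vasculature effect), the classifier built on the four spectral bins
separates the classes best, and the paired signed-rank test confirms the
spectral-over-conventional advantage across the 50 cross-validation
repeats. AUC ± values are standard deviations over repeats.

The same analysis is scriptable from a shell:

```bash
spectromics run --n-pos 13 --n-neg 12 --seed 0 --out results/demo
spectromics report --results results/demo --out results/demo/figures
```

and the individual stages (`simulate`, `decompose`, `segment`, `features`,
`analyze`) operate on NIfTI volumes and CSV feature tables for use with
external data. See `docs/methods.md` for the model, the pinned numerical
choices, and what the synthetic cohorts do and do not emulate.

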