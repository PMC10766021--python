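# ki67cl

Spatial colocalization scoring of Ki67 immunohistochemistry for breast
cancer risk stratification, with the survival machinery to validate it.

## The problem

Ki67 is a nuclear marker of proliferating cells. The conventional
automated Ki67 index of a whole-slide image — the fraction of
Ki67-positive tumor cells in the invasive region — ignores *where* the
proliferating cells sit. Two slides with the same 20% positivity can look
completely different: one has its Ki67-positive cells packed into a few
hot spots, the other has them scattered evenly among the resting tumor
cells. The Ki67CL score captures that difference as a single number, for
pathologists and computational-pathology researchers studying
intermediate-risk (ER+/HER2−) breast cancer.

## The score

Given classified cell centroids of one slide (Ki67±, tumor/nontumor),
tumor cells are grouped into spatial clusters by average-linkage
agglomerative clustering (Euclidean metric, 300-pixel linkage threshold
at ×40, on a random subset of at most 10,000 cells, with the remainder
assigned by the nearest-neighbor rule). The slide-level score is the
unweighted mean of the per-cluster binary Shannon diversity:

```
Ki67CL = −(1/C) Σᵢ [ pᵢ⁺ log₂ pᵢ⁺ + (1 − pᵢ⁺) log₂(1 − pᵢ⁺) ]
```

where pᵢ⁺ is the Ki67-positive fraction of tumor cells in cluster *i* and
C the number of clusters. Ki67CL ∈ [0, 1]: 0 when every cluster is pure
(fully segregated slide), 1 when every cluster is perfectly balanced
(maximally intermixed). The AutoKi67 ratio — Ki67-positive tumor cells
over all tumor cells in the invasive region — is computed alongside for
comparison.

The package also implements:

- region handling (tumor / DCIS / normal polygons as GeoJSON) with the
  two scoring settings: whole-slide (with DCIS) and invasive-only
  (without DCIS);
- the survival validation protocol: Kaplan–Meier stratification with
  log-rank testing, 3-fold cross-validated cutoff selection (combined
  p = min(1, 2 × median of fold p-values), combined C-index =
  mean ± SD), Harrell's concordance index, and univariate/multivariate
  Cox regression with hazard ratios and 95% CIs;
- the deterministic post-processing of a dot-regression cell detector:
  Gaussian dot-to-density mapping, 252-px patch tiling, per-channel
  local-maxima extraction, 15-px cross-channel merging, and 20-px
  one-to-one detection matching with agreement metrics;
- a synthetic-data generator for slides (with a mixing dial controlling
  colocalization at fixed positivity), survival cohorts (two-group
  proportional hazards tied to the true score), and probability maps.

## Worked example

```python
import numpy as np
from ki67cl import (SlideSimConfig, CohortSimConfig, simulate_slide,
                    simulate_cohort, score_slide)
from ki67cl.survival import cross_validate_marker, records_to_frame

# a partly segregated slide: 9 blobs, 30% Ki67 positivity, mixing 0.4
cells, _ = simulate_slide(SlideSimConfig(n_blobs=9, cells_per_blob=60,
                                         mixing=0.4, positivity=0.3, seed=11))
s = score_slide(cells, seed=11)
print(f"ki67cl={s.ki67cl:.3f} autoki67={s.autoki67:.3f} "
      f"clusters={s.n_clusters} tumor_cells={s.n_tumor_cells}")

# validate a marker on a simulated 600-patient cohort
rng = np.random.default_rng(11)
scores = rng.uniform(0, 1, 600)
df = records_to_frame(simulate_cohort(scores, CohortSimConfig(n_patients=600, seed=11)))
cv = cross_validate_marker(df, k=3, seed=11)
print(f"combined_p={cv.combined_p:.2e} "
      f"combined_c={cv.combined_c_mean:.3f}+/-{cv.combined_c_sd:.3f} "
      f"cutoff={cv.chosen_cutoff:.3f}")
```

prints

```
ki67cl=0.201 autoki67=0.185 clusters=9 tumor_cells=540
combined_p=9.96e-06 combined_c=0.590+/-0.003 cutoff=0.480
```

The slide's Ki67CL of 0.201 reflects mostly pure clusters (mixing 0.4
means most blobs are single-class); its AutoKi67 of 0.185 is near the
configured 30% positivity given blob-level class sampling. On the cohort,
patients whose marker exceeds 0.5 carry twice the baseline hazard by
construction, and the cross-validated protocol detects that
(combined p ≈ 1e−5) with a concordance of 0.59 for the continuous marker.

A command-line interface mirrors the library:

```sh
ki67cl simulate --seed 3 --out-dir run/      # cells.csv, survival.csv, manifest
ki67cl score run/cells.csv --out-dir run/    # slide scores CSV
ki67cl cv --scores run/scores.csv --survival run/survival.csv --out-dir run/
ki67cl survival --scores ... --survival ... --cutoff 0.375 --out-dir run/
ki67cl eval-detect --predictions pred.csv --truths truth.csv --out-dir run/
```

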