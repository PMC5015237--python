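# hotnode

Computer-assisted detection of sentinel-lymph-node (SLN) candidates on paired
SPECT/CT volumes, with the confusion-matrix machinery used to evaluate such a
reader against experts, and a seeded digital-phantom generator for testing the
whole chain without patient data.

## The problem

Preoperative lymphoscintigraphy with Tc-99m nanocolloid produces a SPECT
volume in which the sentinel node appears as a small focal tracer accumulation
("hot spot") — dwarfed by the peritumoral injection depot — together with a
co-registered low-dose CT for anatomical context. Reading these hybrid
datasets is slow and requires combined nuclear-medicine/radiology expertise.
`hotnode` implements a classical computer-assisted reader for this task:

1. **SPECT segmentation.** Both volumes are resampled to a common 1 mm
   isotropic grid (cubic B-spline), and SPECT voxels below 1 % of the
   reference activity are zeroed. Local maxima under a moving 3×3×3 mask
   become seeds; from each seed a region is grown over the 26-neighbourhood,
   absorbing a neighbour *n* of an accepted voxel *c* iff
   `0 < v(n) ≤ v(c)` (descent only — a value increase is never crossed).
   Voxels claimed by two or more regions ("common voxels", saddle zones
   between touching foci) are deleted from all regions, so no hot spot is
   absorbed by a hotter neighbour and the final regions are pairwise disjoint.
2. **CT segmentation.** Every voxel is assigned one of four tissue classes by
   Hounsfield thresholds — air (HU < −200), fat (−200 ≤ HU < −20), muscle
   (−20 ≤ HU < 150), bone (HU ≥ 150) — and the bone mask is regularised by a
   morphological closing.
3. **Classification.** Each hot spot becomes a *true* (candidate SLN) or
   *false* finding. Lymph nodes cannot be extracorporal, in bone, or in air,
   and are embedded in fatty/connective tissue, so the hard criteria test the
   tissue composition of a thin shell around the focus (the CT values *inside*
   a hot spot carry no usable signal at low-dose resolution). The dominant
   injection-site spot is eliminated. Each finding gets an ordinal score
   `p = w_SPECT · (peak / global max) + w_CT · (shell soft-tissue fraction)`,
   a side (left/right of the body midline) and a drainage region
   (inguinal/secondary relative to an axial landmark plane), and the two
   probability-ordered lists are offered for expert correction.
4. **Evaluation.** From crosstab cells a (TP), b (FP), c (FN), d (TN):
   sensitivity `a/(a+c)`, specificity `d/(b+d)`, false-positive rate
   `b/(b+d)`, false-negative rate `c/(a+c)`; d may legitimately be unknown,
   in which case the dependent rates are reported as undefined.

## Worked example

Generate a phantom (ellipsoidal body, pelvis-surrogate bones, four planted
nodes, three decoys, a dominant injection depot; Poisson counting noise and
CT noise on), run detection on the native-resolution volumes, and score
against ground truth:

```sh
hotnode phantom --seed 11 --out-dir demo --native
hotnode detect --ct demo/ct_native.nii.gz --spect demo/spect_native.nii.gz \
               --landmark-plane-z-mm 56 --out demo/findings.json --seed 11
hotnode eval --findings demo/findings.json --truth demo/truth.json
```

prints

```
4 true / 4 false findings -> demo/findings.json
Phantom ground-truth match
--------------------------
  true-positive  (a):      4
  false-positive (b):      0
  false-negative (c):      0
  true-negative  (d):      4
  total             :      8

  Sensitivity         100.0 %
  Specificity         100.0 %
  False-positive rate 0.000
  False-negative rate 0.000
```

All four planted nodes were recovered as true findings (e.g. label 2,
score 0.472, right inguinal, centroid (31.8, 49.0, 39.1) mm); the false list
holds the injection depot (`injection_site`), the bone-embedded decoy
(`bone_context`), the extracorporal decoy (`extracorporal`) and the
air-adjacent decoy (`air_context`), each with the rules that fired.

Crosstab statistics work on plain count tables too:

```sh
printf 'a,b,c,d\n127,88,16,572\n' > counts.csv
hotnode stats --counts counts.csv
```

```
  Sensitivity         88.8 %
  Specificity         86.7 %
  False-positive rate 0.133
  False-negative rate 0.112
  Correction rate     12.95 %
```

i.e. of 803 findings classified by such a reader and then corrected by
experts, 88 were demoted and 16 promoted — a 12.95 % correction rate — giving
88.8 % sensitivity and 86.7 % specificity for the automated pass.

## Layout

| module | contents |
| --- | --- |
| `hotnode.imaging` | `Volume` model, NIfTI/DICOM I/O, resampling, background suppression |
| `hotnode.hotspots` | seed detection, region growing, common-voxel deletion |
| `hotnode.tissue` | HU classification, bone closing, body mask |
| `hotnode.classify` | features, injection-site elimination, verdicts, ranking, corrections |
| `hotnode.stats` | crosstabs, rates, truth matching, per-unit rollups |
| `hotnode.phantom` | seeded phantom generator and native-resolution degradation |
| `hotnode.cli` | `hotnode phantom / detect / correct / stats / eval` |

See `docs/methods.md` for the model assumptions, parameter defaults and known
limitations.
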