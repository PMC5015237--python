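# Methods

## Imaging model and coordinate conventions

A `Volume` is a 3-D scalar grid with voxel spacing, world origin and a
modality tag. Axis 0 is x (patient-left = increasing x), axis 1 is y
(anterior–posterior), axis 2 is z (inferior–superior); the world coordinate
of voxel *i* is `origin + i · spacing`. SPECT values are counts and are
clamped to ≥ 0 on load (negative values can only be reconstruction
artefacts). SPECT and CT are assumed co-registered, as on a hybrid scanner;
no registration is performed.

Native lattices are ~4×4×4 mm (SPECT) and ~1×1×5 mm (CT); all analysis runs
on a common 1 mm isotropic grid.

## Resampling

Resampling uses the cubic B-spline *basis expansion* (`scipy.ndimage.zoom`
with `prefilter=False`) rather than the interpolating spline. The
interpolating spline rings around isolated peaks; because SPECT output must
be non-negative, clamping those negative lobes would systematically inflate
total counts (by ~80 % for an isolated hot voxel). The basis expansion is a
smoothing spline: non-negative for non-negative input, a partition of unity
(constants are preserved to float precision), and it conserves the grid
integral `Σv · voxel volume` up to boundary effects. The price is extra blur
of roughly σ = voxel/√3 per axis of the *input* grid — an accepted trade-off;
edge handling replicates border values. Grid edges of input and output are
aligned, so the output origin shifts by `(target − source)/2` per axis.
Label grids use nearest-neighbour (order 0) resampling.

## Background suppression

Reconstructed counts are not calibrated to injected MBq, so "below 1 % of
the injected activity" is operationalised semi-quantitatively: zero every
voxel below `fraction × reference`, with `fraction = 0.01` and the reference
being the global maximum voxel (default) or the total counts (selectable).
A literal 1 % of a 150 MBq injection per voxel would erase every true node;
1 % of the depot-dominated maximum removes diffuse background while keeping
node peaks, which sit at roughly 1.5–10 % of the maximum under the phantom's
activity ratios. The operation is idempotent and never zeroes the global
maximum. It is applied after resampling by default; applying it before is a
config switch (`suppress_before_resample`), since the noise floor differs
slightly between the native and interpolated grids.

## Hot-spot segmentation

Seeds are voxels ≥ all in-bounds 26-neighbours with positive value (moving
3×3×3 mask; border voxels use truncated neighbourhoods). A connected
plateau of equal maximal values yields one seed at its lexicographically
smallest index — the tie rule is needed for determinism; adjacent candidate
maxima are provably equal-valued, so plateau detection is exact.

Each seed grows independently over the original volume: neighbour *n* of an
accepted voxel *c* is accepted iff `0 < v(n) ≤ v(c)`. The claim-set equals
monotone-path reachability (all voxels connected to the seed by a
non-increasing positive path); growth is realised with an explicit stack
(identical contract to the recursive formulation, no depth limit). Voxels
claimed by ≥ 2 seeds are deleted from every claim-set afterwards; a region
that loses its seed or empties is discarded with a log entry. Labels are
assigned in descending peak order. Centroids are intensity-weighted.

Disjointness is enforced at the shared-voxel level; remaining voxels of
distinct regions may still be adjacent, which is *reported*
(`adjacent_pair_count`) rather than eroded away. If two foci merge into a
single local maximum under the system blur, they are segmented as one larger
hot spot — the method's resolution limit, inherited from the imaging chain,
not a defect.

## CT tissue classification

Hounsfield thresholds partition the whole real line with lower-inclusive
half-open intervals: air < −200 ≤ fat < −20 ≤ muscle < 150 ≤ bone. The
boundary convention (a voxel at exactly −200 HU is fat) is a determinism
choice; the table's printed bounds touch and do not state inclusivity.
Classification is total and monotone in HU.

Bone is closed morphologically (ball element, default radius 3 mm,
configurable) to bridge trabecular gaps without joining distinct bones at
phantom scale; the input is padded before closing and the result is unioned
with the original mask, so closing is extensive and idempotent by
construction. A radius below the voxel size is a logged no-op.

The body mask is the largest 26-connected non-air component with holes
filled per axial slice, so interior gas pockets count as body. No denoising
precedes classification; robustness to CT noise is exercised downstream, at
the level of shell fractions, not of individual voxel labels.

## Finding classification

Hard criteria for a *true* finding (all must hold): not the injection site;
≥ 50 % of member voxels inside the body; shell soft-tissue (fat+muscle)
fraction ≥ 0.5; shell bone fraction ≤ 0.3; shell air fraction ≤ 0.3; volume
≥ 8 mm³. The shell is the 2 mm dilation of the region minus the region. All
thresholds live in `ClassifierConfig`; none are hard-coded. CT values inside
the hot spot are deliberately unused — at low-dose CT resolution nodal
tissue is not resolvable, but the immediate vicinity is a stable feature.

The score `p = 0.5 · normalized peak + 0.5 · shell soft-tissue fraction`
(weights configurable, clipped to [0, 1]) is an *ordinal* ranking quantity,
not a calibrated probability. It is monotone in the soft-tissue fraction by
construction. True findings are listed by descending score, false findings
by ascending score (most confidently false first); ties break by descending
peak then label.

Injection-site elimination: in `auto_max_activity` mode the single spot with
maximal total counts is forced false (the depot dominates every node's
uptake by design ≥ 5×, in practice ≥ 50×); `given_coordinate` mode instead
flags every spot whose centroid lies within 30 mm of a supplied coordinate,
for operators who know the injection location.

Side and region use a single axial landmark plane (inguinal below, secondary
above) and the body-centroid midline (left iff centroid x > midline; exact
ties go right, logged). A computable anatomical rule for the territory split
does not exist without an atlas, which is out of scope; phantoms carry the
plane in their ground truth.

Expert corrections move findings between lists; true→false moves are
tallied as false-positive corrections of the program, false→true as
false-negative corrections. Corrections never create or destroy findings.

## Evaluation statistics

`rates` computes sensitivity `a/(a+c)`, specificity `d/(b+d)`, FP rate
`b/(b+d)`, FN rate `c/(a+c)`. Undefined denominators (unknown d, or empty
positive column) propagate as `None`, never as numeric sentinels; the
complementarity identities (sensitivity + FN rate = 1, specificity +
FP rate = 1) hold exactly whenever defined. `crosstab_from_lists` derives
the cells from a program/corrected list pair over the same label set.
`per_unit_rollup` reports, separately, the per-unit crosstab rates and the
simple event proportions over all units — two different quantities (a
false-negative *rate* conditions on positives; a failure *proportion* counts
over all units).

Phantom scoring (`match_to_truth`) matches true findings to planted nodes
greedily in descending score within 10 mm. Greedy rather than
optimal-assignment matching is a deliberate simplification: phantom nodes
are separated far beyond the matching radius, so the two coincide; the
radius is a knob (`MatchSpec`).

Report rendering rounds percentages to one decimal and proportions to three
decimals; full-precision values are always retained in JSON.

## The phantom

The generator emulates the statistical structure the detector assumes, not
anatomy:

* **Geometry** (96×96×128 mm grid at 1 mm): ellipsoidal body (semi-axes
  42×34×62 mm) with a 10 mm fat shell over a muscle core; three bone
  cylinders as a pelvis surrogate (one "spine", two "femora"); one 8 mm
  interior air pocket (bowel gas).
* **CT**: class-centre HU values (air −1000, fat −100, muscle 40, bone 700)
  plus Gaussian noise (sd 20 HU). Centres sit well inside the threshold
  intervals so noise rarely flips labels.
* **SPECT**: point activities convolved with a Gaussian PSF (FWHM 8 mm, the
  reconstruction filter scale of the emulated system). The injection depot
  (10⁶ counts) is additionally spread by a depot σ of 6 mm — an intradermal
  peritumoral depot is physically extended — which fixes the ratio between
  the global maximum and node peaks: with it, a node at 0.3 % of the
  injected activity peaks at ~1.5–2.5 % of the maximum and survives the 1 %
  threshold. Node activities default to Uniform(0.3 %, 2 %) of the injection
  activity. Optional Poisson sampling adds counting noise.
* **Placement**: four canonical sites (two inguinal, one iliac, one
  para-aortic) with ±2 mm jitter, or rejection-sampled random sites.
  Pairwise separations exceed 24 mm (3× PSF FWHM) and every node lies
  ≥ 30 mm from the depot — the depot's above-threshold footprint (~22 mm
  radius) plus one PSF FWHM. A node closer to the depot sits on the tail's
  slope, has no local maximum of its own, and is absorbed into the depot
  spot; that absorption is the documented resolution limit, so the phantom's
  study conditions place nodes beyond it (consistently, the classifier's
  coordinate-mode exclusion radius is also 30 mm).
* **Decoys**: one focus inside the spine cylinder, one outside the body, one
  in the air pocket, each at 0.4 % activity, exercising the bone / 
  extracorporal / air exclusion rules.
* **Determinism**: one integer seed; per-purpose sub-streams (placement,
  fractions, CT noise, Poisson) are spawned in a fixed order so toggling one
  noise source does not perturb the others.

`degrade_to_native` block-averages the 1 mm volumes to the native lattices
(SPECT 4×4×4, CT 1×1×5; trailing partial blocks average the voxels that
exist), so end-to-end tests exercise the resampling stage. 128 is not
divisible by 5, so the degraded CT grows two extra axial slices on
round-trip; the pipeline crops co-registered grids to their common shape.

What the phantom does *not* model: tomographic reconstruction and its
correlated noise, attenuation and scatter, anthropomorphic anatomy, organ
parenchyma (the parenchymous-organ exclusion is approximated by the tissue
rules), and reader variability. Passing the phantom study therefore shows
the pipeline implements its stated contracts under PSF blur and counting
noise — it does not certify clinical sensitivity/specificity, which were
measured on patients in the source setting and are not reproducible without
patient data.

## Problem sizes in the distributed checks

The phantom study runs 20 seeded phantoms at the full 96×96×128 study
geometry (≈1 minute on one CPU); the segmentation-oracle equivalence check
samples 1000 random grids up to 6×6×6 with values in {0..4}, where
exhaustive path enumeration is tractable; the tissue-partition property uses
10⁶ random HU values.

## Known limitations

* Strict non-adjacency of distinct hot spots is not guaranteed by the
  common-voxel rule; residual adjacency is counted and logged, not eroded.
* Under heavy counting noise two seeds can arise inside one physical focus;
  their mutual overlap then deletes most of the focus (both claim nearly the
  same descent set). This is the specified algorithm behaving as specified;
  it is rare after the smoothing resampling step.
* The probability score is ordinal; scores are comparable within one run,
  not across configs.
* The DICOM reader handles plain axially-stacked single-frame series only.
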