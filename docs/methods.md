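# Methods

This note documents the models implemented in `noduletrack`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Coordinate conventions

All coordinates are millimetres in a fixed right-handed patient frame
(x lateral, y anterior–posterior, z cranio-caudal, positive cranial). No
voxel grid exists anywhere in the package, so slice indexing and image
spacing never enter. The estimated affine maps **baseline space into
follow-up space**; serialized transforms carry an explicit
`"frame": "baseline_to_followup"` field to avoid direction ambiguity.

## Registration

The inter-exam deformation is modelled as one global affine transform
`T(x) = Ax + t` (rotation, isotropic or anisotropic scale, shear, and
translation; no deformable component). It is estimated from anatomical
landmark sets by trimmed iterative closest point:

- **Initialization** — identity linear part, translation aligning the moving
  centroid onto the fixed centroid. The expected motions (rotations up to
  ~10°, scale changes of a few percent, translations up to ~20 mm) are well
  inside ICP's basin of convergence from this start.
- **Correspondence** — exact nearest neighbour from each moving landmark to
  the fixed set, ties broken by the lower fixed-point index so runs are
  deterministic. When both exams carry landmark labels,
  `use_labels=True` corresponds by label instead; the pairing is then fixed
  and ICP collapses to a single least-squares fit. Nearest-neighbour mode is
  the default because labelled correspondence cannot tolerate relabelling
  errors and the labelled problem is otherwise trivial.
- **Fit** — the affine minimizing the summed squared correspondence
  distances, solved by `numpy.linalg.lstsq` on homogeneous coordinates. A
  rank-deficient system (coplanar landmarks) yields the minimum-norm
  solution and sets `rank_deficient`; at least four correspondences are
  required.
- **Trimming** — each fit excludes the `ceil(f·n)` worst correspondences,
  default `trim_fraction = 0.1`. Trimming is the minimal robustness
  mechanism against landmarks that are occluded, missed, or spurious in one
  exam; set it to 0 for exact-recovery work.
- **Convergence** — stop when the trimmed RMS changes by less than
  `rms_tol_mm = 1e-6` or after `max_iter = 100` iterations. At landmark
  scale (tens of points) each iteration costs microseconds, so the tight
  tolerance is free and makes exact-recovery tests meaningful. The trimmed
  RMS is provably non-increasing across iterations (new correspondences can
  only shorten distances, and the new fit minimizes over them); the
  diagnostics record the full RMS history and a divergence guard aborts if
  the RMS ever exceeds 10× its initial value.

Registration is equivariant under a common rigid motion of both exams:
correspondence distances, and therefore every downstream matching decision,
are unchanged.

## Target selection and pairing

The evaluated targets are the `top_k = 10` largest solid baseline lesions
with diameter in `[5, 30]` mm, both bounds inclusive. Diameter ties at the
cutoff are broken by lexicographically smaller lesion id (deterministic).
Subsolid and mixed-texture lesions are excluded at selection; lesions whose
ground truth says the nodule truly vanished are excluded later, at
adjudication, because that exclusion requires truth.

Mapped baseline centroids are paired with follow-up detections one-to-one:
all candidate pairs with Euclidean distance **strictly below**
`threshold_mm = 15` are sorted by distance (exact ties by baseline id, then
follow-up id) and accepted greedily. Greedy assignment is deterministic and
order-independent, and coincides with the maximum-cardinality,
minimum-total-distance assignment whenever distinct nodules are not crowded
at the threshold scale — the regime this pipeline is designed for, and the
regime verified exhaustively in the tests. In heavily crowded scenes
(several nodules within 15 mm of each other) greedy can differ from the
global optimum; that is a known limitation, not a target of this design.
Distances are centroid-to-centroid; surface-to-surface distances would
require segmentations that do not exist in this data-minimalistic setting.

### End-to-end guarantee

When the true deformation is exactly affine, every nodule is detected in
both exams, and distinct true nodules stay more than twice the threshold
apart after registration, the pipeline recovers the truth exactly: both
matching rates are 100%. With detection dropout probability `p` as the only
error source, the conditional rate stays 100% while the overall rate
concentrates at `1 − p` — the two denominators cleanly separate detection
failure from assignment failure. Both properties are asserted in the test
suite.

## Outcome taxonomy and rates

Each selected baseline lesion receives exactly one outcome:

| outcome | meaning |
|---|---|
| `false_positive_detection` | the baseline detection is not a true nodule |
| `correct_match` | paired with its true counterpart |
| `incorrect_assignment` | paired with a different nodule |
| `missed_matching` | a true nodule left unpaired (undetected at follow-up, or outside the threshold) |

The four categories partition the evaluated lesions. Rates come with
explicit denominators: overall = correct / (evaluated − false positives);
conditional = correct / (nodules whose counterpart was detected in both
exams — truth information passed in explicitly; without it the code falls
back to correct + incorrect, which is equivalent when every miss is a
detection failure). Per-case rates divide a case's correct matches by its
evaluated true nodules; any zero denominator is reported as undefined with
a flag, never as silent NaN. A baseline lesion evaluated against two
follow-up exams of the same patient counts once per pair throughout.

## Statistics

- **χ² independence** — plain Pearson chi-square on the r×c contingency
  table (no Yates correction, as appropriate for association screening at
  these sample sizes), df = (r−1)(c−1), computed via
  `scipy.stats.chi2_contingency`. Pearson residuals `(O − E)/√E` are
  exported per cell for association plots; their squares sum to the χ²
  statistic. Expected cells below 5 trigger a warning, not an error. A
  zero row or column margin is a degenerate table: the stratified view then
  reports rates but no test, rather than fabricating zero residuals.
- **Mann–Whitney U** — two-sided; exact null enumeration when the smaller
  group has ≤ 8 observations and there are no ties, otherwise the tie- and
  continuity-corrected normal approximation (`scipy.stats.mannwhitneyu`).
  The continuity correction keeps exact and asymptotic p-values within 0.02
  of each other at n = 8 vs 8. Pairwise p-values are reported unadjusted;
  a Holm adjustment is available but off by default, matching common
  practice for screening analyses.

## The synthetic generator

`SyntheticConfig` defaults describe the cohort the pipeline is meant to be
evaluated on; one master seed spawns independent per-case (and per-follow-up)
streams so any case is reproducible in isolation and identical configs give
byte-identical tables.

**Geometry.** Each case gets two half-ellipsoid lungs (semi-axes ≈ 50–55 ×
80–85 × 100–105 mm, jittered ±8%), truncated below by a paraboloid
diaphragm dome, with a stylized vessel tree of line segments radiating from
each hilum. Only three distance queries matter — to the pleural surface
(radial distance to the ellipsoid), to the diaphragm (vertical clearance
above the dome), and to the nearest vessel segment — because localization
semantics are defined through them:

- juxtaphrenic: diaphragm distance ≤ `contact_tol_mm` (2.0 mm
  operationalizes "directly adjacent", which is otherwise unquantified);
- else juxtavascular: vessel distance ≤ `contact_tol_mm`;
- else peripheral: pleural distance ≤ `pleura_margin_mm` (10 mm);
- else parenchymal.

The precedence (juxtaphrenic > juxtavascular > peripheral > parenchymal)
makes the categories exclusive; diaphragm contact is the rarest and most
specific, so it wins.

**Nodules.** Per-exam total counts follow the cohort regimes
(<20 / 20–50 / >50 with weights 0.608 / 0.203 / 0.190) or a fixed count.
Placement respects the localization mix (default 0.497 / 0.313 / 0.149 /
0.041) with geometric consistency enforced by rejection sampling (bounded
retries; infeasible requests raise a placement error). Diameters are
log-normal, σ = 0.3703 fitted from the target interquartile range on the
log scale and μ = 2.1667 calibrated by root-finding so the median **after**
truncation to [5, 30] mm is exactly 9.0 mm (truncated IQR ≈ [7.2, 11.4] mm
versus the target [7.1, 11.7]). A small fraction (5%) of nodules are
subsolid and thus dropped at selection.

**Follow-up construction.** All baseline points are first displaced by a
smooth caudal diaphragm shift `Δz = −s·exp(−d/λ)` (default magnitude
`s = 10` mm at the diaphragm, e-folding `λ = 30` mm; an idealization of the
breathing-state difference between visits, for which no quantitative model
is published — both knobs are exposed), then mapped by a random affine
drawn within `rotation ≤ 10°`, `scale ∈ [0.95, 1.05]`,
`|translation| ≤ 20 mm` per axis. The recorded ground-truth transform is the
affine alone, so with the shift at zero the truth is exact by construction.
Nodule positions additionally receive isotropic Gaussian jitter
(`residual_jitter_mm = 1.0`, detection-centroid variability at voxel scale).

**Detection simulation.** Follow-up detection dropout has base probability
`dropout_prob = 0.08`, increased by `dropout_count_coupling = 0.001` per
nodule in the exam (detection is harder in crowded lungs) and multiplied by
per-localization factors (0.75 / 1.4 / 1.7 / 2.0 for parenchymal /
peripheral / juxtavascular / juxtaphrenic — CAD finds air-surrounded
parenchymal nodules most easily and vessel- or diaphragm-abutting ones
least easily). Landmarks are occluded at follow-up with probability
`occlusion_per_nodule × count` (default 0.002), degrading registration in
high-count exams. False positives are injected at baseline at
`fp_rate = 0.3` expected per exam; because selection keeps the ten largest
lesions, false positives survive selection mostly in low-count exams — the
overrepresentation the evaluation reproduces. Nodules truly disappear with
`disappear_prob = 0.03` (sampled once per case, removed from every
follow-up, excluded at adjudication). Minimum nodule separation defaults to
2 mm (no overlapping detections); recovery experiments raise it to 35 mm to
enter the guaranteed regime.

**What the generator does not emulate.** No image content of any kind —
attenuation, texture, emphysema or fibrosis (absent from the target cohort
anyway), respiratory mechanics beyond the single diaphragm displacement
field, nodule growth or shrinkage between exams, baseline detection misses
(the evaluation starts from lesions registered at baseline by design), or
follow-up false positives. Passing tests therefore demonstrate the
correctness and the failure-mode structure of the *matching pipeline* under
controlled error sources; they do not certify performance on real CT data,
where detection and landmark errors are correlated with anatomy in ways a
stylized geometry cannot capture.

## Problem sizes used in validation

The default synthetic study is 100 cases / 153 pairs (~1,300 evaluated
lesions), the scale the pipeline targets; recovery and sweep experiments in
the test suite use 20–100 cases with fixed per-case counts of 6–80 nodules,
chosen so that each direction check rests on several hundred nodules per
grid point. The exhaustive assignment oracle runs on 1,000 random instances
with up to 6 lesions per side, the largest size at which exhaustive
enumeration stays trivial.

## Known limitations

- A single global affine cannot represent differential motion; the caudal
  shift deliberately violates it near the diaphragm, and the resulting
  juxtaphrenic failures are a feature of the evaluation, not a bug of the
  simulator.
- Greedy pairing is optimal only away from threshold-scale crowding (above).
- The per-localization detection factors and the diaphragm-shift magnitude
  are plausibility choices where no quantitative measurements are published;
  both are configuration fields, and every qualitative claim in the test
  suite is a direction check, not a fit to those defaults.
- Statistical conventions (two-sided tests, inclusive 20–50 count bin,
  unadjusted pairwise p-values) follow the conservative defaults stated
  above; alternatives are a flag away but change no shipped result.
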