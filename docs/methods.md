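# Methods

## Scope

The package models the *reading* of dual-phase amyloid PET, not its
acquisition: inputs are reconstructed 3D volumes (NIfTI-1), and every
decision is ratio- or window-based so absolute activity calibration never
enters. Voxel indices are 0-based; world coordinates are RAS+ mm;
interpolation is trilinear with zero fill (smooth PET data, closed-form
testability).

## Phantom

The synthetic anatomy is a concentric-ellipsoid head: a white-matter
core, a cortical grey-matter shell whose outer surface carries a
sinusoidal radial perturbation (amplitude 3.5 % of the local radius,
azimuthal frequency 7, elevational frequency 4) that carves flat sulci
and thin gyral ribbons, ventricular plus sulcal CSF, and inferior
cerebellar and pons/peduncle ellipsoids. The shell is split into the
eight regions a visual amyloid read inspects by azimuthal sector — a
schematic, not an anatomical atlas; it exists to stress the edge
delineation and the regional rating logic, not to look like a brain.

Parameters that matter (defaults in parentheses):

- `shape` (96×96×80) and `spacing` (2 mm isotropic): desk-scale grids;
  all geometry is specified in mm so coarser test grids reuse the same
  anatomy.
- `gm_thickness` (4 mm) and `atrophy` (0): ribbon thickness is
  `gm_thickness · (1 − atrophy)`; the generator refuses specs whose
  ribbon falls below one voxel, and ventricles dilate by a factor
  `1 + 1.5·atrophy`.
- Early-phase levels: GM 1.0, WM 0.35, pons 0.8, CSF 0.05. Late-phase
  levels relative to the white-matter level: cortical region r at
  `0.40 + 0.70·burden[r]`, cerebellar cortex 0.40, pons 0.55. These are
  calibration constants of this package, chosen so that a burden sweep
  crosses the visual positivity boundary (GM/WM = 1) inside [0, 1] — at
  burden 6/7 — and so that the early threshold default separates WM from
  GM. The pons late-phase ratio 0.55 is likewise a calibration constant,
  not a measured value.
- `noise_scale` (200 expected counts per unit intensity): Poisson
  surrogate noise, voxel → Poisson(scale·v)/scale, seeded. This
  reproduces count-limited speckle; it does not model reconstruction
  correlations, scatter, or partial-volume effects.
- `motion_sigma` (0 mm): isotropic Gaussian blur in mm emulating
  intra-frame head movement. On an amyloid-free phantom a 4 mm blur
  strictly raises every regional GM/WM ratio — the false-positive
  mechanism of late-frame motion — which the tests assert directionally.

What passing phantom-based tests shows: that the edge threshold, the
windowing arithmetic, the regional grading and the end-to-end
burden→score monotonicity behave as designed on images with the stated
contrast structure and Poisson-like noise. It does not show performance
on real anatomy, real tracer kinetics, or reconstruction artefacts.

## Registration

Rigid-only (both phases come from the same session and scanner), six
parameters: extrinsic x-y-z Euler angles about the fixed volume's grid
centre plus a translation. The metric is normalized cross-correlation
over a head mask (fixed-phase intensity above 5 % of the 99th-percentile
robust maximum); NCC is smooth and adequate because both phases are PET
with strongly correlated structure. The optimizer is coordinate descent
at downsample factors 4, 2, 1 (Gaussian smoothing before decimation);
step sizes start at 2·factor (mm and degrees share the scale), halve
when a full sweep gains < 1e-4 in NCC, and the level stops at a 0.1·factor
step floor or 100 sweeps. The initial guess is the identity. On noiseless
phantoms the recovered transform matches an imposed misalignment within
about 0.05 mm/0.05°; the tests assert 1 mm/1° (noiseless) and
2 mm/2° (Poisson noise at scale 200).

Numerical note: warping a volume through T and then T⁻¹ involves two
trilinear resamplings and incurs an irreducible interpolation error of
order 0.2–1 % of peak even on smooth data; the exactness of the inverse
is therefore asserted parametrically (composition within 1e-9 of the
identity) and the image-space round trip at 1 % of peak.

## Edge extraction and display

- Edge threshold default: 0.45 × robust_max(early, 0.99). Homogeneous of
  degree 1 in intensity, and positioned between the phantom's WM (0.35)
  and GM (1.0) levels; overridable wherever it is used (the manual
  adjustment of an interactive read becomes an explicit parameter).
- Speckle control: 26-connected components smaller than 1 % of the
  largest are dropped before edge formation.
- The edge map is the retained mask minus its 6-neighbour erosion: a
  one-voxel shell marking both the outer cortical surface and the inner
  GM/WM interface.
- Display window: lower 0, upper = mean(late | reference)/0.9, putting
  the reference mean at 90 % of the range. The mean (not the peak) is
  used for noise robustness; the reference statistic is not standardized
  anywhere, so this is a design choice recorded in output manifests.
- Colour tables are open piecewise-linear approximations (spectrum,
  edges, warm metal) shipped as explicit stop lists; vendor lookup
  tables are proprietary and not reproduced.

## Automated rater

Regional levels are medians (robust to spillover voxels). Grade
cutpoints: clearly abnormal at ratio ≥ 1.00 (inclusive, mirroring "the
same or higher"), borderline from 0.90. Scan positivity requires a
clearly abnormal region; an ambiguous best grade therefore resolves
negative. The five-point score (5 at ratio ≥ 1.10; 4 for clearly
abnormal below that; 3 borderline; 2 for best ratio in [0.70, 0.90);
1 below) and the confidence map
`1 + min(4, floor(|max_ratio − 1.00| / 0.05))` are operational
conventions of this package for producing machine ratings in the same
format as human ones; they are not calibrated against readers.

Without an anatomy label map, the grey-matter mask is the supra-threshold
early region itself, white matter is the head interior minus the dilated
grey-matter mask (eroded once), and the regional split reuses the same
azimuthal sectors as the phantom about the grey-matter centroid; on the
default phantom the label-free regional ratios agree with the labelled
path within 0.05.

## Study simulation

A one-dimensional latent-signal model: subject signal ±μ/2 with
prevalence 0.47, rater perception = signal + N(0, 1/d²) with
method-specific discrimination d, binary call = sign, five-point score by
fixed cutpoints (−1.5, −0.5, 0.5, 1.5), confidence = 1 + min(4,
⌊|perception|⌋). Defaults: 120 subjects, 5 raters, μ = 2, d = 1.75 (std
display) and 2.1 (edge-overlay display). The discriminations were
calibrated analytically — a per-rater flip probability Φ(−μd/2) of ≈ 4 %
and ≈ 1.7 % makes roughly one-fifth vs one-twelfth of five-reader panels
non-unanimous — which lands the mean binary Fleiss κ near 0.84 and 0.93
and unanimity near 81 % and 91 % at the default size. `d = 0` is the
pure-noise limit (unit-variance noise, no signal), giving chance-level
agreement. The model claims no psychometric realism; it exists to give
the agreement statistics a ground truth with a known ordering.

## Statistics

All agreement statistics are computed from their definitions (see
README for the formulas) and cross-checked in the tests against
independent implementations: statsmodels for Cohen's κ (point and
variance, both weightings) and the Fleiss κ point value, pingouin for
ICC(A,1) and its interval, scipy for χ² and the paired t. The Fleiss CI
uses the large-sample overall-kappa SE with z = 1.96. The Pearson χ²
deliberately applies no continuity correction. Missing data policy:
pairwise-complete deletion for two-rater kappas and the paired t;
complete-case (subject-level) deletion for Fleiss, ICC and concordance
counts. Binary categories are coded {negative = 1, positive = 2}
internally; ratings CSVs use {0, 1} with 1 = positive. Reported values
round to 2 decimals (kappas, ICC, CI bounds) and 1 decimal (percents);
full precision is kept internally.

Degenerate-input policy: kappas raise when chance agreement is 1; the
paired t reports t = 0, p = 1 for identically zero differences and flags
nonzero constant differences (`zero_variance`, p → 0); registration
refuses constant volumes; `robust_max` refuses all-zero volumes; an
empty edge map is a legal return value, not an error.

## Problem sizes

Tests run phantoms at 96×96×80×2 mm (pipeline properties) and
48×48×40×4 mm (registration recovery, which is the costly operation);
the study simulator uses 50 replicates of 120 subjects × 5 raters × 2
methods. These sizes were chosen as the smallest at which each property
is meaningfully exercised.

## Known limitations

- Schematic anatomy: no gyral variability, no partial-volume modelling,
  no kinetics over the uptake interval; results on phantoms bound what
  the code does, not clinical performance.
- Registration assumes same-session initialization (identity guess) and
  rigid motion only; large initial misalignments beyond the multiresolution
  capture range (~tens of mm/degrees) are out of scope.
- The automated rater's five-point and confidence mappings are
  conventions, not models of human readers; only the binary positivity
  rule mirrors the standard visual criterion.
- The published per-pair Cohen kappas, ICCs and paired-t p-values derive
  from raw ratings that were never released; those statistics are
  validated by oracle equivalence on synthetic panels, not by
  reproduction of the published numbers.
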