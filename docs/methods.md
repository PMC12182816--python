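# Methods

## The problem

2D through-plane phase-contrast (PC) CINE CMR encodes the through-plane
blood velocity in the image phase: a phase of ±π maps to ±VENC (cm/s).
Eddy currents, concomitant (Maxwell) gradient fields and gradient
imperfections add a spatially smooth, temporally constant *background
velocity offset* to every frame. Integrated over a vessel cross-section and
a cardiac cycle, offsets of well under 1 cm/s shift net flow and
regurgitation fraction by clinically meaningful amounts. The reference
remedy — repeating the identical sequence on a static gel phantom and
subtracting its velocity image — is accurate but impractical in routine
use, so image-based corrections estimate the offset from *static tissue*
(chest wall, liver, muscle), whose true velocity is ~0, and subtract a
fitted smooth surface.

`pccor` implements such a correction with a deliberately restricted
non-linear model, an automatic failure-mode evaluation that triages each
dataset into `use-npccor` / `use-uncorrected` / `perform-rescan`, flow and
regurgitation quantification, the static-phantom reference correction and a
first-order baseline, plus a synthetic scene generator that makes the whole
pipeline testable with no clinical data.

## Background model

The offset is modelled on the imaging plane, using magnet-frame pixel
positions (x, y, z) in cm, as

    v_bg = c0 + c1·x + c2·y + c3·z + c4·S(x, y, z)

where S is the spatial shape of the Maxwell concomitant field,

    S0 = A(x² + y²)/4 + B z² − C xz − D yz,

with (A, B, C, D) the time integrals of (Gz², Gx²+Gy², GxGz, GyGz) over the
gradient waveform. Only the *shape* of S matters — the physical prefactor
γ/2B₀ and amplitude are absorbed into the fitted c4 — so S is normalised to
unit RMS over the image before entering the design matrix. The gradient
moments are configuration (`ConcomitantModel.moments`); the default
symmetric bipolar flow-encoding model (1, 1, 0, 0) gives the canonical bowl
shape, and the simulator records its true moments with every scene so all
closed-loop tests are self-consistent. A full 10-term quadratic model was
deliberately not used: with scarce or noisy static tissue it over-fits, and
the single concomitant-shaped quadratic term captures the dominant
non-linear component.

### Coefficient identifiability

On a single slice, the plane equation makes z an exact affine function of
x and y, so the columns (1, x, y, z) are rank-deficient for *every* plane:
a surface determines its coefficients only up to the plane's null vector.
Two conventions follow from this fact:

* the sample solver detects collinearity by pivoted QR on standardised
  columns and zeroes the dropped coefficient (one dropped column is
  structural and expected on any plane);
* every *reported* coefficient vector — fitted or simulator ground truth —
  is the canonical minimum-norm representative of its surface over the full
  pixel grid (`canonical_coefficients`). Two equal surfaces therefore always
  map to identical coefficient vectors, which is what makes exact-recovery
  tests on coefficients well-posed. Surfaces themselves are always compared
  directly as well.

## Static-tissue identification

1. **Global mask** — pixels with mean magnitude above 10% of the
   mean-magnitude image maximum and velocity SD below 7.5 cm/s across all
   phases.
2. **Linear pre-fit** — a first-order plane is fitted to the masked mean
   velocity; if its value at the FoV centre exceeds 0.6 cm/s, the plane is
   subtracted and the mask re-derived. "Offset at the FoV centre" is our
   reading of the plane/scan-plane separation: it is the only scalar in
   cm/s comparable to the 0.6 cm/s threshold used everywhere else near the
   vessel. The pre-corrected stack is used *only* for identification; all
   fitted samples come from the original velocities.
3. **Iterative pruning** — four passes of robust outlier rejection against
   the 5-term model: remove |residual| > 3·(1.4826·MAD). The cut has an
   absolute floor (`prune_min_cut`, 0.05 cm/s, far below clinical relevance
   and far above numerical noise): in near-noise-free data the outliers' own
   leverage footprint would otherwise set the MAD and trigger cascading
   removal of perfectly valid pixels. Pruning never shrinks a mask below the
   minimum fit size; an undersized mask is left for the failure-mode logic
   to flag.
4. **Quiescent mask** — the same magnitude/SD criteria evaluated over the
   quiescent (diastasis) window only, minus the global mask, then pruned.
   The quiescent window is the cyclic block of ⌈0.2·N⌉ phases minimising the
   summed spatial-mean |frame-to-frame velocity change| over tissue-level
   magnitude pixels (air pixels carry uniform phase noise and are excluded
   from the activity measure); ties break to the smallest starting index.
   Quiescent-mask pixels — typically peri-vessel tissue ghosted during
   systole — contribute their quiescent-phase mean velocity to the fit,
   which is how measurements near the vessel are up-weighted without
   explicit weights.

The fit is ordinary least squares over the union of both masks, one equally
weighted sample per pixel. An **over-fitting guard** evaluates the fitted
surface on a 4 cm-radius disc at the FoV centre (where the vessel is
assumed to sit): if the mean |surface| there is below 0.6 cm/s the
correction is withheld. Mean |surface| rather than |mean surface| is the
default (a sign-alternating surface still distorts per-pixel flow); the
alternative is a configuration switch.

## Failure modes and triage

* **FM1 — insufficient static tissue**: union mask < 5% of FoV pixels
  (strict inequality).
* **FM2 — insufficient velocity-to-noise ratio**: features are the VNR
  (SD of the temporal-mean velocity over static pixels) and slope/curvature
  summaries from three equal vertical strips and three equal horizontal
  bands (static pixels only; remainder rows/columns go to the last band;
  an empty band marks the features incomplete). The shipped default rule —
  flag when VNR > 3 cm/s or features are incomplete — is a transparent
  stand-in; `train_failure_tree` regenerates a depth-≤3 decision tree from
  labelled synthetic data, serialises to human-readable JSON and reloads
  losslessly.
* **FM3 — uncorrected better than corrected**: inside the smallest
  FoV-centred disc whose static-pixel fraction reaches 15% ("fraction of
  ROI pixels" reading; the "fraction of all static voxels" reading is a
  configuration switch), the absolute mean static-tissue velocity
  (signed-mean-then-absolute by default) must strictly decrease after
  correction; "equal or smaller before" flags, which deliberately includes
  the guard-skip case corrected ≡ uncorrected.

Triage: FM1 ∨ FM2 → `perform-rescan`; FM3 alone → `use-uncorrected`;
no flags → `use-npccor`.

Classification success is judged per class: `use-npccor` by whether the
corrected net flow is within 10% of the phantom-corrected reference;
`use-uncorrected` by the *selected* (uncorrected) series — the
literal alternative (judging the corrected series) is available as
`literal_use_uncorrected=True`; `perform-rescan` by *both* series being
outside 10%.

## Flow quantification

Flow rate per phase is the velocity sum over the lumen contour times pixel
area (cm/s · cm² = ml/s); phase duration is RR/N (uniform retrospective
gating). Forward/backward volumes split per pixel and per phase (the
per-phase-aggregate split is a switch). Regurgitation fraction =
backward/forward·100; severity grades: none < 5, mild [5, 20), moderate
[20, 33] (AAo) / [20, 40] (PA), severe beyond — the severe cut is strict
(">33%"/">40%"), so boundary values grade moderate. The Hofman phantom QC
accepts a phantom only when in-vivo and phantom static-ROI temporal-mean
velocities agree within 0.6 cm/s.

## Synthetic scenes

`PhantomConfig` defaults describe the emulated acquisition: 96×96 grid at
3 mm pixels (28.8 cm FoV), 30 phases over a 1000 ms cycle, VENC 180 cm/s, a
slightly double-oblique plane off isocenter (tilt 12°, roll 8°, offset
(1, −2, 5) cm — the obliquity keeps the z and concomitant columns
non-degenerate, as for clinical plane prescriptions), an elliptical torso
(10.5 × 8.5 cm semi-axes, magnitude 100) in near-zero air, and a 12 mm
radius vessel at the FoV centre peaking at 100 cm/s over a 10-phase
half-sine systole (plug profile by default; Poiseuille available; an
optional diastolic half-sine lobe exercises every regurgitation grade).
Velocity noise is Gaussian at 0.6 cm/s in tissue and uniform over ±VENC in
air; all velocities are clipped to the encoding range. The vessel disc is
anti-aliased by 4×4 sub-pixel coverage so the discretised flow integral
matches the analytic πr²-based volumes to well under 1%, and the analytic
beat volumes are stored as ground truth.

Peri-vessel ghosting is modelled as an annulus (1–1.6 vessel radii) whose
pixels receive a fixed random systole-shaped disturbance of ~25 cm/s
amplitude — large enough to fail the 7.5 cm/s whole-cycle SD criterion,
absent during diastasis — which is precisely the population the quiescent
mask exists to recover.

Per-scanner background-offset scales follow the reported per-scanner
distributions of the uncorrected mean |offset| over static tissue —
median (IQR) 0.7 (0.1–1.0), 1.4 (0.6–2.9) and 0.2 (0.1–0.4) cm/s for
scanners 1–3. `OffsetSampler` draws a log-normal master amplitude whose
median matches exactly and whose quartile ratio matches the reported IQR
ratio, applies it to an isotropic random mix of the five basis terms, and
rescales so the realised static-tissue mean |offset| equals the drawn
amplitude. (A log-normal cannot reproduce scanner 1's asymmetric IQR
exactly; its median is still exact.)

Cohorts mix scenarios: *nominal*; *fm1* (torso shrunk to 3% of the FoV);
*fm2* (temporally frozen spatial velocity roughness of 6 cm/s — the
signature of insufficient VNR in the temporal-mean image); *fm3*
(offset-free scenes, where any applied surface can only inject error near
the vessel, so the guard/FM3 pair should route to `use-uncorrected`).

### What the simulator does not emulate

No k-space physics: no ghosting correlations, partial-volume flow
displacement, FoV wrap-around (aliasing), phase wraps above VENC, coil
shading, or breathing drift. Offsets are injected at image level and lie
exactly in the fitting basis — real residual offsets do not, so the exact
cancellation seen in tests bounds the best case, not typical performance.
Passing tests demonstrate the machinery is correct and self-consistent
under the stated model; they do not certify clinical accuracy on scanner
data.

## Numerical choices

* Least squares via column standardisation + pivoted QR; rank tolerance
  1e-10 relative; dropped columns get exactly zero coefficients and a
  warning (beyond the structural one-per-plane deficiency).
* Canonical coefficients via `numpy.linalg.lstsq` with rcond 1e-8 over the
  full grid.
* Subtracting a fitted surface and adding it back agrees with the input to
  rounding error (~1 ulp), not bit-exactly; conservation tests assert
  machine precision. Skip paths (guard withheld) return the input object
  unchanged.
* FoV centre is the continuous centre of the pixel grid; for even grids it
  lies between pixels and distances are measured to that point, so no
  tie-break is needed.
* FM3 ROI radii are searched over the sorted pixel-centre distances, with
  tie-groups of equal distance treated atomically; if no radius qualifies
  the full FoV is used and flagged in diagnostics.
* McNemar: exact binomial for fewer than 25 discordant pairs,
  continuity-corrected χ² otherwise; b = c = 0 gives p = 1. Weighted kappa
  defaults to linear disagreement weights (common for ordinal severity;
  quadratic available) with the Fleiss–Cohen–Everitt asymptotic 95% CI.

## Problem sizes

Validation cohorts use n = 200 scenes per scanner profile and 100
replicates per engineered failure scenario; Monte-Carlo recovery uses 200
replicates of ≥5000 static samples at 1 cm/s noise. These sizes give
binomial standard errors of ~2–4 percentage points on the reported
fractions, comfortably resolving the directional effects being tested.

## Known limitations

* The FM2 decision tree shipped by default is a VNR threshold rule, not a
  clinically trained model; the training harness exists but any tree it
  produces reflects the synthetic labelling used.
* DICOM support covers classic one-file-per-frame magnitude+phase pairs
  with Rescale-based phase scaling and the common private VENC tag;
  enhanced multiframe files and vendor-specific phase conventions beyond a
  linear map are out of scope.
* No FoV-aliasing detection, no automatic vessel segmentation, no
  k-space-level corrections.
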