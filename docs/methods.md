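# Methods

## The measurement principle

A cylindrical lens placed between the tube lens and the camera makes the
image of a point emitter elliptical, with the ellipticity depending on the
emitter's axial position z.  Fitting each fluorescent focus with an
elliptical 2D Gaussian gives a sub-pixel lateral centroid and two
independent widths, and the width ratio r = σx/σy encodes depth.  The
bench calibration (purified GFP immobilized on a coverslip, imaged at five
stage offsets between −0.5 and +0.5 µm) is summarized by a second-order
polynomial

    r(z) = 2.4 z² + 2.8 z + 1.2        (z in µm, R² = 0.96)

which this package treats as the reference relation throughout: the
calibration module re-fits it from per-level width summaries, the
simulator renders with it, and the localization module inverts it.

### Calibration fitting and inversion

`fit_ratio_polynomial` fits the quadratic by (weighted) least squares on
the per-level mean ratios; weights are 1/SE² when per-level standard
errors exist, the coefficient covariance is the exact generalized
least-squares form in that case and residual-scaled otherwise, and R² is
computed on the unweighted ratios.  A fit whose derivative 2az + b changes
sign inside the working range is flagged non-invertible and can only be
used for forward prediction.

`ratio_to_z` solves a z² + b z + (c − r) = 0 analytically and accepts the
unique root inside the working range; ratios outside the attainable
interval [r(z_min), r(z_max)] are rejected (the localization is kept
2D-only), never clamped.  The 1σ confidence interval is the delta method
applied to the fit covariance Σ:

    var(z) = g·Σ·gᵀ / (dr/dz)²,   g = (z², z, 1).

The fit covariance is the only variance source in this interval; the
measurement error of an individual ratio is propagated separately (below).

## Synthetic movies

The simulator is the package's ground-truth source and emulates the
acquisition conditions end to end:

- **Motion.** Isotropic Brownian trajectories with i.i.d. Gaussian
  per-axis steps of variance 2·D·dt; nominal D = 1 µm²/s and dt = 5 ms
  (the ~4.7 ms exposure rounded to a uniform frame interval).  Initial
  positions are uniform in a box; trajectories are not reflected —
  molecules that leave the field or the axial span simply stop being
  rendered, as defocused molecules do.
- **PSF.** Analytic mode integrates an elliptical Gaussian over each
  93 nm pixel.  The widths follow the constant-volume idealization
  σx = σ0·√r(z), σy = σ0/√r(z) with σ0 = 250 nm; rendering uses
  σy(z) from its fitted quadratic and σx(z) = r(z)·σy(z) so that the
  rendered ratio reproduces the reference relation identically at every
  depth (re-fitting rendered spots recovers the calibration — the
  simulation→calibration closure test).  σ0 = 250 nm was chosen so that
  simulated spots reproduce the instrument's measured precision structure:
  ~40 nm lateral scatter at a single-GFP photon budget with axial scatter
  2–3× poorer.  Template mode instead pastes the nearest plane of a
  reference stack built by linear interpolation of mean foci images at
  93 nm axial steps.
- **Camera.** Pixel counts are drawn as Poisson(expected_photons·gain +
  offset) with offset 100 counts.  The offset's shot noise and the signal
  shot noise are not separated; EM-gain excess noise is not modelled.
  Noiseless rendering returns the expectation itself and conserves
  photons exactly, which the tests use as an oracle.
- **Photon budgets.** 1000 photons/frame is the single-GFP-like budget
  used in the precision study; 2500 photons/frame is the default tracking
  budget, representing a partially bleached GFP-tagged cluster in the
  low-signal-to-noise regime the method is designed for (peak
  signal-to-noise ≈ 4–6 over the 10-count background noise).

The two-channel cell-image generator (elliptical cells with contained
elliptical nuclei, flat intensities plus the same camera noise) exists to
exercise segmentation; it makes no attempt at realistic cell texture,
membranes or out-of-focus light.

## Localization

Candidates are local maxima above the frame median plus k = 5 robust
(MAD-based) noise standard deviations, merged within one PSF width
(4 px).  Each candidate is fitted over a 16×16 px window with the
elliptical Gaussian *integrated over pixel areas* — fitting the sampled
(non-integrated) model to pixel-integrated data inflates σ² by about
a²/12, which matters because the width ratio carries the depth signal.
The fitted scale parameter is directly the integrated intensity in
counts.  Fits that fail to converge, pin a width at its bounds, or sit
closer than two mean widths to another focus (overlapping foci are a
known error source and are refused rather than modelled) are rejected
with reason codes.

Two error models accompany each focus:

- **Lateral** precision uses the standard photon-count form
  σ_loc² = s²/N + a²/(12N) + 8π·s⁴·b²/(a²·N²), with s the fitted width of
  the relevant axis, a = 93 nm, N the photon count and b the background
  noise sd in photons.
- **Axial** error propagates the width-fit covariance (including the
  σx–σy cross term, from the Jacobian at the least-squares solution)
  into the ratio and divides by the local calibration slope:
  σ_z = sd(r)/|dr/dz|.  This is the package's own construction — the
  axial error build-up is not standardized — and it reproduces the
  empirical axial scatter of repeated fits to within ~10–15%.

## Tracking and diffusion

Greedy nearest-neighbour linking per frame pair under a maximum jump of
5·√(2·D_max·dt) (D_max = 3 µm²/s by default), deterministic with a
documented tie-break (lower focus index), no gap closing by default.
Time-averaged MSDs are computed per dimension over all ordered pairs at
each lag; pairs lacking a measured z at either end drop out of the z and
3D components.  The per-track z and 3D diffusion estimates additionally
require the track to be fully 3D-localized: a 2D-only localization marks
a track that brushed the edge of the axial working range, where the
surviving z measurements are censored toward the interior and would bias
the estimate low.

The apparent microscopic diffusion coefficient is a one-parameter linear
fit of the first four MSD points,

    MSD(τ) = 2·d·D·τ + C,   slope = Σ(MSD−C)·τ / Στ²,

with the intercept C fixed (not bounded) at the theoretical
localization-error floor 2·Σ_axes σ_axis², using the per-axis
photon-count precision above — including for the z component.  Fixing the
z intercept at the (much smaller) photon-count precision rather than the
axial error model is deliberate and matches how the method is defined:
the residual axial measurement noise then offsets the downward bias that
the 1 µm working range imposes on z displacements (pairs are only
observed when both endpoints are measurable, which censors large
excursions — on its own this censoring depresses recovered D_z by
~15% at D = 1 µm²/s, dt = 5 ms).  The validation study shows the net
recovery is within 10% per dimension under the default conditions; using
the full axial error model as the z intercept over-subtracts and leaves
D_z biased low.  Tracks need ≥5 localizations (four lags); negative
slopes are reported as D ≤ 0, flagged, and classified immobile.

A track with D at or below 0.1 µm²/s is classified immobile
(operationally: DNA-bound); the intensity-weighted centroid of an
immobile track defines a putative binding-site position.

## Segmentation

Five-frame averages of the cell-body (GFP) and nuclear-marker (mCherry)
channels are thresholded by Otsu's bimodal-histogram method.  Two
robustness refinements are applied: the split is accepted only if the
foreground mean exceeds the background mean by 4 background-noise sds
(so pure-noise frames yield empty masks), and when it does not, Otsu is
re-applied to the pixels above the current threshold (up to three times)
— plain Otsu fails when the foreground, e.g. a nucleus, occupies ~1% of
the field.  Masks are hole-filled and objects below 2 µm² discarded.
Touching cells are split by a seeded watershed on the negated distance
transform with nucleus labels as basins: the label count equals the seed
count and the labels partition the seeded mask exactly; cell regions
without a nucleus seed are dropped with a warning.  Track assignment uses
the lateral intensity centroid pixel (nucleus → cytoplasm → outside); z
is ignored because the masks are 2D, a documented limitation.

## Pairwise-distance statistics

Immobile nuclear track centroids form the observed site set; pairs are
taken within cells only (distances between different nuclei carry no
architectural information), giving Σ_c m_c(m_c−1)/2 distances.  Predicted
sites come from scanning both strands of a genome for an IUPAC motif
(minus-strand hits are matches of the motif's reverse complement,
reported at forward 1-based coordinates; N in a sequence never matches)
and linearly interpolating each hit's position along a bp-anchored 3C
polymer polyline.  Distances beyond the 1 µm working range can be
truncated from the predicted distribution before comparison.  Means are
reported ± sd/√n; the comparison is a two-sample Student's t-test
(equal-variance by default, Welch by flag).  Pairwise distances from one
cell are correlated, so sd/√n understates the true uncertainty — a
caveat inherited by any analysis of this form.

## Validation studies and problem sizes

`astig3d.validation` packages the two closed-loop studies:

- `diffusion_recovery_study`: by default hundreds of single-molecule
  movies (64×64 px, 30 frames) at D = 1 µm²/s through the full pipeline;
  the per-dimension means of the per-track estimates are the recovery
  result.  One molecule per movie keeps greedy linking unambiguous, so
  the study measures localization and MSD-fit fidelity rather than
  crowding robustness.  The test suite runs 200–250 movies and the
  reproduction script 400; per-track estimates are Gamma-like with a
  long right tail, so means carry ~3–4% standard error at these sizes.
- `precision_study`: ≥500 repeated fits of a stationary focal-plane spot
  at the single-GFP budget; lateral sd ≈ 40 nm and axial/lateral ratio
  2–3 under the defaults.

## Known limitations

- Motion blur within the exposure is not simulated (positions are
  instantaneous), and the MSD time base uses the frame interval.
- Single-emitter fitting only; foci closer than ~2 widths are discarded,
  so simultaneous sub-µm binding sites must be resolved in time (as
  transient binding and stepwise bleaching do in practice).
- The z working range censors axial displacements; recovered D_z is
  accurate only because the intercept convention compensates (above).
  At much higher photon budgets the compensation shrinks and D_z would
  read low.
- The delta-method z confidence interval covers calibration uncertainty
  only; total axial error additionally needs the per-focus ratio error.
- Compartment assignment is 2D; tracks above/below a nucleus are called
  nuclear.
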