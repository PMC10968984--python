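# Methods

## Decay model and simulator

Each foreground pixel of a simulated TCSPC acquisition emits a Poisson
number of photons (mean `mean_photons_per_pixel`).  A photon belongs to the
protein-bound NAD(P)H component with probability f_b (the *intensity*
fraction, i.e. the share of detected photons, not a molar fraction) and
its arrival time is drawn from Exp(τ_bound), otherwise from Exp(τ_free).
The instrument response is modeled as a constant timing offset plus
zero-mean Gaussian jitter; arrival times are then wrapped modulo the laser
repetition period and binned.  Background pixels (outside the
`foreground_mask`) receive flat dark counts at 1 % of the foreground rate,
uniform over the binned window, so that intensity thresholding has
something to reject.

Default acquisition geometry: 40 MHz repetition rate, 80 ps bins, 312 bins,
512×512 px (tests and desk-scale runs use 12–64 px squares).  312 × 80 ps =
24.96 ns is marginally shorter than the 25 ns period; photons wrapped into
that dead interval (≈1e-5 of all photons for nanosecond lifetimes) are
accumulated in the final bin so that the histogram conserves every
generated photon exactly.

Component lifetimes default to τ_free = 0.4 ns and τ_bound = 3.4 ns, the
conventional NAD(P)H endpoint values from the two-component phasor
literature; both are parameters, not constants.  IRF defaults: σ = 100 ps
jitter, zero offset.  The calibration standard is mono-exponential with
τ_ref = 4 ns (fluorescein).

Experiments pair `n_fov` control with `n_fov` treated acquisitions
(default 15, constrained to a configurable 12–20 range, matching typical
per-condition FLIM sampling of organoid cultures) plus one calibration
cube.  Per-FOV seeds are derived from the master seed with a counter-based
`SeedSequence(master, spawn_key=(arm, fov))` scheme, so adding FOVs or arms
never reshuffles earlier ones, and identical parameters + seed give
bit-identical cubes.

### What the simulator does not emulate

Detector afterpulsing and pile-up, realistic (asymmetric) IRF shapes,
spectral crosstalk or a second redox channel, spatial organoid morphology,
and biological FOV-to-FOV heterogeneity beyond photon noise (each simulated
FOV shares the arm's true f_b).  Passing tests therefore demonstrate that
the analysis chain correctly inverts this idealized forward model at
realistic photon budgets — not that it is robust to every instrument
artifact of real hardware.  Conversely, the FOV-homogeneity assumption
makes the type-I checks conservative in the dimension they probe: all
dispersion between FOVs is estimation noise.

## Phasor analysis

The transform uses bin centers t_k = (k + 0.5)·Δ and ω = 2π·f_rep·harmonic
(harmonic 1 by default; first harmonic is the standard choice for NAD(P)H).
For a periodically excited decay evaluated at a harmonic of the repetition
rate, the continuous-time phasor of a mono-exponential is exactly
(1, ωτ)/(1+(ωτ)²); binning, IRF offset and jitter multiply every pixel's
phasor by one lifetime-independent complex factor.  Referencing exploits
this: the intensity-weighted mean phasor of the measured standard, divided
into the theoretical phasor of τ_ref, gives a rotation+scale correction
applied to all acquisitions.  No analytic discretization (sinc) correction
is applied — referencing cancels it, which the calibration-invariance tests
verify rather than assume.  Pixels below the intensity threshold (default
100 photons) are masked invalid.  Optional 3×3 median smoothing (default
1 pass, applied after referencing) is per-channel on g and s and leaves
intensity untouched.

Numerical notes: an all-zero cube yields an all-invalid field with a logged
warning, not an exception; a measured standard phasor at the origin is a
hard error; calibration requires ≥100 valid standard pixels; applying a
correction twice is rejected.

## Free/bound unmixing and distribution curves

Calibrated pixel phasors are orthogonally projected onto the chord joining
the free and bound endpoint phasors; f_b is the normalized projected
distance from the free endpoint, clipped to [0, 1] so that noise excursions
off the chord can never leave the physical range.  Orthogonal (rather than
radial) projection is the standard two-component practice and is validated
against an independent least-squares decay-fit oracle in the tests.

Each FOV contributes one histogram of f_b over its valid pixels,
normalized to unit area over [0, 1] with 100 equal bins by default (the
binning of published fractional-distribution curves is not standardized;
100 bins keeps half-bin quantization of the mean below 5e-3, and the tests
check that doubling the bin count moves the distribution mean by <1e-3).
A condition's mean curve is the per-bin mean ± sd across FOV histograms
with equal FOV weights — pooling pixels instead would destroy the per-bin
dispersion the scoring stage needs.  The curve also carries each FOV's mean
f_b, required by the response gate below; the CSV writer preserves these in
comment headers.

The distribution axis is the **bound** fraction: a drug response appears as
a shift toward higher f_b (more oxidative, less proliferative metabolism).

## The %DR statistic

Two curves (control, treated) on identical bins are compared in two stages:

1. **Global gate.**  One-sided Welch t-test on the per-FOV mean bound
   fractions, alternative "treated > control".  If p ≥ α (default 0.05),
   %DR = 0.  Without the gate, the ≈α fraction of per-bin false positives
   would give nearly every null comparison a small nonzero %DR.
2. **Significant region and area.**  Per-bin two-sided Welch t-tests from
   the curves' mean/sd/n summaries, with a directional filter: a bin is
   significant when the treated mean density exceeds the control's and
   p < α.  %DR = 100 × Σ_significant (treated mean density × bin width) —
   the area of the treated curve inside the significantly bound-shifted
   region.

No multiple-testing correction is applied across bins: the gate controls
the family-level error, and corrected per-bin tests would only shrink the
significant region.  Degenerate bins with zero variance in both arms score
p = 1 when the means agree and p = 0 otherwise.  %DR is clipped to
[0, 100]; a shift toward the free side can never score, because both the
gate and the directional filter point bound-ward.

Classification: responder (Resp) iff %DR ≥ 5, else non-responder (NR), with
the boundary value itself a responder.  The threshold and α are
configurable.

## Cohort aggregation

Per-sample results are tabulated sorted by ascending %DR within treatment;
summaries report NR/Resp counts with percentages rounded half-up to
integers.  Core/peripheral and primary/recurrent portions of one patient's
tumor are independent rows.  Concordance between two treatment arms
cross-tabulates labels over shared samples, reports discordant samples, and
flags whether one arm's non-responders are a subset of the other's.

## Problem sizes and determinism

Desk-scale study conditions used by the test suite and the acceptance
script: 64×64 px FOVs at 5000 photons/px for single-experiment checks;
16×16 px at 600–800 photons/px for the replicated null (200 experiments)
and effect-size (4 × 50 experiments) suites; 12×12 px at 10⁶ photons/px for
calibration-invariance checks.  All randomness flows from explicit integer
seeds through `numpy.random.SeedSequence`; writers emit deterministic bytes
(HDF5 with `track_times=False`, floats at 9 significant digits), so rerun
results are byte-identical.

## Known limitations

- Referencing corrects a single rotation+scale factor; wavelength- or
  count-rate-dependent instrument drift within a session is out of scope.
- The per-bin Welch tests treat bins independently; spatially correlated
  pixel noise within a FOV is summarized only through the FOV-level
  dispersion.
- %DR saturates: any clearly separated pair of curves scores near 100, so
  the statistic ranks responders by confidence-weighted overlap, not by
  effect size.
- Vendor TCSPC formats (PTU/SPC) are not read; data enter via HDF5 or
  TIFF+JSON.
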