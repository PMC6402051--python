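# Methods

This note documents the models, conventions and numerical choices
behind `pc4dflow`, and what the synthetic phantom does and does not
emulate.

## Data model and conventions

Velocity datasets are 5-way arrays `(3 components, nx, ny, nz, nt)` in
cm/s on an axis-aligned grid (`world = origin + spacing · index`, mm),
with a cyclic cardiac time axis: retrospectively gated reconstructions
cover exactly one RR interval, so phase `t` and `t + n_phases` are the
same cardiac time and all temporal integrals are cyclic. On disk a
dataset is three 4D NIfTI series plus a JSON sidecar carrying the VENC
(cm/s per axis), RR interval (ms) and phase count; a single 5D NIfTI is
accepted on read. Units throughout match clinical reporting: cm/s for
velocity, mL/s and mL/beat for flow, mJ for kinetic energy.

The default acquisition geometry mirrors a typical whole-heart 4D-flow
protocol: 2.9 mm isotropic voxels, 40 reconstructed phases, VENC
150 cm/s. The VENC is a free parameter of the sidecar (protocol tables
vary by scanner); 150 cm/s is a typical great-vessel setting.

## Phase encoding and its corruptions

The forward model maps velocity to encoded phase per axis,

    φ = wrap_[−π,π)( π (v + b(x) + ε) / VENC ),

with `b(x)` a first-order background offset — affine in world
coordinates, static in time, emulating eddy-current/concomitant-field
offsets — and `ε ~ N(0, σ)` phase noise, default σ = 5% of VENC.
Background coefficients default to uniform draws within ±5 cm/s
(constant term) and ±0.05 cm/s/mm (gradients), magnitudes typical of
uncorrected clinical data. Wrapping at the VENC produces the aliasing
the unwrapper must undo.

**Background correction.** The model is fitted per velocity component
by ordinary least squares of the *time-averaged* velocity over
stationary voxels against `[1, x, y, z]`. Fitting the temporal mean
(rather than per phase) matches the static model class; on noiseless
affine data the fit is exact to machine precision. A coplanar stationary
mask makes the normal matrix rank-deficient; the error names the world
direction with no spread (smallest singular vector of the centred point
cloud). For in-vivo-like data without an explicit mask,
`auto_stationary_mask` selects voxels with temporal velocity SD below a
threshold (default 2 cm/s).

**Unwrapping** is temporal-only: scanning cyclically from the phase of
minimum global mean speed (where velocities are assumed within the
VENC), each voxel's series is corrected by ±2·VENC whenever the
inter-phase jump exceeds the VENC. This is the minimal-total-variation
correction among single-wrap choices; steps that would need more than
one wrap are corrected by one wrap and counted in a returned flag. No
spatial region-growing is attempted — the simplest method that is fully
testable against phantom truth, and sufficient when inter-phase velocity
jumps stay below the VENC.

Order of operations is decode → background fit/subtract → unwrap. The
stationary region is assumed unaliased (|v + b| < VENC there), so the
fit is insensitive to wraps in the flow region; subtracting the static
model preserves inter-phase jumps, so unwrapping is unaffected by the
order.

## Flow quantification

Planes are defined in world mm by an origin, unit normal and orthonormal
in-plane basis. Velocity components are sampled at pixel centres by
trilinear interpolation and projected onto the normal. ROI integration
sums `v·ΔA` over pixels whose centres lie inside the polygon (even–odd
rule; exact edge hits resolved by a half-open convention via an
infinitesimal bias), giving mL/s; the beat volume is the cyclic
trapezoid of the rate over the RR interval, which for uniformly spaced
phases is mean rate × period. Contours transfer between planes through
world coordinates; transfer between non-coplanar planes projects the
out-of-plane component away with a warning. Flow is signed positive
along the plane normal (`--flip` negates). 2D-flow acquisitions are
represented as single-plane flow curves in the same data model, so a
"2D vs 4D" comparison is two pipeline runs, not a special code path.

## Kinetic energy

KE(t) = Σ over segmented voxels of ½·ρ·V·|v|², in mJ (ρ in g/mL, V in
mL, |v| in cm/s; conversion factor 1e-4). Blood density defaults to
1.06 g/mL, phantom water to 1.00 g/mL, both configurable and recorded
in outputs. Per-phase segmentations are honoured; a static mask is
broadcast with a warning. Summary metrics (peak systolic / early
diastolic / late diastolic, cycle mean) take the cycle partition as
explicit RR fractions (defaults 0.35 and 0.70), because systole/diastole
boundaries derive from cine timing that this package does not model;
each window must contain at least one phase.

## The synthetic phantom

**Womersley tube.** The pump program is a periodic flow-rate waveform
Q(t) stored as Fourier coefficients with the DC term pinned to
SV/period, so the per-beat volume equals the programmed stroke volume
exactly — this is the construction truth the pipeline is validated
against. The default waveform is a half-sine ejection occupying 35% of
the cycle, truncated to 16 harmonics; the truncated series itself *is*
the program, so truth and simulated field share one waveform. The axial
velocity is the exact Womersley solution per harmonic (Bessel-function
profile; the zero-frequency term is the Poiseuille parabola), evaluated
at voxel centres. Defaults: tube radius 13 mm (a realistic great-vessel
calibre that the 2.9 mm protocol voxel resolves — about 4.5 voxels per
radius), water viscosity 1 mm²/s, stroke volumes spanning 12–37 mL at a
1000 ms period, giving peak velocities up to ≈ 40 cm/s. Voxels outside
the tube are exactly stationary; the stationary mask excludes a
one-voxel guard annulus at the wall. A two-tube variant superposes two
identical tubes for mass-conservation and QP/QS checks.

**Hill vortex.** The vortex-ring dataset samples the lab-frame Hill
spherical vortex (sphere radius 16 mm, translation speed 30 cm/s,
velocity continuous across the boundary and divergence-free), static
across phases. Truth KE inside the sphere is computed by 400-point
Gauss–Legendre product quadrature of the closed-form axisymmetric field
— independent of any voxel grid — rather than a textbook constant, to
avoid transcription risk. The matching measurement segments voxels
whose centres fall inside the sphere; the residual disagreement is the
voxelization error under study (≈1.3% at 2.9 mm, <0.1% at half
spacing).

**What the phantom does not emulate:** k-space acquisition and parallel
imaging reconstruction, respiratory motion (an optional Resp− mode only
inflates phase noise), partial-volume signal mixing at walls, vessel
compliance and flow profile skew, and intra-voxel dephasing. Passing
phantom tests therefore demonstrates correctness of the quantification
chain and its corrections under realistic discretization and noise, not
robustness to scanner-specific artefacts.

## Statistics

Differences are oriented test − reference everywhere. Bland–Altman bias
uses the sample SD (n−1); limits of agreement use 1.96·SD. Regression
treats the reference as x. The paired Wilcoxon test drops zero
differences, midranks ties, uses W = min(W+, W−), and computes the
two-sided p exactly by full enumeration of the 2ⁿ sign assignments for
n ≤ 20 (ties handled exactly through the midranks), switching to the
normal approximation with tie correction (no continuity correction)
above. No multiple-testing correction is applied; each comparison is
reported with its own p. The comparison-table builder pairs tidy
measurements on user-declared keys, drops and counts incomplete pairs,
and is invariant to input row order.

## Problem sizes and runtimes

The validation suite and the acceptance script use tube grids of
32 × 32 × 16 voxels × 40 phases (the tube cross-section with a
stationary margin; the solution is translation-invariant along the
axis, so a short axial extent loses nothing), vortex grids of 24³ (48³
at half spacing) at a single phase (the field is static), 10 noise
seeds × 5 pump programs for the noisy sweeps, and a 10-subject paired
cohort. These sizes give sub-millilitre Monte-Carlo error on recovered
volumes while the full acceptance run completes in well under a minute
per stage.

## Known limitations

- Only axis-aligned (diagonal-affine) grids are supported on read.
- Temporal unwrapping cannot recover voxels wrapped at the reference
  (minimum-speed) phase, or jumps beyond 3·VENC (flagged, not fixed).
- The background model is first-order; higher-order eddy-current
  structure and Maxwell terms are out of scope.
- The exact Wilcoxon enumeration is O(2ⁿ); n > 20 falls back to the
  normal approximation.
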