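# Methods

This note records the models, conventions and numerical choices behind
`spiralflow`, and what the synthetic experiments do and do not show.

## Sampling design (`trajectory`)

Pseudo-spiral arms follow r(φ) = φ² with φ sampled at n = 100 uniformly
spaced values on [0, 2πl] (endpoints included, l = 3 turns), read as
"linearly increasing angle".  The radius is normalised so the arm's last
point reaches k_y = N_ky/2 − 1 grid units; for asymmetric matrices k_z is
rescaled by (N_kz/2 − 1)/(N_ky/2 − 1) so the gridded arm spans exactly the
valid zero-centred index range on both axes.  Points are rounded to the
nearest grid node with exact halves pulled toward zero, and out-of-range
points are clamped rather than dropped so the n·l parameterisation (and
the per-arm scan time) is preserved; duplicates inside an arm are kept in
the schedule — the TR is spent either way — and merged later by the
binning counts.  Successive arms rotate by the order-7 tiny golden angle
180°/(τ + 6) = 23.628°, accumulated and reduced modulo 360°; order 7 is
the member of the tiny-golden-angle family whose value matches the
protocol's printed increment.  A schedule emits whole arms until the
readout budget N_fully/R_target is reached, so the realised R differs
from the target by at most one arm quantum.

The readout direction k_x is never undersampled and is abstracted to a
per-event hybrid-space axis; one "event" is one (k_y, k_z) sample of one
flow segment, 4 events (reference, x, y, z) per profile, one TR
(8.9 ms) each.

## Cardiac binning (`binning`)

"Absolute" binning uses a fixed frame duration = nominal RR / N_card; an
event's frame is ⌊(t − preceding R-top)/duration⌋ and events landing at
frame ≥ N_card (the tail of long beats) are rejected rather than folded
into the last frame.  Under RR variability the trailing frames
systematically collect less data, so the last frames (2 by default) are
flagged and excluded from flow-curve summaries while still being
reconstructed.  Duplicate acquisitions of one (profile, frame, segment)
cell are averaged through the count companion of the k-t mask; the
scanner-side bitmask that would prevent such duplicates in a real
prospective implementation is not simulated.  The effective acceleration
is recomputed retrospectively as grid size over sampled-cell count and is
reported alongside the target R (it is larger, since duplicates and
rejections do not add coverage).

## Digital phantom (`phantom`)

The scene is a rigid straight tube of radius 3 mm along the readout axis
of an (8, 64, 64) voxel grid at 0.8 mm isotropic resolution — a
deliberately simplified, analytically known stand-in for a compliant
carotid phantom, scaled down from a 160×160×40 in-plane matrix so a full
sweep runs on a laptop.  Flow is laminar Poiseuille at every instant:
v = 2Q(t)/(πa²)(1 − ρ²/a²) along the axis, zero transverse components.
The inlet waveform is a raised-cosine systolic pulse on a diastolic
baseline occupying 30% of a 1000 ms cycle, with pulse height and baseline
solved in closed form so the peak is exactly 10 ml/s and the cycle mean
exactly 3 ml/s; only peak, mean and period are physiologically
constrained, the shape itself is a modelling choice.  RR intervals are
i.i.d. normal with mean 1000 ms and 5% SD, truncated at ±3 SD (the
realised coefficient of variation is therefore ≈ 4.9%).  Event velocities
use the waveform phase within the current simulated beat (the waveform
stretches with each beat), so RR variability produces genuine
cardiac-frame blur against the fixed binning grid.

Four-point referenced encoding maps the segment-d velocity component to
image phase π·v_d/venc (venc = 150 cm/s); the complex image is the
magnitude map (lumen 1.0, background 0.3 — the background exercises
partial-volume behaviour at the wall) times that phase factor, weighted
by each of 4 smooth complex coil maps (Gaussian lobes ringing the
phase-encode plane; 4 coils is a desk-scale stand-in for 32/8-channel
arrays).  The orthonormal 2D DFT over the phase-encode plane is fixed
project-wide, making Parseval checks and the adjoint-equals-inverse
property exact.  I.i.d. complex Gaussian noise of SD 0.02 (relative to
the unit lumen magnitude, typical high-SNR scanner conditions) is added
per k-space sample.  For speed, events are grouped by their instantaneous
flow rate quantised at 0.005 ml/s (≈ 0.04 cm/s velocity, far below the
noise floor) so each distinct image is transformed once; the quantum is
configurable and 0 disables it.

Not modelled, by design: wall compliance and motion, Womersley inertial
profiles, turbulence, in-flow enhancement/T1 effects, eddy-current or
concomitant-field phase offsets.  Passing tests therefore demonstrate
correctness of the pipeline on smooth laminar flow, not performance on
complex in-vivo hemodynamics, where temporal-TV reconstructions are known
to behave worse.

## Reconstruction (`recon`)

Per flow segment the solver approximately minimises
½‖F_U m − y‖₂² + λ·TV_t(m).  The data term is the conventional squared
ℓ2 (the objective is sometimes written with an un-squared norm; the
squared form is what standard CS-MRI solvers implement).  TV_t is the ℓ1
norm of first-order temporal differences with cyclic boundary — cardiac
frames are periodic.  The solver is monotone FISTA: accelerated proximal
gradient with step 1/L (L = max over voxels of Σ_c|S_c|², the exact
Lipschitz constant under the orthonormal DFT), where each accepted
iterate is the better of the proximal candidate and the previous iterate,
so the tracked objective is non-increasing by construction.  The
temporal-TV proximal map is solved by FISTA on its dual (a projection
onto a per-difference modulus ball), 100 inner iterations, which for the
~10-frame series used here is accurate to near machine precision.  Data
are normalised so the zero-filled reconstruction has unit peak magnitude,
which makes λ = 0.01 transferable across scene scales; λ and the 10 outer
iterations follow the protocol defaults.  Initialisation is the
zero-filled solution; with full sampling and λ = 0 that initial point is
already the least-squares solution and the solver is a fixed point there.
Coil maps are the known simulation maps (no ESPIRiT-style
self-calibration).  Phase-offset correction (first-order spatial
polynomial fitted on static voxels) exists as an explicit post-step but
is off by default because the simulator introduces no offsets.

## Hemodynamics (`hemodynamics`)

Flow rate uses the through-plane velocity component, Q(t) = Σ v⊥·ΔA.
Integrating the speed instead would be positively biased and inconsistent
with 2D-flow practice, so the through-plane convention is used even
though "absolute velocity" phrasing is common.  Peak systole is the
non-discarded frame with the highest mean speed in the lumen, earliest
frame on ties.

The wall mesh is the marching-cubes isosurface of the lumen mask at
level 0.5; inward normals follow the gradient of the Gaussian-smoothed
mask interpolated at the vertices, orientation-checked against the lumen
centroid.  For WSS, each wall point gets a deterministic local frame
(z' = inward normal; x' built from the coordinate axis with the smallest
normal component; y' completes the right-handed triad).  The two
tangential velocity components are sampled tri-linearly at k = 4 points
spaced one voxel (0.8 mm) along the inward normal, the wall sample is
clamped to zero to honour the no-slip/no-through assumption, and a
least-squares quadratic — a spline with no interior knots, exact for the
parabolic profiles at hand — provides the wall derivative at z' = 0.
τ = η(∂v_x'/∂z', ∂v_y'/∂z', 0) with η = 3.2·10⁻³ Pa·s is rotated back to
global coordinates and is exactly tangential by construction.  Points
whose sampling ray leaves the grid are flagged invalid and excluded.
At 0.8 mm resolution with a 3 mm radius the mean wall shear of a steady
Poiseuille flow is recovered to within the 15% discretisation bound
(vertex positions are only voxel-accurate, and the clamped wall sample
sits slightly off the analytic wall).

Comparison resampling exploits that synthetic runs share geometry: WSS is
paired by nearest reference wall point (pairs beyond 2 voxels dropped and
counted), velocities voxel-wise on the reference lumen.  The rigid
registration a real multi-scan study needs is replaced by this identity
mapping.  Stroke volume is the rectangle-rule integral of Q over
non-discarded frames; with 2 of 10 frames discarded it underestimates the
full-cycle integral by the diastolic tail, which is reported as-is rather
than extrapolated.

## Statistics and the sweep (`stats`, `experiment`)

Bland-Altman reports mean difference, SD and mean ± 1.96 SD limits of
agreement; the percent bias divides by the grand mean of pair averages
(the denominator convention is stated because it is often left implicit).
Orthogonal regression is total least squares with equal error variances
(classic Deming, ratio 1), closed form on the 2×2 covariance.  One
consequence worth knowing: with noisy data this estimator is equivariant
to scaling both variables jointly but not to rescaling one variable
alone; the test suite asserts one-sided scale equivariance only on exact
linear data where it holds.

The sweep driver runs R ∈ {2, 10, 20} by default on one shared scene and
heartbeat sequence (10 reconstructed frames, last 2 discarded), compares
each run voxel-wise against the lowest-R reference at peak systole, and
also reports the analytic ground truth.  The desk-scale problem sizes —
64×64 phase encodes, 8 readout slices, 10 frames, 4 coils — were chosen
so the full sweep completes in a few minutes on one CPU while keeping the
undersampling physics (variable density, frame incoherence, duplicate
merging, frame starvation under RR variability) intact.  Reconstructed
peak values are judged against the *frame-averaged* analytic truth (the
waveform averaged over each frame's binning windows), because a binned
acquisition cannot resolve faster dynamics; the residual gap to the
instantaneous waveform peak is temporal-resolution loss, not solver
error.

## Known limitations

- The phantom's laminar, axially uniform flow makes temporal TV an
  unrealistically good prior; degradation trends with R are qualitative,
  not quantitative predictions for in-vivo scans.
- Marching-cubes vertices are voxel-accurate; WSS carries an O(voxel/radius)
  discretisation bias, visible as the 15% Poiseuille tolerance.
- No arrhythmia rejection, respiratory gating, or fold-back of
  rejected long-beat data; rejected events are simply dropped.
- Velocity wrap (|v| > venc) is simulated faithfully but no unwrapping is
  implemented; the default scene stays below venc.
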