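# Methods

This note documents the models, numerical choices and limitations of
`ktpulse`.  It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Forward model

The excitation block is a kT-points train: `n_subpulses` ideal
rectangular subpulses of duration `subpulse_duration` separated by
zero-RF gaps of `blip_duration` in which symmetric triangle/trapezoid
gradient blips play.  Defaults: 5 × 200 μs subpulses, 100 μs blips,
TR = 8 ms, RF raster Δt = 10 μs, i.e. τ = 1.4 ms and 100 RF-on samples.

Flip angles are computed in the small-tip-angle (STA) regime from the
system matrix

    A[m, n] = i γ m0 Δt · exp(i 2π ΔB0(r_m) (t_n − τ)) · exp(i r_m·k(t_n)),

with α_m = |Σ_q s_q(r_m) (A b_q)_m| / m0.  Conventions that matter:

* Off-resonance is stored in Hz and enters as `exp(i 2π ΔB0 (t − τ))`;
  the gyromagnetic ratio γ = 2.6752218744×10⁸ rad s⁻¹ T⁻¹ is a fixed
  constant.
* RF samples exist only where RF can be non-zero; blip gaps carry no
  columns of A.  Sample times are the right edges of the Δt bins, so the
  final sample sits exactly at τ and carries no off-resonance phase.
* Excitation k-space follows the time-reversed gradient integral: the
  last subpulse sits at k = 0 and subpulse j accumulates the negatives
  of all later blip moments.  k is piecewise constant (one value per
  subpulse) because no gradients play during RF-on intervals.
* Excitation phase is ignored throughout (magnitude targets).

The sequence B1rms is β_m = √((1/TR) Σ_n Δt |Σ_q s_q(r_m) b_q(t_n)|²),
with the modulus squared taken on the complex channel sum (required for
a real-valued β).  β is independent of the blip moments.

### Shape factors and the B1rms lower bound

For a unit-duration, unit-amplitude envelope with mean p1 and mean-square
p2, an on-resonance pulse without gradients satisfies
α = γ p1 √(TR τ / p2) · β exactly; with off-resonance or gradients the
relation becomes an upper bound on α.  Hence the smallest B1rms able to
deliver α_des is β_min = √p2 · α_des / (γ p1 √(TR τ)).  For the default
binary train p1 = p2 = 5/7 and β_min(15°) = 0.346 μT, β_min(3°) =
0.0692 μT; the default design targets are 1.2·β_min = 0.415 μT and
0.083 μT (0.42 / 0.08 μT at two decimals).  β_min is invariant under
zero-padding of the envelope, which the tests exercise by lengthening
the gaps.

## Constraints

All operational constraints are evaluated on the subpulse-constant RF:

* Global and local SAR are time-averaged quadratic forms
  (1/TR) Σ_n Δt bᴴ Q b; local SAR is the max over a list of
  virtual-observation-point (VOP) matrices.
* Per-channel average power is **defined** as forward power into 50 Ω
  with the peak-to-average factor of a constant envelope,
  P_q = mean_TR(|v_q|²)/(2·50).  This is a modeling choice (the quantity
  a P_max limit refers to is vendor-specific) and rescales what a given
  P_max means; it is stated prominently for that reason.
* Gradient amplitude and slew limits are folded exactly into a per-axis
  box bound on the blip moment: a symmetric triangle (slew-limited) or
  trapezoid (amplitude-limited) of duration 100 μs at 30 mT/m and
  80 T/m/s yields |Δk| ≤ 53.5 rad/m per axis.
* Default limits: SAR_10g ≤ 20 W/kg, V ≤ 207 V per channel, P ≤ 24 W
  per channel.  No number is fixed for global SAR by the operating-mode
  convention alone, so the global limit is disabled unless configured.

## Hybrid optimization

The cost is the convex combination of squared weighted NRMSEs of α and β
about scalar targets; reports show the square roots.  Variables are the
interleaved real/imaginary parts of the per-channel subpulse amplitudes
plus the blip moments (92 parameters at 8 channels).  The solver is
SLSQP with analytic gradients of the cost and of every constraint;
gradient correctness is enforced against central finite differences at
1e-5 relative tolerance.  Hessians are not supplied.

Multi-start: random complex RF scaled so the weighted mean flip angle
hits α_des in the least-squares sense (then shrunk, if needed, to strict
constraint feasibility), blip moments uniform within ±20% of the box
bound.  Starts are drawn from a seeded generator; the best feasible
solution wins, ties broken by lower local SAR.  Solutions that end on a
constraint boundary are snapped back inside it (a ≤1e-9-relative
rescale) so reported margins are non-negative.  Default 10 starts for
single designs and 5 for sweep grids; solver tolerance ftol = 1e-9,
maxiter = 500.

Voxel compression: k-means (scikit-learn) on standardized feature
vectors [Re s_q, Im s_q, ΔB0, x, y, z] of in-mask voxels; the compressed
problem uses cluster centroids with summed voxel weights, and all
reported maps/errors are recomputed on the full voxel set.  Default 500
clusters.

λ = 0 reproduces a dedicated flip-angle-only design exactly (the β term
enters with an exact zero weight), and λ = 1 a pure-B1rms design.  The
λ grid helper places points logarithmically denser near 0 and 1, with
both endpoints included, mirroring how the trade-off only moves near the
ends.  For sweeps, per-grid-point seeds are derived deterministically
from the sweep seed.

The RF-shim baseline uses magnitude least squares with variable
exchange: re-phase the target to the current field phase, solve the
weighted linear least-squares problem, repeat; the objective is monotone
non-increasing and the CP mode (with its closed-form optimal amplitude)
is always one of the starts.

## Spin physics

The Bloch simulator integrates hard-pulse rotations per RF sample about
the rotating-frame effective field and treats each blip gap as free
precession plus the spatial phase ramp r·Δk; its sign conventions are
chosen so its small-tip limit reproduces the STA system matrix.  It is
validated against an independent rotation-composition (matrix
exponential) oracle to 1e-10.

The two-pool (binary spin-bath) SPGR steady state rotates the free pool
instantaneously by the actual flip angle each TR, spoils its transverse
magnetization perfectly, and propagates the longitudinal pair through
relaxation, exchange and a *constant* semisolid saturation rate
W = π g(Δ) (γβ)² over the whole TR.  The continuous-saturation choice
(rather than discrete per-pulse saturation) is the regime in which the
closed-form apparent-R1 expression is derived, and the dual-flip-angle
fit of simulated signals at a shared β reproduces that expression to a
few percent, which the tests assert at 5%.  The 2×2 matrix exponential
uses the analytic spectral form (the generator always has real
eigenvalues); the steady state is solved in closed form per voxel.

Lineshapes: Gaussian by default, g(Δ) = (T2s/√(2π)) exp(−(2πΔT2s)²/2),
finite on resonance with g(0) ≈ 3.99 μs at T2s = 10 μs.  A
super-Lorentzian is available; because its orientation integral diverges
on resonance, values inside |Δ| < 1 kHz are a cubic fit to the wings at
1–2 kHz — the standard extrapolation for on-resonance MT work.  Which
lineshape and g(0) best describe tissue is treated as a free tissue
parameter.

## Dual-flip-angle fitting

With constant TR the spoiled GRE signal is linear in x = s/tan α versus
y = s/sin α with slope E1 = exp(−TR·R1); two angles give the exact
two-point solution, more angles fall back to ordinary least squares.
Fits use the Bloch-simulated per-voxel flip angles, so flip-angle errors
are corrected while B1rms-driven saturation bias is not — that is the
mechanism under study.  Slopes outside (0, 1) are flagged invalid and
yield NaN, never a silently clamped value.  Optional Gaussian noise is
added to the complex signals before the magnitude is taken; it is off by
default.

## Synthetic phantom

The phantom emulates the qualitative structure of measured 7T data, not
any subject:

* Ellipsoidal head (semi-axes 86/103/94 mm inside a 240 mm FOV, default
  32³ grid) with concentric WM/GM/CSF shells at 78% and 92% of the
  normalized radius.  RAS axes, voxel-center coordinates, isocenter at
  the mask centroid.
* Eight channels on a 15 cm ring.  Each channel's magnitude decays
  exponentially with distance from its position and its phase rolls
  linearly with that distance; both slopes scale with
  (brightening − 1), so brightening = 1 gives exactly uniform fields
  and the default 1.8 gives a circularly-polarized combination whose
  center exceeds the mask-edge median by ≥1.3× — the central-brightening
  pattern of real head coils.  Per-channel gain/phase jitter and smooth
  random perturbations (also scaled by brightening − 1) are seeded.
  Channel amplitude is 0.0075 μT/V so that a 15° CP rectangle needs
  ≈100 V, placing the hardware limits at realistic distances.
* ΔB0 is a seeded random quadratic form plus one Gaussian hotspot
  (σ = 18 mm), normalized to a ±150 Hz range.
* Tissue parameters (WM R1f = 0.5 s⁻¹, R1s = 3 s⁻¹, k_fs = 2 s⁻¹,
  M0s = 0.13; GM R1f = 0.45, k_fs = 1, M0s = 0.07; CSF R1f = 0.25,
  M0s = 0; T2s = 10 μs everywhere) are config defaults typical of brain
  at 7T, not ground truth; k_sf always derives from detailed balance
  k_fs·M0f = k_sf·M0s.
* The SAR model is random Hermitian-PSD (A·Aᴴ) VOP matrices scaled so
  the 15° CP reference pulse sits at 25% of the local SAR limit, with
  the global-SAR matrix at 40% of the reference local SAR.  It
  reproduces the *structure* of a compressed vendor model, not its
  values.

What the phantom does not emulate: electromagnetic field simulation of
real coils, realistic anatomy, receive sensitivities, imaging noise and
reconstruction artifacts, motion, or amplifier drift.  Passing tests
therefore demonstrate the mechanism (B1rms-controlled MT bias and its
removal by the hybrid design) and the correctness of the numerics, not
in-vivo effect sizes.

## Problem sizes used by the test suite

Unit and oracle tests run on tiny synthetic setups.  Phantom-level tests
use the default 32³ grid with 500 clusters and 5 starts (end-to-end R1
ordering; a 4 β_des × 7 λ sweep), and a 16³ grid with 150–200 clusters
for optimizer unit tests — sizes chosen as the desk-scale analog of the
full protocol.  All randomness flows from fixed seeds, and reruns are
bit-identical.

## Known limitations

* STA-based design: valid for small tips (the 3°/15° excitation regime);
  inversion/refocusing designs and finite-T2s during-pulse dynamics are
  out of scope.
* Only kT-points trajectories (no spokes/spirals); scalar uniform
  targets by default.
* Perfect spoiling is assumed in the SPGR model; incomplete-spoiling
  corrections are out of scope.
* The power-constraint definition is a stated convention (see above).
* The per-acquisition B1rms in the R1 pipeline means each flip angle
  carries its own saturation level; the closed-form apparent R1 applies
  exactly only when both acquisitions share one β, and the pipeline's
  bias direction relative to that expression can differ in sign.
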