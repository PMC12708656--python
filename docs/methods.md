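# Methods

## Model

`nematurb` integrates a minimal hydrodynamic model of an incompressible,
defect-free active nematic film on the doubly periodic unit square. The
state is a single scalar field, the director angle θ(**r**, t), with
director **n** = (cos θ, sin θ) of unit norm (the system is assumed deep in
the nematic phase, so the order-parameter magnitude is constant and no
topological defects exist). Flow alignment is neglected.

At zero Reynolds number the flow is slaved to the director. Writing the
velocity through a stream function, v = (∂_y ψ, −∂_x ψ), the curl of the
Stokes force balance gives a linear, instantaneously solvable problem

    −∇⁴ψ = (R/2A) ∇⁴θ + S [ ½(∂_xx − ∂_yy) sin 2θ − ∂_xy cos 2θ ],

and the director angle evolves by advection, co-rotation with the local
vorticity, and elastic relaxation,

    ∂_t θ = −(∂_y ψ)(∂_x θ) + (∂_x ψ)(∂_y θ) − ½∇²ψ + (1/A) ∇²θ .

Lengths are in units of the box size L, time in units of the active time
τ_a = η/|ζ| (above) or the nematic relaxation time τ_r = γL²/K, with
1 τ_r = A τ_a. Dimensionless groups:

- **A = L²/ℓ_c²** — the activity number, the sole bifurcation parameter;
  ℓ_c = √(K/(|ζ|R)) is the active length.
- **R = γ/η** — viscosity ratio (default 1).
- **S = ζ/|ζ| ∈ {−1, +1}** — sign of the active stress. Without flow
  alignment, contractile (S = −1) and extensile (S = +1) systems map onto
  each other by a global π/2 rotation of the director; the package's
  default is contractile with the director initially along x̂.

Linearizing about the aligned state θ = 0 decouples Fourier modes; each
mode (k_x, k_y) grows at the real rate

    s(k) = S (k_x² − k_y²)/(2k²) − (R + 4) k²/(4A)        [1/τ_a],

so the first instability is the long-wavelength spontaneous-flow (bend)
instability at A_c = (R + 4) k_min²/2 with k_min = 2π, i.e. A_c = 10π² ≈
98.7 for R = 1. This closed form is the analytic oracle for the simulator's
linear regime (`nematurb.linear`).

## Discretization

- **Stokes solve**: pseudo-spectral on n×n modes with the 2/3 anti-aliasing
  rule applied to the right-hand side; the zero mode of ψ (undetermined by
  the equation) is set to zero. All derivatives of ψ are spectral.
- **Director dynamics**: Peaceman–Rachford alternating-direction-implicit
  (ADI) stepping in τ_r units, where the elastic diffusion coefficient is
  exactly 1 independent of A (so a fixed Δt remains consistent during
  activity ramps). Each half step treats the second-difference diffusion
  along one axis implicitly — an exact cyclic tridiagonal solve, realized
  by a Sherman–Morrison/Cholesky factorization whose (circulant, symmetric)
  inverse is precomputed and applied as one matrix product per sweep — and
  everything else explicitly. θ derivatives are second-order centered
  finite differences. ψ is recomputed from θ once per step and frozen
  across the two half steps; the overall scheme is first order in time
  (verified by the convergence test), which at the default Δt puts the
  splitting bias of measured linear growth rates at the percent level;
  linear-rate measurements therefore use Δt/4.
- **Time step**: Δt = 1.8×10⁻⁵ τ_r at the reference resolution n = 256.
  At other resolutions the default scales as Δt(n) = 1.8×10⁻⁵ (256/n)²,
  the stability limit of the explicitly treated active backflow at the
  dealiasing cutoff. Deep in the chaotic regime the explicit centered
  advection imposes a second, resolution-independent limit Δt ≲ 2/v_rms²
  (velocities in L/τ_r); high-activity desk runs at n = 128 therefore use
  Δt = 3.6×10⁻⁵. A CFL estimate is monitored and warns (not aborts) above 1.
- **Resolution guard**: runs require n > 2√A (at least two grid points per
  active length); deliberately under-resolved runs must opt in and warn.
- **θ is stored unwrapped** (not mod π). The model is defect-free by
  construction; if nearest-neighbour angle jumps exceed π/2 a warning
  signals incipient winding/under-resolution rather than any unwrapping.

## Noise

Realizations are generated by adding Gaussian white noise to θ for a short
initial transient: amplitude D = 5×10⁻⁴ L²/τ_r for 10⁻² τ_r (ensembles), or
D = 5×10⁻⁶ as a tiny symmetry-breaking seed during low-activity ramps. The
discretization convention is space–time white noise: per-node increments of
standard deviation √(2 D Δt)/Δx, which keeps the physical noise level
grid-independent. The noise only seeds symmetry breaking — the subsequent
evolution is deterministic — so results are insensitive to the convention,
but it is recorded in output metadata.

## Chaos diagnostics

Deviations w = θ̃ − θ are propagated as shadow trajectories: the companion
field θ̃ follows the full nonlinear dynamics with the same stepper as the
reference (no tangent-linear code), and w is rescaled to ‖w‖ = 10⁻⁶
(Euclidean norm over all nodes) every 10⁻³ τ_r. The maximal Lyapunov
exponent is the time average of the logarithmic growth increments; varying
the rescaling parameters by an order of magnitude does not change the
estimates (tested). Stretching numbers α (finite-time Lyapunov exponents)
average the same increments over 5×10⁻³ τ_r windows, so the MLE equals the
mean stretching number exactly. Spectra of m exponents use m companions
with Gram–Schmidt orthonormalization at every rescaling.

Two consequences of the model's symmetries matter for interpretation:
uniform θ shifts (rotations of the aligned state) and, for symmetry-broken
laminar states, translations are exactly neutral, so laminar states have
zero — not negative — leading exponents. A Lyapunov exponent is treated as
"vanishing" when |λ|·T ≤ 3 at integration time T (the estimator's
resolution). On an exact fixed point the neutral direction ultimately
dominates any deviation, which is the correct physical answer (Λ = 0);
recovering a specific negative eigenvalue instead requires projecting the
neutral component out, as the estimator-validation test does.

The chaotic fraction f_c of an ensemble pools all stretching numbers at one
activity, smooths them with a Gaussian KDE (Silverman bandwidth), and takes
the probability mass above the density minimum between the peak nearest
zero and the dominant positive peak. A unimodal distribution gives f_c = 0
or 1 according to whether its single peak lies within a configurable
tolerance of zero (default 1/τ_r). The valley rule is the package's own
documented choice; only the peak-separation idea, not a threshold rule, is
prescribed by the underlying study.

## Protocols

- **Ensemble transition scan**: independent realizations (aligned + noise
  burst, per-realization seeds spawned from a master seed by a counter
  scheme) at each activity; reports ensemble mean ± s.e.m. of MSV and MLE,
  pooled stretching histograms and f_c. Reference-scale parameters (32–64
  realizations, 600 τ_r at 256²) are the defaults; desk tests use smaller
  ensembles and shorter times.
- **Quasi-static ramps**: activity stepped by ΔA with a fixed relaxation
  window per step, recording MSV (and components) just before each
  increment; optional seeding bursts below a configurable activity.
  Reference schedule: ΔA = 1 per 2 τ_r (bifurcation diagram), ΔA = 100 per
  2.5 τ_r (hysteresis scan).
- **Hysteresis loops**: an up ramp and a down ramp sharing the turning
  state; a discontinuity detector flags the first step with a relative MSV
  change above 50% on each branch (the underlying study identifies jumps
  visually; the 50% rule is this package's documented choice).
- **Flow-state labels**: a heuristic classifier (quiescent / steady or
  oscillatory laminar / chaotic) based on MSV level, mean stretching
  number, and a periodogram peak ≥ 5× the median level; vortex counting
  uses strict local extrema of ψ above 1% of max|ψ|.

## Locating the bifurcation thresholds at desk scale

Two thresholds have quantitative reference values and deserve comment on
how they are measured here.

**Primary (spontaneous-flow) threshold.** Short deterministic runs of a
seeded single mode at n = 64 bracket growth against decay in steps of
ΔA = 5; interpolating the measured modal rates to zero reproduces the
analytic A_c = 10π² to a tenth of a percent. Rate measurements use Δt/4
to keep the splitting bias negligible.

**Secondary threshold (shear → vortex flow).** Naive quasi-static ramps of
the shear branch are unreliable at n = 128 desk schedules, for a physical
reason: the saturated 1D shear profile keeps coarsening on a slow timescale
(the effective nematic diffusivity (R+4)/(4A) + cos(2θ)/2 is small or
negative at large θ amplitude), so every finite activity increment kicks a
slowly readjusting profile and transiently amplifies transverse
perturbations. Ramp detectors that carry transverse seeding across steps
consequently fire far below the quasi-static threshold, while the director
winds through rotated orientations that make a naive v_y-versus-v_x test
misread rotated members of the shear family as vortex flow. The package
therefore measures the onset from settled independent realizations: for
each activity on a ΔA = 10 grid, an aligned-plus-noise-burst realization
(the ensemble generator itself) relaxes for 3.5 τ_r; below threshold it
settles into single-component shear flow (minor MSV component at the
numerical floor, whichever axis carries the flow), and the onset is the
first activity whose settled state is genuinely two-dimensional (minor
component above 1% of the major one). At n = 128 this gives onset ≈ 360,
within 10% of the reference value ≈ 330 from near-adiabatic continuation
at 256².

**Subcritical bistability.** At n = 128 the two-vortex family does not
terminate in the reference location (A ≈ 941): it continues smoothly,
becoming oscillatory, beyond A = 1700. Instead, a *steady* four-vortex
state (the smaller grid prefers a checkerboard packing over the
three-vortex stripe) coexists bistably with the oscillatory two-vortex
family over roughly A ∈ [700, 1550] — e.g. MSV 579 versus ~1260 at
A = 950, seed-reproducible. The hysteresis test sweeps this steady family
quasi-statically from its quench point: on the way up it survives to
A ≈ 1600 before jumping (+131% MSV) onto the chaotic/oscillatory family;
on the way down it survives only to A ≈ 700 before jumping back (+110%).
The up-transition exceeding the down-transition by a factor ~2 in activity
is the subcritical-bistability signature at this resolution. Because the
post-jump state is a long-lived chaotic transient rather than a
quasi-static branch, a single closed up-then-down loop cannot ride both
families; the two sweeps therefore share the quench state rather than the
turning state. MSV at each ramp step is time-averaged over the trailing
quarter of the relaxation window, since oscillatory states make
instantaneous-MSV jump detection meaningless.

## Desk-scale problem sizes

The validation suite runs the full pipelines at reduced scale, chosen once
as defaults: grids of 32–128 points, single realizations or ensembles of
3–4, integration times of 0.3–5 τ_r, and coarse ramp schedules
(ΔA = 10–50). At these scales the qualitative sequence — quiescent →
shear → vortex states → chaos, with subcritical jumps and laminar/chaotic
discrimination by stretching numbers — is reproducible; quantitative
thresholds that depend on near-adiabatic continuation shift with ramp
speed and resolution, as described above.

## What the synthetic inputs do and do not emulate

All inputs are generated internally (aligned states, seeded single modes,
noise bursts); there is no external data. The generator reproduces the
study conditions — initial alignment, burst amplitudes and durations,
per-realization seeds — exactly at reduced resolution. It does not emulate
experimental imperfections (finite anchoring, defects, friction,
confinement), so passing tests validate the numerical method and the
model's internal structure, not agreement with any experimental system.

## Known limitations

- First-order-in-time splitting; linear-rate measurements need refined Δt.
- The unwrapped-θ representation cannot follow defect nucleation; runs that
  wind up warn and should be treated as under-resolved.
- MLE estimates carry O(1/T) estimator noise; "zero" exponents are only
  defined up to the |λ|T ≤ 3 resolution rule.
- The oscillation detector requires ≥ ~3 periods inside the analysis
  window; slower oscillations are labelled steady.
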