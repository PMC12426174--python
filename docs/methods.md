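# Methods

## Model and assumptions

The catheter wall is treated as a one-dimensional annulus R1 < r < R2 of
length L with a single constant diffusivity D. Assumptions inherited from
the physical setup:

* the lumen is closed and dry during the whole experiment → zero flux at R1
  in every stage;
* end faces and the balloon orifice are ignored (sample length L only scales
  volumes and areas);
* the loading bath is concentrated enough to stay at CL during the entire
  load, and both baths are well stirred;
* an LbL coating (∼1 μm against a 1 mm wall) changes surface affinity only:
  it is represented by condition-specific partition coefficients γL, γD,
  never by a second diffusivity or an explicit coating layer;
* no degradation, binding, or convective transport inside the wall.

Surface exchange is a Robin condition −D ∂C/∂r = k (C − γ·C_bath) at r = R2.
The default is the well-mixed limit k ≫ D, where the boundary value is pinned
at γ·C_bath (Dirichlet); finite k is supported for both stages. The delivery
bath is a finite reservoir of volume V_PBS coupled by an ODE that gains
exactly the flux the wall loses; V_PBS = ∞ (`SINK`) pins the bath at zero
concentration and release is then bookkept from the wall-mass decrement.

## Canonical units and parameters

Everything is cm / hours / μg / μg·cm⁻³. Defaults:

| parameter | default | meaning |
|---|---|---|
| D | 1.744×10⁻⁵ cm²/h | ciprofloxacin diffusivity in silicone, shared across conditions |
| γL | 1.478 (uncoated), 3.928 (LbL) | loading-bath partition coefficient |
| γD | 0.7688 (uncoated), 1.282 (LbL) | delivery-bath partition coefficient |
| CL | 1330 μg/cm³ | loading-bath concentration (1.33 mg/mL) |
| kL, kD | well-mixed sentinel (∞) | surface mass-transfer coefficients |
| V_PBS | 250 cm³ | delivery reservoir volume |
| protocol | t0 = 12 h, t1 = 36 h, t_end = 396 h | load / rest / delivery boundaries |
| geometry | 14Fr: R1 = 0.135, R2 = 0.235 cm; 20Fr: 0.235 / 0.335 cm; L = 2.5 cm | measured device dimensions |

V_PBS is not a device constant but an experimental choice; 250 cm³ is
effectively a sink for the ∼100–300 μg loadings here (the equilibrium
correction γD·V_wall/V_PBS is ≈ 4×10⁻⁴). It is deliberately an explicit,
overridable parameter — including a pure-sink mode — because release
plateaus are sensitive to it in smaller baths. The two gauge codes map only
to the measured diameter pairs above; the nominal 1 Fr = 1/3 mm convention
disagrees with the measured devices, so arbitrary gauges must be given as
explicit geometry.

## Numerics

**Discretisation.** Vertex-centred finite volume on a uniform grid: nodes at
R1 … R2, cell faces at midpoints, cell volumes the exact annular shells
π(r_out² − r_in²)L, which telescope to the exact wall volume. Fluxes are
differenced in conservation form, so total mass is conserved to rounding; a
direct finite-difference of the expanded Laplacian would not give that, and
the package's conservation audits (rest-stage defect < 10⁻¹⁰, delivery-stage
wall + reservoir defect < 10⁻⁸) are the reason the finite-volume form was
chosen. Observed spatial order on the loading problem is 2.0 (Richardson
51/101/201 triplet).

**Time stepping.** Implicit Euler by default. The loading stage starts from
a genuine discontinuity (the surface concentration jumps from 0 to γL·CL at
t = 0⁺), where Crank–Nicolson's marginal damping produces oscillatory
transients; implicit Euler damps them monotonically. Crank–Nicolson is
available (`scheme="crank-nicolson"`) for smooth problems. Because every
stage has constant coefficients, the one-step propagator is formed once per
stage by dense LU and each step is a single matrix–vector product.

**Wall–reservoir coupling.** During delivery the wall unknowns and CD are
solved in one linear system per step. In the well-mixed case the reservoir
ODE is replaced by an exact discrete total-mass row (Σ V_i C_i + V_PBS·CD
constant) together with the Dirichlet constraint C(R2) = γD·CD, so the
coupled scheme conserves mass by construction rather than approximately;
with finite kD the flux terms enter wall and reservoir rows with opposite
signs and cancel exactly. Operator splitting was rejected because it leaks
mass at exactly the tolerance the audits check.

**Defaults.** n_nodes = 201; dt = 0.01 h (load), 0.05 h (rest), 0.1 h
(delivery). These resolve the loading boundary layer (penetration depth
√(D·dt) per step ≪ node spacing growth) and meet every audit and oracle
tolerance while a full 396 h protocol runs in ∼0.1 s. Stage boundaries are
hit exactly (the step count is rounded, the step size adjusted). The
snapshot at t0 is the load-stage final state; boundary-condition switches
apply from the first step of the later stage.

**Degenerate inputs and guards.** A rest stage of zero duration (t1 = t0) is
allowed and skipped. Negative concentrations beyond −10⁻¹⁰ × scale raise a
`NumericalInstabilityError` advising a smaller dt; no clamping is applied,
since silent clamping would falsify the mass audits. A zero-mass delivery
stage makes the relative audit undefined and is reported as such rather
than as zero.

**Closed-form oracles** used by the test suite: early loading uptake
2γL·CL·√(Dt/π) (semi-infinite half-space; valid while √(Dt) ≪ wall and
≪ R2, matched within 1% at t = 0.5 h on 801 nodes); the delivery
equilibrium CD∞ = M(t1)/(γD·V_wall + V_PBS) (matched within 0.5% on a
6000 h run); and the k → ∞ Robin limit reproducing the Dirichlet solution
(released mass within 0.1% at k = 10⁴ cm/h).

## Synthetic data generator

The generator emulates the study design: cumulative-release measurements of
control and LbL-coated catheters in both sizes under the 12/24/360 h
protocol, 20 sampling times front-loaded toward the burst phase (hour 1
through day 15), and additive Gaussian noise. The default noise law is
`additive-relative`: sd = 3% of the condition's noise-free plateau,
homoscedastic within a profile — a declared stand-in for replicate scatter,
since the real replicate noise law is unknown. Noisy values are clamped at
zero. Seeds propagate through `numpy.random.SeedSequence`, so identical
seeds give byte-identical datasets.

What the generator does **not** emulate: within-replicate correlation over
time (real cumulative curves have correlated errors because each time point
shares the same physical sample), evaporation or bath replacement,
measurement-specific heteroscedasticity, and any model misspecification
(the mean curve *is* the model). Passing closed-loop recovery tests
therefore demonstrates estimator correctness and identifiability under the
stated noise, not robustness of the model itself against real catheters.

## Parameter estimation

Joint trust-region-reflective least squares (scipy) on release-per-area
residuals, with numerical Jacobians; parameters are log-transformed, which
enforces positivity and makes curvature-based uncertainties relative. D is
shared across conditions and sizes by construction (per-condition D behind
`share_diffusivity=False`); kL, kD are not fitted by default. A simulation
failure during optimisation returns large finite penalty residuals instead
of raising, so the optimizer can back away.

Residual weighting is uniform by default. When the noise scales with each
condition's plateau (as the default generator's does), dividing each
dataset's residuals by its plateau (`relative_weighting=True`) is exactly
the generalised-least-squares objective, and the Monte-Carlo recovery study
uses it: over 20 seeded replicates at 3% noise the median relative error of
D is ≈ 6% weighted versus ≈ 12% unweighted.

**Identifiability.** From a single profile, D and γL are nearly collinear:
amplitude scales with γL√D, and within a 360 h window the release curve
barely reaches the bend (diffusion time L²/D ≈ 570 h) that would pin D
independently. The joint fit across conditions with shared D improves the
conditioning of the D–γL curvature block by more than two orders of
magnitude. γD, by contrast, is intrinsically weakly identified whenever the
reservoir is sink-like (at V_PBS = 250 cm³ it perturbs the curve at the
10⁻⁴ level), which dominates the full curvature spectrum of *any* fit to
such data; γD only becomes estimable from noisy data in small baths. The
full-matrix condition number is reported in `FitResult.curvature_condition`.

## Design choices where the design was open

* Release is normalised by the external lateral area 2πR2L only — the area
  the reservoir equation uses — not the total wetted area.
* Sweep outputs are resampled onto a fixed 1 h delivery grid so protocol
  variants are directly comparable.
* CSV dialect is fixed (UTF-8, comma, period decimal, header required) and
  reading validates hard, with row numbers, instead of coercing.
* The CLI writes one `manifest.json` per run with the fully resolved
  configuration; identical manifests give byte-identical CSV payloads.

## Known limitations

* Strictly radial 1-D: no axial/azimuthal transport, no end faces, no
  balloon orifice.
* One diffusivity for the whole wall; an explicit two-layer coating model is
  out of scope.
* No drug degradation, binding, or empirical release laws (Higuchi,
  Korsmeyer–Peppas) — the mechanistic model is the point.
* The fit quantifies uncertainty only through local Gauss–Newton curvature;
  no posterior sampling.
* All validation beyond the closed forms is against the package's own
  synthetic data; see the generator caveats above for what that does and
  does not establish.
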