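# Methods

This note documents the models, estimators and numerical choices behind
`memperm`, in the spirit of a simulation package's model documentation.
Everything quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external runs.

## Scope and units

The package reconstructs membrane-permeation free energetics and
permeability from collective-variable (CV) time series. The CVs are
membrane-normal distances: either a single coordinate `cv_cq` (the
drug's distance from the membrane center along z) or the pair
(`cv_ring`, `cv_tail`) for the two moieties of a flexible permeant.
Units are fixed project-wide to Å, ps, kJ·mol⁻¹ and K (the PLUMED
convention), with kT = 0.0083144621·T kJ·mol⁻¹. Permeabilities are
converted to cm·s⁻¹ (1 Å·ps⁻¹ = 10⁴ cm·s⁻¹) only when reported.

## Synthetic landscapes

Because microsecond atomistic membrane trajectories are not reproducible
at desk scale, every estimator is exercised on analytic model
landscapes sampled by overdamped Langevin dynamics. The landscape is a
sum of Gaussian features along projected coordinates:

    F(z) = −A·[g(z−z₀; σ_w) + g(z+z₀; σ_w)] + B·g(z; σ_b) + bulk level,

with interfacial wells at ±z₀ and a core feature at z = 0. The two
amplitudes are calibrated by a small fixed-point solve so that the
*constructed* observables hold exactly despite Gaussian overlap:
F(z_min) − F(bulk) = −(interfacial depth) and F(0) − F(z_min) = +(core
rise), with z_min the true minimizer. Gradients are analytic.

In 2D the same profile acts on the moiety midpoint m = (ring + tail)/2,
plus a smooth coupling penalty C·(1 − exp(−(ring − tail)²/2w_c²)) that
emulates the connectivity of the two moieties; the minimum free energy
path is the ring = tail diagonal by construction, which gives the path
estimators a known ground truth.

Default feature parameters echo the published chloroquine profiles —
interfacial depth 40 kJ·mol⁻¹ and core rise 11 kJ·mol⁻¹ for the neutral
species — but the geometry is compressed (wells at 5 Å, bulk plateau
reached by ~12 Å, reflective walls at 15 Å for the 2D runs; the 1D
sampler's default wall stays at 45 Å) so that well-tempered runs
converge in tens of nanoseconds of model time on one CPU. Widths
(σ_w = 2 Å, σ_b = 3 Å, w_c = 1.5 Å) were chosen so the well-to-core
segment of the profile is monotone, as in the atomistic profiles; with
narrow non-overlapping features the model would instead interpose a
spurious bulk-level hump between well and core.

The charged-protomer landscape is the neutral one plus a core-localised
Gaussian penalty (default width σ_b) whose height at z = 0 equals the
prescribed core destabilisation exactly and which vanishes in bulk.

## Langevin sampler

Euler–Maruyama integration of overdamped dynamics per CV coordinate,

    ds = [−β D(s) ∇(F+V) + ∇D(s)] dt + √(2 D(s) dt) dW,

in the Itô convention with the spurious drift ∇D included, so a
position-dependent diffusivity leaves the Boltzmann density invariant
(verified by a KS test against the uniform density on a flat landscape).
Boundaries are reflective. D(z) is either constant or a smooth Gaussian
dip from D_bulk to D_core (defaults 0.5 Å²·ps⁻¹; the two-level test
profile uses 0.6/0.2). A validation step warns when the predicted
per-step drift approaches the smallest feature width; a step larger
than 10 feature widths aborts with the step index. All noise flows
from a single `numpy` PCG64 generator per run, so equal seeds give
bit-identical trajectories.

Time step: the biased runs use dt = 0.02 ps, restrained diffusion
windows dt = 0.01 ps. The equilibrium-density check uses dt = 0.005 ps
because the Euler–Maruyama stationary density carries an O(dt) bias that
is visible at the 0.1 kJ·mol⁻¹ level on steep landscapes.

## Well-tempered metadynamics

Gaussian kernels (height w₀ = 1.2 kJ·mol⁻¹, σ = 0.5 Å per CV, pace
2 ps) are deposited with tempered heights w = w₀·exp(−V(s,t)/((γ−1)kT)),
γ = 20 for the neutral and 25 for the charged protomer. The bias and
its analytic gradient are accumulated on a uniform grid (0.01 Å spacing
by default; the scaled-down runs use 0.05–0.1 Å, which is still ≥5
nodes per kernel σ); the integrator reads the bias force by multilinear
interpolation, while kernel heights are computed from the exact
truncated kernel sum so that a HILLS ledger alone reproduces every
height. Kernels are truncated at 8σ per dimension; this keeps grid
accumulation within 1e-10 of brute-force summation even for thousands
of stacked kernels (6σ, the more common choice, leaves ~1e-8 per
kernel, which would break that contract).

The reweighting offset is recomputed from the grid after every
deposition in the standard time-dependent-bias form

    c(t) = (1/β) ln [ ∫ e^{γβV/(γ−1)} ds / ∫ e^{βV/(γ−1)} ds ],

with trapezoidal weights and log-sum-exp guarding. c(t) rises as the
bias fills; individual depositions may lower it transiently — the exact
per-deposition bound is Δc ≥ −h/(γ−1) for a kernel of height h — so the
monotonicity property is asserted against that bound plus the long-run
trend, not as a strict per-step inequality.

## FES estimation

Frame weights are exp(β(V(s,t) − c(t))), with V replayed from the
ledger on the same grid/interpolation the engine used (or taken from
the recorded per-frame bias). The default burn-in discards the first
1/9 of frames, mirroring the discard fraction of the source protocol;
histograms default to 0.5 Å bins (the kernel σ), separate from the
0.01 Å bias grid. Unvisited bins are masked, never imputed.

Errors: three contiguous post-burn-in blocks; each block FES is aligned
to the full estimate by its mean offset on commonly visited bins, and
the per-bin error is the standard error over blocks. Bins missing from
any block carry a masked (NaN) error.

Symmetrization averages mirror bins in probability space,
F_sym = −kT·ln[(e^{−βF(s)} + e^{−βF(−s)})/2] (s → −s on both axes in
2D); this preserves Boltzmann populations, is idempotent, and the
choice over arithmetic averaging of F is deliberate and documented
here because the two differ where mirror bins disagree. Where only one
of a mirror pair is visited its value is copied, since the missing side
carries no statistics. The asymmetry diagnostic reports
max |F(s) − F(−s)| over doubly visited pairs and is compared with the
block error.

Bulk referencing ("bulk-zero") sets the mean F over the bulk region
|z| ≥ bulk_cut to zero; in 2D the region is additionally restricted to
the ring ≈ tail diagonal band, because off-diagonal bulk bins carry the
coupling penalty and do not represent solvated states. An independent
cross-estimate F = −γ/(γ−1)·V(s, t_end) is kept solely as a consistency
check; near the reflective walls (within ~1 Å) both estimators carry
boundary artifacts, so consistency properties are asserted on interior
bins.

## String-method MFEP

Zero-temperature string method on the bicubic interpolant of the 2D
FES: steepest-descent displacement of interior images along the
perpendicular gradient component, then equal-arc-length
reparameterization, iterated until the maximum perpendicular gradient
drops below `tol` (default 0.5 kJ·mol⁻¹·Å⁻¹). The step size is bounded
by the inverse local Hessian norm estimated from spline second
derivatives (explicit-Euler stability), with a displacement cap of 0.3
image spacings. Masked bins are filled with a +100 kJ·mol⁻¹ penalty
above the visited maximum before interpolation so paths cannot cross
unsampled regions; minima candidates require a fully visited 3×3
neighbourhood because the interpolant rings next to penalty steps.
Defaults: 48 images, straight-line initialization (optional waypoints);
ties between equal channels are resolved by whichever basin the first
downhill iterations enter — deterministic for a given surface. The
saddle found this way is validated in the tests against a minimax
flood-fill oracle on the raw grid.

## Protomer coupling

The neutral surface is raised by the aqueous acid–base shift
kT·ln10·(pKa − pH) — 20.18 kJ·mol⁻¹ at pKa 10.4, pH 7, 310 K — so that
bulk populations reproduce the Henderson–Hasselbalch ratio, then the
pair is combined by the exact two-state partition sum
F_comb = −kT·ln(e^{−βF₀'} + e^{−βF₊}). This log-sum-exp form (rather
than an arithmetic population-weighted mean of F) makes the
population/combination identities exact: −kT·ln pᵢ = Fᵢ − F_comb and
the kT·ln2 mixing bounds hold to machine precision. Only the
neutral/monoprotonated pair is combined; the second protonation
(pKa1 = 8.1) is carried as metadata. Proton-transfer kinetics are not
modelled; the sign change of ΔF = F₊ − F₀' marks where the preferred
protomer flips (at the water/lipid interface for the model pair, where
the core penalty equals the aqueous shift).

## Diffusion and permeability

D(z) is estimated from harmonically restrained windows (default spring
10 kJ·mol⁻¹·Å⁻², a stiffness that localises the window to ~0.5 Å at
310 K) via the positional-autocorrelation estimator
D = var(z)²/∫⟨δz(0)δz(t)⟩dt. The ACF integral runs to the first
zero-crossing sustained for 5 lags, falling back to 10× the 1/e decay
time; the error is a 5-block standard error, and a split-half variance
ratio outside [0.5, 2] rejects non-stationary windows. Ladders of ≥5
windows build D(z) with linear interpolation and mirror symmetrization.

Permeability comes from the inhomogeneous solubility-diffusion model,
1/P = ∫ e^{βF(z)}/D(z) dz, with F the membrane-normal profile
referenced to bulk (|F| ≤ 1 kJ·mol⁻¹ enforced at the bounds). For 2D
surfaces F(z) is the Boltzmann marginal over the moiety midpoint — the
ISD integral is over the membrane normal, not the MFEP arc length; the
MFEP profile is kept for mechanistic plots. Quadrature is trapezoidal
at the grid resolution with a half-resolution (Richardson) consistency
estimate; F and D uncertainties propagate to first order and are
reported as a symmetric ±. In the full pipeline the profile's bulk
level is read from a ±1 Å band around the integration bounds rather
than from the outermost bins, which sit against the reflective wall.

The external-field operation reports the scalar scale 2·E·μ (10 mV·Å⁻¹
and 5.8 D give 2.33 kJ·mol⁻¹) and can tilt a surface by
−E·μ·c(z) for a bounded orientation-coupling profile c(z) ∈ [−1, 1];
no electrostatics beyond this scalar coupling is modelled.

## Pipeline, reproducibility, problem sizes

A single YAML config drives landscape → two metadynamics runs → FES →
MFEP → protomer combination → windows → ISD. All randomness derives
from one seed through named CRC-keyed substreams, and artifacts embed
the config hash; re-running a config reproduces every artifact
byte-for-byte (asserted in the acceptance tests).

Problem sizes were chosen as the package's study conditions: the 1D
double-well benchmark runs 40 ns of model time (2×10⁶ steps), the 2D
landscape recovery 160 ns (8×10⁶ steps, ~80,000 kernels), diffusion
windows 10⁶ steps, and the demo pipeline 12 ns per protomer. At these
sizes the 1D barrier is recovered within ~0.3 kJ·mol⁻¹ and the 2D
depth/rise within ~2 kJ·mol⁻¹ of construction; the dominant residual on
the 2D depth is well-versus-bulk convergence of the tempered bias, which
shrinks roughly with run length.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the estimators
assume: diffusive CV dynamics on landscapes with interfacial minima, a
core barrier, bulk plateaus, optional position-dependent D, and paired
protomer surfaces. It does not contain lipids, water, orientational or
conformational degrees of freedom, hidden slow modes orthogonal to the
CVs, or force-field specifics. Passing tests therefore validate the
*estimators and pipeline plumbing* — reweighting, error analysis,
path finding, protomer weighting, ISD — not the ability of the CVs or
the sampling protocol to capture a real membrane's physics, and the
atomistic reference permeabilities (tens of cm·s⁻¹) are not desk-scale
targets.

## Known limitations

- Single-run reweighting only; no WHAM/MBAR combination of runs.
- Bias within ~1 Å of a reflective wall is distorted (kernel mass
  leaks past the boundary); analyses exclude that margin.
- The Euler–Maruyama density bias is O(dt); halve dt to check.
- The zero-temperature string on a noisy FES follows spline wiggles;
  `tol` below the gradient noise level will not converge.
- Permeability errors are first-order propagation with independent-bin
  assumptions; correlated FES noise makes them optimistic.
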