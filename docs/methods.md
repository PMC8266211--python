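# Methods

## Constitutive models

The leaflet tissue is treated as incompressible, anisotropic and
hyperelastic with a single preferred (collagen) direction `f0`. All three
strain-energy functions depend on `I1 = tr(C)` and `I4 = f0.(C f0)` with
`C = F^T F`; `I4` is the squared fiber stretch. Their Cauchy stresses share
the structure

```
sigma = -p I + alpha(I1, I4) B + beta(I1, I4) f (x) f,
alpha = 2 dW/dI1,  beta = 2 dW/dI4,  B = F F^T,  f = F f0.
```

W1 is exponential in both the isotropic (cross-fiber) and fiber terms, W2
couples both invariants inside one exponential, and W3 is neo-Hookean in
the cross-fiber direction with an exponential fiber term. Stress-like
parameters are in kPa; exponents are dimensionless. All parameters are
constrained non-negative, which is also the lower bound used in fitting.
W2's ground-matrix modulus is named `mu` within its parameter set only; it
is unrelated to any fluid viscosity.

Limits `k2 -> 0` (W1) and `b -> 0` (W3) are handled analytically
(`k1/2 (I4-1)^2`, `a/2 (I4-1)^2`) so the zero lower bound is admissible.
Exponent arguments are capped at 60 inside evaluations; physiological
parameter/stretch combinations stay one to two orders of magnitude below
the cap, which exists so that extreme multi-start initials produce large
finite losses instead of overflow.

### Planar-biaxial response

Biaxial tests are modeled shear-free with the fiber along the
circumferential test axis: `F = diag(l1, l2, l3)`, `l3 = 1/(l1 l2)` from
exact incompressibility. Plane stress (`sigma33 = 0`) fixes the pressure
analytically, `p = alpha l3^2`, giving

```
sigma11 = alpha (l1^2 - l3^2) + beta l1^2,
sigma22 = alpha (l2^2 - l3^2).
```

A bisection-on-`p` oracle in the tests confirms the elimination to
`|sigma33| < 1e-10` kPa. Marker-based experiments can carry small shears;
the diagonal-`F` idealization ignores them.

### Fiber strain and stress

Fiber strain is `f0.(E f0) = (I4-1)/2` with `E` the Green strain. For the
fiber stress the deformed direction `F f0` (magnitude `sqrt(I4)`) is
**normalized** before the quadratic form, so the measure is the true normal
traction along the fiber. The unnormalized convention would scale the same
quantity by `I4`; reported closed-valve stresses cannot distinguish the
two, and the normalized form was chosen for its physical interpretation.

## Biaxial calibration

The loss is the unweighted sum over points of squared Cauchy-stress
residuals in both directions. Minimization uses SciPy's trust-region
reflective least squares with bounds `[0, inf)`, `ftol = 1e-10` and at most
5000 evaluations per start. Because the exponential laws possess local
minima, 20 restarts are drawn log-uniformly from `[1e-2, 1e3]` per
parameter (seeded); the best local solution wins. Noiseless synthetic data
return the generating parameters of all three laws to machine precision;
W2's `(c0, c1)` pair is the least identifiable direction, so its tolerance
is stated on the predicted curves as well as the parameters.

Goodness of fit: `R^2 = 1 - SSE/SST` with SST pooled over both stress
components about their common mean (one R^2 per sample), flagged undefined
(NaN) when SST = 0. The per-sample "average error" is the RMSE
`sqrt(SSE/(2n))` in kPa — chosen because it is in stress units and of the
magnitude of published per-law error summaries — and is aggregated across
samples as mean +- sample SD (ddof = 1; SD = 0 for a single sample).

## Rule-based fiber architectures

Scalar fields are solved on the leaflet mid-surface with linear triangular
elements and the cotangent-weight Laplacian (symmetric, zero row sums;
zero-area triangles are rejected by index). Dirichlet constraints are
applied by reduction and the reduced system solved with a sparse direct
factorization; the residual is checked below 1e-10.

* **FD1**: point constraints `u = 1` and `u = 0` at the two commissure
  corner vertices (where the free edge meets the attachment edge), natural
  conditions elsewhere. Point Dirichlet data are borderline in the
  continuum but well-posed discretely; this literal construction is kept
  and the corner labels are configurable.
* **FD2**: `u = 0` / `u = 1` on the two attachment-edge halves.

Fibers are per-triangle (the gradient of a linear field is element-wise
constant), normalized to unit length and tangent to the facet by
construction. Where `|grad u|` falls below `1e-12 * range(u) / diameter` —
FD1 has an interior saddle where this can happen — the triangle inherits
the area-weighted average direction of its edge neighbors; with no valid
neighbor it keeps a zero vector and a warning is emitted.

On a polar-structured annular sector the angular harmonic `theta/dtheta` is
reproduced to solver precision, so convergence order is measured on the
radial log-harmonic, where the scheme shows the expected ~2nd order in L2.

## Windkessel afterload

`C dPwk/dt + Pwk/Rp = Q`, `Pao = Q Rc + Pwk`, with flow positive into the
aorta and the distal reference pressure at ground. Defaults
`Rc = 0.033 mmHg s/mL`, `Rp = 0.79 mmHg s/mL`, `C = 1.75 mL/mmHg`,
`Pwk0 = 85 mmHg` are standard human systemic values (time constant
`Rp C = 1.3825 s`). The update holds `Q` constant over each sampling
interval (left-sampled) and applies the exact exponential solution, so the
integration is unconditionally stable and error-free for sampled flow; the
only discretization effect is the sampling of `Q` itself.

## Hemodynamic indices

All integrals are trapezoidal with linear interpolation at event-window
endpoints (second-order, grid-agnostic). Cycle events `t_bs`, `t_es`
(begin/end systole), `t_close` (full closure) and the cycle end are
explicit inputs; an optional detector places `t_bs`/`t_es` at the
first/last crossing of `Q` through 1% of its peak and `t_close` at the
first time after `t_es` where `|Q|` stays within that threshold for at
least 10 ms.

* `V_F` integrates forward flow over systole; `V_R`/`V_L` integrate reverse
  flow over the closing/leakage windows and are stored as magnitudes.
* `RF = (V_R + V_L)/V_F * 100%` (undefined for `V_F <= 0`).
* `TPG` averages the near-valve gradient `P_nlv - P_nao` over systole;
  near-valve pressures default to the inlet/outlet pressures when absent.
* `EOA = Q_rms / (51.6 sqrt(dP/rho))` with `Q` in mL/s, `dP` in mmHg and
  `rho` in g/mL; `dP` defaults to the mean systolic TPG.
* `E_L = 0.1333 * integral (P_ao - P_lv) Q dt` over the cycle. The
  conversion 1 mmHg mL = 0.13332 mJ follows from SI constants; the
  four-digit factor 0.1333 is used in the formula. The integral is negative
  when the valve transmits net forward work, so the magnitude is reported
  (a `signed=True` escape hatch keeps the raw value).

## Multi-criteria scoring

Twelve criteria are scored per case by min-max rescaling with a fixed
direction registry: lower-is-better for fitting error, opening/closing
durations, regurgitation flow, strain/stress variation, RF, TPG and energy
loss; higher-is-better for opening orifice, forward flow and EOA. The
strain/stress "variation" is the absolute belly vs top-center difference —
the absolute value is required because the circumferential architecture
loads the top-center region harder than the belly. In table-reproduction
mode each score is rounded **half-up** to two decimals before totaling
(verified necessary to match the published two-decimal table, whose totals
sum its printed entries); full precision is the default otherwise. An
all-equal criterion scores 1 for every case (no information, no penalty).
Three criteria whose raw vectors are only partially published (opening
orifice, forward flow, regurgitation flow) are accepted pre-normalized.

## Synthetic-data generators

* **Biaxial protocol.** Stress-controlled 1:1 loading: target stress levels
  `linspace(0, peak]` with the peak from Laplace's law for a thin spherical
  shell (radius of curvature 2 cm, transvalvular pressure 120 mmHg, leaflet
  thickness 0.04 cm, giving 399.96 kPa). The stretches realizing each level
  are found by Powell-hybrid root finding in log-stretch variables with
  continuation from the previous level (a Levenberg-Marquardt fallback
  covers stiff-exponential starts). Multiplicative Gaussian noise
  `(1 + cv * eps)` is applied per stress channel, seeded. Preconditioning
  is modeled only as "start from the zero-load reference". An equal-stretch
  mode is also provided.
* **Cycle waveforms.** A quasi-static orifice model: prescribed smooth LV
  pulse (baseline 12 mmHg, peak 110 mmHg, onset 0.05 s, duration 0.42 s
  over a 0.8 s cycle), a smoothstep opening fraction (opening ramp 0.09 s,
  pre-close at 0.22 s, closing ramp 0.16 s — the opening/closing times of
  the simulated cases — residual leak fraction 0.004), and
  `Q = 51.6 * EOA_ref * A(t) * sign(dP) sqrt(|dP|)` solved self-consistently
  with the Windkessel outlet (`EOA_ref = 4.0 cm^2`), stepped at 0.2 ms.
  Defaults were chosen once so the forward volume lands in the 60-100 mL
  physiological band; the resulting indices (RF ~7.7%, TPG ~6.1 mmHg,
  EOA ~3.5 cm^2, E_L ~92 mJ) sit inside the bands spanned by published
  valve simulations. This surrogate reproduces the *structure* real cycles
  have (systolic ejection, brief closing backflow, small leakage, event
  times) but none of the spatial physics — no jet dynamics, no leaflet
  inertia, no flow oscillations after closure — so tests passing on it
  certify the index computations, not any FSI prediction.
* **Leaflet meshes.** A semi-lunar patch of the 1.3 cm aortic tube surface:
  the attachment edge dips 1.2 cm below the commissures at the belly
  center, the free edge is the horizontal commissure-to-commissure arc.
  The structured grid is welded at the commissures (degenerate triangles
  dropped) and labeled with the commissure corners, the two attachment
  halves (the belly-center vertex belongs to neither, keeping the sets
  disjoint) and the free edge. The patch lies on the cylinder — it does not
  model belly bulge or coaptation geometry — which makes the
  circumferential architecture analytically checkable.

## Problem sizes and determinism

Default test/problem sizes: 25-point biaxial protocols; 200 noisy fitting
replicates at 3 restarts each (20 restarts for single calibrations); fiber
benchmarks at grid resolutions 8-32; surrogate cycles at 4001 samples.
Every stochastic component takes a seed (NumPy `default_rng`), and all
generators are bit-reproducible given one.

## Known limitations

* No viscoelasticity, no compressibility, no shear terms in the biaxial
  kinematics, and no 3-D stress analysis of the leaflet.
* FD1's point constraints make the continuum problem only marginally
  posed; refinement studies of FD1 compare discrete solutions rather than
  an analytic limit.
* The scoring stage reproduces a fixed published comparison; it does not
  propagate uncertainty into ranks or support alternative weightings.
* The waveform surrogate is phenomenological; its parameters are design
  choices, not fitted quantities.
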