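# Methods

## Measurement model

The image `x` lives on an `N1 × N2` complex grid. Measurements are
`y = U F x + η` with `F` the *unitary* 2-D DFT (zero frequency at the grid
center for mask geometry) and `U` a binary restriction to `M` k-space
locations. Unitarity is load-bearing: it makes `U*U` an orthogonal projector
diagonal in the Fourier basis, which is what gives the coefficient
subproblem below an exact closed form. Noise is i.i.d. circularly symmetric
complex Gaussian with per-component standard deviation `σ_n`, so
`E‖η‖² = 2 M σ_n²`; the helper `sigma_sq_from_noise` adds 5% relative slack
by default so the constraint level is feasible for typical draws.

Masks are generated as variable-density random Cartesian patterns: a fully
sampled central calibration block (default side fraction 0.08 per axis) plus
locations drawn without replacement with probability
`(1 − r/√2)^e + 10⁻⁴` where `r` is the normalized distance from the k-space
center and `e = 4` by default. Exactly `round(fraction · N)` locations are
set, and a fixed seed is bit-reproducible. This generator is a stand-in with
the visual character of published variable-density patterns, not a
reproduction of any particular one; `uniform_random` and `full` patterns are
also available.

## Tight frames

All frames are Parseval-normalized: `Ψ*Ψ = I` *and* `‖Ψx‖ = ‖x‖`, verified
numerically at construction (a frame failing the 1e-10 tightness check is
rejected). Parseval normalization is required, not cosmetic: the analytic
coefficient update is the exact subproblem minimizer only when `ΨΨ*` is an
orthogonal projector.

* **SIDWT** — undecimated separable 2-D wavelet frame, implemented via
  FFT-domain à-trous transfer functions with periodic boundary extension
  (periodic extension preserves exact tightness; symmetric extension does
  not and is therefore not offered). Orthonormal filters are scaled by
  `1/√2` per level so that `|H|² + |G|² = 1` pointwise, making the frame
  exactly tight; redundancy is `3·levels + 1`. Default: Daubechies-4,
  3 levels — a conventional choice for piecewise-smooth MR images, exposed
  in the configuration.
* **Orthogonal DWT** — PyWavelets `wavedec2/waverec2` with periodization
  boundaries (orthonormal, `D = N`, two-sided inverse).
* **TIDCT** — orthonormal DCT on non-overlapping patches, repeated over all
  cyclic shifts of the tiling grid and scaled by `1/√(#tilings)`; redundancy
  `patch_size²`. When the patch spans an axis, shifting along that axis is
  skipped (cyclic shifts of a full-image transform add redundancy without
  new structure), so `patch_size = image size` degenerates to the plain
  orthogonal 2-D DCT.

Coefficients are flat complex vectors, subband-major and row-major within a
subband; solvers treat them as opaque vectors, so only self-consistency of
the ordering matters.

## Solvers

All three solvers expose the balance through `γ = ρ/(ρ+β) ∈ [0,1]`
(`γ = 1` synthesis, `γ = 0` analysis). γ is the user-facing knob because the
closed-form update is written in γ and is numerically stable at both
endpoints; `γ = 0` is handled as the exact `β → ∞` limit rather than a large
finite penalty.

**C-SALSA-B** (constrained form). ADMM with the splitting `z = α`, a
coefficient-domain multiplier `d` and a measurement-domain multiplier `h`:

1. closed-form coefficient update (`alpha_update`, see README for the
   formula) — exact minimizer of its subproblem, verified against an
   independent conjugate-gradient solve of the normal equations;
2. `z ← soft-threshold_{λ/ρ}(α − d)` with complex magnitude shrinkage
   (`max(|v| − t, 0)·v/|v|`; the real-signal sign form is the special case);
3. `h ← h − δ_h (UFΨ*α − y)`;  4. `d ← d − δ_d (α − z)`.

Initialization: `z₁ = Ψ(F*U*y)` (zero-filled warm start), `d₁ = 0`,
`h₁ = 0`. Stopping combines the early-stopping rule `‖y − UFΨ*α‖² ≤ σ²`
with a relative-change test on `x̂` (default tol 1e-5) and an iteration cap
(default 100), because the constraint alone never triggers in noiseless
simulation with `σ² = 0`. The solvers never stop before iteration 2: the
first ADMM iterate can coincide exactly with the (data-consistent)
zero-filled warm start, which would otherwise satisfy both tests vacuously.

**ADMM-B** (penalized form). Same splitting on
`λ‖z‖₁ + (β/2)‖(I−ΨΨ*)α‖² + (δ/2)‖y − UFΨ*α‖²`; its coefficient subproblem
is the same closed form with the fidelity weight `δ` in place of `μ` and no
measurement multiplier. The fidelity weight defaults to 1 and an optional
over-relaxation factor (default 1, i.e. off) is exposed. Stops on relative
change or the iteration cap.

**APG.** FISTA on the penalized form: smooth part
`f(α) = (β/2)‖(I−ΨΨ*)α‖² + (δ/2)‖UFΨ*α − y‖²` with gradient
`β(I−ΨΨ*)α + δΨF*U*(UFΨ*α − y)` and Lipschitz constant `L = β + δ`
(sharp for Parseval frames and unitary DFT); prox step is soft-thresholding
at `λ/L`; momentum `t_{k+1} = (1+√(1+4t_k²))/2`. Monotone restart (default
on) falls back to a plain proximal-gradient step from the current iterate
whenever the accelerated candidate would increase the objective, which
guarantees a non-increasing objective; plain momentum is available behind
the flag. APG requires `γ > 0` — the analysis limit has no smooth gradient.

Defaults follow the reference parameterization: `λ = 0.05`, `γ = 0.5`
(`β = 1`), `ρ = μ = δ_h = δ_d = 1` for C-SALSA-B; `λ = 0.01` for ADMM-B;
`λ = 0.005`, `L = 2` for APG. A NaN/Inf guard runs every iteration and
raises a `DivergenceError` naming the likely offending parameters instead of
returning garbage.

Per-iteration traces record the regularization objective
`λ‖z‖₁ + (β/2)‖(I−ΨΨ*)α‖²` (for APG, the full penalized objective, which is
what its monotonicity guarantee covers), the constraint value
`‖y − UFΨ*α‖²`, and RLNE against the ground truth when provided. All
solvers are deterministic given (y, mask, config).

## Synthetic data

The phantom generators stand in for scanner images, which are not shipped.
They emulate the property the sparse models rely on — piecewise-smooth
magnitude with sharp boundaries (≥ 90% of wavelet energy in ≤ 10% of
coefficients for all default specs, asserted in tests) — plus an optional
smooth random phase as a surrogate for off-resonance/coil phase. They do
*not* simulate scanner physics: no coil sensitivity profiles, relaxation
contrast, motion, or structured (non-Gaussian) noise. Passing tests
therefore demonstrate correctness of the operators and solvers and the
qualitative model behavior (error ordering, limit equivalences, convergence
ranking), not clinical image quality on real acquisitions.

Default problem sizes: 64×64 for tests and the acceptance script, 256×256
for the CLI experiment runners — the package's standard desk-scale and
experiment-scale choices. The frozen test fixture is a 64×64 Shepp–Logan
phantom, 40% variable-density mask, no noise, seed 1234.

## Numerical and design notes

* The closed-form update is validated two ways: analytically (projector
  split: the off-range component scales by `γ`, the range component solves a
  diagonal Fourier system) and numerically against `subproblem_oracle`, a
  conjugate-gradient solve of the normal equations to 1e-13 relative
  residual, independent of the closed-form path.
* Soft-thresholding at `t = 0` is the identity; the zero coefficient maps to
  zero (no division by `|v|`).
* Full-sampling consistency checks use a small `λ = 10⁻⁴` (and a large
  fidelity weight for the penalized baselines): the penalized models have a
  soft-threshold bias floor proportional to `λ/δ`, so exact-recovery checks
  isolate solver correctness from regularization bias.
* In the solver comparison, iterations-to-threshold uses a relative target
  (1.05 × the best final RLNE among solvers) rather than fixed iteration
  counts, which depend on data scale. At desk scale the penalized baselines
  can converge to visibly higher floors than the constrained solver because
  they minimize differently weighted objectives; the comparison reports all
  floors alongside the threshold crossings.
* Known limitations: Cartesian masks only (no radial/spiral trajectories or
  parallel imaging); no adaptive/directional frames (the `FrameOperator`
  contract is the extension point); convergence is demonstrated empirically,
  not proven here.
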