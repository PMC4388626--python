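"""Sparse reconstruction solvers for the constrained balanced model.

The balanced model penalizes, in addition to the l1 norm of the frame
coefficients ``alpha``, the distance of ``alpha`` from the range of the
analysis operator:

    min_alpha  lambda ||z||_1 + (beta/2) ||(I - Psi Psi*) alpha||_2^2
    s.t.       ||y - U F Psi* alpha||_2^2 <= sigma^2,   z = alpha.

``beta = 0`` recovers the synthesis model (search over all coefficients) and
``beta -> inf`` the analysis model (alpha constrained to canonical
coefficients, equivalent to penalizing ||Psi x||_1).  The balance is
parameterized by

    gamma = rho / (rho + beta)  in [0, 1],

with gamma = 1 synthesis and gamma = 0 analysis; gamma is the user-facing
knob and the analysis endpoint is handled exactly rather than via a large
finite beta.

Three solvers are provided:

* :func:`csalsa_b` — ADMM on the *constrained* formulation (split augmented
  Lagrangian with a measurement-domain multiplier ``h`` and a
  coefficient-domain multiplier ``d``); the coefficient subproblem has the
  closed-form solution implemented in :func:`alpha_update`, exact for
  Parseval frames and unitary Fourier sampling.
* :func:`admm_b` — ADMM on the unconstrained (penalized) form with data
  fidelity weight ``delta_fid``.
* :func:`apg` — accelerated proximal gradient (FISTA-type momentum, optional
  monotone restart) on the unconstrained form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .frames import FrameOperator
from .kspace import KSpaceData, mask_adjoint, _fft_centered, _ifft_centered
from .metrics import rlne

__all__ = [
    "SolverConfig",
    "SolverResult",
    "AuxState",
    "DivergenceError",
    "gamma_from_beta",
    "beta_from_gamma",
    "soft_threshold",
    "alpha_update",
    "subproblem_oracle",
    "csalsa_b",
    "admm_b",
    "apg",
    "iterations_to_threshold",
    "SOLVERS",
]


class DivergenceError(RuntimeError):
    """Raised when solver iterates become non-finite."""


def gamma_from_beta(beta: float, rho: float) -> float:
    """Balance parameter gamma = rho / (rho + beta); maps beta 0 -> 1, inf -> 0."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if np.isinf(beta):
        return 0.0
    return rho / (rho + beta)


def beta_from_gamma(gamma: float, rho: float) -> float:
    """Inverse map; gamma = 0 corresponds to the exact analysis limit beta = inf."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    if gamma == 0.0:
        return np.inf
    return rho * (1.0 - gamma) / gamma


@dataclass
class SolverConfig:
    """Solver parameters.

    Defaults follow the reference parameterization for C-SALSA-B
    (lambda_ = 0.05, gamma = 0.5 i.e. beta = 1, rho = mu = delta_h =
    delta_d = 1).  The unconstrained baselines additionally use
    ``delta_fid`` (data-fidelity weight) and their own typical l1 weights
    (0.01 for ADMM-B, 0.005 for APG) — pass those explicitly.
    """

    lambda_: float = 0.05
    gamma: float = 0.5
    rho: float = 1.0
    mu: float = 1.0
    delta_h: float = 1.0
    delta_d: float = 1.0
    sigma_sq: float = 0.0
    max_iter: int = 100
    tol: float = 1e-5
    delta_fid: float = 1.0
    relax: float = 1.0  # ADMM-B over-relaxation factor; 1 = none
    monotone_restart: bool = True  # APG restart on objective increase

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        for name in ("lambda_", "sigma_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("rho", "mu", "delta_h", "delta_d", "delta_fid", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def beta(self) -> float:
        return beta_from_gamma(self.gamma, self.rho)

    @classmethod
    def from_beta(cls, beta: float, **kwargs) -> "SolverConfig":
        rho = kwargs.get("rho", 1.0)
        return cls(gamma=gamma_from_beta(beta, rho), **kwargs)

    def replace(self, **kwargs) -> "SolverConfig":
        return replace(self, **kwargs)


@dataclass
class AuxState:
    """ADMM auxiliary variables: split coefficients z, multipliers d and h."""

    z: np.ndarray  # length D
    d: np.ndarray  # length D, coefficient-domain multiplier
    h: np.ndarray  # length M, measurement-domain multiplier


@dataclass
class SolverResult:
    """Reconstruction plus per-iteration diagnostics."""

    image: np.ndarray
    coefficients: np.ndarray
    trace_objective: np.ndarray
    trace_constraint: np.ndarray
    trace_rlne: np.ndarray | None
    iterations_run: int
    solver: str = ""
    config: SolverConfig | None = None

    def __post_init__(self):
        n = self.iterations_run
        assert len(self.trace_objective) == n and len(self.trace_constraint) == n
        if self.trace_rlne is not None:
            assert len(self.trace_rlne) == n


def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Complex magnitude shrinkage max(|v| - t, 0) * v/|v| (prox of t*||.||_1).

    Reduces to max(|x| - t, 0) * sgn(x) for real input; zeros stay zero.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    v = np.asarray(v)
    if t == 0:
        return v.copy()
    mag = np.abs(v)
    scale = np.maximum(mag - t, 0.0)
    out = np.zeros_like(v)
    nz = mag > 0
    out[nz] = v[nz] * (scale[nz] / mag[nz])
    return out


def _forward_samples(x: np.ndarray, mask_grid: np.ndarray) -> np.ndarray:
    """U F x as a length-M vector."""
    return _fft_centered(x)[mask_grid]


def alpha_update(
    state: AuxState,
    y: KSpaceData,
    frame: FrameOperator,
    mu: float,
    rho: float,
    gamma: float,
) -> np.ndarray:
    """Closed-form coefficient update of the split augmented Lagrangian.

    Exact unique minimizer of

        (beta/2)||(I - Psi Psi*) a||^2 + (mu/2)||U F Psi* a - y - h||^2
        + (rho/2)||a - z - d||^2

    for a Parseval frame and unitary DFT, with gamma = rho/(rho+beta):

        a = (mu/(mu+rho)) Psi F* U* (y + h) + gamma (z + d)
            + Psi F* [(1-gamma) I - (mu/(mu+rho)) U* U] F Psi* (z + d).

    ``mu = 0`` is accepted (zero-weight data term), in which case the update
    reduces to gamma (z+d) + (1-gamma) Psi Psi* (z+d).
    """
    if mu < 0 or rho <= 0:
        raise ValueError("mu must be >= 0 and rho > 0")
    mask_grid = y.mask.grid
    c = mu / (mu + rho)
    s = state.z + state.d
    w = y.samples + state.h

    xs = frame.synthesis(s)
    ks = _fft_centered(xs)
    inner = (1.0 - gamma) * ks
    inner[mask_grid] -= c * ks[mask_grid]
    a = gamma * s + frame.analysis(_ifft_centered(inner))
    if c > 0:
        a += c * frame.analysis(mask_adjoint(w, y.mask))
    return a


def subproblem_oracle(
    state: AuxState,
    y: KSpaceData,
    frame: FrameOperator,
    mu: float,
    rho: float,
    beta: float,
    rtol: float = 1e-13,
    maxiter: int = 2000,
) -> np.ndarray:
    """Iterative linear-solver reference for the coefficient subproblem.

    Solves the normal equations

        [beta (I - Psi Psi*) + mu (U F Psi*)*(U F Psi*) + rho I] a
            = mu (U F Psi*)* (y + h) + rho (z + d)

    by conjugate gradients (the operator is Hermitian positive definite).
    For beta = inf the problem is solved over the range of Psi via the
    image-domain normal equations and mapped back with the analysis operator.
    Intended for small instances as an independent check of
    :func:`alpha_update`.
    """
    mask = y.mask
    s = state.z + state.d
    w = y.samples + state.h
    D = frame.n_coefficients

    if np.isinf(beta):
        # constrained to range(Psi): substitute a = Psi x, solve for x
        N = frame.n_pixels

        def mv_img(xf):
            x = xf.reshape(frame.shape)
            k = _fft_centered(x)
            kk = np.zeros_like(k)
            kk[mask.grid] = k[mask.grid]
            return (mu * _ifft_centered(kk) + rho * x).ravel()

        op = LinearOperator((N, N), matvec=mv_img, dtype=np.complex128)
        rhs = (mu * mask_adjoint(w, mask) + rho * frame.synthesis(s)).ravel()
        sol, info = cg(op, rhs, rtol=rtol, atol=0.0, maxiter=maxiter)
        if info != 0:
            raise RuntimeError(f"CG did not converge (info={info})")
        return frame.analysis(sol.reshape(frame.shape))

    def mv(af):
        a = af.ravel()
        pa = frame.analysis(frame.synthesis(a))
        k = _fft_centered(frame.synthesis(a))
        samp = k[mask.grid]
        ata = frame.analysis(mask_adjoint(samp, mask))
        return beta * (a - pa) + mu * ata + rho * a

    op = LinearOperator((D, D), matvec=mv, dtype=np.complex128)
    rhs = mu * frame.analysis(mask_adjoint(w, mask)) + rho * s
    sol, info = cg(op, rhs, rtol=rtol, atol=0.0, maxiter=maxiter)
    if info != 0:
        raise RuntimeError(f"CG did not converge (info={info})")
    return sol


def _check_finite(a: np.ndarray, it: int, solver: str) -> None:
    if not np.all(np.isfinite(a.view(np.float64))):
        raise DivergenceError(
            f"{solver}: non-finite iterate at iteration {it}; the penalty or "
            "multiplier-step parameters (mu, rho, delta_h, delta_d, delta_fid) "
            "are likely too large for this problem"
        )


def _offrange_sq(a: np.ndarray, frame: FrameOperator) -> float:
    p = frame.range_projection(a)
    return float(np.linalg.norm(a - p) ** 2)


def _objective(lam, beta, z_l1, offrange_sq):
    # the analysis limit (beta = inf) keeps alpha in the range by
    # construction, so the quadratic penalty term is identically zero
    if np.isinf(beta):
        return lam * z_l1
    return lam * z_l1 + 0.5 * beta * offrange_sq


def csalsa_b(
    y: KSpaceData,
    frame: FrameOperator,
    config: SolverConfig | None = None,
    x_true: np.ndarray | None = None,
) -> SolverResult:
    """Constrained split augmented Lagrangian shrinkage for the balanced model.

    ADMM on the equality-constrained reformulation with early stopping on the
    measurement-consistency level: iterate the closed-form coefficient update,
    soft-thresholding of the split variable, and the two multiplier updates

        h <- h - delta_h (U F Psi* a - y),    d <- d - delta_d (a - z),

    terminating when ||y - U F Psi* a||^2 <= sigma^2 *and* the relative
    change of the reconstruction falls below ``tol``, or at ``max_iter``.
    """
    cfg = config or SolverConfig()
    gamma, rho, mu, lam = cfg.gamma, cfg.rho, cfg.mu, cfg.lambda_
    beta = cfg.beta
    mask = y.mask

    x0 = mask_adjoint(y.samples, mask)  # zero-filled warm start
    state = AuxState(
        z=frame.analysis(x0),
        d=np.zeros(frame.n_coefficients, dtype=np.complex128),
        h=np.zeros(mask.n_samples, dtype=np.complex128),
    )
    x_prev = x0
    obj_tr, con_tr, rlne_tr = [], [], [] if x_true is not None else None
    alpha = state.z
    n_run = 0
    for it in range(1, cfg.max_iter + 1):
        alpha = alpha_update(state, y, frame, mu, rho, gamma)
        _check_finite(alpha, it, "csalsa_b")
        state.z = soft_threshold(alpha - state.d, lam / rho)
        x_hat = frame.synthesis(alpha)
        resid = _forward_samples(x_hat, mask.grid) - y.samples
        state.h = state.h - cfg.delta_h * resid
        state.d = state.d - cfg.delta_d * (alpha - state.z)

        constraint = float(np.linalg.norm(resid) ** 2)
        obj_tr.append(
            _objective(lam, beta, float(np.abs(state.z).sum()), _offrange_sq(alpha, frame))
        )
        con_tr.append(constraint)
        if rlne_tr is not None:
            rlne_tr.append(rlne(x_hat, x_true))
        n_run = it

        rel = np.linalg.norm(x_hat - x_prev) / max(np.linalg.norm(x_prev), 1e-30)
        x_prev = x_hat
        # the first iterate can coincide with the zero-filled warm start
        # (exactly data-consistent), so never stop before the thresholded
        # split variable has fed back into the coefficient update
        if it > 1 and constraint <= cfg.sigma_sq and rel < cfg.tol:
            break

    return SolverResult(
        image=x_prev,
        coefficients=alpha,
        trace_objective=np.asarray(obj_tr),
        trace_constraint=np.asarray(con_tr),
        trace_rlne=None if rlne_tr is None else np.asarray(rlne_tr),
        iterations_run=n_run,
        solver="csalsa_b",
        config=cfg,
    )


def admm_b(
    y: KSpaceData,
    frame: FrameOperator,
    config: SolverConfig | None = None,
    x_true: np.ndarray | None = None,
) -> SolverResult:
    """ADMM on the unconstrained (penalized) balanced objective.

    Same splitting z = alpha as :func:`csalsa_b`, but the data term enters as
    a quadratic penalty (delta_fid/2)||U F Psi* a - y||^2; the coefficient
    subproblem is the same closed form with the fidelity weight in place of
    mu and no measurement multiplier.  Stops on relative change < tol or at
    max_iter.  ``relax`` > or < 1 applies standard ADMM over-relaxation to
    the split variable before the z and d updates.
    """
    cfg = config or SolverConfig(lambda_=0.01)
    gamma, rho, lam, delta = cfg.gamma, cfg.rho, cfg.lambda_, cfg.delta_fid
    beta = cfg.beta
    mask = y.mask

    x0 = mask_adjoint(y.samples, mask)
    state = AuxState(
        z=frame.analysis(x0),
        d=np.zeros(frame.n_coefficients, dtype=np.complex128),
        h=np.zeros(mask.n_samples, dtype=np.complex128),  # unused (stays 0)
    )
    x_prev = x0
    obj_tr, con_tr, rlne_tr = [], [], [] if x_true is not None else None
    alpha = state.z
    n_run = 0
    for it in range(1, cfg.max_iter + 1):
        alpha = alpha_update(state, y, frame, delta, rho, gamma)
        _check_finite(alpha, it, "admm_b")
        a_eff = alpha if cfg.relax == 1.0 else cfg.relax * alpha + (1 - cfg.relax) * state.z
        state.z = soft_threshold(a_eff - state.d, lam / rho)
        state.d = state.d - cfg.delta_d * (a_eff - state.z)

        x_hat = frame.synthesis(alpha)
        resid = _forward_samples(x_hat, mask.grid) - y.samples
        obj_tr.append(
            _objective(lam, beta, float(np.abs(state.z).sum()), _offrange_sq(alpha, frame))
        )
        con_tr.append(float(np.linalg.norm(resid) ** 2))
        if rlne_tr is not None:
            rlne_tr.append(rlne(x_hat, x_true))
        n_run = it

        rel = np.linalg.norm(x_hat - x_prev) / max(np.linalg.norm(x_prev), 1e-30)
        x_prev = x_hat
        if it > 1 and rel < cfg.tol:
            break

    return SolverResult(
        image=x_prev,
        coefficients=alpha,
        trace_objective=np.asarray(obj_tr),
        trace_constraint=np.asarray(con_tr),
        trace_rlne=None if rlne_tr is None else np.asarray(rlne_tr),
        iterations_run=n_run,
        solver="admm_b",
        config=cfg,
    )


def smooth_gradient(
    a: np.ndarray,
    y: KSpaceData,
    frame: FrameOperator,
    beta: float,
    delta: float,
) -> np.ndarray:
    """Gradient of f(a) = (beta/2)||(I-P)a||^2 + (delta/2)||U F Psi* a - y||^2."""
    if np.isinf(beta):
        raise ValueError("gradient undefined in the analysis limit (beta = inf)")
    resid = _forward_samples(frame.synthesis(a), y.mask.grid) - y.samples
    g = delta * frame.analysis(mask_adjoint(resid, y.mask))
    if beta > 0:
        g = g + beta * (a - frame.range_projection(a))
    return g


def apg(
    y: KSpaceData,
    frame: FrameOperator,
    config: SolverConfig | None = None,
    x_true: np.ndarray | None = None,
) -> SolverResult:
    """Accelerated proximal gradient (FISTA) on the penalized balanced model.

    Smooth part f(a) = (beta/2)||(I-P)a||^2 + (delta_fid/2)||UFPsi* a - y||^2
    with Lipschitz constant L = beta + delta_fid (Parseval frame, unitary
    DFT); proximal step is soft-thresholding at lambda/L; standard momentum
    t_{k+1} = (1 + sqrt(1 + 4 t_k^2))/2.  With ``monotone_restart`` (default)
    the momentum is reset whenever the objective would increase, which keeps
    the objective non-increasing.
    """
    cfg = config or SolverConfig(lambda_=0.005)
    if cfg.gamma == 0.0:
        raise ValueError(
            "apg requires gamma > 0: the analysis limit beta = inf has no "
            "smooth gradient; use csalsa_b for gamma = 0"
        )
    beta, delta, lam = cfg.beta, cfg.delta_fid, cfg.lambda_
    L = beta + delta
    mask = y.mask

    def fval(a):
        resid = _forward_samples(frame.synthesis(a), mask.grid) - y.samples
        val = 0.5 * delta * float(np.linalg.norm(resid) ** 2)
        if beta > 0:
            val += 0.5 * beta * _offrange_sq(a, frame)
        return val, float(np.linalg.norm(resid) ** 2)

    def obj(a):
        f, con = fval(a)
        return lam * float(np.abs(a).sum()) + f, con

    x0 = mask_adjoint(y.samples, mask)
    alpha = frame.analysis(x0)
    v = alpha.copy()
    t = 1.0
    cur_obj, _ = obj(alpha)
    x_prev = x0
    obj_tr, con_tr, rlne_tr = [], [], [] if x_true is not None else None
    n_run = 0
    for it in range(1, cfg.max_iter + 1):
        cand = soft_threshold(v - smooth_gradient(v, y, frame, beta, delta) / L, lam / L)
        cand_obj, cand_con = obj(cand)
        if cfg.monotone_restart and cand_obj > cur_obj:
            # restart: plain proximal-gradient step from the current iterate,
            # which is guaranteed to descend for step 1/L
            cand = soft_threshold(
                alpha - smooth_gradient(alpha, y, frame, beta, delta) / L, lam / L
            )
            cand_obj, cand_con = obj(cand)
            t = 1.0
        _check_finite(cand, it, "apg")
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        v = cand + ((t - 1.0) / t_new) * (cand - alpha)
        alpha, t, cur_obj = cand, t_new, cand_obj

        x_hat = frame.synthesis(alpha)
        obj_tr.append(cand_obj)
        con_tr.append(cand_con)
        if rlne_tr is not None:
            rlne_tr.append(rlne(x_hat, x_true))
        n_run = it

        rel = np.linalg.norm(x_hat - x_prev) / max(np.linalg.norm(x_prev), 1e-30)
        x_prev = x_hat
        if it > 1 and rel < cfg.tol:
            break

    return SolverResult(
        image=x_prev,
        coefficients=alpha,
        trace_objective=np.asarray(obj_tr),
        trace_constraint=np.asarray(con_tr),
        trace_rlne=None if rlne_tr is None else np.asarray(rlne_tr),
        iterations_run=n_run,
        solver="apg",
        config=cfg,
    )


def iterations_to_threshold(trace: np.ndarray, threshold: float) -> int | None:
    """First (1-based) iteration at which the trace is <= threshold, else None."""
    idx = np.nonzero(np.asarray(trace) <= threshold)[0]
    return int(idx[0]) + 1 if idx.size else None


SOLVERS = {"csalsa_b": csalsa_b, "admm_b": admm_b, "apg": apg}
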