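"""Convergent iterative solvers for TV-regularized DBT reconstruction.

Three model formulations share one least-squares data term
``LS(x) = ||Mx - b||^2``:

* **SGP** (scaled gradient projection) minimizes ``LS + lambda * TV_beta``
  under ``x >= 0`` with a diagonal scaling matrix, alternating
  Barzilai-Borwein step lengths and an Armijo backtracking line search.
* **FP** (lagged-diffusivity fixed point) minimizes the unconstrained
  ``LS + lambda * TV_beta`` by solving, at each outer step, the linearized
  system ``(2 M^T M + lambda L(x)) d = -grad f(x)`` with a fixed small
  number of conjugate-gradient iterations; nonnegativity is enforced once on
  the final iterate.
* **CP** (Chambolle-Pock) solves the constrained form
  ``min TV(x) s.t. ||Mx - b|| <= epsilon, x >= 0`` through a primal-dual
  splitting with the four-block operator ``K = (M; Dx; Dy; Dz)`` and step
  ``tau = sigma = 1 / ||K||``.

A fully automatic, decreasing regularization-weight schedule is available
for the lambda-weighted objectives: the first iteration runs unregularized,
``lambda_1`` balances the data fit and TV of the first iterate, and
``lambda_k = lambda_1 / k`` afterwards.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .projector import ProjectionStack, Volume, get_projector
from .regularization import (
    _forward_diff,
    _forward_diff_adjoint,
    apply_diffusion_operator,
    tv,
    tv_beta,
    tv_beta_gradient,
)

__all__ = [
    "SolverConfig",
    "SGPOptions",
    "FPOptions",
    "CPOptions",
    "SolverTrace",
    "CPState",
    "MatrixOperator",
    "LineSearchError",
    "DegenerateScheduleError",
    "least_squares",
    "ls_gradient",
    "objective",
    "sgp_scaling",
    "tv_gradient_split",
    "bb_steplength",
    "BBState",
    "armijo_linesearch",
    "conjugate_gradient",
    "power_method_norm",
    "cp_dual_ball_prox",
    "cp_dual_gradient_prox",
    "lambda_schedule",
    "auto_lambda1",
    "rho_schedule",
    "stopping_criterion",
    "sgp_solve",
    "fp_solve",
    "cp_solve",
    "fp_outer_iterations",
]


class LineSearchError(RuntimeError):
    """Armijo backtracking exhausted its budget without sufficient decrease."""


class DegenerateScheduleError(ValueError):
    """The automatic lambda rule is undefined (flat first iterate, TV = 0)."""


# --------------------------------------------------------------------------
# configuration / bookkeeping containers
# --------------------------------------------------------------------------


@dataclass
class SGPOptions:
    sigma: float = 1e-4        # Armijo sufficient-decrease parameter, in (0, 1)
    gamma_: float = 0.5        # backtracking factor, in (0, 1)
    alpha_min: float = 1e-10
    alpha_max: float = 1e10
    bb_memory: int = 3         # BB2 values remembered by the alternation rule
    bb_threshold: float = 0.5  # switch to BB2 when bb2/bb1 falls below this
    max_backtracks: int = 50

    def __post_init__(self):
        if not 0 < self.sigma < 1 or not 0 < self.gamma_ < 1:
            raise ValueError("sigma and gamma_ must lie in (0, 1)")
        if not 0 < self.alpha_min <= self.alpha_max:
            raise ValueError("need 0 < alpha_min <= alpha_max")


@dataclass
class FPOptions:
    cg_iters: int = 4  # inner conjugate-gradient iterations per outer step

    def __post_init__(self):
        if self.cg_iters < 1:
            raise ValueError("cg_iters must be >= 1")


@dataclass
class CPOptions:
    epsilon: float | None = None  # noise-ball radius; None -> nu * ||b||
    nu: float = 0.01
    theta: float = 1.0            # extrapolation weight, in [0, 1]
    power_iters: int = 2          # power-method iterations estimating ||K||
    seed: int = 0                 # seed of the power-method start vector

    def __post_init__(self):
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must lie in [0, 1]")


#: constant regularization weights used when the automatic schedule is off,
#: chosen per solver (the fixed-point model is solved with a smaller weight).
DEFAULT_LAMBDA = {"sgp": 0.005, "cp": 0.005, "fp": 0.001}


@dataclass
class SolverConfig:
    """All tunable solver parameters.

    ``lambda_`` may be a nonnegative float (constant weight) or ``"auto"``
    for the decreasing schedule.  ``max_iter`` counts SGP/CP iterations or
    FP *outer* iterations; ``tol`` is the relative objective-change stopping
    tolerance (0 disables early stopping).
    """

    lambda_: float | str = "auto"
    beta: float = 0.001
    max_iter: int = 100
    tol: float = 1e-6
    sgp: SGPOptions = field(default_factory=SGPOptions)
    fp: FPOptions = field(default_factory=FPOptions)
    cp: CPOptions = field(default_factory=CPOptions)

    def __post_init__(self):
        if isinstance(self.lambda_, str):
            if self.lambda_ != "auto":
                raise ValueError("lambda_ must be a float or 'auto'")
        elif self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if isinstance(self.sgp, dict):
            self.sgp = SGPOptions(**self.sgp)
        if isinstance(self.fp, dict):
            self.fp = FPOptions(**self.fp)
        if isinstance(self.cp, dict):
            self.cp = CPOptions(**self.cp)

    @property
    def auto_lambda(self) -> bool:
        return self.lambda_ == "auto"


@dataclass
class SolverTrace:
    """Per-iteration history of a solver run."""

    objective_values: list = field(default_factory=list)
    lambda_values: list = field(default_factory=list)
    residual_norms: list = field(default_factory=list)
    tv_values: list = field(default_factory=list)
    eta_values: list = field(default_factory=list)
    step_accept_counts: list = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False
    seed: int | None = None
    accounted_iterations: int | None = None
    state: object = None  # solver-specific final internal state

    def record(self, objective, lam, residual, tv_value, eta=np.nan, backtracks=0):
        self.objective_values.append(float(objective))
        self.lambda_values.append(float(lam))
        self.residual_norms.append(float(residual))
        self.tv_values.append(float(tv_value))
        self.eta_values.append(float(eta))
        self.step_accept_counts.append(int(backtracks))
        self.iterations_run = len(self.objective_values)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.iterations_run + 1),
                "objective": self.objective_values,
                "residual_norm": self.residual_norms,
                "tv": self.tv_values,
                "lambda": self.lambda_values,
                "eta_or_tau": self.eta_values,
            }
        )


@dataclass
class CPState:
    """Primal/dual variables of the Chambolle-Pock iteration."""

    x: np.ndarray
    x_bar: np.ndarray
    y: np.ndarray
    w: np.ndarray  # shape (3,) + vol_shape
    gamma_norm: float


# --------------------------------------------------------------------------
# operators: matrix-free geometry-backed or explicit matrices (for oracles)
# --------------------------------------------------------------------------


class MatrixOperator:
    """Explicit-matrix stand-in for the projector pair (used in tests)."""

    def __init__(self, m: np.ndarray, vol_shape, proj_shape=None):
        self.m = np.asarray(m, dtype=np.float64)
        self.vol_shape = tuple(vol_shape)
        self.proj_shape = tuple(proj_shape) if proj_shape is not None else (self.m.shape[0],)
        if self.m.shape != (int(np.prod(self.proj_shape)), int(np.prod(self.vol_shape))):
            raise ValueError("matrix shape inconsistent with vol/proj shapes")

    def forward(self, x: np.ndarray) -> np.ndarray:
        return (self.m @ x.ravel()).reshape(self.proj_shape)

    def adjoint(self, b: np.ndarray) -> np.ndarray:
        return (self.m.T @ b.ravel()).reshape(self.vol_shape)


class _GeometryOperator:
    def __init__(self, g: Geometry):
        self.geometry = g
        self._proj = get_projector(g)
        self.vol_shape = g.grid_shape
        self.proj_shape = (g.n_angles, g.detector_rows, g.detector_cols)

    def forward(self, x):
        return self._proj.forward(x)

    def adjoint(self, b):
        return self._proj.adjoint(b)


def _as_operator(g):
    if isinstance(g, Geometry):
        return _GeometryOperator(g)
    if hasattr(g, "forward") and hasattr(g, "adjoint"):
        return g
    raise TypeError("expected a Geometry or an operator with forward/adjoint")


def _prepare(b, g):
    """Normalize (projections, geometry-or-operator) to plain arrays."""
    op = _as_operator(g)
    b_arr = b.values if isinstance(b, ProjectionStack) else np.asarray(b, dtype=np.float64)
    if b_arr.shape != tuple(op.proj_shape):
        raise ValueError(f"projection shape {b_arr.shape} does not match {op.proj_shape}")
    if isinstance(g, Geometry):
        wrap = lambda v: Volume(v, g)  # noqa: E731
    else:
        wrap = lambda v: v  # noqa: E731
    return op, b_arr, wrap


def _x0_array(x0, op):
    if x0 is None:
        return np.zeros(op.vol_shape)
    arr = x0.values if isinstance(x0, Volume) else np.asarray(x0, dtype=np.float64)
    if arr.shape != tuple(op.vol_shape):
        raise ValueError("x0 shape does not match the reconstruction grid")
    return arr.copy()


# --------------------------------------------------------------------------
# objective pieces
# --------------------------------------------------------------------------


def least_squares(x, b, g=None) -> float:
    """Data-fit term ``||Mx - b||^2`` (squared Euclidean norm over all data)."""
    op, b_arr, _ = _prepare(b, g if g is not None else b.geometry)
    xv = x.values if isinstance(x, Volume) else np.asarray(x, dtype=np.float64)
    r = op.forward(xv) - b_arr
    return float(np.vdot(r, r).real)


def ls_gradient(x, b, g=None):
    """Gradient ``2 (M^T M x - M^T b)``, matrix-free (one forward, one adjoint)."""
    op, b_arr, wrap = _prepare(b, g if g is not None else b.geometry)
    xv = x.values if isinstance(x, Volume) else np.asarray(x, dtype=np.float64)
    return wrap(2.0 * op.adjoint(op.forward(xv) - b_arr))


def objective(x, b, g=None, lambda_: float = 0.0, beta: float = 0.001) -> float:
    """Penalized objective ``LS(x) + lambda * TV_beta(x)``."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    val = least_squares(x, b, g)
    if lambda_ > 0:
        xv = x.values if isinstance(x, Volume) else x
        val += lambda_ * tv_beta(xv, beta)
    return val


def tv_gradient_split(x: np.ndarray, beta: float):
    """Split ``grad TV_beta(x) = V_tv(x) - U_tv(x)`` with both parts >= 0 for x >= 0.

    Derived from the weighted-Laplacian form ``L(x) x``: ``V_tv`` collects
    the (positive) diagonal contributions, ``U_tv`` the neighbor terms.
    """
    grads = [_forward_diff(x, a) for a in range(3)]
    inv_phi = 1.0 / np.sqrt(sum(d**2 for d in grads) + beta**2)
    v_part = np.zeros_like(x)
    u_part = np.zeros_like(x)
    for a in range(3):
        inv_phi_up = np.roll(inv_phi, 1, axis=a)
        v_part += x * (inv_phi + inv_phi_up)
        u_part += np.roll(x, -1, axis=a) * inv_phi + np.roll(x, 1, axis=a) * inv_phi_up
    return v_part, u_part


def sgp_scaling(x: np.ndarray, v_part: np.ndarray, rho_k: float) -> np.ndarray:
    """Diagonal scaling entries ``s_j = clip(x_j / V_j, 1/rho_k, rho_k)``."""
    if rho_k < 1:
        raise ValueError("rho_k must be >= 1")
    if np.any(v_part <= 0):
        raise ValueError("positive gradient part V must be strictly positive")
    return np.clip(x / v_part, 1.0 / rho_k, rho_k)


# --------------------------------------------------------------------------
# step lengths and line search
# --------------------------------------------------------------------------


def bb_steplength(s_prev, y_prev, s_diag, alpha_min=1e-10, alpha_max=1e10):
    """Raw scaled Barzilai-Borwein step lengths ``(bb1, bb2)``.

    Inner products are weighted through the diagonal scaling ``S``:
    ``bb1 = <s, S^-2 s> / <s, S^-1 y>`` and ``bb2 = <s, S y> / <y, S^2 y>``.
    A rule whose curvature denominator is nonpositive is safeguarded to
    ``alpha_max``.
    """
    s = np.asarray(s_prev, dtype=np.float64).ravel()
    y = np.asarray(y_prev, dtype=np.float64).ravel()
    d = np.asarray(s_diag, dtype=np.float64).ravel()
    sy1 = float(np.dot(s / d, y))
    bb1 = float(np.dot(s / d, s / d) / sy1) if sy1 > 0 else alpha_max
    yy2 = float(np.dot(y * d, y * d))
    sy2 = float(np.dot(s, d * y))
    bb2 = float(sy2 / yy2) if (yy2 > 0 and sy2 > 0) else alpha_max
    clip = lambda a: float(np.clip(a, alpha_min, alpha_max))  # noqa: E731
    return clip(bb1), clip(bb2)


class BBState:
    """Adaptive alternation between the two scaled BB rules.

    Uses BB2 (with a short memory, taking the minimum of recent values) when
    ``bb2 / bb1`` drops below a threshold, BB1 otherwise.
    """

    def __init__(self, alpha0=1.0, alpha_min=1e-10, alpha_max=1e10, memory=3, threshold=0.5):
        self.alpha = float(np.clip(alpha0, alpha_min, alpha_max))
        self.alpha_min = alpha_min
        self.alpha_max = alpha_max
        self.threshold = threshold
        self._bb2_history = collections.deque(maxlen=memory)

    def update(self, s_prev, y_prev, s_diag) -> float:
        bb1, bb2 = bb_steplength(s_prev, y_prev, s_diag, self.alpha_min, self.alpha_max)
        self._bb2_history.append(bb2)
        if bb2 / bb1 < self.threshold:
            self.alpha = min(self._bb2_history)
        else:
            self.alpha = bb1
        return self.alpha


def armijo_linesearch(f, x, d, grad, f_x, sigma=1e-4, gamma_=0.5, max_backtracks=50):
    """Backtracking line search enforcing sufficient decrease.

    Returns ``(eta, x_new, f_new, n_backtracks)`` with the largest
    ``eta in {1, gamma, gamma^2, ...}`` satisfying
    ``f(x + eta d) <= f(x) + sigma * eta * <grad, d>``.
    """
    gtd = float(np.vdot(grad, d).real)
    if gtd > 0:
        raise ValueError("d is not a descent direction (<grad, d> > 0)")
    eta = 1.0
    for n in range(max_backtracks + 1):
        x_new = x + eta * d
        f_new = f(x_new)
        if f_new <= f_x + sigma * eta * gtd:
            return eta, x_new, f_new, n
        eta *= gamma_
    raise LineSearchError(f"no sufficient decrease after {max_backtracks} backtracks")


def conjugate_gradient(apply_H, rhs, n_iters: int):
    """Run exactly ``n_iters`` CG iterations for ``H d = rhs`` from ``d = 0``.

    No residual-based stop: truncated CG is used deliberately as an inexact
    inner solver.  ``apply_H`` must be symmetric positive (semi)definite.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    d = np.zeros_like(rhs)
    r = rhs.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    for _ in range(n_iters):
        if rs == 0.0:
            break
        hp = apply_H(p)
        php = float(np.vdot(p, hp).real)
        if not np.isfinite(php) or php <= 0:
            raise ValueError("operator is not positive definite along the search direction")
        a = rs / php
        d += a * p
        r -= a * hp
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
    if not np.all(np.isfinite(d)):
        raise ValueError("conjugate gradient produced non-finite values")
    return d


# --------------------------------------------------------------------------
# schedules and stopping
# --------------------------------------------------------------------------


def rho_schedule(k: int) -> float:
    """Scaling-bound sequence ``rho_k = 1 + 10^15 / k^2.1`` (k >= 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 + 1e15 / k**2.1


def auto_lambda1(x1, b, g=None, beta_unused=None) -> float:
    """Balance weight ``lambda_1 = LS(x^(1)) / TV(x^(1))`` of the auto schedule."""
    xv = x1.values if isinstance(x1, Volume) else np.asarray(x1, dtype=np.float64)
    tv1 = tv(xv)
    if tv1 == 0.0:
        raise DegenerateScheduleError("TV(x^(1)) = 0: automatic lambda rule undefined")
    return least_squares(x1, b, g) / tv1


def lambda_schedule(k: int, lambda1: float | None = None) -> float:
    """Decreasing weight sequence: ``lambda_0 = 0``, ``lambda_k = lambda_1 / k``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 0.0
    if lambda1 is None:
        raise ValueError("lambda1 is required for k >= 1")
    return lambda1 / k


def stopping_criterion(trace, tol: float = 1e-6) -> bool:
    """Relative objective-change test ``|f_k - f_{k-1}| / |f_k| < tol``.

    The absolute value makes the test usable for non-monotone iterations.
    A vanishing current objective is flagged as converged-degenerate.
    """
    values = trace.objective_values if isinstance(trace, SolverTrace) else list(trace)
    if len(values) < 2:
        raise ValueError("need at least two objective values")
    f_k, f_prev = values[-1], values[-2]
    if f_k == 0.0:
        return True
    return abs(f_k - f_prev) / abs(f_k) < tol


# --------------------------------------------------------------------------
# SGP
# --------------------------------------------------------------------------


def sgp_solve(b, g, config: SolverConfig | None = None, x0=None):
    """Scaled gradient projection for ``min LS + lambda TV_beta, x >= 0``.

    Every iterate is nonnegative and the objective is monotone
    non-increasing (Armijo guarantee).  Returns ``(volume, trace)``.
    """
    config = config or SolverConfig()
    op, b_arr, wrap = _prepare(b, g)
    x = np.maximum(_x0_array(x0, op), 0.0)
    beta = config.beta
    opts = config.sgp
    trace = SolverTrace()

    auto = config.auto_lambda
    lam = 0.0 if auto else float(config.lambda_)
    lam1 = None

    mtb = op.adjoint(b_arr)
    floor = 1e-12  # keeps the positive gradient part strictly positive

    def make_f(lam_now):
        cache = {}

        def f(xv):
            mx = op.forward(xv)
            cache["mx"] = mx
            r = mx - b_arr
            val = float(np.vdot(r, r).real)
            if lam_now > 0:
                val += lam_now * tv_beta(xv, beta)
            return val

        return f, cache

    def grad_and_v(xv, lam_now, mtmx):
        grad = 2.0 * (mtmx - mtb)
        v_part = 2.0 * mtmx + floor
        if lam_now > 0:
            grad = grad + lam_now * tv_beta_gradient(xv, beta)
            v_tv, _ = tv_gradient_split(xv, beta)
            v_part = v_part + lam_now * v_tv
        return grad, v_part

    f_fun, f_cache = make_f(lam)
    f_x = f_fun(x)
    mtmx = op.adjoint(f_cache["mx"])
    grad, v_part = grad_and_v(x, lam, mtmx)

    zero_start = not np.any(x > 0)
    gnorm = float(np.linalg.norm(grad))
    xnorm = float(np.linalg.norm(x))
    if xnorm > 0 and gnorm > 0:
        alpha0 = 1.3 * xnorm / gnorm
    elif zero_start and gnorm > 0:
        # exact line minimizer of the quadratic data term along the first
        # (projected-gradient) direction; scale-invariant in b, unlike a
        # unit step
        md = op.forward(-grad)
        mdmd = float(np.vdot(md, md).real)
        alpha0 = float(np.vdot(md, b_arr).real) / mdmd if mdmd > 0 else 1.0
        alpha0 = alpha0 if alpha0 > 0 else 1.0
    else:
        alpha0 = 1.0
    bb = BBState(alpha0, opts.alpha_min, opts.alpha_max, opts.bb_memory, opts.bb_threshold)

    for k in range(1, config.max_iter + 1):
        rho = rho_schedule(k)
        if zero_start and k == 1:
            # Eq.-(14)-style scaling is degenerate at an identically zero
            # start (all ratios x_j / V_j vanish); take a plain projected
            # gradient first step instead.
            s_diag = np.ones_like(x)
        else:
            s_diag = sgp_scaling(x, v_part, rho)
        d = np.maximum(x - bb.alpha * s_diag * grad, 0.0) - x
        gtd = float(np.vdot(grad, d).real)
        if gtd >= 0.0 or not np.any(d):
            # projected stationary point for the current weight
            mx = op.forward(x)
            res = float(np.linalg.norm(mx - b_arr))
            trace.record(f_x, lam, res, tv_beta(x, beta), eta=0.0)
            trace.converged = True
            break

        eta, x_new, f_new, n_bt = armijo_linesearch(
            f_fun, x, d, grad, f_x, opts.sigma, opts.gamma_, opts.max_backtracks
        )
        if not np.isfinite(f_new):
            raise FloatingPointError("non-finite objective in SGP")
        mx_new = f_cache["mx"]
        res = float(np.linalg.norm(mx_new - b_arr))
        trace.record(f_new, lam, res, tv_beta(x_new, beta), eta=eta, backtracks=n_bt)

        # next-iteration regularization weight
        if auto:
            if k == 1:
                lam1 = auto_lambda1(x_new, b_arr, op)
            lam_next = lambda_schedule(k, lam1)
        else:
            lam_next = lam

        mtmx_new = op.adjoint(mx_new)
        grad_new, v_part_new = grad_and_v(x_new, lam_next, mtmx_new)
        bb.update(x_new - x, grad_new - grad, s_diag)

        x, grad, v_part = x_new, grad_new, v_part_new
        if lam_next != lam:
            lam = lam_next
            f_fun, f_cache = make_f(lam)
            f_x = f_fun(x)  # objective under the new weight
        else:
            f_x = f_new

        if config.tol > 0 and trace.iterations_run >= 2 and stopping_criterion(trace, config.tol):
            trace.converged = True
            break

    return wrap(x), trace


# --------------------------------------------------------------------------
# FP
# --------------------------------------------------------------------------


def fp_outer_iterations(total_iterations: int, cg_iters: int) -> int:
    """Outer FP steps whose accounted cost matches a total iteration budget.

    One outer step counts as ``1 + cg_iters`` iterations, so a budget of 15
    with 4 inner CG iterations allows 3 outer steps.
    """
    return max(1, total_iterations // (1 + cg_iters))


def fp_solve(b, g, config: SolverConfig | None = None, x0=None):
    """Lagged-diffusivity fixed point for ``min LS + lambda TV_beta``.

    Each outer step solves ``(2 M^T M + lambda L(x)) d = -grad f(x)`` with
    exactly ``config.fp.cg_iters`` CG iterations, applied matrix-free.
    Intermediate iterates may go negative; the nonnegativity projection is
    applied once to the returned volume.
    """
    config = config or SolverConfig(lambda_=DEFAULT_LAMBDA["fp"])
    op, b_arr, wrap = _prepare(b, g)
    x = _x0_array(x0, op)
    beta = config.beta
    cg_iters = config.fp.cg_iters
    trace = SolverTrace()

    auto = config.auto_lambda
    lam1 = None
    mtb = op.adjoint(b_arr)

    for k in range(config.max_iter):
        lam = lambda_schedule(k, lam1) if auto else float(config.lambda_)

        mx = op.forward(x)
        grad = 2.0 * (op.adjoint(mx) - mtb)
        if lam > 0:
            grad = grad + lam * tv_beta_gradient(x, beta)

        if lam > 0:
            x_frozen = x.copy()

            def apply_h(v):
                return 2.0 * op.adjoint(op.forward(v)) + lam * apply_diffusion_operator(
                    x_frozen, v, beta
                )

        else:

            def apply_h(v):
                return 2.0 * op.adjoint(op.forward(v))

        d = conjugate_gradient(apply_h, -grad, cg_iters)
        x = x + d
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite iterate in FP")

        if auto and k == 0:
            lam1 = auto_lambda1(x, b_arr, op)

        mx = op.forward(x)
        res = float(np.linalg.norm(mx - b_arr))
        f_val = res**2 + (lam * tv_beta(x, beta) if lam > 0 else 0.0)
        trace.record(f_val, lam, res, tv_beta(x, beta), eta=1.0)

        if config.tol > 0 and trace.iterations_run >= 2 and stopping_criterion(trace, config.tol):
            trace.converged = True
            break

    trace.accounted_iterations = trace.iterations_run * (1 + cg_iters)
    return wrap(np.maximum(x, 0.0)), trace


# --------------------------------------------------------------------------
# CP
# --------------------------------------------------------------------------


def power_method_norm(g, n_iters: int = 2, seed: int = 0, shape=None) -> float:
    """Estimate ``Gamma ~ ||K||`` for ``K = (M; Dx; Dy; Dz)`` by power iteration.

    Runs ``n_iters`` power-method steps on ``K^T K`` from a seeded random
    start and returns the square root of the last Rayleigh quotient (a lower
    bound on ``||K||`` up to rounding).  ``g`` may be a Geometry, an
    operator, or a callable applying ``K^T K`` directly (then ``shape`` is
    required).
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    if callable(g) and not hasattr(g, "forward"):
        if shape is None:
            raise ValueError("shape is required when g is a callable")
        apply_ktk = g
    else:
        op = _as_operator(g)
        shape = op.vol_shape

        def apply_ktk(v):
            out = op.adjoint(op.forward(v))
            for a in range(3):
                out = out + _forward_diff_adjoint(_forward_diff(v, a), a)
            return out

    rng = np.random.default_rng(seed)
    v = rng.standard_normal(shape)
    nrm = float(np.linalg.norm(v))
    if nrm == 0.0:
        raise ValueError("zero start vector")
    v /= nrm
    rayleigh = 0.0
    for _ in range(n_iters):
        u = apply_ktk(v)
        rayleigh = float(np.vdot(v, u).real)
        nu = float(np.linalg.norm(u))
        if nu == 0.0:
            break
        v = u / nu
    return float(np.sqrt(max(rayleigh, 0.0)))


def cp_dual_ball_prox(y, mxbar_minus_b, sigma: float, epsilon: float):
    """Dual update of the data-fit block: shrink ``y + sigma (M x_bar - b)``.

    ``y_new = max(||y_bar|| - sigma * epsilon, 0) * y_bar / ||y_bar||`` with
    the global 2-norm over all detector data; ``y_bar = 0`` maps to 0.
    """
    ybar = y + sigma * mxbar_minus_b
    n = float(np.linalg.norm(ybar))
    if n == 0.0:
        return ybar
    return (max(n - sigma * epsilon, 0.0) / n) * ybar


def cp_dual_gradient_prox(w, x_bar, sigma: float, lambda_: float):
    """Dual update of the TV block: per-voxel projection onto the lambda-ball.

    ``w`` has shape ``(3,) + vol_shape``.  ``w_bar = w + sigma * grad(x_bar)``;
    each voxel's 3-vector is scaled by ``lambda / max(lambda, |w_bar|_j)``.
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be > 0 for the TV dual projection")
    xb = x_bar.values if isinstance(x_bar, Volume) else np.asarray(x_bar, dtype=np.float64)
    wbar = w + sigma * np.stack([_forward_diff(xb, a) for a in range(3)])
    mag = np.sqrt(np.sum(wbar**2, axis=0))
    return wbar * (lambda_ / np.maximum(lambda_, mag))


def cp_solve(b, g, config: SolverConfig | None = None, x0=None):
    """Chambolle-Pock primal-dual solver for the constrained TV model.

    Solves ``min lambda TV(x) s.t. ||Mx - b|| <= epsilon, x >= 0`` with
    ``tau = sigma = 1 / Gamma`` and extrapolation weight ``theta``.  The
    automatic lambda schedule is not applied here (the weight enters only
    the dual TV projection; the data fit is governed by ``epsilon``), so an
    ``"auto"`` config falls back to the constant default weight.  With
    ``lambda_ = 0`` the TV dual block is dropped and the iteration reduces
    to a nonnegative feasibility solve of the data-fit ball.
    """
    config = config or SolverConfig(lambda_=DEFAULT_LAMBDA["cp"])
    op, b_arr, wrap = _prepare(b, g)
    beta = config.beta
    opts = config.cp
    lam = DEFAULT_LAMBDA["cp"] if config.auto_lambda else float(config.lambda_)
    epsilon = opts.epsilon if opts.epsilon is not None else opts.nu * float(np.linalg.norm(b_arr))

    gamma = power_method_norm(op, n_iters=opts.power_iters, seed=opts.seed)
    if gamma <= 0:
        raise ValueError("power method returned a nonpositive norm estimate")
    tau = sigma = 1.0 / gamma

    x = np.maximum(_x0_array(x0, op), 0.0)
    x_bar = x.copy()
    y = np.zeros(op.proj_shape)
    w = np.zeros((3,) + tuple(op.vol_shape))
    trace = SolverTrace(seed=opts.seed)

    for _ in range(config.max_iter):
        y = cp_dual_ball_prox(y, op.forward(x_bar) - b_arr, sigma, epsilon)
        if lam > 0:
            w = cp_dual_gradient_prox(w, x_bar, sigma, lam)
        div = op.adjoint(y)
        for a in range(3):
            div = div + _forward_diff_adjoint(w[a], a)
        x_new = np.maximum(x - tau * div, 0.0)
        x_bar = x_new + opts.theta * (x_new - x)
        x = x_new
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite iterate in CP")

        res = float(np.linalg.norm(op.forward(x) - b_arr))
        f_val = res**2 + (lam * tv_beta(x, beta) if lam > 0 else 0.0)
        trace.record(f_val, lam, res, tv_beta(x, beta), eta=tau)

        if config.tol > 0 and trace.iterations_run >= 2 and stopping_criterion(trace, config.tol):
            trace.converged = True
            break

    trace.state = CPState(x=x, x_bar=x_bar, y=y, w=w, gamma_norm=gamma)
    return wrap(x), trace
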