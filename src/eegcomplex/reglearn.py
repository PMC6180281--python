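"""Native L1 / elastic-net penalized logistic regression.

The fitted problem (maximization form) is

    sum_i [ y_i (b0 + b.x_i) - log(1 + exp(b0 + b.x_i)) ]
        - lambda * sum_j [ (1 - alpha) b_j^2 + alpha |b_j| ]

with an unpenalized intercept.  alpha = 1 is the lasso; alpha = 0 is ridge.
Penalized fits use monotone accelerated proximal gradient descent (FISTA with
a fallback step whenever acceleration would increase the objective), which
yields exact zeros through soft-thresholding; the unpenalized case uses damped
Newton / IRLS.  Convergence is certified by the subgradient (KKT) residual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

try:  # coordinate descent is JIT-compiled when numba is available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

logger = logging.getLogger(__name__)

__all__ = [
    "PenalizedLRModel",
    "penalized_objective",
    "fit_penalized_lr",
    "lambda_path",
    "select_lambda_nested",
    "predict_proba",
]


@dataclass
class PenalizedLRModel:
    beta0: float
    beta: np.ndarray
    lam: float
    alpha: float
    objective: float
    converged: bool
    n_iter: int
    kkt_residual: float = np.nan
    objective_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def active_set(self) -> np.ndarray:
        """Indices of features with non-zero coefficients."""
        return np.flatnonzero(self.beta != 0.0)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p with one row per element of y")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    return X, y


def penalized_objective(
    beta0: float,
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """Penalized log-likelihood (the quantity the solver maximizes)."""
    X, y = _check_xy(X, y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    beta = np.asarray(beta, dtype=float).ravel()
    eta = beta0 + X @ beta
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    penalty = lam * float(np.sum((1.0 - alpha) * beta**2 + alpha * np.abs(beta)))
    return loglik - penalty


def _kkt_residual(
    beta: np.ndarray, grad: np.ndarray, lam: float, alpha: float
) -> float:
    """Largest violation of the subgradient optimality conditions.

    ``grad`` is the gradient of the log-likelihood (maximization form) with
    respect to beta, i.e. X^T (y - p).
    """
    res = np.where(
        beta != 0.0,
        np.abs(grad - lam * alpha * np.sign(beta) - 2.0 * lam * (1.0 - alpha) * beta),
        np.maximum(np.abs(grad) - lam * alpha, 0.0),
    )
    return float(res.max()) if res.size else 0.0


def _soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _fit_unpenalized(
    X: np.ndarray, y: np.ndarray, tol: float, max_iter: int
) -> PenalizedLRModel:
    """Damped Newton (IRLS with step halving).  On separable data the MLE
    does not exist; the iteration cap is reached and ``converged`` is False.
    """
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    coef = np.zeros(p + 1)
    obj = penalized_objective(coef[0], coef[1:], X, y, 0.0, 1.0)
    path = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xa @ coef
        prob = expit(eta)
        grad = Xa.T @ (y - prob)
        if np.abs(grad).max() <= tol:
            converged = True
            break
        w = np.maximum(prob * (1.0 - prob), 1e-10)
        # Newton direction from the weighted least-squares normal equations.
        A = (Xa * w[:, None]).T @ Xa
        A[np.diag_indices_from(A)] += 1e-12
        try:
            step = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, grad, rcond=None)[0]
        t = 1.0
        for _ in range(50):
            cand = coef + t * step
            cand_obj = penalized_objective(cand[0], cand[1:], X, y, 0.0, 1.0)
            if cand_obj >= obj:
                break
            t *= 0.5
        else:
            converged = True  # no ascent direction left: numerically stationary
            break
        coef, obj = cand, cand_obj
        path.append(obj)
    eta = Xa @ coef
    prob_final = expit(eta)
    # Strict sign separation at a finite iterate proves the data are
    # linearly separable, hence the MLE does not exist.
    separated = bool(np.all(np.where(y == 1.0, eta > 0, eta < 0))) and p > 0
    if separated:
        # Perfect separation with saturated logits: the MLE does not exist
        # and the coefficients are diverging, whatever the gradient says.
        converged = False
    if not converged:
        warnings.warn(
            "unpenalized logistic regression did not converge; the data "
            "appear linearly separable (coefficients diverge)"
            if separated
            else "unpenalized logistic regression hit the iteration cap",
            RuntimeWarning,
            stacklevel=3,
        )
    prob = expit(Xa @ coef)
    grad_beta = X.T @ (y - prob)
    return PenalizedLRModel(
        beta0=float(coef[0]),
        beta=coef[1:],
        lam=0.0,
        alpha=1.0,
        objective=obj,
        converged=converged,
        n_iter=it,
        kkt_residual=float(np.abs(grad_beta).max()) if p else 0.0,
        objective_path=np.asarray(path),
    )


@_njit(cache=True)
def _cd_sweeps(XF, w, r, beta, beta0, l1, l2, delta_tol, max_sweeps):
    """Cyclic coordinate descent on the penalized weighted least squares
    subproblem.  ``r`` is the working residual z - beta0 - X beta and is
    updated in place along with ``beta``; returns the new intercept.
    """
    n, p = XF.shape
    for _ in range(max_sweeps):
        max_delta = 0.0
        sw = 0.0
        swr = 0.0
        for i in range(n):
            sw += w[i]
            swr += w[i] * r[i]
        d0 = swr / sw
        beta0 += d0
        for i in range(n):
            r[i] -= d0
        if abs(d0) > max_delta:
            max_delta = abs(d0)
        for j in range(p):
            wxx = 0.0
            rho = 0.0
            for i in range(n):
                wxij = w[i] * XF[i, j]
                wxx += wxij * XF[i, j]
                rho += wxij * r[i]
            rho += beta[j] * wxx
            if rho > l1:
                bj = (rho - l1) / (wxx + 2.0 * l2)
            elif rho < -l1:
                bj = (rho + l1) / (wxx + 2.0 * l2)
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                beta[j] = bj
                for i in range(n):
                    r[i] -= d * XF[i, j]
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < delta_tol:
            break
    return beta0


def _fit_cd(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    tol: float,
    max_iter: int,
    beta0: float,
    beta: np.ndarray,
) -> PenalizedLRModel:
    """IRLS outer loop around coordinate descent, with a step-halving
    safeguard that keeps the (maximization) objective non-decreasing."""
    XF = np.asfortranarray(X)
    l1, l2 = lam * alpha, lam * (1.0 - alpha)
    obj = penalized_objective(beta0, beta, X, y, lam, alpha)
    path = [obj]
    delta_tol = max(tol * 1e-2, 1e-12)
    outer_cap = min(100, max_iter)
    converged = False
    kkt = np.nan
    it = 0
    for it in range(1, outer_cap + 1):
        eta = beta0 + X @ beta
        prob = expit(eta)
        w = np.maximum(prob * (1.0 - prob), 1e-6)
        z_resid = (y - prob) / w
        prev0, prevb = beta0, beta.copy()
        new_beta = beta.copy()
        new_beta0 = _cd_sweeps(XF, w, z_resid.copy(), new_beta, beta0, l1, l2,
                               delta_tol, 1000)
        t = 1.0
        cand0, cand, cand_obj = new_beta0, new_beta, -np.inf
        for _ in range(30):
            cand0 = prev0 + t * (new_beta0 - prev0)
            cand = prevb + t * (new_beta - prevb)
            cand_obj = penalized_objective(cand0, cand, X, y, lam, alpha)
            if cand_obj >= obj - 1e-12:
                break
            t *= 0.5
        beta0, beta = cand0, cand
        # Snap float dust from boundary soft-threshold cases to exact zero.
        beta[np.abs(beta) < 1e-12] = 0.0
        obj = max(obj, cand_obj)
        path.append(obj)
        prob = expit(beta0 + X @ beta)
        grad = X.T @ (y - prob)
        kkt = _kkt_residual(beta, grad, lam, alpha)
        if kkt <= tol and abs(float(np.sum(y - prob))) <= tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "penalized LR (cd) did not reach tol=%.1e in %d outer iterations "
            "(KKT %.2e)", tol, outer_cap, kkt,
        )
    return PenalizedLRModel(
        beta0=float(beta0),
        beta=beta,
        lam=lam,
        alpha=alpha,
        objective=obj,
        converged=converged,
        n_iter=it,
        kkt_residual=float(kkt),
        objective_path=np.asarray(path),
    )


def fit_penalized_lr(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    beta0_init: float | None = None,
    beta_init: np.ndarray | None = None,
    solver: str = "auto",
) -> PenalizedLRModel:
    """Solve the penalized problem; see module docstring for the objective.

    ``beta_init``/``beta0_init`` enable warm starts along a lambda path.
    ``solver`` is "auto" (coordinate descent when numba is available, else
    proximal gradient), "cd", or "fista".
    """
    X, y = _check_xy(X, y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if y.size < 2 or y.min() == y.max():
        raise ValueError("need at least 2 samples with both classes present")
    if lam == 0.0:
        return _fit_unpenalized(X, y, tol, max_iter)
    if solver == "auto":
        solver = "cd" if _HAVE_NUMBA else "fista"
    ybar = y.mean()
    start0 = float(beta0_init) if beta0_init is not None else float(np.log(ybar / (1 - ybar)))
    startb = (
        np.asarray(beta_init, dtype=float).copy()
        if beta_init is not None
        else np.zeros(X.shape[1])
    )
    if solver == "cd":
        return _fit_cd(X, y, lam, alpha, tol, max_iter, start0, startb)
    if solver != "fista":
        raise ValueError(f"unknown solver {solver!r}")
    return _fit_fista(X, y, lam, alpha, tol, max_iter, start0, startb)


def _fit_fista(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    tol: float,
    max_iter: int,
    beta0: float,
    beta: np.ndarray,
) -> PenalizedLRModel:
    n, p = X.shape
    # Lipschitz bound for the smooth part (logistic loss + quadratic penalty),
    # intercept column included.
    sv = np.linalg.norm(np.column_stack([np.ones(n), X]), 2)
    lip = sv * sv / 4.0 + 2.0 * lam * (1.0 - alpha)
    step = 1.0 / lip
    l1 = lam * alpha

    def smooth_grad(b0: float, b: np.ndarray) -> tuple[float, np.ndarray]:
        prob = expit(b0 + X @ b)
        return float(np.sum(prob - y)), X.T @ (prob - y) + 2.0 * lam * (1.0 - alpha) * b

    def prox_step(b0: float, b: np.ndarray) -> tuple[float, np.ndarray]:
        g0, g = smooth_grad(b0, b)
        return b0 - step * g0, _soft_threshold(b - step * g, step * l1)

    obj = penalized_objective(beta0, beta, X, y, lam, alpha)
    path = [obj]
    # FISTA extrapolation state.
    zb0, zb, t_acc = beta0, beta.copy(), 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cand0, cand = prox_step(zb0, zb)
        cand_obj = penalized_objective(cand0, cand, X, y, lam, alpha)
        if cand_obj < obj:
            # Acceleration overshot: plain step from the last iterate and
            # momentum restart keep the objective monotone.
            cand0, cand = prox_step(beta0, beta)
            cand_obj = penalized_objective(cand0, cand, X, y, lam, alpha)
            t_acc = 1.0
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc)) / 2.0
        mom = (t_acc - 1.0) / t_next
        zb0 = cand0 + mom * (cand0 - beta0)
        zb = cand + mom * (cand - beta)
        t_acc = t_next
        beta0, beta = cand0, cand
        obj = max(obj, cand_obj)
        path.append(obj)
        if it % 10 == 0 or it < 10:
            prob = expit(beta0 + X @ beta)
            grad = X.T @ (y - prob)
            kkt = _kkt_residual(beta, grad, lam, alpha)
            if kkt <= tol and abs(np.sum(y - prob)) <= tol:
                converged = True
                break
    prob = expit(beta0 + X @ beta)
    grad = X.T @ (y - prob)
    kkt = _kkt_residual(beta, grad, lam, alpha)
    if not converged:
        logger.warning(
            "penalized LR did not reach tol=%.1e in %d iterations (KKT %.2e)",
            tol,
            max_iter,
            kkt,
        )
    return PenalizedLRModel(
        beta0=beta0,
        beta=beta,
        lam=lam,
        alpha=alpha,
        objective=obj,
        converged=converged,
        n_iter=it,
        kkt_residual=kkt,
        objective_path=np.asarray(path),
    )


def lambda_path(
    X: np.ndarray, y: np.ndarray, alpha: float, K: int = 50
) -> np.ndarray:
    """Decreasing log-spaced lambda grid from lambda_max (all-zero solution)
    down to 1e-3 * lambda_max."""
    X, y = _check_xy(X, y)
    if alpha <= 0:
        raise ValueError("alpha must be > 0 (ridge has no finite lambda_max)")
    if K < 2:
        raise ValueError("grid size K must be >= 2")
    lam_max = float(np.abs(X.T @ (y - y.mean())).max()) / alpha
    if lam_max <= 0:
        raise ValueError("degenerate design: lambda_max is 0")
    return np.geomspace(lam_max, 1e-3 * lam_max, K)


def _grouped_folds(
    groups: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal subjects round-robin into folds, per class, after shuffling."""
    subj_class: dict[str, float] = {}
    for g, yi in zip(groups, y):
        subj_class.setdefault(g, yi)
    fold_of: dict[str, int] = {}
    for cls in (0.0, 1.0):
        subs = sorted(s for s, c in subj_class.items() if c == cls)
        if len(subs) < n_folds:
            raise ValueError(
                f"need >= {n_folds} distinct subjects per class, "
                f"got {len(subs)} for class {int(cls)}"
            )
        subs = list(np.array(subs, dtype=object)[rng.permutation(len(subs))])
        for i, s in enumerate(subs):
            fold_of[s] = i % n_folds
    assign = np.array([fold_of[g] for g in groups])
    return [np.flatnonzero(assign == k) for k in range(n_folds)]


def select_lambda_nested(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    alpha: float,
    inner_folds: int = 5,
    grid_size: int = 50,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 5_000,
) -> float:
    """Pick lambda minimizing mean held-out binomial deviance over a
    subject-grouped inner cross-validation; ties go to the sparser model."""
    X, y = _check_xy(X, y)
    groups = np.asarray(groups)
    grid = lambda_path(X, y, alpha, grid_size)
    rng = np.random.default_rng(seed)
    folds = _grouped_folds(groups, y, inner_folds, rng)
    deviance = np.zeros((inner_folds, grid.size))
    for k, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(y.size), test_idx)
        Xtr, ytr = X[train], y[train]
        Xte, yte = X[test_idx], y[test_idx]
        b0, b = None, None
        for j, lam in enumerate(grid):
            model = fit_penalized_lr(
                Xtr, ytr, lam, alpha, tol=tol, max_iter=max_iter,
                beta0_init=b0, beta_init=b,
            )
            b0, b = model.beta0, model.beta
            eta = model.beta0 + Xte @ model.beta
            # Binomial deviance via logaddexp for overflow safety.
            deviance[k, j] = 2.0 * float(
                np.sum(np.logaddexp(0.0, eta) - yte * eta)
            )
    mean_dev = deviance.mean(axis=0)
    best = int(np.argmin(mean_dev))  # argmin takes the first (largest) lambda on ties
    return float(grid[best])


def predict_proba(model: PenalizedLRModel, X: np.ndarray) -> np.ndarray:
    """Per-row probability of the positive class."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.beta.size:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.beta.size}"
        )
    return expit(model.beta0 + X @ model.beta)
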