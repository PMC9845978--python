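"""Phylogenetic logistic regression for binary tip traits.

The model: tip trait y_i ~ Bernoulli(mu_i) with mu = logistic(X beta), and
residual correlation between tips decaying with patristic distance,

    R(alpha)_ij = exp(-alpha * d_ij),

the stationary correlation of a two-state switching process on the tree.
alpha >= 0 is the phylogenetic signal parameter in units of inverse
(normalized) tree height: large alpha means tips are effectively
independent, small alpha means strong shared history.

Estimation couples two pieces:

* at fixed alpha, beta solves Firth-penalized phylogenetic estimating
  equations — an iteratively reweighted scheme with working covariance
  V = W^{1/2} R(alpha) W^{1/2}, W = diag(mu(1-mu)), and the Jeffreys-prior
  ("Firth") correction that keeps estimates finite under separation and
  reduces small-sample bias;
* alpha is a working-correlation parameter estimated by residual moment
  matching: standardized residuals r_i = (y_i - mu_i)/sqrt(mu_i(1-mu_i))
  have unit variance and E[r_i r_j] equal to the between-tip trait
  correlation, so alpha minimizes the squared mismatch
  sum_{i != j} (r_i r_j - R(alpha)_ij)^2 over a bounded log range,
  alternating with the beta update.

Matching alpha to the *binary-scale* residual correlation (rather than
maximizing a Gaussian working likelihood, which is badly miscalibrated
for 0/1 data and can collapse standard errors as R(alpha) approaches
singularity) keeps the model-based covariance F^{-1} honest: when
R(alpha-hat) tracks the realized correlation of y, the model-based and
sandwich covariances of the estimating function coincide.

Standard errors come from the working Fisher information
F = X' W^{1/2} R^{-1} W^{1/2} X at the solution; p-values are two-sided
Wald.  In the independence limit (R -> I) the whole scheme reduces exactly
to ordinary Firth-penalized logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.special import expit, ndtr
from sklearn.base import BaseEstimator

from .phylo import PatristicDistances

_MU_EPS = 1e-10
_MAX_STEP = 5.0  # damping bound on a single Newton step, log-odds units


def tip_correlation(dist: PatristicDistances | np.ndarray, alpha: float) -> np.ndarray:
    """Between-tip correlation matrix R(alpha)_ij = exp(-alpha d_ij)."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    D = dist.matrix if isinstance(dist, PatristicDistances) else np.asarray(dist, float)
    return np.exp(-alpha * D)


def _chol_with_jitter(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky of R, escalating a diagonal jitter if needed."""
    bumps = (0.0, 1e-10, 1e-8, 1e-6)
    last_exc: Exception | None = None
    for bump in bumps:
        try:
            M = R if bump == 0.0 else R + bump * np.eye(R.shape[0])
            L = linalg.cholesky(M, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            return L, logdet
        except linalg.LinAlgError as exc:  # pragma: no cover - rare path
            last_exc = exc
    raise linalg.LinAlgError(
        f"correlation matrix not positive definite even after jitter: {last_exc}"
    )


def _firth_irls(
    y: np.ndarray,
    X: np.ndarray,
    L: np.ndarray | None,
    beta0: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    firth: bool = True,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Solve the (Firth-) penalized estimating equations at fixed correlation.

    ``L`` is the lower Cholesky factor of R(alpha); ``None`` means R = I
    (ordinary Firth logistic).  Returns (beta, Fisher information, converged).

    The Jeffreys ("Firth") adjustment is the exact gradient of
    0.5 * logdet F(beta) for the working information
    F = X' W^{1/2} R^{-1} W^{1/2} X:

        U*(beta) = X' W^{1/2} R^{-1} W^{-1/2} (y - mu) + X' (q * (1/2 - mu)),
        q = diag( W^{1/2} R^{-1} W^{1/2} X F^{-1} X' ),

    which reduces to the textbook Firth score X'(y - mu + h(1/2 - mu)) at
    R = I and, unlike whitened-space leverages, is invariant to tip
    ordering.
    """
    beta = beta0.astype(float).copy()
    n, p = X.shape
    converged = False
    F = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        w = mu * (1.0 - mu)
        sw = np.sqrt(w)
        A = sw[:, None] * X
        if L is not None:
            SX = linalg.solve_triangular(L, A, lower=True)
        else:
            SX = A
        F = SX.T @ SX
        try:
            Finv = np.linalg.inv(F)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular design matrix: {exc}") from exc
        t = (y - mu) / sw
        if L is not None:
            t = linalg.solve_triangular(L, t, lower=True)
        U = SX.T @ t
        if firth:
            if L is not None:
                B = linalg.solve_triangular(L.T, SX, lower=False)  # R^{-1} A
            else:
                B = SX
            q = sw * np.einsum("ij,ij->i", B @ Finv, X)
            U = U + X.T @ (q * (0.5 - mu))
        step = Finv @ U
        biggest = float(np.max(np.abs(step)))
        if biggest > _MAX_STEP:
            step *= _MAX_STEP / biggest
        beta = beta + step
        if biggest < tol:
            converged = True
            break
    return beta, F, converged


def _std_residuals(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    mu = np.clip(expit(X @ beta), _MU_EPS, 1.0 - _MU_EPS)
    return (y - mu) / np.sqrt(mu * (1.0 - mu))


def _moment_loss(r: np.ndarray, D: np.ndarray, alpha: float) -> float:
    """Alpha-dependent part of sum_{i != j} (r_i r_j - R(alpha)_ij)^2.

    Expanding the square, only -2 sum_{i != j} r_i r_j R_ij and
    sum_{i != j} R_ij^2 involve alpha; both reduce to dense quadratic /
    Frobenius forms with the diagonal subtracted off.
    """
    R = np.exp(-alpha * D)
    s1 = float(r @ r)
    cross = float(r @ (R @ r)) - s1  # sum_{i != j} r_i r_j R_ij
    frob = float(np.sum(R * R)) - R.shape[0]
    return -2.0 * cross + frob


@dataclass
class PhyloGLMFit:
    """Result of one phylogenetic logistic regression fit."""

    beta: np.ndarray
    se: np.ndarray
    alpha: float
    p_values: np.ndarray
    converged: bool
    alpha_at_bound: bool
    n_tips: int
    coef_names: list[str] = field(default_factory=list)
    loglik: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "alpha": float(self.alpha),
            "p_values": [float(p) for p in self.p_values],
            "converged": bool(self.converged),
            "alpha_at_bound": bool(self.alpha_at_bound),
            "n_tips": int(self.n_tips),
            "coef_names": list(self.coef_names),
            "loglik": float(self.loglik),
        }


def wald_p(fit: PhyloGLMFit, coef_index: int) -> tuple[float, int]:
    """Two-sided Wald p-value and coefficient sign for one coefficient."""
    if not 0 <= coef_index < len(fit.beta):
        raise IndexError(
            f"coefficient index {coef_index} out of range for {len(fit.beta)} coefficients"
        )
    b = float(fit.beta[coef_index])
    se = float(fit.se[coef_index])
    if b == 0.0:
        return 1.0, 0
    z = b / se
    p = float(2.0 * ndtr(-abs(z)))
    return max(p, np.finfo(float).tiny), int(np.sign(b))


class PhyloLogisticRegression(BaseEstimator):
    """Logistic regression with phylogenetically correlated residuals.

    Parameters
    ----------
    alpha_bounds : (float, float)
        Search range for the signal parameter on the height-normalized
        tree.  Hitting a bound sets ``alpha_at_bound_`` rather than being
        silently clamped.
    firth : bool
        Apply the Jeffreys-prior penalty (keeps coefficients finite under
        separation; reduces small-sample bias).  Default True.
    max_iter : int
        Outer (alpha-profile) iteration cap.
    inner_max_iter : int
        Cap on the reweighted estimating-equation iterations per alpha.
    tol : float
        Convergence tolerance on the coefficient step.
    fit_intercept : bool
        Prepend an intercept column to the design matrix.

    Attributes (after ``fit``)
    --------------------------
    beta_ : full coefficient vector (intercept first when fitted)
    coef_, intercept_ : sklearn-style views of ``beta_``
    se_ : standard errors per coefficient
    alpha_ : estimated signal parameter
    p_values_ : two-sided Wald p-values per coefficient
    converged_, alpha_at_bound_, n_tips_ : diagnostics
    """

    def __init__(
        self,
        alpha_bounds: tuple[float, float] = (1e-3, 1e3),
        firth: bool = True,
        max_iter: int = 100,
        inner_max_iter: int = 50,
        tol: float = 1e-8,
        fit_intercept: bool = True,
    ):
        self.alpha_bounds = alpha_bounds
        self.firth = firth
        self.max_iter = max_iter
        self.inner_max_iter = inner_max_iter
        self.tol = tol
        self.fit_intercept = fit_intercept

    # ------------------------------------------------------------------
    def fit(self, X, y, D: PatristicDistances | np.ndarray = None):
        """Fit to tip data.

        Parameters
        ----------
        X : (n, p) design matrix of tip predictors (without intercept
            unless ``fit_intercept=False``).
        y : (n,) binary response per tip, aligned with ``D``.
        D : patristic distance structure (``PatristicDistances`` or a
            plain symmetric matrix) over the same tips in the same order.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if D is None:
            raise ValueError("D (patristic distances) is required")
        Dm = D.matrix if isinstance(D, PatristicDistances) else np.asarray(D, float)
        n = y.shape[0]
        if X.shape[0] != n or Dm.shape != (n, n):
            raise ValueError(
                f"shape mismatch: y has {n} tips, X {X.shape}, D {Dm.shape}"
            )
        uniq = np.unique(y)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        if uniq.size < 2:
            raise ValueError("degenerate response: y is constant")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")

        Xd = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise np.linalg.LinAlgError("singular design matrix")

        amin, amax = self.alpha_bounds
        if not (0 < amin < amax):
            raise ValueError("alpha_bounds must satisfy 0 < amin < amax")

        # deterministic initialization: ordinary (independence) solution
        b_init = np.zeros(Xd.shape[1])
        ybar = min(max(float(y.mean()), 1e-3), 1 - 1e-3)
        b_init[0 if self.fit_intercept else 0] = math.log(ybar / (1 - ybar))
        beta_ind, _, _ = _firth_irls(
            y, Xd, None, b_init, self.inner_max_iter, self.tol, self.firth
        )

        # alternate: alpha from residual moments at current beta, then beta
        # re-solved under R(alpha)
        beta = beta_ind
        alpha = float("nan")
        conv = True
        F = np.empty((Xd.shape[1], Xd.shape[1]))
        outer_rounds = max(self.max_iter, 1)
        for _ in range(outer_rounds):
            r = _std_residuals(y, Xd, beta)

            def loss(log_alpha: float) -> float:
                return _moment_loss(r, Dm, math.exp(float(log_alpha)))

            res = optimize.minimize_scalar(
                loss,
                bounds=(math.log(amin), math.log(amax)),
                method="bounded",
                options={"maxiter": self.max_iter, "xatol": 1e-6},
            )
            candidates = [float(res.x), math.log(amin), math.log(amax)]
            best_la = min(candidates, key=loss)
            new_alpha = math.exp(best_la)
            R = np.exp(-new_alpha * Dm)
            L, _ = _chol_with_jitter(R)
            beta, F, conv = _firth_irls(
                y, Xd, L, beta, self.inner_max_iter, self.tol, self.firth
            )
            if np.isfinite(alpha) and abs(math.log(new_alpha) - math.log(alpha)) < 1e-5:
                alpha = new_alpha
                break
            alpha = new_alpha

        Finv = np.linalg.inv(F)
        se = np.sqrt(np.clip(np.diag(Finv), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = np.clip(2.0 * ndtr(-np.abs(z)), np.finfo(float).tiny, 1.0)

        self.beta_ = beta
        self.intercept_ = float(beta[0]) if self.fit_intercept else 0.0
        self.coef_ = beta[1:] if self.fit_intercept else beta
        self.se_ = se
        self.alpha_ = float(alpha)
        self.p_values_ = pvals
        self.converged_ = bool(conv)
        self.alpha_at_bound_ = bool(
            alpha <= amin * (1 + 1e-3) or alpha >= amax * (1 - 1e-3)
        )
        self.n_tips_ = n
        mu_hat = np.clip(expit(Xd @ beta), _MU_EPS, 1.0 - _MU_EPS)
        self.loglik_ = float(np.sum(y * np.log(mu_hat) + (1 - y) * np.log(1 - mu_hat)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept_ + X @ self.coef_
        p1 = expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def result_(self, coef_names: list[str] | None = None) -> PhyloGLMFit:
        names = coef_names or (
            ["intercept"] + [f"x{i}" for i in range(len(self.coef_))]
            if self.fit_intercept
            else [f"x{i}" for i in range(len(self.beta_))]
        )
        return PhyloGLMFit(
            beta=self.beta_.copy(),
            se=self.se_.copy(),
            alpha=self.alpha_,
            p_values=self.p_values_.copy(),
            converged=self.converged_,
            alpha_at_bound=self.alpha_at_bound_,
            n_tips=self.n_tips_,
            coef_names=names,
            loglik=self.loglik_,
        )


def fit_phyloglm(
    y, X, dist: PatristicDistances | np.ndarray, coef_names=None, **opts
) -> PhyloGLMFit:
    """Functional wrapper around :class:`PhyloLogisticRegression`."""
    est = PhyloLogisticRegression(**opts)
    est.fit(X, y, D=dist)
    return est.result_(coef_names=coef_names)


# ---------------------------------------------------------------------------
# Batched bivariate fitting over a fixed alpha grid
# ---------------------------------------------------------------------------
#
# The observer bootstrap refits hundreds of thousands of small
# intercept + one-predictor models on the SAME tree.  Those fits share the
# Cholesky factors of R(alpha) on a fixed log-spaced alpha grid, and the
# reweighted iterations vectorize across models, which is what makes
# B = 100..1000 bootstrap replicates tractable.


def alpha_grid(bounds: tuple[float, float] = (1e-3, 1e3), size: int = 13) -> np.ndarray:
    return np.exp(np.linspace(math.log(bounds[0]), math.log(bounds[1]), size))


@dataclass
class GridPoint:
    """One alpha on the profiling grid with its precomputed factors."""

    alpha: float
    R: np.ndarray
    L: np.ndarray
    frob_offdiag: float  # sum_{i != j} R_ij^2, the alpha part of the moment loss


def grid_cholesky(
    dist: PatristicDistances | np.ndarray, alphas: np.ndarray
) -> list[GridPoint]:
    """Precompute R(alpha), its Cholesky and Frobenius term per grid alpha."""
    Dm = dist.matrix if isinstance(dist, PatristicDistances) else np.asarray(dist, float)
    out = []
    for a in alphas:
        R = np.exp(-a * Dm)
        L, _ = _chol_with_jitter(R)
        out.append(
            GridPoint(
                alpha=float(a),
                R=R,
                L=L,
                frob_offdiag=float(np.sum(R * R)) - R.shape[0],
            )
        )
    return out


@dataclass
class BatchFitResult:
    """Vectorized results for J bivariate models sharing one tree."""

    beta0: np.ndarray
    beta1: np.ndarray
    se1: np.ndarray
    p1: np.ndarray
    alpha: np.ndarray
    converged: np.ndarray
    valid: np.ndarray  # False where y or x was degenerate


def _batch_irls(
    Y: np.ndarray,
    Xp: np.ndarray,
    L: np.ndarray | None,
    B0: np.ndarray,
    cols: np.ndarray,
    firth: bool,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, dict, np.ndarray]:
    """Vectorized Firth IRLS for the models in ``cols`` at one fixed L.

    ``B0`` is (2, J_total); only columns ``cols`` are updated.  Returns the
    updated coefficient block (2, |cols|), the 2x2 information components
    and the per-model convergence flags.
    """
    n = Y.shape[0]
    Yc = Y[:, cols]
    Xc = Xp[:, cols]
    B = B0[:, cols].copy()
    J = len(cols)
    conv = np.zeros(J, dtype=bool)
    F00 = F01 = F11 = det = np.ones(J)
    for _ in range(max_iter):
        Eta = B[0][None, :] + Xc * B[1][None, :]
        Mu = np.clip(expit(Eta), _MU_EPS, 1.0 - _MU_EPS)
        W = Mu * (1.0 - Mu)
        SW = np.sqrt(W)
        A = np.empty((n, 2 * J))
        A[:, 0::2] = SW
        A[:, 1::2] = SW * Xc
        S = linalg.solve_triangular(L, A, lower=True) if L is not None else A
        S1 = S[:, 0::2]
        S2 = S[:, 1::2]
        F00 = np.einsum("ij,ij->j", S1, S1)
        F01 = np.einsum("ij,ij->j", S1, S2)
        F11 = np.einsum("ij,ij->j", S2, S2)
        det = np.maximum(F00 * F11 - F01 * F01, 1e-300)
        T = (Yc - Mu) / SW
        if L is not None:
            T = linalg.solve_triangular(L, T, lower=True)
        U0 = np.einsum("ij,ij->j", S1, T)
        U1 = np.einsum("ij,ij->j", S2, T)
        if firth:
            Bm = linalg.solve_triangular(L.T, S, lower=False) if L is not None else S
            B1m = Bm[:, 0::2]
            B2m = Bm[:, 1::2]
            C1 = (B1m * F11[None, :] - B2m * F01[None, :]) / det[None, :]
            C2 = (-B1m * F01[None, :] + B2m * F00[None, :]) / det[None, :]
            G = SW * (C1 + C2 * Xc) * (0.5 - Mu)
            U0 = U0 + G.sum(axis=0)
            U1 = U1 + np.einsum("ij,ij->j", Xc, G)
        step0 = (F11 * U0 - F01 * U1) / det
        step1 = (-F01 * U0 + F00 * U1) / det
        biggest = np.maximum(np.abs(step0), np.abs(step1))
        scale = np.where(biggest > _MAX_STEP, _MAX_STEP / np.maximum(biggest, 1e-300), 1.0)
        B[0] += step0 * scale
        B[1] += step1 * scale
        conv = biggest < tol
        if conv.all():
            break
    info = {"F00": F00, "F01": F01, "F11": F11, "det": det}
    return B, info, conv


def _batch_residuals(Y: np.ndarray, Xp: np.ndarray, B: np.ndarray) -> np.ndarray:
    Eta = B[0][None, :] + Xp * B[1][None, :]
    Mu = np.clip(expit(Eta), _MU_EPS, 1.0 - _MU_EPS)
    return (Y - Mu) / np.sqrt(Mu * (1.0 - Mu))


def batch_fit_bivariate(
    Y: np.ndarray,
    Xp: np.ndarray,
    chols: list[GridPoint],
    firth: bool = True,
    max_iter: int = 30,
    tol: float = 1e-7,
    selection_rounds: int = 2,
) -> BatchFitResult:
    """Fit J models y_j ~ intercept + x_j jointly over an alpha grid.

    ``Y`` and ``Xp`` are (n, J): column j holds model j's response and
    predictor.  Mirrors the single-fit alternation: solve the
    independence fit, pick each model's grid alpha by the residual moment
    loss, re-solve at the selected alphas (models sharing a grid point are
    solved together against one Cholesky factor), and repeat the selection
    with the updated residuals.  Degenerate columns (constant y or x) are
    masked out as invalid.
    """
    Y = np.asarray(Y, dtype=float)
    Xp = np.asarray(Xp, dtype=float)
    n, J = Y.shape
    valid = (Y.max(axis=0) > Y.min(axis=0)) & (Xp.max(axis=0) > Xp.min(axis=0))

    ybar = np.clip(Y.mean(axis=0), 1e-3, 1 - 1e-3)
    B = np.vstack([np.log(ybar / (1 - ybar)), np.zeros(J)])
    all_cols = np.arange(J)
    B_new, info, conv = _batch_irls(Y, Xp, None, B, all_cols, firth, max_iter, tol)
    B[:, all_cols] = B_new

    def select(resid: np.ndarray) -> np.ndarray:
        s1 = np.einsum("ij,ij->j", resid, resid)
        losses = np.empty((len(chols), J))
        for k, gp in enumerate(chols):
            cross = np.einsum("ij,ij->j", resid, gp.R @ resid) - s1
            losses[k] = -2.0 * cross + gp.frob_offdiag
        return np.argmin(losses, axis=0)

    sel = select(_batch_residuals(Y, Xp, B))
    info_all = {k: np.zeros(J) for k in ("F00", "F01", "F11", "det")}
    conv_all = np.zeros(J, dtype=bool)
    for _ in range(selection_rounds):
        for k in np.unique(sel):
            cols = np.flatnonzero(sel == k)
            B_k, info_k, conv_k = _batch_irls(
                Y, Xp, chols[k].L, B, cols, firth, max_iter, tol
            )
            B[:, cols] = B_k
            for key in info_all:
                info_all[key][cols] = info_k[key]
            conv_all[cols] = conv_k
        new_sel = select(_batch_residuals(Y, Xp, B))
        if (new_sel == sel).all():
            break
        sel = new_sel

    se1 = np.sqrt(info_all["F00"] / info_all["det"])
    alpha = np.array([chols[k].alpha for k in sel])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = B[1] / se1
    p1 = np.clip(2.0 * ndtr(-np.abs(z)), np.finfo(float).tiny, 1.0)
    p1 = np.where(valid, p1, np.nan)
    return BatchFitResult(
        beta0=B[0],
        beta1=B[1],
        se1=se1,
        p1=p1,
        alpha=np.where(valid, alpha, np.nan),
        converged=conv_all & valid,
        valid=valid,
    )
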