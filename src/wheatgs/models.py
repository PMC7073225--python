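"""Seven genomic prediction models with a scikit-learn estimator contract.

All estimators regress a line-level phenotype (typically the BLUE) on a
marker design or a genomic relationship matrix and predict genomic estimated
breeding values (GEBVs) for new lines:

``RidgeRegression``
    beta = (X'X + lambda I)^-1 X'y with the intercept unpenalized; lambda by
    inner 5-fold cross-validation over a log grid when not supplied.
``PseudoinverseRegression`` (GenInv)
    the minimum-norm least-squares solution beta = (X'X)^+ X'y via SVD.
``MarkerBLUP`` (BLUP)
    the same ridge normal equations with the shrinkage fixed from a plug-in
    heritability, lambda = m (1 - h2) / h2.
``RRBLUP``
    the marker-effect mixed model y = 1 mu + Z u + eps, u ~ N(0, I sigma_u^2),
    variance components by spectral (eigendecomposition) REML.
``GBLUP``
    the line-level mixed model u ~ N(0, G sigma_u^2) on a genomic
    relationship matrix; prediction for new lines through the G cross-block.
``LassoGS``
    coordinate descent on (1/2n)||y - X beta||^2 + lambda ||beta||_1,
    intercept unpenalized, lambda by inner CV on a geometric grid from
    lambda_max when not supplied.
``RandomForestGS``
    a seeded regression forest (bootstrap lines, variance-reduction splits
    over ``mtry`` markers per node, prediction = mean over trees).

The marker design comes from :func:`build_design` (centered coding by
default; residual missing calls marker-mean filled and logged) and the GRM
from :func:`vanraden_grm`.  Thin ``fit_*`` wrappers mirror the estimators
for script use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .forest import RandomForestGS  # noqa: F401  (part of the model set)
from .matrix import GenotypeMatrix

MODEL_IDS = (
    "BLUP", "GBLUP", "RRBLUP", "RidgeReg", "GenInv", "LASSO", "RForest",
)


# ---------------------------------------------------------------------------
# design and relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class MarkerDesign:
    """Coded marker matrix ready for model fitting (no missing entries)."""

    X: np.ndarray  # n_lines x n_markers
    line_ids: list[str]
    marker_ids: list[str]
    coding: str  # raw | centered | centered-scaled
    missing_policy: str
    column_means: np.ndarray  # raw-code means used for centering / filling
    column_scales: np.ndarray
    allele_freq: np.ndarray  # observed alt-allele frequency per marker
    n_filled: int  # count of missing calls filled at construction

    @property
    def n_lines(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]

    def rows(self, line_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.line_ids)}
        idx = np.array([lookup[str(s)] for s in line_ids], dtype=int)
        return self.X[idx]


def build_design(
    genotypes: GenotypeMatrix,
    coding: str = "centered",
    missing_policy: str = "marker_mean",
    drop_constant: bool = True,
) -> MarkerDesign:
    """Code the genotype matrix for model fitting.

    Residual missing calls (markers that survived QC un-imputed) are filled
    per ``missing_policy`` — ``marker_mean`` (default) or ``zero`` after
    centering (equivalent) — and the fill count is recorded.  Markers left
    constant after coding carry no information and are dropped with a
    warning when ``drop_constant``.
    """
    if coding not in ("raw", "centered", "centered-scaled"):
        raise ValueError(f"unknown coding {coding!r}")
    if missing_policy not in ("marker_mean", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    calls = genotypes.calls
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(calls, axis=0)
    if np.isnan(means).any():
        raise ValueError("all-missing marker in design; apply QC first")
    n_filled = int(np.isnan(calls).sum())
    if missing_policy == "marker_mean":
        X = np.where(np.isnan(calls), means[None, :], calls)
    else:
        X = np.where(np.isnan(calls), 0.0, calls)
    freq = means / 2.0
    scales = X.std(axis=0, ddof=0)
    keep = np.ones(X.shape[1], dtype=bool)
    if drop_constant:
        keep = scales > 0
        if not keep.all():
            _w.warn(
                f"dropped {int((~keep).sum())} constant markers from design",
                UserWarning,
            )
    X = X[:, keep]
    means_k, scales_k, freq_k = means[keep], scales[keep], freq[keep]
    if coding in ("centered", "centered-scaled"):
        X = X - X.mean(axis=0)
    if coding == "centered-scaled":
        X = X / scales_k
    marker_ids = [m for m, k in zip(genotypes.marker_ids, keep) if k]
    return MarkerDesign(
        X=X,
        line_ids=list(genotypes.line_ids),
        marker_ids=marker_ids,
        coding=coding,
        missing_policy=missing_policy,
        column_means=means_k,
        column_scales=scales_k,
        allele_freq=freq_k,
        n_filled=n_filled,
    )


@dataclass
class GRM:
    """Genomic relationship matrix with its line order."""

    G: np.ndarray
    line_ids: list[str]
    method: str = "vanraden"

    def block(self, rows, cols) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.line_ids)}
        ri = np.array([lookup[str(s)] for s in rows], dtype=int)
        ci = np.array([lookup[str(s)] for s in cols], dtype=int)
        return self.G[np.ix_(ri, ci)]


def vanraden_grm(design: MarkerDesign, ridge: float = 1e-8) -> GRM:
    """G = W W' / (2 sum p_k (1 - p_k)) with W the centered marker matrix.

    ``ridge`` is added to the diagonal for numerical positive
    semi-definiteness.  Mean diagonal is ~1 for panels near allele-frequency
    equilibrium.
    """
    if design.coding == "raw":
        W = design.X - design.X.mean(axis=0)
    elif design.coding == "centered":
        W = design.X
    else:  # centered-scaled: undo the scaling for the VanRaden denominator
        W = design.X * design.column_scales
    p = design.allele_freq
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    G = W @ W.T / denom
    G[np.diag_indices_from(G)] += ridge
    return GRM(G=G, line_ids=list(design.line_ids), method="vanraden")


# ---------------------------------------------------------------------------
# spectral REML for the single-random-component mixed model
# ---------------------------------------------------------------------------

def reml_single_component(
    y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None
) -> dict:
    """REML variance components for y = X b + u + eps, u ~ N(0, K sigma_u^2).

    One eigendecomposition of the covariate-projected kernel, then a 1-D
    profiled restricted likelihood in delta = sigma_eps^2 / sigma_u^2,
    optimized by bounded scalar search on log10(delta) in [-8, 8].
    Returns sigma2_u, sigma2_e, delta, beta (GLS), and the REML log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]
    # project out fixed effects: S = I - X (X'X)^-1 X'
    Q, _ = np.linalg.qr(X)
    SKS = K - Q @ (Q.T @ K) - (K @ Q) @ Q.T + Q @ (Q.T @ K @ Q) @ Q.T
    xi, U = np.linalg.eigh((SKS + SKS.T) / 2.0)
    order = np.argsort(xi)[::-1]
    xi, U = xi[order][: n - p], U[:, order][:, : n - p]
    xi = np.maximum(xi, 0.0)
    Sy = y - Q @ (Q.T @ y)
    eta = U.T @ Sy
    nf = n - p

    def neg_restricted_ll(log10_delta: float) -> float:
        d = 10.0**log10_delta
        denom = xi + d
        # tiny floor keeps the profiled likelihood finite for constant y
        quad = max(np.sum(eta**2 / denom), 1e-300)
        return -0.5 * (
            nf * np.log(nf / (2 * np.pi))
            - nf
            - nf * np.log(quad)
            - np.sum(np.log(denom))
        )

    res = minimize_scalar(
        neg_restricted_ll, bounds=(-8.0, 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(
            f"REML optimization failed: {res.message}; "
            f"final value {res.fun:.6g} at log10(delta)={res.x:.3f}"
        )
    delta = 10.0**res.x
    sigma2_u = float(np.sum(eta**2 / (xi + delta)) / nf)
    sigma2_e = float(delta * sigma2_u)
    V_inv_y_part = None  # computed by callers as needed
    # GLS fixed effects with V = sigma2_u (K + delta I)
    A = K + delta * np.eye(n)
    Ainv_X = np.linalg.solve(A, X)
    Ainv_y = np.linalg.solve(A, y)
    beta = np.linalg.solve(X.T @ Ainv_X, X.T @ Ainv_y)
    return {
        "sigma2_u": sigma2_u,
        "sigma2_e": sigma2_e,
        "delta": float(delta),
        "beta": beta,
        "loglik": float(-res.fun),
        "_Ainv_resid": Ainv_y - Ainv_X @ beta,
        "_unused": V_inv_y_part,
    }


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _ridge_solve(Xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """(X'X + lam I)^-1 X'y via whichever of the primal (m x m) or dual
    (n x n) normal equations is smaller; lam = 0 falls back to the
    minimum-norm least-squares solution."""
    n, m = Xc.shape
    if lam == 0.0:
        return np.linalg.lstsq(Xc, yc, rcond=None)[0]
    if m <= n:
        return np.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T @ yc)
    alpha = np.linalg.solve(Xc @ Xc.T + lam * np.eye(n), yc)
    return Xc.T @ alpha


class _LinearGSBase(BaseEstimator, RegressorMixin):
    """Shared fit/predict plumbing for intercept + marker-effect models."""

    model_id = "base"

    def _fit_center(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n, m) and y length n")
        self.x_mean_ = X.mean(axis=0)
        self.intercept_ = float(y.mean())
        return X - self.x_mean_, y - self.intercept_

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + (X - self.x_mean_) @ self.coef_


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.array_split(perm, k)


class RidgeRegression(_LinearGSBase):
    """Ridge regression on marker codes (model id ``RidgeReg``).

    Solves (X'X + lambda I)^-1 X'y on the centered design, intercept
    unpenalized.  ``lambda_`` may be fixed; when ``None`` it is chosen by
    inner ``cv`` -fold cross-validation minimizing squared error over
    ``n_grid`` log-spaced candidates in [10^-3, 10^5] scaled by m.
    """

    model_id = "RidgeReg"

    def __init__(self, lambda_=None, cv: int = 5, n_grid: int = 13,
                 random_state: int = 0):
        self.lambda_ = lambda_
        self.cv = cv
        self.n_grid = n_grid
        self.random_state = random_state

    @staticmethod
    def _solve(Xc, yc, lam):
        return _ridge_solve(Xc, yc, lam)

    def fit(self, X, y):
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        Xc, yc = self._fit_center(X, y)
        if self.lambda_ is None:
            lam = self._select_lambda(Xc, yc)
        else:
            lam = float(self.lambda_)
        self.lambda_selected_ = lam
        self.coef_ = self._solve(Xc, yc, lam)
        return self

    def _select_lambda(self, Xc, yc) -> float:
        m = Xc.shape[1]
        grid = m * np.logspace(-3, 5, self.n_grid)
        rng = np.random.default_rng(self.random_state)
        folds = _kfold_indices(len(yc), min(self.cv, len(yc)), rng)
        errs = np.zeros(len(grid))
        for f in folds:
            mask = np.ones(len(yc), dtype=bool)
            mask[f] = False
            Xt, yt = Xc[mask], yc[mask]
            Xv, yv = Xc[f], yc[f]
            mu_t = yt.mean()
            for i, lam in enumerate(grid):
                b = self._solve(Xt, yt - mu_t, lam)
                errs[i] += np.sum((yv - mu_t - Xv @ b) ** 2)
        return float(grid[int(np.argmin(errs))])


class PseudoinverseRegression(_LinearGSBase):
    """Minimum-norm least squares beta = (X'X)^+ X'y (model id ``GenInv``).

    Computed as pinv(X) y via SVD; singular values below
    ``rtol * sigma_max`` (default 1e-10 times the larger matrix dimension)
    are treated as zero.
    """

    model_id = "GenInv"

    def __init__(self, rtol: float | None = None):
        self.rtol = rtol

    def fit(self, X, y):
        Xc, yc = self._fit_center(X, y)
        rtol = self.rtol
        if rtol is None:
            rtol = 1e-10 * max(Xc.shape)
        self.coef_ = np.linalg.pinv(Xc, rcond=rtol) @ yc
        return self


class MarkerBLUP(_LinearGSBase):
    """Ridge-family model with plug-in shrinkage (model id ``BLUP``).

    The marker-effect mixed model implies shrinkage
    lambda = sigma_eps^2 / sigma_u^2 = m (1 - h2) / h2 under an equal-variance
    marker prior; here h2 is supplied externally (e.g., the phenotypic
    plot-level heritability from the trial ANOVA).  When ``h2`` is None the
    estimator falls back to spectral REML (making it RRBLUP-equivalent).
    """

    model_id = "BLUP"

    def __init__(self, h2: float | None = 0.5):
        self.h2 = h2

    def fit(self, X, y):
        Xc, yc = self._fit_center(X, y)
        m = Xc.shape[1]
        if self.h2 is not None:
            if not 0 < self.h2 < 1:
                raise ValueError("h2 must be in (0, 1)")
            lam = m * (1.0 - self.h2) / self.h2
        else:
            K = Xc @ Xc.T
            fit = reml_single_component(yc, K)
            lam = fit["delta"]
        self.lambda_selected_ = float(lam)
        self.coef_ = _ridge_solve(Xc, yc, lam)
        return self


class RRBLUP(_LinearGSBase):
    """Ridge-regression BLUP of marker effects with REML shrinkage.

    y = 1 mu + Z u + eps with u ~ N(0, K sigma_u^2), K = I by default
    (an alternative marker-covariance K may be injected).  sigma_u^2 and
    sigma_eps^2 come from spectral REML on the line-space kernel Z K Z';
    marker effects are u = K Z'(Z K Z' + delta I)^-1 (y - mu).
    """

    model_id = "RRBLUP"

    def __init__(self, marker_K: np.ndarray | None = None):
        self.marker_K = marker_K

    def fit(self, X, y):
        Xc, yc = self._fit_center(X, y)
        n, m = Xc.shape
        if n < 2:
            raise ValueError(">=2 lines required")
        if self.marker_K is None:
            K_line = Xc @ Xc.T
        else:
            K_line = Xc @ self.marker_K @ Xc.T
        fit = reml_single_component(yc, K_line)
        self.sigma2_u_ = fit["sigma2_u"]
        self.sigma2_e_ = fit["sigma2_e"]
        self.delta_ = fit["delta"]
        alpha = np.linalg.solve(
            K_line + self.delta_ * np.eye(n), yc
        )
        if self.marker_K is None:
            self.coef_ = Xc.T @ alpha
        else:
            self.coef_ = self.marker_K @ Xc.T @ alpha
        return self


class GBLUP(BaseEstimator, RegressorMixin):
    """Line-level genomic BLUP on a relationship matrix (model id ``GBLUP``).

    ``fit`` takes the training-by-training block of G (or a :class:`GRM`
    plus training line IDs); ``predict`` takes the new-by-training
    cross-block.  Variance components by spectral REML; the ratio
    sigma_u^2/(sigma_u^2 + sigma_e^2) estimates heritability on a
    mean-diagonal-1 GRM.
    """

    model_id = "GBLUP"

    def __init__(self, variance_ratio: float | None = None):
        # optional fixed lambda = sigma_e^2/sigma_u^2; REML when None
        self.variance_ratio = variance_ratio

    def fit(self, K_train: np.ndarray, y):
        K = np.asarray(K_train, dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.size
        if K.shape != (n, n):
            raise ValueError("K_train must be n x n for n = len(y)")
        self.intercept_ = float(y.mean())
        yc = y - self.intercept_
        if self.variance_ratio is None:
            fit = reml_single_component(yc, K)
            self.sigma2_u_ = fit["sigma2_u"]
            self.sigma2_e_ = fit["sigma2_e"]
            self.delta_ = fit["delta"]
        else:
            self.delta_ = float(self.variance_ratio)
            self.sigma2_u_ = np.nan
            self.sigma2_e_ = np.nan
        self.alpha_ = np.linalg.solve(K + self.delta_ * np.eye(n), yc)
        if self.variance_ratio is None:
            # genetic variance at the line level is mean(diag K) * sigma_u^2
            # (the mean diagonal is ~1 for HW-like panels, ~2 fully inbred)
            kd = float(np.mean(np.diag(K)))
            self.h2_reml_ = float(
                kd * self.sigma2_u_ / (kd * self.sigma2_u_ + self.sigma2_e_)
            )
        else:
            self.h2_reml_ = np.nan
        return self

    def predict(self, K_cross: np.ndarray) -> np.ndarray:
        K_cross = np.asarray(K_cross, dtype=float)
        return self.intercept_ + K_cross @ self.alpha_

    def fitted_values(self, K_train: np.ndarray) -> np.ndarray:
        return self.predict(K_train)


class LassoGS(_LinearGSBase):
    """L1-penalized marker regression by coordinate descent (``LASSO``).

    Minimizes (1/2n)||y - mu - X beta||^2 + lambda ||beta||_1 on the
    centered design (intercept unpenalized).  With a fixed ``lambda_`` the
    stated objective is solved directly; otherwise lambda is selected by
    inner ``cv``-fold CV on a geometric grid of ``n_grid`` values from
    lambda_max = max |X'(y - ybar)| / n downward.  Convergence: max
    coefficient change < ``tol`` per sweep.
    """

    model_id = "LASSO"

    def __init__(self, lambda_=None, cv: int = 5, n_grid: int = 15,
                 grid_ratio: float = 0.05, tol: float = 1e-7,
                 max_sweeps: int = 50_000, random_state: int = 0):
        self.lambda_ = lambda_
        self.cv = cv
        self.n_grid = n_grid
        self.grid_ratio = grid_ratio
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    @staticmethod
    def _soft(z: float, t: float) -> float:
        return np.sign(z) * max(abs(z) - t, 0.0)

    def _descend(self, Xc, yc, lam, beta0=None, tol=None):
        """Cyclic coordinate descent with active-set iteration.

        Full sweeps alternate with cheap sweeps over the current active set.
        Stops when the max coefficient change in a full sweep drops below
        ``tol``, or when the penalized objective can no longer decrease in
        floating point (a stall within 1e-13 relative is convergence).
        """
        n, m = Xc.shape
        if tol is None:
            tol = self.tol
        col_sq = (Xc**2).sum(axis=0) / n
        beta = np.zeros(m) if beta0 is None else beta0.copy()
        resid = yc - Xc @ beta

        def sweep(indices) -> float:
            nonlocal resid
            md = 0.0
            for j in indices:
                if col_sq[j] == 0:
                    continue
                bj = beta[j]
                rho = (Xc[:, j] @ resid) / n + col_sq[j] * bj
                new = self._soft(rho, lam) / col_sq[j]
                if new != bj:
                    resid += Xc[:, j] * (bj - new)
                    beta[j] = new
                    md = max(md, abs(new - bj))
            return md

        def objective() -> float:
            return 0.5 * (resid @ resid) / n + lam * np.abs(beta).sum()

        n_sweeps = 0
        prev_obj = objective()
        max_delta = np.inf
        while n_sweeps < self.max_sweeps:
            max_delta = sweep(range(m))
            n_sweeps += 1
            obj = objective()
            if max_delta < tol or prev_obj - obj <= 1e-13 * max(1.0, obj):
                return beta, n_sweeps
            prev_obj = obj
            active = np.flatnonzero(beta)
            while n_sweeps < self.max_sweeps:
                md_a = sweep(active)
                n_sweeps += 1
                obj = objective()
                stalled = prev_obj - obj <= 1e-13 * max(1.0, obj)
                prev_obj = obj
                if md_a < tol or stalled:
                    break
        raise RuntimeError(
            f"coordinate descent did not converge in {self.max_sweeps} "
            f"sweeps (lambda={lam:.4g}, last max change {max_delta:.3g})"
        )

    def lambda_max(self, X, y) -> float:
        Xc = np.asarray(X, dtype=float)
        Xc = Xc - Xc.mean(axis=0)
        yc = np.asarray(y, dtype=float)
        yc = yc - yc.mean()
        return float(np.max(np.abs(Xc.T @ yc)) / len(yc))

    def fit(self, X, y):
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        Xc, yc = self._fit_center(X, y)
        if self.lambda_ is None:
            lam = self._select_lambda(Xc, yc)
        else:
            lam = float(self.lambda_)
        self.lambda_selected_ = lam
        self.coef_, self.n_sweeps_ = self._descend(Xc, yc, lam)
        return self

    def _grid(self, Xc, yc):
        lam_max = np.max(np.abs(Xc.T @ yc)) / len(yc)
        if lam_max <= 0:
            return np.array([0.0])
        return np.geomspace(lam_max, lam_max * self.grid_ratio, self.n_grid)

    def _select_lambda(self, Xc, yc) -> float:
        grid = self._grid(Xc, yc)
        rng = np.random.default_rng(self.random_state)
        folds = _kfold_indices(len(yc), min(self.cv, len(yc)), rng)
        errs = np.zeros(len(grid))
        for f in folds:
            mask = np.ones(len(yc), dtype=bool)
            mask[f] = False
            Xt, yt = Xc[mask], yc[mask]
            Xv, yv = Xc[f], yc[f]
            mu_t = yt.mean()
            beta = None
            for i, lam in enumerate(grid):  # warm-started path
                # path fits only rank candidates; a looser
                # tolerance is ample and much cheaper
                beta, _ = self._descend(Xt, yt - mu_t, lam, beta0=beta,
                                        tol=max(self.tol, 1e-4))
                errs[i] += np.sum((yv - mu_t - Xv @ beta) ** 2)
        return float(grid[int(np.argmin(errs))])


# ---------------------------------------------------------------------------
# registry and functional wrappers
# ---------------------------------------------------------------------------

def make_model(model_id: str, **params):
    """Instantiate one of the seven estimators by its model id."""
    registry = {
        "BLUP": MarkerBLUP,
        "GBLUP": GBLUP,
        "RRBLUP": RRBLUP,
        "RidgeReg": RidgeRegression,
        "GenInv": PseudoinverseRegression,
        "LASSO": LassoGS,
        "RForest": RandomForestGS,
    }
    if model_id not in registry:
        raise ValueError(f"unknown model id {model_id!r}; one of {MODEL_IDS}")
    return registry[model_id](**params)


def fit_ridge(design: MarkerDesign, y, lambda_=None) -> RidgeRegression:
    return RidgeRegression(lambda_=lambda_).fit(design.X, y)


def fit_geninv(design: MarkerDesign, y) -> PseudoinverseRegression:
    return PseudoinverseRegression().fit(design.X, y)


def fit_rrblup(design: MarkerDesign, y) -> RRBLUP:
    return RRBLUP().fit(design.X, y)


def fit_blup(design: MarkerDesign, y, h2: float | None = 0.5) -> MarkerBLUP:
    return MarkerBLUP(h2=h2).fit(design.X, y)


def fit_gblup(grm: GRM, y, line_ids=None) -> GBLUP:
    if line_ids is None:
        K = grm.G
    else:
        K = grm.block(line_ids, line_ids)
    return GBLUP().fit(K, y)


def fit_lasso(design: MarkerDesign, y, lambda_=None) -> LassoGS:
    return LassoGS(lambda_=lambda_).fit(design.X, y)


def fit_rforest(design: MarkerDesign, y, n_trees: int = 500,
                mtry: int | None = None, seed: int = 0) -> RandomForestGS:
    return RandomForestGS(
        n_trees=n_trees, mtry=mtry, random_state=seed
    ).fit(design.X, y)
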