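"""Sparse Insulation Model (SIM).

Two-stage estimation of per-bin insulation effects from a contact matrix:

1. The polymer (distance) effect is removed by a negative-binomial
   regression of counts on a cubic B-spline basis of log genomic distance,
   ``log E[y|d] = b0 + f(d)``, with the NB dispersion estimated from the
   data.  Residuals are taken on the log scale,
   ``z = log(y + c) - (b0 + f(d))`` with a small pseudocount ``c``, so a
   bin's coefficient is an additive effect on log contact frequency.

2. Sparse per-bin effects are estimated by L0-penalized (best-subset)
   least squares of z on the in-betweenness indicators,
   ``min (1/N) sum (z - b0 - X b)^2 + lambda * ||b||_0``,
   with lambda chosen by K-fold cross-validation of the mean squared
   error.  When the candidate set is large, a lasso prefilter keeps bins
   with |coef| above a threshold.

Negative selected coefficients mark TAD borders (insulation), positive
ones TAD facilitators.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .design import InsulationDesign, PairTable, build_insulation_design, build_pair_table
from .hic_io import BinTable, ContactMatrix

__all__ = [
    "DistanceTrend",
    "InsulationFit",
    "fit_distance_trend",
    "compute_residuals",
    "prefilter_lasso",
    "fit_best_subset",
    "classify_borders",
    "run_sim",
]


# ---------------------------------------------------------------------------
# distance (polymer) trend


@dataclass
class DistanceTrend:
    """Fitted NB spline regression of counts on log distance."""

    knots: np.ndarray  # full knot vector (cubic)
    coef: np.ndarray  # [intercept, spline coefficients]
    alpha: float  # NB dispersion (0 => Poisson)
    family: str  # "nb" or "poisson"
    d_range: tuple[float, float]

    def basis(self, d: np.ndarray) -> np.ndarray:
        d = np.clip(np.asarray(d, dtype=float), *self.d_range)
        B = BSpline.design_matrix(d, self.knots, 3).toarray()
        return np.column_stack([np.ones(len(d)), B[:, 1:]])

    def predict_logmean(self, d: np.ndarray) -> np.ndarray:
        return self.basis(d) @ self.coef

    def predict_mean(self, d: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_logmean(d))

    def expected_log(self, d: np.ndarray, pseudocount: float) -> np.ndarray:
        """Fitted log-scale trend: E[log(y + c) | d] under the fitted family.

        Uses the second-order (delta-method) correction
        ``log(mu + c) - Var(y)/(2 (mu + c)^2)`` with Var = mu (Poisson) or
        mu (1 + alpha mu) (NB), so residuals are mean-zero per distance
        under the fitted null rather than carrying a distance-dependent
        Jensen offset.
        """
        mu = self.predict_mean(d)
        var = mu * (1.0 + self.alpha * mu)
        return np.log(mu + pseudocount) - var / (2.0 * (mu + pseudocount) ** 2)


def _spline_design(d: np.ndarray, df: int):
    """Cubic B-spline basis on log distance, knots at quantiles."""
    lo, hi = float(d.min()), float(d.max())
    uniq = np.unique(d)
    df = int(min(df, max(len(uniq) - 1, 1)))
    n_interior = max(df - 4, 0)
    if n_interior:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(uniq, qs)
    else:
        interior = np.array([])
    if hi == lo:
        hi = lo + 1e-9
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    B = BSpline.design_matrix(np.clip(d, lo, hi), knots, 3).toarray()
    # drop the first basis column in favor of an explicit intercept
    design = np.column_stack([np.ones(len(d)), B[:, 1:]])
    return design, knots, (lo, hi)


def _mom_alpha(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments NB dispersion from Pearson-type residuals."""
    dof = max(len(y) - n_params, 1)
    num = np.sum(((y - mu) ** 2 - mu) / mu**2)
    return float(max(num / dof, 0.0))


def fit_distance_trend(pairs: PairTable, spline_df: int = 8) -> DistanceTrend:
    """Fit ``log E[y|d] = b0 + f(d)`` with a negative-binomial GLM.

    Dispersion is estimated by profile maximum likelihood with a
    method-of-moments starting value; if the NB fit fails to converge the
    model falls back to Poisson with a warning.
    """
    y = np.asarray(pairs.y, dtype=float)
    if pairs.n < 50:
        raise ValueError("need at least 50 pairs to fit the distance trend")
    if not (y > 0).any():
        raise ValueError("all counts are zero; cannot fit distance trend")
    design, knots, d_range = _spline_design(pairs.d, spline_df)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, design, family=sm.families.Poisson()).fit(maxiter=100)
        alpha = _mom_alpha(y, pois.mu, design.shape[1])
        if alpha <= 1e-8:
            return DistanceTrend(knots, np.asarray(pois.params), 0.0, "poisson", d_range)
        try:
            res = pois
            for _ in range(4):
                res_new = sm.GLM(
                    y, design, family=sm.families.NegativeBinomial(alpha=alpha)
                ).fit(maxiter=100, start_params=res.params)
                alpha_new = _mom_alpha(y, res_new.mu, design.shape[1])
                res = res_new
                if alpha_new <= 1e-8 or abs(alpha_new - alpha) < 1e-3 * alpha:
                    alpha = max(alpha_new, 1e-8)
                    break
                alpha = alpha_new
            # profile-ML refinement of the dispersion at the fitted mean
            from scipy.optimize import minimize_scalar
            from scipy.special import gammaln

            mu = np.maximum(res.mu, 1e-12)

            def negll(log_a):
                a = np.exp(log_a)
                r = 1.0 / a
                return -np.sum(
                    gammaln(y + r)
                    - gammaln(r)
                    + r * np.log(r / (r + mu))
                    + y * np.log(mu / (r + mu))
                )

            opt = minimize_scalar(
                negll, bounds=(np.log(alpha) - 3, np.log(alpha) + 3), method="bounded"
            )
            if opt.success and np.isfinite(opt.fun):
                alpha = float(np.exp(opt.x))
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite NB parameters")
            return DistanceTrend(knots, np.asarray(res.params), alpha, "nb", d_range)
        except Exception:
            warnings.warn(
                "negative-binomial trend fit failed; falling back to Poisson",
                RuntimeWarning,
            )
            return DistanceTrend(knots, np.asarray(pois.params), 0.0, "poisson", d_range)


def compute_residuals(
    pairs: PairTable, trend: DistanceTrend, pseudocount: float | None = None
) -> np.ndarray:
    """Log-scale residuals ``z = log(y + c) - fitted log-scale trend``.

    The trend term is the model-implied expected log count
    (:meth:`DistanceTrend.expected_log`), so residuals are mean-zero at
    every distance under the fitted null.  The pseudocount ``c`` defaults
    to 1 for raw counts and half the smallest positive value for
    normalized data, guaranteeing finiteness.
    """
    y = np.asarray(pairs.y, dtype=float)
    if pseudocount is None:
        if pairs.normalized:
            pos = y[y > 0]
            pseudocount = float(pos.min()) / 2 if len(pos) else 1.0
        else:
            pseudocount = 1.0
    return np.log(y + pseudocount) - trend.expected_log(pairs.d, pseudocount)


# ---------------------------------------------------------------------------
# lasso prefilter


def prefilter_lasso(
    z: np.ndarray,
    design: InsulationDesign,
    threshold: float = 0.2,
    trigger: int = 5000,
    seed: int = 1789,
    force: bool = False,
) -> np.ndarray:
    """Candidate bins whose CV-lasso coefficient magnitude exceeds threshold.

    Applied only when the candidate count exceeds ``trigger`` (or when
    forced); below the trigger the full candidate set is returned
    unchanged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if design.n_candidates <= trigger and not force:
        return design.candidate_bins.copy()
    from sklearn.linear_model import LassoCV

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(cv=10, random_state=seed, alphas=50, max_iter=5000)
        model.fit(design.X, z)
    keep = design.candidate_bins[np.abs(model.coef_) > threshold]
    if len(keep) == 0:
        warnings.warn("lasso prefilter selected no bins", RuntimeWarning)
    return keep


# ---------------------------------------------------------------------------
# L0 best-subset selection


@dataclass
class InsulationFit:
    """Sparse per-bin insulation estimates (exact zeros off-support)."""

    beta: np.ndarray  # length p; exact zeros for unselected bins
    intercept: float
    lambda_: float
    cv_curve: pd.DataFrame  # columns: lambda, cv_mse
    candidate_bins: np.ndarray
    bins: BinTable | None = None
    labels: np.ndarray | None = None  # set by classify_borders

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.beta)

    def to_frame(self) -> pd.DataFrame:
        """BED-like per-bin table (1-based bin ids in the `bin` column)."""
        labels = self.labels
        if labels is None:
            labels = classify_borders(self).labels
        df = pd.DataFrame(
            {
                "bin": np.arange(self.p) + 1,
                "beta": self.beta,
                "class": np.where(
                    self.beta < 0, "border", np.where(self.beta > 0, "facilitator", "null")
                ),
                "tier": labels,
            }
        )
        if self.bins is not None:
            df.insert(0, "chrom", self.bins.chrom)
            df.insert(1, "start", self.bins.starts)
            df.insert(2, "end", self.bins.ends)
        return df

    def border_regions(self) -> list[tuple[int, int]]:
        """Selected border bins merged when <= 1 bin apart (human-readable)."""
        borders = np.flatnonzero(self.beta < 0)
        regions: list[tuple[int, int]] = []
        for b in borders:
            if regions and b - regions[-1][1] <= 2:
                regions[-1] = (regions[-1][0], b)
            else:
                regions.append((b, b))
        return regions


class _CenteredProblem:
    """Centered Gram-form sufficient statistics for L0 least squares."""

    def __init__(self, X: sp.csr_matrix, z: np.ndarray, rows: np.ndarray | None = None):
        if rows is not None:
            X = X[rows]
            z = z[rows]
        self.n = X.shape[0]
        self.k = X.shape[1]
        self.xbar = np.asarray(X.mean(axis=0)).ravel()
        self.zbar = float(z.mean()) if self.n else 0.0
        G = np.asarray((X.T @ X).todense(), dtype=float)
        self.G = G - self.n * np.outer(self.xbar, self.xbar)
        self.Xtz = np.asarray(X.T @ z).ravel() - self.n * self.xbar * self.zbar
        zc = z - self.zbar
        self.SSz = float(zc @ zc)
        self.diag = np.diag(self.G).copy()

    def objective(self, beta: np.ndarray, lam: float) -> float:
        sse = self.SSz - 2 * beta @ self.Xtz + beta @ self.G @ beta
        return sse / self.n + lam * np.count_nonzero(beta)

    def sse(self, beta: np.ndarray) -> float:
        return self.SSz - 2 * beta @ self.Xtz + beta @ self.G @ beta


@numba.njit(cache=True)
def _cd_sweeps(G, Xtz, diag, n, lam, beta, active, max_sweeps):  # pragma: no cover
    k = beta.shape[0]
    Gb = G @ beta
    for _ in range(max_sweeps):
        changed = False
        for j in range(k):
            if not active[j]:
                continue
            cj = Xtz[j] - Gb[j] + diag[j] * beta[j]
            if cj * cj / (diag[j] * n) > lam:
                newval = cj / diag[j]
            else:
                newval = 0.0
            if newval != beta[j]:
                delta = newval - beta[j]
                for t in range(k):
                    Gb[t] += G[t, j] * delta
                beta[j] = newval
                changed = True
        if not changed:
            break
    return beta


def _cd_l0(prob: _CenteredProblem, lam: float, beta0=None, max_sweeps: int = 200):
    """Cyclic coordinate descent with hard L0 thresholding, then OLS polish."""
    k = prob.k
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    active = prob.diag > 1e-12
    beta = _cd_sweeps(
        prob.G, prob.Xtz, prob.diag, float(prob.n), lam, beta, active, max_sweeps
    )
    # polish: exact OLS on the final support
    supp = np.flatnonzero(beta)
    if len(supp):
        Gs = prob.G[np.ix_(supp, supp)]
        bs, *_ = np.linalg.lstsq(Gs, prob.Xtz[supp], rcond=None)
        beta = np.zeros(k)
        beta[supp] = bs
    return beta


def _swap_search(prob: _CenteredProblem, lam: float, beta: np.ndarray, max_rounds: int = 20):
    """Local swap moves: try replacing each selected coordinate by the best
    alternative (given the rest); accept improving swaps and re-polish.
    Escapes the order-dependent local minima of plain cyclic CD."""
    beta = beta.copy()
    ok = prob.diag > 1e-12
    safe_diag = np.where(ok, prob.diag, 1.0)
    for _ in range(max_rounds):
        improved = False
        Gb = prob.G @ beta
        sse = prob.sse(beta)
        for j in np.flatnonzero(beta):
            # residual correlations with coordinate j removed (O(k))
            c = prob.Xtz - Gb + beta[j] * prob.G[:, j]
            sse_base = sse + beta[j] ** 2 * prob.diag[j] + 2 * beta[j] * (
                prob.Xtz[j] - Gb[j]
            )
            gain = np.where(ok, c**2 / safe_diag, -np.inf)
            gain[beta != 0] = -np.inf  # members other than j stay
            gain[j] = c[j] ** 2 / safe_diag[j] if ok[j] else -np.inf
            l = int(np.argmax(gain))
            if l == j or gain[l] <= 0:
                continue
            if (sse_base - gain[l]) < sse - 1e-12:
                cand = beta.copy()
                cand[j] = 0.0
                cand[l] = c[l] / prob.diag[l]
                beta = _cd_l0(prob, lam, beta0=cand)
                Gb = prob.G @ beta
                sse = prob.sse(beta)
                improved = True
        if not improved:
            break
    return beta


def _cd_l0_multistart(prob, lam, warm=None, n_restarts=2, seed=0):
    candidates = [None]
    if warm is not None:
        candidates.append(warm)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        init = np.zeros(prob.k)
        if prob.k:
            picks = rng.choice(prob.k, size=min(5, prob.k), replace=False)
            ok = prob.diag[picks] > 1e-12
            init[picks[ok]] = prob.Xtz[picks[ok]] / prob.diag[picks[ok]]
        candidates.append(init)
    best, best_obj = None, np.inf
    for c in candidates:
        b = _cd_l0(prob, lam, beta0=c)
        b = _swap_search(prob, lam, b)
        obj = prob.objective(b, lam)
        if obj < best_obj - 1e-12:
            best, best_obj = b, obj
    return best


def _exhaustive_l0(prob: _CenteredProblem, lam: float) -> np.ndarray:
    """Exact best-subset minimizer by enumeration (small candidate sets).

    Subset OLS solutions are independent of lambda, so they are computed
    once per problem and cached; each call only re-scores the penalty.
    """
    k = prob.k
    cache = getattr(prob, "_enum_cache", None)
    if cache is None:
        cache = [((), np.zeros(0), prob.SSz)]
        for size in range(1, k + 1):
            for supp in itertools.combinations(range(k), size):
                s = np.array(supp)
                if (prob.diag[s] <= 1e-12).any():
                    continue
                Gs = prob.G[np.ix_(s, s)]
                bs, *_ = np.linalg.lstsq(Gs, prob.Xtz[s], rcond=None)
                sse = prob.SSz - 2 * bs @ prob.Xtz[s] + bs @ Gs @ bs
                cache.append((supp, bs, float(sse)))
        prob._enum_cache = cache
    best_beta = np.zeros(k)
    best_obj = np.inf
    for supp, bs, sse in cache:
        obj = sse / prob.n + lam * len(supp)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_beta = np.zeros(k)
            best_beta[list(supp)] = bs
    return best_beta


def _solve(prob, lam, algorithm, warm=None, exhaustive_limit=12, seed=0, fast=False):
    if algorithm == "exhaustive" or (algorithm == "auto" and prob.k <= exhaustive_limit):
        return _exhaustive_l0(prob, lam)
    if fast:  # path fits inside CV: plain CD with warm start
        return _cd_l0(prob, lam, beta0=warm)
    return _cd_l0_multistart(prob, lam, warm=warm, seed=seed)


def _lambda_grid(prob: _CenteredProblem, n_lambda: int) -> np.ndarray:
    ok = prob.diag > 1e-12
    if not ok.any() or prob.n == 0:
        return np.array([1.0])
    lam_max = float(np.max(prob.Xtz[ok] ** 2 / (prob.diag[ok] * prob.n)))
    lam_max = max(lam_max, 1e-12) * 1.001
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def fit_best_subset(
    z: np.ndarray,
    design: InsulationDesign,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    cv_folds: int = 10,
    seed: int = 1789,
    algorithm: str = "auto",
    bins: BinTable | None = None,
    max_support: int = 100,
    selection_rule: str = "1se",
) -> InsulationFit:
    """L0-penalized least squares of residuals on the insulation design.

    lambda is chosen to minimize the mean K-fold cross-validated MSE over a
    log-spaced, data-driven grid (descending; ties go to the sparser,
    larger-lambda model).  Unselected coefficients are exact zeros.  Fold
    assignment is a seeded shuffle, deterministic given ``seed``.

    ``algorithm``: "auto" (exhaustive for <= 12 candidates, coordinate
    descent with restarts otherwise), "cd", or "exhaustive".
    ``max_support`` caps the model size along the lambda path (grid points
    past the cap are never selected), bounding runtime on dense solutions.
    ``selection_rule``: "1se" (default) picks the largest lambda whose
    mean CV MSE is within one standard error of the minimum — the
    standard sparsity-favoring rule, which keeps the selected model empty
    when no variable carries real signal; "min" picks the exact minimum.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    p = design.p
    z = np.asarray(z, dtype=float)
    if design.n_candidates == 0:
        return InsulationFit(
            beta=np.zeros(p),
            intercept=float(z.mean()) if len(z) else 0.0,
            lambda_=np.inf,
            cv_curve=pd.DataFrame({"lambda": [], "cv_mse": []}),
            candidate_bins=np.array([], dtype=int),
            bins=bins,
        )
    X = design.X.tocsr()
    n = X.shape[0]
    full = _CenteredProblem(X, z)
    if lambda_grid is None:
        lambda_grid = _lambda_grid(full, n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(n) % cv_folds

    cv_mse_f = np.full((cv_folds, len(lambda_grid)), np.inf)
    for f in range(cv_folds):
        train = np.flatnonzero(fold_id != f)
        val = np.flatnonzero(fold_id == f)
        prob = _CenteredProblem(X, z, rows=train)
        Xval = X[val]
        zval = z[val]
        warm = None
        for li, lam in enumerate(lambda_grid):
            beta = _solve(prob, lam, algorithm, warm=warm, seed=seed + f, fast=True)
            warm = beta
            b0 = prob.zbar - prob.xbar @ beta
            pred = b0 + np.asarray(Xval @ beta).ravel()
            cv_mse_f[f, li] = np.mean((zval - pred) ** 2)
            if np.count_nonzero(beta) > max_support:
                break
    cv_mse = cv_mse_f.mean(axis=0)  # inf past any fold's support cap

    min_li = int(np.argmin(cv_mse))  # first index = largest lambda on ties
    if selection_rule == "1se":
        finite = np.isfinite(cv_mse_f[:, min_li])
        se = float(cv_mse_f[finite, min_li].std(ddof=1) / np.sqrt(finite.sum()))
        best_li = int(np.argmax(cv_mse <= cv_mse[min_li] + se))
    elif selection_rule == "min":
        best_li = min_li
    else:
        raise ValueError("selection_rule must be 'min' or '1se'")
    lam = float(lambda_grid[best_li])
    beta_c = _solve(full, lam, algorithm, seed=seed)
    intercept = full.zbar - full.xbar @ beta_c
    beta = np.zeros(p)
    beta[design.candidate_bins] = beta_c
    return InsulationFit(
        beta=beta,
        intercept=float(intercept),
        lambda_=lam,
        cv_curve=pd.DataFrame({"lambda": lambda_grid, "cv_mse": cv_mse}),
        candidate_bins=design.candidate_bins.copy(),
        bins=bins,
    )


# ---------------------------------------------------------------------------
# classification and pipeline


def classify_borders(
    fit: InsulationFit, strong: float = -2.0, moderate: float = -1.2
) -> InsulationFit:
    """Tier border bins by effect size; label facilitators and nulls.

    Borders: beta < strong -> "strong"; strong <= beta < moderate ->
    "moderate"; moderate <= beta < 0 -> "weak".  beta > 0 ->
    "facilitator"; beta == 0 -> "null".
    """
    if not (strong < moderate < 0):
        raise ValueError("need strong < moderate < 0")
    b = fit.beta
    labels = np.full(fit.p, "null", dtype=object)
    labels[b > 0] = "facilitator"
    labels[(b < 0) & (b >= moderate)] = "weak"
    labels[(b < moderate) & (b >= strong)] = "moderate"
    labels[b < strong] = "strong"
    fit.labels = labels
    return fit


def run_sim(
    m: ContactMatrix,
    max_gap: int = 10,
    spline_df: int = 8,
    n_lambda: int = 50,
    cv_folds: int = 10,
    seed: int = 1789,
    prefilter_threshold: float = 0.2,
    prefilter_trigger: int = 5000,
    force_prefilter: bool = False,
    strong: float = -2.0,
    moderate: float = -1.2,
    algorithm: str = "auto",
    selection_rule: str = "1se",
) -> InsulationFit:
    """Full SIM pipeline on one chromosome.

    pairs -> distance trend -> residuals -> (lasso prefilter) ->
    L0 best subset with CV-selected lambda -> border classification.
    Masked bins are never candidates; pairs touching them are dropped
    before the trend fit.
    """
    pairs = build_pair_table(m, max_gap=max_gap)
    trend = fit_distance_trend(pairs, spline_df=spline_df)
    z = compute_residuals(pairs, trend)
    candidates = np.flatnonzero(~m.mask)
    design = build_insulation_design(pairs, candidate_bins=candidates)
    kept = prefilter_lasso(
        z,
        design,
        threshold=prefilter_threshold,
        trigger=prefilter_trigger,
        seed=seed,
        force=force_prefilter,
    )
    if len(kept) < design.n_candidates:
        design = design.restrict(kept)
    fit = fit_best_subset(
        z,
        design,
        n_lambda=n_lambda,
        cv_folds=cv_folds,
        seed=seed,
        algorithm=algorithm,
        bins=m.bins,
        selection_rule=selection_rule,
    )
    return classify_borders(fit, strong=strong, moderate=moderate)
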