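"""Model-II (SMA) and Model-I (OLS / species random-intercept) regression on log-log data.

Allometric lines are established with standardized major axis (SMA) regression,
the symmetric Model-II estimator whose slope is sign(r)·sd(y)/sd(x); prediction
uses Model-I fits (ordinary least squares, or a Gaussian mixed model with a
per-species random intercept) because only those yield prediction intervals for
a new observation.  Everything here operates on natural-log transformed
variables; back-transformation bias is removed with the lognormal correction
factor CF = exp(σ̂²/2).

All estimators are implemented directly (SMA with grouped common-slope
likelihood-ratio tests has no Python equivalent; the one-random-intercept mixed
model is fitted by profiling the likelihood over the variance ratio), and the
mixed model is cross-checked against an independent general-purpose
implementation in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LogLogDataset",
    "SMAGroupFit",
    "SMAFit",
    "ModelOneFit",
    "GrubbsResult",
    "DegenerateDataError",
    "ConvergenceError",
    "fit_sma",
    "fit_ols",
    "fit_random_intercept",
    "select_model",
    "grubbs_filter",
    "grubbs_critical_value",
    "correction_factor",
    "profile_ci_sigma_species",
]


class DegenerateDataError(ValueError):
    """Raised when a dataset has too few points or zero variance to fit."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails; such models are discarded upstream."""


@dataclass
class LogLogDataset:
    """Paired natural-log predictor/response values with optional grouping.

    ``x`` is ln(predictor in m²) (e.g. ln A_CB or ln A_CB_Est), ``y`` is
    ln(response) (leaf area in m² or leaf dry mass in kg).  ``group`` is a
    coarse categorical (plant functional type) used for grouped SMA fits and
    optional fixed effects; ``species`` labels drive the random intercept.
    """

    x: np.ndarray
    y: np.ndarray
    group: Optional[np.ndarray] = None
    species: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 3:
            raise DegenerateDataError("need at least 3 points")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("x and y must be finite (filter missing values first)")
        for name in ("group", "species"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != self.x.shape:
                    raise ValueError(f"{name} must match x in length")
                setattr(self, name, v)

    @property
    def n(self) -> int:
        return self.x.size

    def subset(self, mask: np.ndarray) -> "LogLogDataset":
        return LogLogDataset(
            self.x[mask],
            self.y[mask],
            None if self.group is None else self.group[mask],
            None if self.species is None else self.species[mask],
        )


# ---------------------------------------------------------------------------
# SMA (Model II)
# ---------------------------------------------------------------------------


@dataclass
class SMAGroupFit:
    group: str
    n: int
    slope: float
    slope_ci95: Tuple[float, float]
    elevation: float            # response at predictor = 1 m² (exp of intercept)
    elevation_ci95: Tuple[float, float]
    r2: float
    intercept_ln: float         # ln-scale intercept
    x_mean: float
    residual_var: float         # ln-scale residual variance about the SMA line
    slope_var: float


@dataclass
class SMAFit:
    """Grouped SMA fit with common-slope test and pairwise elevation comparisons.

    ``common_slope_p`` is the probability from the likelihood-ratio test that
    all groups share one slope (χ² with groups−1 df); ``pairwise_elevation``
    maps group pairs to Sidak-corrected p-values for equal elevation, computed
    at the common slope (populated only when the slopes are homogeneous at the
    5% level and more than one group is present).
    """

    groups: Dict[str, SMAGroupFit]
    common_slope: Optional[float] = None
    common_slope_p: Optional[float] = None
    pairwise_elevation: Dict[Tuple[str, str], float] = field(default_factory=dict)
    robust: bool = False

    def __getitem__(self, g: str) -> SMAGroupFit:
        return self.groups[g]

    @property
    def single(self) -> SMAGroupFit:
        """The only group's fit (convenience for ungrouped data)."""
        (fit,) = self.groups.values()
        return fit


def _huber_moments(x: np.ndarray, y: np.ndarray, k: float = 1.345,
                   tol: float = 1e-8, max_iter: int = 50):
    """Huber-weighted means/variances/covariance of (x, y).

    Weights w_i = min(1, k/d_i) with d_i the bivariate standardized distance
    under the current moment estimates; iterated to convergence.  Falls back to
    classical moments if the weighted covariance degenerates.
    """
    w = np.ones_like(x)
    prev = None
    cur = None
    for _ in range(max_iter):
        sw = w.sum()
        mx, my = np.sum(w * x) / sw, np.sum(w * y) / sw
        dx, dy = x - mx, y - my
        denom = sw - (w ** 2).sum() / sw  # unbiased-ish weighted denominator
        vx = np.sum(w * dx * dx) / denom
        vy = np.sum(w * dy * dy) / denom
        cxy = np.sum(w * dx * dy) / denom
        cur = (mx, my, vx, vy, cxy)
        if prev is not None and max(abs(a - b) for a, b in zip(cur, prev)) < tol:
            break
        prev = cur
        det = vx * vy - cxy * cxy
        if det <= 0 or vx <= 0 or vy <= 0:
            break
        # standardized distance under current bivariate scatter
        q = (dx * dx * vy - 2 * dx * dy * cxy + dy * dy * vx) / det
        d = np.sqrt(np.maximum(q, 1e-300))
        scale = math.sqrt(2.0)  # E[d] ≈ sqrt(2) for bivariate normal
        w = np.minimum(1.0, k * scale / d)
    return cur


def _group_moments(x: np.ndarray, y: np.ndarray, robust: bool):
    if robust:
        return _huber_moments(x, y)
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    cxy = np.cov(x, y, ddof=1)[0, 1]
    return mx, my, vx, vy, cxy


def _sma_one_group(x, y, robust: bool, alpha: float, label: str) -> SMAGroupFit:
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"group {label!r}: need ≥ 3 points, got {n}")
    use_robust = robust
    if robust and n < 5:
        warnings.warn(
            f"group {label!r}: robust SMA needs ≥ 5 points (n={n}); "
            "falling back to standard SMA",
            stacklevel=3,
        )
        use_robust = False
    mx, my, vx, vy, cxy = _group_moments(x, y, use_robust)
    if vx <= 0 or vy <= 0:
        raise DegenerateDataError(f"group {label!r}: zero variance in x or y")
    r = cxy / math.sqrt(vx * vy)
    r = min(1.0, max(-1.0, r))
    sign = -1.0 if r < 0 else 1.0
    b = sign * math.sqrt(vy / vx)
    a = my - b * mx

    # slope CI: b*(sqrt(B+1) ± sqrt(B)),  B = F_{1,n-2;1-α}(1-r²)/(n-2)
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r * r) / (n - 2)
    lo = b * (math.sqrt(B + 1) - math.sqrt(B))
    hi = b * (math.sqrt(B + 1) + math.sqrt(B))
    slope_ci = (min(lo, hi), max(lo, hi))

    # residual variance about the SMA line, with an (n-2)-type correction
    res_var = max(vy - 2 * b * cxy + b * b * vx, 0.0) * (n - 1) / (n - 2)
    slope_var = b * b * (1 - r * r) / (n - 2)
    int_var = res_var / n + mx * mx * slope_var
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    elev_ci = (math.exp(a - t * math.sqrt(int_var)), math.exp(a + t * math.sqrt(int_var)))

    return SMAGroupFit(
        group=label, n=n, slope=b, slope_ci95=slope_ci,
        elevation=math.exp(a), elevation_ci95=elev_ci, r2=r * r,
        intercept_ln=a, x_mean=mx, residual_var=res_var, slope_var=slope_var,
    )


def _residual_fitted_corr2(b: float, mom) -> float:
    """Squared correlation between SMA residual (y−bx) and fitted (y+bx) axes."""
    _, _, vx, vy, cxy = mom
    num = vy - b * b * vx
    den = (vy - 2 * b * cxy + b * b * vx) * (vy + 2 * b * cxy + b * b * vx)
    if den <= 0:
        return 1.0
    return min(num * num / den, 1.0)


def _common_slope(moments: Dict[str, tuple], ns: Dict[str, int]) -> Tuple[float, float]:
    """Common SMA slope and the LR statistic −Σ n_i ln(1 − r_i²(b̂))."""

    def negll(logb: float, sign: float) -> float:
        b = sign * math.exp(logb)
        return sum(-ns[g] * math.log(max(1 - _residual_fitted_corr2(b, m), 1e-12))
                   for g, m in moments.items())

    # allometric slopes share the sign of the pooled covariance
    sign = 1.0 if sum(m[4] for m in moments.values()) >= 0 else -1.0
    mags = [math.sqrt(m[3] / m[2]) for m in moments.values()]
    lo, hi = math.log(min(mags)) - 2.0, math.log(max(mags)) + 2.0
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), args=(sign,),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return sign * math.exp(res.x), res.fun


def fit_sma(d: LogLogDataset, robust: bool = False, alpha: float = 0.05) -> SMAFit:
    """Fit SMA lines, per group when ``d.group`` is set, pooled otherwise.

    With more than one group the likelihood-ratio test for a common slope is
    run (χ², groups − 1 df); when slopes are homogeneous at ``alpha`` the
    elevations are compared pairwise at the common slope with Sidak-corrected
    p-values.
    """
    labels = d.group if d.group is not None else np.array(["all"] * d.n)
    fits: Dict[str, SMAGroupFit] = {}
    moments: Dict[str, tuple] = {}
    ns: Dict[str, int] = {}
    for g in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        mask = labels == g
        x, y = d.x[mask], d.y[mask]
        fits[str(g)] = _sma_one_group(x, y, robust, alpha, str(g))
        use_robust = robust and x.size >= 5
        moments[str(g)] = _group_moments(x, y, use_robust)
        ns[str(g)] = int(mask.sum())

    out = SMAFit(groups=fits, robust=robust)
    if len(fits) < 2:
        return out

    b_com, lr = _common_slope(moments, ns)
    out.common_slope = b_com
    out.common_slope_p = float(stats.chi2.sf(lr, len(fits) - 1))

    if out.common_slope_p > alpha:
        # elevation comparison at the common slope; common-slope variance from
        # inverse-variance pooling of the per-group slope variances
        inv = sum(1.0 / f.slope_var for f in fits.values())
        var_bc = 1.0 / inv
        m = len(fits) * (len(fits) - 1) // 2
        keys = list(fits)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                fi, fj = fits[keys[i]], fits[keys[j]]
                zi = fi.intercept_ln + (fi.slope - b_com) * fi.x_mean
                zj = fj.intercept_ln + (fj.slope - b_com) * fj.x_mean
                var = (fi.residual_var / fi.n + fj.residual_var / fj.n
                       + (fi.x_mean - fj.x_mean) ** 2 * var_bc)
                z = (zi - zj) / math.sqrt(var)
                p = 2 * stats.norm.sf(abs(z))
                p_sidak = 1.0 - (1.0 - p) ** m
                out.pairwise_elevation[(keys[i], keys[j])] = float(min(p_sidak, 1.0))
    return out


# ---------------------------------------------------------------------------
# Model I: OLS and species random-intercept mixed model
# ---------------------------------------------------------------------------


@dataclass
class ModelOneFit:
    """A fitted Model-I regression on the ln scale.

    ``params`` starts with (intercept, slope on ln x); any further entries are
    group fixed-effect contrasts.  ``sigma_species`` is the random-intercept
    standard deviation (None for plain OLS).  ``aic`` always comes from the
    full maximum-likelihood fit so it is comparable across candidates;
    variance components of the mixed model are REML estimates.
    """

    kind: str                      # "ols" or "lmm"
    n: int
    param_names: List[str]
    params: np.ndarray
    cov_params: np.ndarray
    residual_sd: float             # ln-scale
    sigma_species: Optional[float]
    aic: float
    loglik_ml: float
    cf: float
    x_mean: float
    x_ss: float                    # Σ(x − x̄)², used by the exact OLS PI
    converged: bool = True

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def intercept_se(self) -> float:
        return float(math.sqrt(self.cov_params[0, 0]))

    @property
    def slope_se(self) -> float:
        return float(math.sqrt(self.cov_params[1, 1]))

    @property
    def n_parameters(self) -> int:
        """Count entering the AIC (fixed effects + variance components)."""
        return len(self.params) + (1 if self.kind == "ols" else 2)

    @property
    def elevation(self) -> float:
        return math.exp(self.intercept)

    def predict_ln(self, u) -> np.ndarray:
        """Point prediction of ln(response) at ln-predictor ``u`` (population level)."""
        u = np.asarray(u, dtype=float)
        return self.intercept + self.slope * u

    def pi_halfwidth(self, u) -> np.ndarray:
        """Half-width ΔPI of the 95% prediction interval for ln(response) at ``u``.

        OLS uses the exact t-based formula
        ``t·s·sqrt(1 + 1/n + (u − x̄)²/Sxx)``; the mixed model uses the normal
        quantile with variance σ² + σ_b² + Var(fixed prediction), i.e. the
        interval for a tree of a new, unobserved species.
        """
        u = np.asarray(u, dtype=float)
        if self.kind == "ols":
            t = stats.t.ppf(0.975, self.n - 2)
            return t * self.residual_sd * np.sqrt(
                1.0 + 1.0 / self.n + (u - self.x_mean) ** 2 / self.x_ss
            )
        z = stats.norm.ppf(0.975)
        x0 = np.stack([np.ones_like(u), u] + [np.zeros_like(u)] * (len(self.params) - 2))
        var_fixed = np.einsum("in,ij,jn->n", x0, self.cov_params, x0)
        var = self.residual_sd ** 2 + (self.sigma_species or 0.0) ** 2 + var_fixed
        return z * np.sqrt(var)

    def slope_ci95(self) -> Tuple[float, float]:
        q = stats.t.ppf(0.975, self.n - 2) if self.kind == "ols" else stats.norm.ppf(0.975)
        return (self.slope - q * self.slope_se, self.slope + q * self.slope_se)

    def intercept_ci95(self) -> Tuple[float, float]:
        q = stats.t.ppf(0.975, self.n - 2) if self.kind == "ols" else stats.norm.ppf(0.975)
        return (self.intercept - q * self.intercept_se, self.intercept + q * self.intercept_se)


def _design(d: LogLogDataset, include_group: bool) -> Tuple[np.ndarray, List[str]]:
    cols = [np.ones(d.n), d.x]
    names = ["intercept", "ln_x"]
    if include_group:
        if d.group is None:
            raise ValueError("include_group=True but dataset has no group labels")
        levels = list(dict.fromkeys(d.group.tolist()))
        for lv in levels[1:]:  # first level is the reference
            cols.append((d.group == lv).astype(float))
            names.append(f"group[{lv}]")
    return np.column_stack(cols), names


def fit_ols(d: LogLogDataset, include_group: bool = False) -> ModelOneFit:
    """Ordinary least squares of ln(y) on ln(x) (optionally + group dummies)."""
    X, names = _design(d, include_group)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p or d.x.var() == 0:
        raise DegenerateDataError("design matrix is rank-deficient (zero x variance?)")
    beta, *_ = np.linalg.lstsq(X, d.y, rcond=None)
    resid = d.y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    if df <= 0:
        raise DegenerateDataError("not enough points for OLS")
    s2 = rss / df
    cov = s2 * np.linalg.inv(X.T @ X)
    sigma2_ml = rss / n
    # Gaussian log-likelihood at the MLE; guard exact fits
    ll = (-0.5 * n * (math.log(2 * math.pi * sigma2_ml) + 1)
          if sigma2_ml > 0 else math.inf)
    aic = -2 * ll + 2 * (p + 1)
    s = math.sqrt(s2)
    return ModelOneFit(
        kind="ols", n=n, param_names=names, params=beta, cov_params=cov,
        residual_sd=s, sigma_species=None, aic=aic, loglik_ml=ll,
        cf=correction_factor(s), x_mean=float(d.x.mean()),
        x_ss=float(((d.x - d.x.mean()) ** 2).sum()),
    )


def _lmm_profile(lam: float, X: np.ndarray, y: np.ndarray,
                 blocks: List[np.ndarray]):
    """GLS quantities at variance ratio λ = σ_b²/σ² with V = I + λ Z Z'."""
    p = X.shape[1]
    A = np.zeros((p, p))
    c = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for idx in blocks:
        Xg, yg = X[idx], y[idx]
        ng = len(idx)
        shrink = lam / (1.0 + lam * ng)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        A += Xg.T @ Xg - shrink * np.outer(sx, sx)
        c += Xg.T @ yg - shrink * sx * sy
        yty += yg @ yg - shrink * sy * sy
        logdet += math.log(1.0 + lam * ng)
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError as e:
        raise ConvergenceError(f"singular GLS system in mixed model: {e}") from e
    Q = max(yty - c @ beta, 0.0)
    return A, beta, Q, logdet


def _lmm_criterion(lam, X, y, blocks, reml: bool) -> float:
    n, p = X.shape
    A, _, Q, logdet = _lmm_profile(lam, X, y, blocks)
    if Q <= 0:
        # a perfect fit makes the Gaussian likelihood unbounded; flag the
        # model as degenerate rather than chasing the boundary
        return math.inf
    if reml:
        df = n - p
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return math.inf
        return df * math.log(2 * math.pi * Q / df) + logdet + logdetA + df
    return n * math.log(2 * math.pi * Q / n) + logdet + n


def fit_random_intercept(d: LogLogDataset, include_group: bool = False) -> ModelOneFit:
    """Gaussian mixed model ln(y) = β₀ + β₁·ln(x) [+ group] + u_species + ε.

    The species random intercept u ~ N(0, σ_b²) is the only random term.  The
    single variance ratio λ = σ_b²/σ² is profiled out of the (restricted)
    likelihood and optimised as a scalar; REML supplies the reported variance
    components, full ML the log-likelihood and AIC (so AICs are comparable
    across fixed-effect structures).  With one species the model degenerates
    exactly to :func:`fit_ols`.
    """
    if d.species is None:
        raise ValueError("dataset has no species labels")
    X, names = _design(d, include_group)
    n, p = X.shape
    species = np.asarray(d.species)
    levels = list(dict.fromkeys(species.tolist()))
    if len(levels) < 2:
        return fit_ols(d, include_group)
    blocks = [np.flatnonzero(species == lv) for lv in levels]

    def crit(t: float, reml: bool) -> float:
        return _lmm_criterion(math.exp(t), X, y_arr, blocks, reml)

    y_arr = d.y
    results = {}
    for reml in (True, False):
        res = optimize.minimize_scalar(
            crit, bounds=(-25.0, 12.0), args=(reml,), method="bounded",
            options={"xatol": 1e-8},
        )
        if not np.isfinite(res.fun):
            raise ConvergenceError("mixed-model likelihood did not converge")
        lam = math.exp(res.x)
        # boundary check: λ = 0 (no species variance)
        if _lmm_criterion(0.0, X, y_arr, blocks, reml) <= res.fun:
            lam = 0.0
        results[reml] = lam

    lam_reml = results[True]
    A, beta, Q, _ = _lmm_profile(lam_reml, X, y_arr, blocks)
    sigma2 = Q / (n - p)
    sigma_b = math.sqrt(lam_reml * sigma2)
    cov = sigma2 * np.linalg.inv(A)

    m2ll_ml = _lmm_criterion(results[False], X, y_arr, blocks, reml=False)
    k = p + 2
    aic = m2ll_ml + 2 * k

    s = math.sqrt(sigma2)
    return ModelOneFit(
        kind="lmm", n=n, param_names=names, params=beta, cov_params=cov,
        residual_sd=s, sigma_species=sigma_b, aic=aic, loglik_ml=-0.5 * m2ll_ml,
        cf=correction_factor(s), x_mean=float(d.x.mean()),
        x_ss=float(((d.x - d.x.mean()) ** 2).sum()),
    )


def profile_ci_sigma_species(d: LogLogDataset, include_group: bool = False,
                             alpha: float = 0.05) -> Tuple[float, float]:
    """Profile-likelihood CI for the species random-intercept sd σ_b.

    Inverts the ML deviance against the χ²(1) quantile.  The lower bound is 0
    when the profile cannot rise above the threshold at the boundary.
    """
    if d.species is None:
        raise ValueError("dataset has no species labels")
    X, _ = _design(d, include_group)
    species = np.asarray(d.species)
    levels = list(dict.fromkeys(species.tolist()))
    blocks = [np.flatnonzero(species == lv) for lv in levels]
    y = d.y

    def dev(lam: float) -> float:
        return _lmm_criterion(lam, X, y, blocks, reml=False)

    res = optimize.minimize_scalar(lambda t: dev(math.exp(t)),
                                   bounds=(-25.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = math.exp(res.x)
    d_min = min(res.fun, dev(0.0))
    if dev(0.0) <= res.fun:
        lam_hat = 0.0
    thresh = d_min + stats.chi2.ppf(1 - alpha, 1)

    def sigma_b_at(lam: float) -> float:
        _, _, Q, _ = _lmm_profile(lam, X, y, blocks)
        return math.sqrt(lam * Q / len(y))

    f = lambda lam: dev(lam) - thresh
    # lower bound
    if lam_hat == 0.0 or f(0.0) < 0:
        lo = 0.0
    else:
        lo = sigma_b_at(optimize.brentq(f, 1e-12, lam_hat, xtol=1e-12))
    # upper bound
    hi_lam = lam_hat if lam_hat > 0 else 1e-8
    upper = hi_lam
    for _ in range(200):
        upper *= 2.0
        if f(upper) > 0:
            break
    else:
        return (lo, math.inf)
    hi = sigma_b_at(optimize.brentq(f, hi_lam, upper, xtol=1e-12))
    return (lo, hi)


def select_model(candidates: Sequence[ModelOneFit]) -> ModelOneFit:
    """Minimum-AIC model among the converged candidates.

    Ties (ΔAIC < 1e-9) go to the model with fewer parameters.
    """
    ok = [c for c in candidates if c is not None and c.converged and math.isfinite(c.aic)]
    if not ok:
        raise ValueError("no successfully fitted candidate models")
    best = min(ok, key=lambda c: (c.aic, c.n_parameters))
    for c in ok:
        if c is not best and abs(c.aic - best.aic) < 1e-9 and c.n_parameters < best.n_parameters:
            best = c
    return best


# ---------------------------------------------------------------------------
# Outlier filtering and bias correction
# ---------------------------------------------------------------------------


@dataclass
class GrubbsResult:
    kept_indices: np.ndarray
    removed_indices: List[int]       # in removal order
    statistics: List[float]          # G at each iteration (incl. final non-removal)
    alpha: float

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(values: np.ndarray, alpha: float = 0.05) -> GrubbsResult:
    """Iteratively remove the most extreme value while Grubbs' G exceeds its critical value.

    G = max|v − mean| / sd with the sample sd (n−1 denominator).  Removal stops
    when no outlier remains, or fewer than 3 values are left.  Deterministic;
    ties broken by first occurrence.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise DegenerateDataError("Grubbs test needs a 1-D sample with n ≥ 3")
    active = list(range(v.size))
    removed: List[int] = []
    gs: List[float] = []
    while len(active) >= 3:
        sub = v[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        g = dev[k] / sd
        gs.append(float(g))
        if g > grubbs_critical_value(len(active), alpha):
            removed.append(active.pop(k))
        else:
            break
    return GrubbsResult(np.array(active, dtype=int), removed, gs, alpha)


def correction_factor(residual_sd: float) -> float:
    """Lognormal back-transformation bias correction CF = exp(σ̂²/2).

    A regression fitted on ln(y) predicts the median of y; multiplying the
    back-transformed prediction by CF recovers the arithmetic mean under
    lognormal residuals.  CF = 1 when the fit is exact.
    """
    if residual_sd < 0:
        raise ValueError("residual sd must be ≥ 0")
    return math.exp(residual_sd ** 2 / 2.0)
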