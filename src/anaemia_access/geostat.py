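"""Model-based geostatistics for severe-vs-other anaemia at admission.

The explanatory model is a Bernoulli-logit regression with a spatially
structured random effect at the enumeration-area (EA) level:

    Y_ik ~ Bernoulli(pi_ik)
    logit(pi_ik) = beta0 + sum_j beta_j x_ij + omega(s_k)

where omega is a zero-mean Gaussian process over EA centroids with Matern
covariance

    C(h) = sigma2 * 2^(1-nu)/Gamma(nu) * (kappa h)^nu * K_nu(kappa h)

(h Euclidean distance in metres, K_nu the modified Bessel function of the
second kind).  Because the number of EAs is at most a few thousand, the
process is represented exactly over the centroids — no mesh or SPDE
approximation.  Inference is a Laplace (Gaussian) approximation over the
joint (beta, omega) at fixed covariance hyperparameters; (sigma2, kappa)
are handled by evaluating the Laplace marginal likelihood on a log-spaced
grid and averaging the conditional fixed-effect posteriors with
marginal-likelihood weights, so hyperparameter uncertainty propagates into
the credible intervals (the same device the nested-Laplace family of
methods uses); nu is held fixed (default 1, the customary 2-D smoothness).
Fixed effects carry weakly informative normal(0, 10^2) priors.  Adjusted
odds ratios are the exponentiated posterior quantiles of the travel-time
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit, gammaln, kv
from scipy.stats import norm

__all__ = [
    "MaternParams",
    "ModelSpec",
    "PosteriorSummary",
    "GeostatError",
    "matern_covariance",
    "matern_covariance_matrix",
    "build_design",
    "univariate_screen",
    "ScreenResult",
    "deviance_residuals",
    "ea_mean_residuals",
    "empirical_variogram",
    "fit_spatial_logit",
    "adjusted_or_table",
]

TT_CLASS_ORDER = ["<30", "30-59", "60-89", ">=90"]


class GeostatError(RuntimeError):
    """Raised for invalid model inputs or failed inference."""


@dataclass(frozen=True)
class MaternParams:
    """Matern covariance hyperparameters.

    sigma2: marginal variance; kappa: inverse-range (1/metres); nu:
    smoothness.  At nu = 1/2 the covariance is exponential,
    sigma2 * exp(-kappa h).
    """

    sigma2: float
    kappa: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0 or self.kappa <= 0 or self.nu <= 0:
            raise GeostatError("require sigma2 >= 0, kappa > 0, nu > 0")


def matern_covariance(h, p: MaternParams):
    """Matern covariance at distance(s) h (metres); sigma2 at h = 0."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise GeostatError("distances must be non-negative")
    if p.sigma2 == 0:
        out = np.zeros_like(h)
        return out if out.ndim else 0.0
    kh = p.kappa * h
    with np.errstate(invalid="ignore"):
        out = (
            p.sigma2
            * np.exp(
                (1 - p.nu) * np.log(2.0)
                - gammaln(p.nu)
                + p.nu * np.log(np.where(kh > 0, kh, 1.0))
            )
            * kv(p.nu, np.where(kh > 0, kh, 1.0))
        )
    out = np.where(kh > 0, out, p.sigma2)
    return out if out.ndim else float(out)


def matern_covariance_matrix(
    coords: np.ndarray, p: MaternParams, jitter_frac: float = 1e-8
) -> np.ndarray:
    """Dense Matern covariance over centroid pairs, with diagonal jitter.

    The jitter added for factorisability is at most ``jitter_frac * sigma2``
    per the numerical contract; a matrix that still fails Cholesky raises.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d = squareform(pdist(coords)) if len(coords) > 1 else np.zeros((1, 1))
    cov = matern_covariance(d, p)
    if p.sigma2 > 0:
        cov = cov + jitter_frac * p.sigma2 * np.eye(len(coords))
        try:
            cholesky(cov, lower=True)
        except np.linalg.LinAlgError as exc:
            raise GeostatError("Matern covariance not positive definite after jitter") from exc
    return cov


# --------------------------------------------------------------------------
# design matrices and covariate screening
# --------------------------------------------------------------------------

_REFERENCE_LEVELS = {"tt_class": "<30", "nutrition": "well", "age_cat": "<1"}


def build_design(
    cohort: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; categoricals dummy-coded.

    Reference levels: travel class "<30" (the exposure contrast of
    interest), nutrition "well", age "<1"; otherwise the first sorted level.
    Numeric columns (PfPR) enter untransformed.
    """
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for cov in covariates:
        s = cohort[cov]
        if s.dtype.kind in "fiu" and s.nunique() > 2:
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(s.astype(str).unique())
            ref = _REFERENCE_LEVELS.get(cov, levels[0])
            if cov == "tt_class":
                levels = [lv for lv in TT_CLASS_ORDER if lv in levels]
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((s.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
    return np.column_stack(cols), names


@dataclass
class ScreenResult:
    selected: list[str]
    p_values: dict[str, float]
    flagged: list[str]  # separation / non-convergence, retained with warning


def univariate_screen(
    cohort: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.2,
    outcome: str = "severe",
    always_keep: tuple[str, ...] = ("tt_class",),
) -> ScreenResult:
    """Single-covariate logistic screens; keep candidates with Wald p < alpha.

    For a categorical candidate the minimum Wald p across non-reference
    levels decides.  The travel-time exposure is always retained.  A
    separated or non-converged fit flags the candidate and keeps it.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    selected, flagged = [], []
    p_values: dict[str, float] = {}
    for cov in candidates:
        X, names = build_design(cohort, [cov])
        if X.shape[1] < 2:
            warnings.warn(f"candidate {cov!r} has a single level; skipped", stacklevel=2)
            continue
        keep = cov in always_keep
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            pvals = fit.pvalues[1:]
            if not fit.mle_retvals.get("converged", True) or np.any(
                np.abs(fit.params) > 10
            ):
                flagged.append(cov)
                keep = True
            p = float(np.min(pvals))
        except Exception:
            flagged.append(cov)
            keep, p = True, np.nan
        p_values[cov] = p
        if keep or (np.isfinite(p) and p < alpha):
            selected.append(cov)
    for cov in always_keep:
        if cov not in selected and cov in cohort.columns:
            selected.append(cov)
    return ScreenResult(selected=selected, p_values=p_values, flagged=flagged)


# --------------------------------------------------------------------------
# variogram diagnostics
# --------------------------------------------------------------------------


def deviance_residuals(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial deviance residuals for Bernoulli outcomes."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    dev = -2 * (y * np.log(p) + (1 - y) * np.log(1 - p))
    return np.sign(y - p) * np.sqrt(dev)


def ea_mean_residuals(
    cohort: pd.DataFrame, covariates: list[str], outcome: str = "severe"
) -> pd.Series:
    """EA-mean deviance residuals from the non-spatial logistic fit."""
    X, _ = build_design(cohort, covariates)
    y = cohort[outcome].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    res = deviance_residuals(y, fit.predict(X))
    return pd.Series(res, index=cohort["ea_id"].to_numpy()).groupby(level=0).mean()


def empirical_variogram(
    values: np.ndarray, coords: np.ndarray, n_bins: int = 12
) -> pd.DataFrame:
    """Empirical semivariogram of per-EA values.

    gamma(h) = 0.5 * mean[(v_i - v_j)^2] over pairs whose separation falls
    in each of ``n_bins`` equal-width lag bins spanning (0, max distance/2].
    Bins without pairs report NaN semivariance.
    """
    values = np.asarray(values, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(values) < 2:
        raise GeostatError("need at least two locations for a variogram")
    d = pdist(coords)
    dv2 = pdist(values[:, None], metric="sqeuclidean")
    max_lag = d.max() / 2.0
    if not np.any(d <= max_lag):  # degenerate geometries (e.g. two EAs)
        max_lag = d.max()
    edges = np.linspace(0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges[1:-1])
    inside = d <= max_lag
    rows = []
    for b in range(n_bins):
        sel = inside & (idx == b)
        rows.append(
            {
                "lag_mid": 0.5 * (edges[b] + edges[b + 1]),
                "semivariance": 0.5 * dv2[sel].mean() if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# the spatial logit
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Specification of the spatial logistic model.

    covariates: cohort columns entering as fixed effects (travel class must
    be among them; reference "<30").  beta_prior_sd: sd of the normal prior
    on every fixed effect.  nu: fixed Matern smoothness.  sigma2_grid /
    kappa_grid: candidate hyperparameter values (None -> defaults built from
    the centroid geometry).  include_iid retains the admission-level
    Gaussian term (off by default: it is weakly identified under a
    Bernoulli likelihood).
    """

    covariates: list[str] = field(default_factory=lambda: ["tt_class"])
    outcome: str = "severe"
    beta_prior_sd: float = 10.0
    nu: float = 1.0
    sigma2_grid: np.ndarray | None = None
    kappa_grid: np.ndarray | None = None
    include_iid: bool = False
    iid_sd: float = 1.0
    max_newton: int = 50
    tol: float = 1e-8


@dataclass
class PosteriorSummary:
    names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    q025: np.ndarray
    q50: np.ndarray
    q975: np.ndarray
    sigma2: float
    kappa: float
    nu: float
    log_marginal: float
    n_newton: int
    grid: pd.DataFrame
    omega_mean: np.ndarray
    separation_flag: bool = False

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "sd": self.sd,
                "q025": self.q025,
                "q50": self.q50,
                "q975": self.q975,
                "aor": np.exp(self.q50),
                "aor_low": np.exp(self.q025),
                "aor_high": np.exp(self.q975),
            },
            index=self.names,
        )


def _laplace_fit(y, M, Q0, logdet_Q0, max_newton, tol, z0=None):
    """Newton MAP of the penalised Bernoulli log-posterior and its Laplace
    marginal likelihood.  Step-halving keeps the objective monotone."""
    n, q = M.shape
    z = np.zeros(q) if z0 is None else z0.copy()

    def objective(z):
        eta = M @ z
        # log-lik with stable log(1 + exp(eta))
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(z @ (Q0 @ z))

    obj = objective(z)
    n_iter = 0
    for n_iter in range(1, max_newton + 1):
        eta = M @ z
        p = expit(eta)
        grad = M.T @ (y - p) - Q0 @ z
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol * max(1.0, abs(obj)):
            break
        w = p * (1 - p)
        H = (M * w[:, None]).T @ M + Q0
        try:
            chol = cho_factor(H, lower=True)
        except np.linalg.LinAlgError as exc:
            raise GeostatError("Hessian not positive definite") from exc
        step = cho_solve(chol, grad)
        # step-halving: the penalised log-posterior must not decrease
        t = 1.0
        for _ in range(40):
            cand = z + t * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            t *= 0.5
        else:
            raise GeostatError(
                f"Newton step-halving failed; gradient norm {gnorm:.3g}"
            )
        z, obj = cand, cand_obj
    else:
        eta = M @ z
        p = expit(eta)
        gnorm = float(np.linalg.norm(M.T @ (y - p) - Q0 @ z))
        if gnorm > 1e-4 * max(1.0, abs(obj)):
            raise GeostatError(
                f"Newton did not converge in {max_newton} iterations; "
                f"gradient norm {gnorm:.3g}"
            )
    p = expit(M @ z)
    w = np.clip(p * (1 - p), 1e-12, None)
    H = (M * w[:, None]).T @ M + Q0
    chol = cho_factor(H, lower=True)
    logdet_H = 2.0 * np.log(np.diag(chol[0])).sum()
    log_marg = objective(z) + 0.5 * logdet_Q0 - 0.5 * logdet_H
    cov = cho_solve(chol, np.eye(len(z)))
    return z, cov, log_marg, n_iter


def _default_grids(coords: np.ndarray, spec: ModelSpec):
    sigma2_grid = (
        np.exp(np.linspace(np.log(1e-2), np.log(4.0), 7))
        if spec.sigma2_grid is None
        else np.asarray(spec.sigma2_grid, dtype=float)
    )
    if spec.kappa_grid is not None:
        kappa_grid = np.asarray(spec.kappa_grid, dtype=float)
    else:
        d = pdist(np.atleast_2d(coords))
        d = d[d > 0]
        if d.size == 0:  # a single EA cannot support a spatial range
            return np.array([]), np.array([])
        kappa_grid = np.exp(
            np.linspace(np.log(2.0 / float(d.max())), np.log(2.0 / float(d.min())), 7)
        )
    return sigma2_grid, kappa_grid


def fit_spatial_logit(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    centroids: pd.DataFrame,
) -> PosteriorSummary:
    """Fit the Bernoulli-logit with Matern GP random effect over EA centroids.

    ``centroids`` must carry columns ea_id, x, y covering every EA in the
    cohort.  Hyperparameters (sigma2, kappa) are selected by Laplace
    marginal likelihood on a log grid (sigma2 = 0, the non-spatial model, is
    always included as a candidate); fixed effects are summarised from the
    Gaussian approximation at the selected hyperparameters.
    """
    X, names = build_design(cohort, spec.covariates)
    y = cohort[spec.outcome].to_numpy(dtype=float)
    p_fix = X.shape[1]

    ea_ids = centroids["ea_id"].astype(str).to_numpy()
    coords = centroids[["x", "y"]].to_numpy(dtype=float)
    ea_index = {e: i for i, e in enumerate(ea_ids)}
    try:
        k_of = np.array([ea_index[str(e)] for e in cohort["ea_id"]])
    except KeyError as exc:
        raise GeostatError(f"admission references unknown EA {exc}") from exc
    n_ea = len(ea_ids)
    A = np.zeros((len(cohort), n_ea))
    A[np.arange(len(cohort)), k_of] = 1.0

    prior_prec_beta = 1.0 / spec.beta_prior_sd**2
    logdet_Q0_beta = p_fix * np.log(prior_prec_beta)

    sigma2_grid, kappa_grid = _default_grids(coords, spec)

    results = []
    candidates = []  # (lm, beta_mean, beta_sd, sigma2, kappa, omega, n_iter)
    # non-spatial candidate: sigma2 = 0 drops omega entirely
    Q0_ns = prior_prec_beta * np.eye(p_fix)
    z_ns, cov_ns, lm_ns, it_ns = _laplace_fit(
        y, X, Q0_ns, logdet_Q0_beta, spec.max_newton, spec.tol
    )
    results.append(
        {"sigma2": 0.0, "kappa": np.nan, "log_marginal": lm_ns, "n_newton": it_ns}
    )
    candidates.append(
        (lm_ns, z_ns, np.sqrt(np.diag(cov_ns)), 0.0, np.nan, np.zeros(n_ea), it_ns)
    )

    M = np.hstack([X, A])
    z_warm = None
    for kappa in kappa_grid:
        for sigma2 in sigma2_grid:
            p_mat = MaternParams(sigma2=sigma2, kappa=kappa, nu=spec.nu)
            Sigma = matern_covariance_matrix(coords, p_mat)
            chol_S = cho_factor(Sigma, lower=True)
            Q_omega = cho_solve(chol_S, np.eye(n_ea))
            logdet_Q_omega = -2.0 * np.log(np.diag(chol_S[0])).sum()
            Q0 = np.zeros((p_fix + n_ea, p_fix + n_ea))
            Q0[:p_fix, :p_fix] = prior_prec_beta * np.eye(p_fix)
            Q0[p_fix:, p_fix:] = Q_omega
            try:
                z, cov, lm, it = _laplace_fit(
                    y,
                    M,
                    Q0,
                    logdet_Q0_beta + logdet_Q_omega,
                    spec.max_newton,
                    spec.tol,
                    z0=z_warm,
                )
            except GeostatError:
                results.append(
                    {
                        "sigma2": sigma2,
                        "kappa": kappa,
                        "log_marginal": np.nan,
                        "n_newton": np.nan,
                    }
                )
                continue
            z_warm = z
            results.append(
                {"sigma2": sigma2, "kappa": kappa, "log_marginal": lm, "n_newton": it}
            )
            candidates.append(
                (lm, z[:p_fix], np.sqrt(np.diag(cov)[:p_fix]), sigma2, kappa,
                 z[p_fix:], it)
            )

    # marginal-likelihood weights over the hyperparameter grid: the final
    # fixed-effect posterior is the weighted normal mixture, so credible
    # intervals carry hyperparameter uncertainty
    lms = np.array([c[0] for c in candidates])
    w = np.exp(lms - lms.max())
    w /= w.sum()
    mus = np.array([np.asarray(c[1])[:p_fix] for c in candidates])
    sds = np.array([np.asarray(c[2])[:p_fix] for c in candidates])
    mean = w @ mus
    var = w @ (sds**2 + mus**2) - mean**2
    sd = np.sqrt(var)
    q025 = _mixture_quantile(0.025, w, mus, sds)
    q50 = _mixture_quantile(0.5, w, mus, sds)
    q975 = _mixture_quantile(0.975, w, mus, sds)

    i_best = int(np.argmax(lms))
    lm, _, _, sigma2, kappa, omega, n_iter = candidates[i_best]
    separation = bool(np.any(np.abs(mean) > 10))
    if separation:
        warnings.warn("possible separation: |beta| > 10 for some coefficient", stacklevel=2)
    return PosteriorSummary(
        names=names,
        mean=mean,
        sd=sd,
        q025=q025,
        q50=q50,
        q975=q975,
        sigma2=float(w @ np.array([c[3] for c in candidates])),
        kappa=float(kappa),
        nu=spec.nu,
        log_marginal=float(lm),
        n_newton=int(n_iter),
        grid=pd.DataFrame(results),
        omega_mean=np.asarray(omega),
        separation_flag=separation,
    )


def _mixture_quantile(q: float, w: np.ndarray, mus: np.ndarray, sds: np.ndarray):
    """Quantiles of a weighted mixture of normals, per coefficient
    (bisection on the mixture CDF)."""
    n_coef = mus.shape[1]
    out = np.empty(n_coef)
    for j in range(n_coef):
        lo = float(np.min(mus[:, j] - 8 * sds[:, j]))
        hi = float(np.max(mus[:, j] + 8 * sds[:, j]))
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            cdf = float(w @ norm.cdf((mid - mus[:, j]) / sds[:, j]))
            if cdf < q:
                lo = mid
            else:
                hi = mid
        out[j] = 0.5 * (lo + hi)
    return out


def adjusted_or_table(
    fit: PosteriorSummary, cohort: pd.DataFrame, crude: dict | None = None
) -> pd.DataFrame:
    """Travel-time association table: N (%), crude OR and AOR per class.

    The crude column, when supplied, comes from the descriptive module's
    estimator (keys = travel classes, values = OddsRatioResult); the AOR
    column exponentiates the spatial-fit posterior quantiles.
    """
    counts = cohort["tt_class"].value_counts()
    total = int(counts.sum())
    coef = fit.coef_table()
    rows = []
    for cls in TT_CLASS_ORDER:
        n = int(counts.get(cls, 0))
        row: dict[str, object] = {
            "tt_class": cls,
            "n": n,
            "pct": 100.0 * n / total if total else np.nan,
        }
        name = f"tt_class[{cls}]"
        if cls == "<30":
            row["crude_or"] = "Ref"
            row["aor"] = "Ref"
        else:
            if crude is not None and cls in crude:
                c = crude[cls]
                row["crude_or"] = f"{c.odds_ratio:.2f} ({c.ci_low:.2f}-{c.ci_high:.2f})"
            if name in coef.index:
                row["aor"] = (
                    f"{coef.loc[name, 'aor']:.2f} "
                    f"({coef.loc[name, 'aor_low']:.2f}-{coef.loc[name, 'aor_high']:.2f})"
                )
                row["aor_value"] = float(coef.loc[name, "aor"])
                row["aor_low"] = float(coef.loc[name, "aor_low"])
                row["aor_high"] = float(coef.loc[name, "aor_high"])
        rows.append(row)
    return pd.DataFrame(rows)
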