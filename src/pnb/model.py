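"""Survival datasets and binomial mixed models with crossed random intercepts.

The response is 1 (alive at interval end) / 0 (dead). Fixed effects are the
nine standardized covariates — log height, conspecific seedling and adult
density, the seedling- and adult-layer phylogenetic index of one variant,
canopy openness, and the first three habitat PCA scores — plus an
intercept. Random intercepts for quadrat and species are crossed.

Fitting is maximum likelihood under the Laplace approximation. The random
effects use the spherical parameterization ``b = lambda * z`` with
``z ~ N(0, I)``, so the two variance parameters ``lambda >= 0`` can sit on
the zero boundary smoothly. For given (beta, lambda) the conditional modes
of z are found by Newton iterations; (lambda, beta) are then optimized
jointly by L-BFGS-B on the Laplace-approximated marginal log-likelihood,
the same objective the standard Laplace GLMM workflow maximizes.
Wald standard errors come from the fixed-effect block of
the inverse joint Hessian at the mode, conditional on the fitted lambdas —
the same convention as the standard mixed-model workflow this mirrors.

AIC counts k = (number of fixed effects including the intercept) + 2
variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .io_core import PlotDataset

__all__ = [
    "SurvivalDataset",
    "ModelSpec",
    "ModelFit",
    "ModelDataError",
    "VARIANTS",
    "variant_columns",
    "build_dataset",
    "fit_glmm",
    "conditional_r2",
    "classify_effect",
]

VARIANTS = ("totpd", "avepd", "apd", "ntpd")

_BASE_COVARIATES = ["height", "s_con", "a_con"]
_HABITAT_COVARIATES = ["light", "pca1", "pca2", "pca3"]


class ModelDataError(ValueError):
    """Raised when a survival dataset cannot be built or is degenerate."""


def variant_columns(variant: str) -> tuple[str, str]:
    """(seedling-layer, adult-layer) covariate column names for an index variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown index variant {variant!r}; choose from {VARIANTS}")
    return f"s_{variant}", f"a_{variant}"


def fixed_effect_names(variant: str) -> list[str]:
    s_col, a_col = variant_columns(variant)
    return _BASE_COVARIATES + [s_col, a_col] + _HABITAT_COVARIATES


@dataclass
class SurvivalDataset:
    """One analysis dataset: standardized covariates + 0/1 outcome per focal."""

    df: pd.DataFrame
    variant: str
    interval: tuple[int, int]
    window_label: str
    fixed_effects: list[str]
    standardization: dict[str, tuple[float, float]]  # column -> (mean, sd)
    n_dropped: int

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """(X with leading intercept column, term names)."""
        X = np.column_stack(
            [np.ones(len(self.df))]
            + [self.df[c].to_numpy(dtype=float) for c in self.fixed_effects]
        )
        return X, ["(Intercept)"] + list(self.fixed_effects)


@dataclass
class ModelSpec:
    index_variant: str
    fixed_effects: list[str] = field(default_factory=list)
    random_effects: tuple[str, str] = ("quadrat_id", "species")

    @classmethod
    def for_variant(cls, variant: str) -> "ModelSpec":
        return cls(index_variant=variant, fixed_effects=fixed_effect_names(variant))


@dataclass
class ModelFit:
    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    lambda_q: float
    lambda_s: float
    sigma2_quadrat: float
    sigma2_species: float
    loglik: float
    aic: float
    k: int
    n_obs: int
    converged: bool
    separation: bool
    message: str = ""
    fixed_linear_predictor_var: float = math.nan

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


# ---------------------------------------------------------------------------
# dataset construction


def build_dataset(
    plot: PlotDataset,
    covariates: pd.DataFrame,
    pca_scores: pd.DataFrame,
    interval: tuple[int, int],
    window=None,
    index_variant: str = "apd",
) -> SurvivalDataset:
    """Assemble the standardized survival dataset for one interval and variant.

    ``covariates`` is the per-(focal, census) table from
    :func:`pnb.indices.compute_covariate_table`. Focal rows are seedlings
    alive at the interval start (and, if ``window`` is given, whose quadrat
    center lies inside it); the outcome is 1 iff alive at the interval end.
    Height is log-transformed, then every continuous covariate is z-scored
    with constants computed from the retained rows of this dataset. Rows
    with any missing covariate are dropped and counted.
    """
    start, end = interval
    if end <= start:
        raise ValueError(f"interval end must exceed start: {interval}")
    s_col, a_col = variant_columns(index_variant)

    status_by_tag = {s.tag: s for s in plot.seedlings}
    qmap = plot.quadrat_map()
    keep_q = {
        q.quadrat_id
        for q in plot.quadrats
        if window is None or window.contains(q.center_x, q.center_y)
    }
    if not keep_q:
        raise ModelDataError(f"no quadrats inside window for interval {interval}")

    cov = covariates[covariates["year"] == start]
    rows = []
    for r in cov.itertuples():
        s = status_by_tag.get(r.tag)
        if s is None or not s.is_alive(start) or s.quadrat_id not in keep_q:
            continue
        rows.append(
            {
                "tag": r.tag,
                "species": r.species,
                "quadrat_id": r.quadrat_id,
                "y": 1 if s.status.get(end) == "alive" else 0,
                "height": math.log(r.height) if r.height > 0 else math.nan,
                "s_con": float(r.s_con),
                "a_con": float(r.a_con),
                s_col: float(getattr(r, s_col)),
                a_col: float(getattr(r, a_col)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ModelDataError(f"no focal seedlings for interval {interval}")

    hab = plot.habitat[["quadrat_id", "gli"]].copy()
    hab["quadrat_id"] = hab["quadrat_id"].astype(str)
    hab = hab.rename(columns={"gli": "light"})
    pca = pca_scores[["quadrat_id", "pca1", "pca2", "pca3"]].copy()
    pca["quadrat_id"] = pca["quadrat_id"].astype(str)
    df = df.merge(hab, on="quadrat_id", how="left").merge(
        pca, on="quadrat_id", how="left"
    )

    effects = fixed_effect_names(index_variant)
    n_before = len(df)
    df = df.dropna(subset=effects).reset_index(drop=True)
    n_dropped = n_before - len(df)
    if df.empty:
        raise ModelDataError(
            f"all rows dropped for interval {interval} variant {index_variant}"
        )

    constants: dict[str, tuple[float, float]] = {}
    for colname in effects:
        vals = df[colname].to_numpy(dtype=float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0 or not math.isfinite(sd):
            raise ModelDataError(f"covariate {colname!r} has zero variance")
        df[colname] = (vals - mu) / sd
        constants[colname] = (mu, sd)

    label = window.label if window is not None else "full"
    return SurvivalDataset(
        df=df,
        variant=index_variant,
        interval=interval,
        window_label=label,
        fixed_effects=effects,
        standardization=constants,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Laplace GLMM


def _group_codes(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(values, sort=True)
    return codes.astype(np.intp), len(uniques)


def _penalized_parts(y, X, gq, gs, nq, ns, lam, beta, zq, zs):
    eta = X @ beta + lam[0] * zq[gq] + lam[1] * zs[gs]
    mu = expit(eta)
    f = float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (zq @ zq + zs @ zs))
    return eta, mu, f


def _hessian_blocks(X, W, gq, gs, nq, ns, lam):
    p = X.shape[1]
    A = (X * W[:, None]).T @ X
    Gq = np.empty((nq, p))
    Gs = np.empty((ns, p))
    for k in range(p):
        Gq[:, k] = np.bincount(gq, weights=W * X[:, k], minlength=nq)
        Gs[:, k] = np.bincount(gs, weights=W * X[:, k], minlength=ns)
    wq = np.bincount(gq, weights=W, minlength=nq)
    ws = np.bincount(gs, weights=W, minlength=ns)
    C = np.bincount(gq * ns + gs, weights=W, minlength=nq * ns).reshape(nq, ns)
    dim = p + nq + ns
    H = np.zeros((dim, dim))
    H[:p, :p] = A
    H[:p, p : p + nq] = lam[0] * Gq.T
    H[p : p + nq, :p] = lam[0] * Gq
    H[:p, p + nq :] = lam[1] * Gs.T
    H[p + nq :, :p] = lam[1] * Gs
    H[p : p + nq, p : p + nq] = np.diag(lam[0] ** 2 * wq + 1.0)
    H[p + nq :, p + nq :] = np.diag(lam[1] ** 2 * ws + 1.0)
    H[p : p + nq, p + nq :] = lam[0] * lam[1] * C
    H[p + nq :, p : p + nq] = lam[0] * lam[1] * C.T
    return H


def _zz_hessian(W, gq, gs, nq, ns, lam):
    wq = np.bincount(gq, weights=W, minlength=nq)
    ws = np.bincount(gs, weights=W, minlength=ns)
    C = np.bincount(gq * ns + gs, weights=W, minlength=nq * ns).reshape(nq, ns)
    Hzz = np.zeros((nq + ns, nq + ns))
    Hzz[:nq, :nq] = np.diag(lam[0] ** 2 * wq + 1.0)
    Hzz[nq:, nq:] = np.diag(lam[1] ** 2 * ws + 1.0)
    Hzz[:nq, nq:] = lam[0] * lam[1] * C
    Hzz[nq:, :nq] = lam[0] * lam[1] * C.T
    return Hzz


def _solve_modes(y, X, gq, gs, nq, ns, lam, beta, zq, zs, max_iter=60, tol=1e-11):
    """Newton maximization over the random effects z for fixed (beta, lambda)."""
    eta, mu, f = _penalized_parts(y, X, gq, gs, nq, ns, lam, beta, zq, zs)
    converged = False
    for _ in range(max_iter):
        r = y - mu
        grad = np.concatenate(
            [
                lam[0] * np.bincount(gq, weights=r, minlength=nq) - zq,
                lam[1] * np.bincount(gs, weights=r, minlength=ns) - zs,
            ]
        )
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        Hzz = _zz_hessian(W, gq, gs, nq, ns, lam)
        try:
            delta = np.linalg.solve(Hzz, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(Hzz, grad, rcond=None)[0]
        step = 1.0
        for _ls in range(30):
            zq2 = zq + step * delta[:nq]
            zs2 = zs + step * delta[nq:]
            eta2, mu2, f2 = _penalized_parts(
                y, X, gq, gs, nq, ns, lam, beta, zq2, zs2
            )
            if f2 >= f - 1e-13:
                zq, zs, eta, mu, f = zq2, zs2, eta2, mu2, f2
                break
            step *= 0.5
        else:
            break
    W = np.clip(mu * (1.0 - mu), 1e-10, None)
    return zq, zs, f, W, converged


def _laplace_loglik(y, X, gq, gs, nq, ns, lam, beta, state):
    """Laplace-approximated marginal log-likelihood at (beta, lambda)."""
    zq, zs = state
    zq, zs, f, W, conv = _solve_modes(y, X, gq, gs, nq, ns, lam, beta, zq, zs)
    Hzz = _zz_hessian(W, gq, gs, nq, ns, lam)
    sign, logdet = np.linalg.slogdet(Hzz)
    if sign <= 0:
        return -np.inf, (zq, zs), conv
    return f - 0.5 * logdet, (zq, zs), conv


def _logistic_mle(y, X, max_iter=50):
    """Plain Newton logistic regression (starting values; exact when lambdas = 0)."""
    beta = np.zeros(X.shape[1])
    beta[0] = math.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < 1e-10:
            break
        W = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * W[:, None]).T @ X
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta)) > 30.0:
            break
    return beta


def fit_glmm(
    dataset: SurvivalDataset,
    spec: ModelSpec | None = None,
    fix_lambda: tuple[float, float] | None = None,
    lambda_bound: float = 8.0,
) -> ModelFit:
    """Fit the logit-link Bernoulli mixed model with crossed random intercepts.

    Deterministic given the data (no stochastic optimizer). Non-convergence
    and separation are flagged on the returned fit, never raised.
    ``fix_lambda`` pins the two relative RE standard deviations (e.g. (0, 0)
    to force a plain logistic regression for oracle comparisons); the two
    variance components are then excluded from k.
    """
    df = dataset.df
    y = df["y"].to_numpy(dtype=float)
    X, terms = dataset.design_matrix()
    gq, nq = _group_codes(df["quadrat_id"])
    gs, ns = _group_codes(df["species"])
    if nq < 2 or ns < 2:
        raise ModelDataError("need >= 2 quadrats and >= 2 species to fit the GLMM")
    p = X.shape[1]

    separation = len(np.unique(y)) < 2
    beta_start = _logistic_mle(y, X)
    state = [np.zeros(nq), np.zeros(ns)]

    def nll(params):
        if fix_lambda is None:
            lam = np.clip(params[:2], 0.0, lambda_bound)
            beta = params[2:]
        else:
            lam = np.asarray(fix_lambda, dtype=float)
            beta = params
        ll, new_state, _ = _laplace_loglik(
            y, X, gq, gs, nq, ns, lam, beta, tuple(state)
        )
        state[0], state[1] = new_state
        return -ll

    if fix_lambda is None:
        x0 = np.concatenate([[0.3, 0.3], beta_start])
        bounds = [(0.0, lambda_bound)] * 2 + [(None, None)] * p
    else:
        x0 = beta_start.copy()
        bounds = [(None, None)] * p
    res = minimize(
        nll,
        x0=x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-7, "eps": 1e-6, "maxiter": 500},
    )
    opt_ok = bool(res.success)
    if fix_lambda is None:
        lam_hat = np.clip(res.x[:2], 0.0, lambda_bound)
        beta = res.x[2:].copy()
    else:
        lam_hat = np.asarray(fix_lambda, dtype=float)
        beta = res.x.copy()

    ll, (zq, zs), final_conv = _laplace_loglik(
        y, X, gq, gs, nq, ns, lam_hat, beta, tuple(state)
    )
    eta, mu, _ = _penalized_parts(y, X, gq, gs, nq, ns, lam_hat, beta, zq, zs)
    W = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = _hessian_blocks(X, W, gq, gs, nq, ns, lam_hat)
    try:
        cov_beta = np.linalg.inv(H)[:p, :p]
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(zvals))

    if np.max(np.abs(beta)) > 10.0:
        separation = True

    k = p + (2 if fix_lambda is None else 0)
    aic = 2.0 * k - 2.0 * ll
    fixed_var = float(np.var(X @ beta))
    fit = ModelFit(
        terms=terms,
        estimates=beta,
        se=se,
        zvalues=zvals,
        pvalues=pvals,
        lambda_q=float(lam_hat[0]),
        lambda_s=float(lam_hat[1]),
        sigma2_quadrat=float(lam_hat[0] ** 2),
        sigma2_species=float(lam_hat[1] ** 2),
        loglik=float(ll),
        aic=float(aic),
        k=k,
        n_obs=len(y),
        converged=bool(opt_ok and final_conv and not separation),
        separation=bool(separation),
        message="" if opt_ok else "outer optimizer did not report success",
        fixed_linear_predictor_var=fixed_var,
    )
    return fit


LOGIT_RESIDUAL_VAR = math.pi**2 / 3.0


def conditional_r2(fit: ModelFit, dataset: SurvivalDataset | None = None) -> float:
    """Variance explained by fixed plus random effects on the latent scale.

    (var(X beta) + sigma2_q + sigma2_s) / (same + pi^2/3).
    """
    vf = fit.fixed_linear_predictor_var
    if dataset is not None:
        X, _ = dataset.design_matrix()
        vf = float(np.var(X @ fit.estimates))
    num = vf + fit.sigma2_quadrat + fit.sigma2_species
    return num / (num + LOGIT_RESIDUAL_VAR)


def classify_effect(p: float, estimate: float) -> tuple[str, str]:
    """Significance band and sign of one coefficient.

    p < .05 -> significant; .05 <= p < .1 -> marginal; else none. A positive
    estimate on a phylogenetic index reads as phylogenetic negative density
    dependence (less-related neighborhoods improve survival).
    """
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.05:
        band = "significant"
    elif p < 0.1:
        band = "marginal"
    else:
        band = "none"
    sign = "positive" if estimate > 0 else ("negative" if estimate < 0 else "zero")
    return band, sign
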