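"""Contrast-coded random-intercept analysis of the cue battery.

Each dependent variable is transformed as ``log(x + 1)`` (count families
are first divided by the statement's token count, so the transform is
``log(rate + 1)`` and zeros stay at zero) and modeled as

    y = b0 + b1*v + b2*m + b3*v*m + u_subject + eps,
    u ~ N(0, sigma_u^2),  eps ~ N(0, sigma^2),

with sum contrasts v in {-0.5 (truth), +0.5 (lie)} and m in {-0.5
(written), +0.5 (transcribed)}, so each main effect is the condition
difference averaged over the other factor. The random intercept absorbs
by-subject style differences across the four repeated statements.

Fitting is restricted maximum likelihood (REML) with the fixed effects
and residual variance profiled out, leaving a bounded one-dimensional
search over the variance ratio ``lambda = sigma_u^2 / sigma^2`` — fully
deterministic. P-values are Wald normal approximations ``2*Phi(-|b/se|)``
(no degrees-of-freedom correction), and family-wise error over the many
dependent variables is controlled by Holm's step-down correction, applied
separately within each effect family (veracity, modality, interaction) by
default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lexicon_features import FeatureConfig, count_feature_names, feature_names

logger = logging.getLogger(__name__)

EFFECT_NAMES = ("intercept", "veracity", "modality", "interaction")

#: Search interval and tolerance for the variance-ratio optimizer.
LAMBDA_MAX = 1e4
LAMBDA_XATOL = 1e-8


class DesignError(ValueError):
    """Design matrix cannot be built or is singular."""


@dataclass
class DesignMatrix:
    """Fixed-effect design plus the subject grouping vector."""

    X: np.ndarray  # (n, 4): intercept, veracity, modality, interaction
    groups: np.ndarray  # (n,) subject ids
    colnames: tuple[str, ...] = EFFECT_NAMES


@dataclass
class MixedModelFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    lambda_ratio: float
    loglik_reml: float
    converged: bool
    n_obs: int
    n_groups: int
    p: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class HolmResult:
    variable: str
    p_raw: float
    p_adj: float
    significant: bool


def normalize_and_transform(
    values, n_tokens=None, normalize: bool = False
) -> np.ndarray:
    """``log(x + 1)`` transform, optionally on per-token rates.

    Count families are divided by the statement's token count before
    adding 1 and taking the log, so a zero count maps to zero on the
    transformed scale; non-count families are transformed directly.
    Missing values propagate as NaN.
    """
    v = np.asarray(values, dtype=float)
    if np.nanmin(v, initial=0.0) < 0:
        raise ValueError("negative values cannot be log(x+1)-transformed")
    if normalize:
        if n_tokens is None:
            raise ValueError("normalize=True requires n_tokens")
        n = np.asarray(n_tokens, dtype=float)
        if np.any(n == 0):
            raise ValueError("n_tokens contains zeros; cannot form per-token rates")
        v = v / n
    return np.log1p(v)


def build_design(meta: pd.DataFrame) -> DesignMatrix:
    """Sum-contrast design from the veracity/modality metadata columns.

    truth -> -0.5, lie -> +0.5; written -> -0.5, transcribed -> +0.5; the
    interaction column is their product.
    """
    for col in ("veracity", "modality", "subject_id"):
        if col not in meta.columns:
            raise DesignError(f"metadata column {col!r} missing")
    v_map = {"truth": -0.5, "lie": 0.5}
    m_map = {"written": -0.5, "transcribed": 0.5}
    bad_v = set(meta["veracity"]) - set(v_map)
    bad_m = set(meta["modality"]) - set(m_map)
    if bad_v or bad_m:
        raise DesignError(f"unknown factor levels: veracity {bad_v}, modality {bad_m}")
    v = meta["veracity"].map(v_map).to_numpy(dtype=float)
    m = meta["modality"].map(m_map).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(v), v, m, v * m])
    return DesignMatrix(X=X, groups=meta["subject_id"].to_numpy())


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sufficient statistics for the block-structured GLS."""
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    _, starts, counts = np.unique(gs, return_index=True, return_counts=True)
    return Xs, ys, starts, counts


def _reml_pieces(Xs, ys, starts, counts, lam):
    """X'V^-1X, X'V^-1y, y'V^-1y and log|V| for V = I + lam * J blocks."""
    p = Xs.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdetV = 0.0
    for s, c in zip(starts, counts):
        Xg = Xs[s : s + c]
        yg = ys[s : s + c]
        shrink = lam / (1.0 + lam * c)
        x1 = Xg.sum(axis=0)
        y1 = yg.sum()
        XtVX += Xg.T @ Xg - shrink * np.outer(x1, x1)
        XtVy += Xg.T @ yg - shrink * x1 * y1
        ytVy += yg @ yg - shrink * y1 * y1
        logdetV += math.log1p(lam * c)
    return XtVX, XtVy, ytVy, logdetV


def _neg2_reml(lam, Xs, ys, starts, counts):
    n, p = Xs.shape
    XtVX, XtVy, ytVy, logdetV = _reml_pieces(Xs, ys, starts, counts, lam)
    sign, logdetA = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - XtVy @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / (n - p)
    return (n - p) * math.log(sigma2) + logdetV + logdetA


def fit_lmm_reml(y, design: DesignMatrix) -> MixedModelFit:
    """Fit the random-intercept model by profiled REML.

    Rows with missing ``y`` are dropped (and logged). Requires at least
    two subjects and a non-singular fixed-effect design on the retained
    rows. Deterministic given its inputs.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    if not keep.all():
        logger.info("dropping %d rows with missing response", int((~keep).sum()))
    X, groups = design.X[keep], design.groups[keep]
    y = y[keep]
    n, p = X.shape
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise DesignError("need at least 2 subjects to fit a random intercept")
    if n <= p:
        raise DesignError(f"too few observations ({n}) for {p} fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("singular fixed-effect design")

    Xs, ys, starts, counts = _group_stats(X, y, groups)

    # Degenerate response: OLS already fits exactly -> all variances zero.
    beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    if rss_ols <= 1e-12 * max(1.0, float(y @ y)):
        return MixedModelFit(
            beta=beta_ols,
            se=np.zeros(p),
            sigma2_subject=0.0,
            sigma2_resid=0.0,
            lambda_ratio=0.0,
            loglik_reml=math.inf,
            converged=True,
            n_obs=n,
            n_groups=n_groups,
            p=np.full(p, np.nan),
        )

    res = optimize.minimize_scalar(
        _neg2_reml,
        bounds=(0.0, LAMBDA_MAX),
        args=(Xs, ys, starts, counts),
        method="bounded",
        options={"xatol": LAMBDA_XATOL},
    )
    lam = float(res.x)
    # The bounded minimizer never evaluates the boundary itself; prefer the
    # lambda=0 (pure OLS) solution when it is at least as good.
    if _neg2_reml(0.0, Xs, ys, starts, counts) <= res.fun:
        lam = 0.0

    XtVX, XtVy, ytVy, logdetV = _reml_pieces(Xs, ys, starts, counts, lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = float(ytVy - XtVy @ beta)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    _, logdetA = np.linalg.slogdet(XtVX)
    neg2 = (n - p) * math.log(sigma2) + logdetV + logdetA
    loglik = -0.5 * (neg2 + (n - p) * (1.0 + math.log(2.0 * math.pi)))
    return MixedModelFit(
        beta=beta,
        se=se,
        sigma2_subject=lam * sigma2,
        sigma2_resid=sigma2,
        lambda_ratio=lam,
        loglik_reml=loglik,
        converged=bool(res.success),
        n_obs=n,
        n_groups=n_groups,
    )


def wald_pvalues(fit: MixedModelFit) -> np.ndarray:
    """Two-sided normal-approximation p-values ``2*Phi(-|b/se|)``.

    Coefficients with zero standard error yield NaN (flagged upstream as
    degenerate fits).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(fit.se > 0, fit.beta / fit.se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    fit.p = p
    return p


def holm_p(p_raw) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        scaled = (m - rank) * p[idx]
        running = max(running, scaled)  # enforce step-down monotonicity
        adj[idx] = min(running, 1.0)
    return adj


def holm_adjust(p_raw, variables=None, alpha: float = 0.05) -> list[HolmResult]:
    """Holm correction over one family of raw p-values."""
    p = np.asarray(p_raw, dtype=float)
    adj = holm_p(p)
    if variables is None:
        variables = [f"var{i}" for i in range(p.size)]
    return [
        HolmResult(
            variable=str(v),
            p_raw=float(pr),
            p_adj=float(pa),
            significant=bool(pa < alpha),
        )
        for v, pr, pa in zip(variables, p, adj)
    ]


def analyze_all(
    table: pd.DataFrame,
    config: FeatureConfig = FeatureConfig(),
    variables: list[str] | None = None,
    min_rows: int = 20,
    holm_family: str = "per_effect",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit one random-intercept model per dependent variable.

    Returns a long-format table: variable x effect with estimate, standard
    error, raw Wald p and Holm-adjusted p. The Holm family is, per effect
    (veracity / modality / interaction), the set of analyzed variables
    (``holm_family="per_effect"``), or all variable-effect pairs pooled
    (``"pooled"``). Variables with fewer than ``min_rows`` usable rows are
    skipped with a log entry.
    """
    if holm_family not in ("per_effect", "pooled"):
        raise ValueError(f"unknown holm_family {holm_family!r}")
    if variables is None:
        present = set(table.columns)
        variables = [n for n in feature_names(config) if n in present]
        if "ne_count" in present:
            variables.append("ne_count")
    count_set = set(count_feature_names(config)) | {"ne_count"}
    design_full = build_design(table)
    n_tokens = table["n_tokens"].to_numpy(dtype=float)

    records = []
    for var in variables:
        raw = table[var].to_numpy(dtype=float)
        usable = int(np.isfinite(raw).sum())
        if usable < min_rows:
            logger.warning("skipping %s: only %d non-missing rows", var, usable)
            continue
        y = normalize_and_transform(raw, n_tokens, normalize=var in count_set)
        fit = fit_lmm_reml(y, design_full)
        p = wald_pvalues(fit)
        for j, eff in enumerate(EFFECT_NAMES):
            records.append(
                {
                    "variable": var,
                    "effect": eff,
                    "b": float(fit.beta[j]),
                    "se": float(fit.se[j]),
                    "p_raw": float(p[j]),
                    "n_used": fit.n_obs,
                    "converged": fit.converged,
                }
            )
    result = pd.DataFrame.from_records(records)
    if result.empty:
        return result
    result["p_holm"] = np.nan
    tested = result["effect"] != "intercept"
    if holm_family == "per_effect":
        for eff in ("veracity", "modality", "interaction"):
            mask = (result["effect"] == eff) & result["p_raw"].notna()
            if mask.any():
                result.loc[mask, "p_holm"] = holm_p(result.loc[mask, "p_raw"])
    else:
        mask = tested & result["p_raw"].notna()
        if mask.any():
            result.loc[mask, "p_holm"] = holm_p(result.loc[mask, "p_raw"])
    result["significant"] = result["p_holm"] < alpha
    return result
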