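"""Multiple imputation (chained equations) and Rubin's-rules pooling.

Imputation operates on the long (unstacked) cohort table, before stacking,
so a covariate imputed once is shared by both outcome channels.  The scheme
is deliberately simple and swappable: each incomplete continuous column is
imputed from a Bayesian linear regression on the complete columns (draw the
residual variance from its scaled inverse-chi-square posterior, the
coefficients from their normal posterior, then add residual noise); an
incomplete binary outcome is imputed from a logistic working model with a
normal posterior draw of its coefficients.  A few chained sweeps let
incomplete columns borrow from one another's current completions.

Pooling follows Rubin (1987): with per-imputation estimates Q_l and
variances U_l, the pooled estimate is their mean, the total variance is
T = W + (1 + 1/m) B with W the mean within-imputation variance and B the
between-imputation sample variance, and the reference degrees of freedom
are (m - 1) (1 + W / ((1 + 1/m) B))^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = ["ImputationSet", "PooledEstimate", "multiple_impute", "rubin_pool",
           "pool_fits"]

#: columns eligible for imputation by default
DEFAULT_IMPUTE_CONTINUOUS = ("weight", "hemoglobin", "baseline_cd4", "cd4_count")
DEFAULT_IMPUTE_BINARY = ("tb_status",)

#: always-observed columns used as predictors when complete
_PREDICTOR_POOL = ("visit", "age", "gender", "weight", "hemoglobin",
                   "baseline_cd4", "who_stage", "oi_status")


@dataclass
class ImputationSet:
    """m completed cohorts plus the description of how they were made."""

    datasets: list
    m: int
    seed: int
    columns: list
    model: dict = field(default_factory=dict)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of one scalar estimate across imputations."""

    estimate: float          # pooled Q-bar
    within: float            # W: mean within-imputation variance
    between: float           # B: between-imputation variance of estimates
    total: float             # T = W + (1 + 1/m) B
    df: float                # Rubin reference degrees of freedom
    se: float
    z: float
    p: float
    m: int


def _design_for(df: pd.DataFrame, target: str, current: pd.DataFrame) -> np.ndarray:
    preds = [c for c in _PREDICTOR_POOL if c != target and c in current.columns]
    X = np.column_stack(
        [np.ones(len(df))] + [current[c].to_numpy(dtype=float) for c in preds]
    )
    return X


def _impute_continuous(current, target, miss_mask, rng):
    X = _design_for(current, target, current)
    y = current[target].to_numpy(dtype=float)
    obs = ~miss_mask
    Xo, yo = X[obs], y[obs]
    n, p = Xo.shape
    if n <= p:
        raise ValueError(f"too few observed values in {target!r} to impute")
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    ssr = float(resid @ resid)
    # posterior draws (normal-inverse-chi-square, noninformative prior)
    sigma2 = ssr / stats.chi2.rvs(df=n - p, random_state=rng)
    XtX_inv = np.linalg.pinv(Xo.T @ Xo)
    L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
    beta = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    draws = X[miss_mask] @ beta + np.sqrt(sigma2) * rng.standard_normal(miss_mask.sum())
    return draws


def _impute_binary(current, target, miss_mask, rng):
    import statsmodels.api as sm

    X = _design_for(current, target, current)
    y = current[target].to_numpy(dtype=float)
    obs = ~miss_mask
    try:
        res = sm.GLM(y[obs], X[obs], family=sm.families.Binomial()).fit()
        beta_hat = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(beta_hat)))
        beta = beta_hat + L @ rng.standard_normal(len(beta_hat))
    except Exception:
        pbar = np.clip(y[obs].mean(), 1e-3, 1 - 1e-3)
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(pbar / (1 - pbar))
    p = expit(X[miss_mask] @ beta)
    return (rng.random(miss_mask.sum()) < p).astype(float)


def multiple_impute(
    records: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    columns: list | None = None,
    n_sweeps: int = 3,
) -> ImputationSet:
    """Produce ``m`` completed cohorts by chained-equations imputation.

    Only the listed ``columns`` (default: the continuous labs/outcome and
    the binary outcome, whichever have missing cells) are imputed; observed
    cells are never altered.  Deterministic under ``seed``.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if columns is None:
        columns = [
            c for c in (*DEFAULT_IMPUTE_CONTINUOUS, *DEFAULT_IMPUTE_BINARY)
            if c in records.columns and records[c].isna().any()
        ]
    for col in columns:
        if records[col].notna().sum() == 0:
            raise ValueError(f"column {col!r} has no observed values")

    masks = {c: records[c].isna().to_numpy() for c in columns}
    seeds = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for l in range(m):
        rng = np.random.default_rng(seeds[l])
        current = records.copy()
        # initial fill: observed mean / mode
        for col in columns:
            vals = records[col].dropna()
            fill = vals.mode().iloc[0] if col in DEFAULT_IMPUTE_BINARY else vals.mean()
            current.loc[masks[col], col] = fill
        for _ in range(n_sweeps if columns else 0):
            for col in columns:
                miss = masks[col]
                if not miss.any():
                    continue
                if col in DEFAULT_IMPUTE_BINARY:
                    draws = _impute_binary(current, col, miss, rng)
                else:
                    draws = _impute_continuous(current, col, miss, rng)
                    if col in ("baseline_cd4", "cd4_count"):
                        draws = np.maximum(np.round(draws), 0.0)
                    elif col == "weight":
                        draws = np.maximum(draws, 1.0)
                    elif col == "hemoglobin":
                        draws = np.maximum(draws, 0.1)
                current.loc[miss, col] = draws
        datasets.append(current)
    return ImputationSet(
        datasets=datasets, m=m, seed=seed, columns=list(columns),
        model={"continuous": "bayesian linear regression draws",
               "binary": "logistic working model draws",
               "n_sweeps": n_sweeps},
    )


def rubin_pool(per_imputation) -> PooledEstimate:
    """Pool one scalar estimate across imputations by Rubin's rules.

    ``per_imputation`` is a sequence of ``(estimate, variance)`` pairs,
    one per completed dataset (variance = squared standard error).
    With zero between-imputation variance the degrees of freedom are
    infinite and the p-value uses the normal reference; otherwise the
    t reference with Rubin's df.
    """
    pairs = list(per_imputation)
    if len(pairs) < 2:
        raise ValueError("need at least 2 imputations to pool")
    est = np.array([p[0] for p in pairs], dtype=float)
    var = np.array([p[1] for p in pairs], dtype=float)
    m = len(est)
    qbar = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(t))
    z = qbar / se if se > 0 else np.nan
    if b == 0.0:
        df = np.inf
        p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    else:
        df = float((m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2)
        p = float(2.0 * stats.t.sf(abs(z), df)) if np.isfinite(z) else np.nan
    return PooledEstimate(estimate=qbar, within=w, between=b, total=float(t),
                          df=df, se=se, z=float(z), p=p, m=m)


def pool_fits(fits) -> pd.DataFrame:
    """Pool every coefficient of a list of :class:`FitResult`-like fits.

    Fits must share the same (channel, term) coefficient layout; returns a
    frame with pooled estimate, within/between variance, total SE, df, p.
    """
    frames = [f.coef for f in fits]
    key0 = list(zip(frames[0]["channel"], frames[0]["term"]))
    for fr in frames[1:]:
        if list(zip(fr["channel"], fr["term"])) != key0:
            raise ValueError("fits have mismatched coefficient layouts")
    rows = []
    for i, (channel, term) in enumerate(key0):
        pooled = rubin_pool(
            [(fr["estimate"].iloc[i], fr["se"].iloc[i] ** 2) for fr in frames]
        )
        rows.append({
            "channel": channel, "term": term, "estimate": pooled.estimate,
            "se": pooled.se, "within": pooled.within, "between": pooled.between,
            "df": pooled.df, "z": pooled.z, "p": pooled.p,
        })
    return pd.DataFrame(rows)
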