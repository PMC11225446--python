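"""Mixed-family GLMM engine: Laplace / adaptive Gauss-Hermite estimation.

Model
-----
Patient *i* contributes count-channel rows (CD4, conditionally Poisson with
log link, or optionally Gaussian on log(1+CD4)) and binary-channel rows
(TB screen, Bernoulli with logit link).  The channels share a Gaussian
subject random intercept ``b_i ~ N(0, sigma_b^2)``; the count channel's
loading on ``b_i`` is fixed at 1 and the binary channel's loading
``lambda`` may be free or fixed.  Conditional on ``b_i`` all of a subject's
rows are independent, so the marginal likelihood is

    L = prod_i  integral  [prod_j f1(y1_ij | b_i)] [prod_j f2(y2_ij | b_i)]
                          phi(b_i; 0, sigma_b^2) db_i

and the cross-outcome covariance is exactly the covariance of the two
conditional means induced by the shared intercept.

The integral is approximated per subject either by the Laplace method
(second-order expansion at the posterior mode of ``b_i``) or by adaptive
Gauss-Hermite quadrature with nodes recentred at the mode and rescaled by
the curvature there; Laplace is AGQ with a single node.  A
correlated-intercepts variant (one intercept per channel, bivariate normal)
is available; it uses the same machinery in two dimensions.

Estimation maximises the marginal log-likelihood by quasi-Newton (BFGS) on
a transformed scale (log sigma_b, atanh rho), with standard errors from the
inverse of a central-difference observed information matrix.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, gammaln, logsumexp

from .data_model import CHANNEL_BINARY, CHANNEL_COUNT
from .schema import CATEGORICAL_LEVELS

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "FitResult",
    "build_design",
    "marginal_loglik",
    "posterior_modes",
    "fit_glmm",
    "fit_separate",
    "fit_statistics",
    "fitted_values",
    "SingularDesignError",
    "DegenerateDataError",
]

DEFAULT_TERMS = ("visit", "weight", "hemoglobin", "baseline_cd4", "oi_status")

_ETA_MAX = 40.0  # cap inside exp() so absurd trial parameters stay finite


class SingularDesignError(ValueError):
    """A requested covariate has no variation in the data (singular column)."""


class DegenerateDataError(ValueError):
    """Data cannot identify the model (e.g. all-0 or all-1 binary channel)."""


@dataclass
class ModelSpec:
    """Which family/link each channel gets, fixed effects, random structure.

    ``count_terms`` / ``binary_terms`` name cohort columns; categorical ones
    (per the schema) are dummy-coded with the LAST level as reference.  An
    intercept is always included.  ``random_effects`` is one of ``"none"``,
    ``"shared_intercept"`` or ``"correlated_intercepts"``;
    ``lambda_binary`` is ``"free"`` or a fixed float (only meaningful for
    the shared-intercept structure).  ``method`` is ``"laplace"`` or
    ``"agq"`` with ``n_nodes`` odd.
    """

    count_terms: Sequence[str] = DEFAULT_TERMS
    binary_terms: Sequence[str] = DEFAULT_TERMS
    count_family: str = "poisson"  # or "gaussian-log"
    random_effects: str = "shared_intercept"
    lambda_binary: float | str = 1.0
    method: str = "laplace"
    n_nodes: int = 21
    gtol: float = 1e-3
    maxiter: int = 500
    sigma_b_start: float = 0.3
    scale_se_by_dispersion: bool = False

    def __post_init__(self):
        if self.count_family not in ("poisson", "gaussian-log"):
            raise ValueError(f"unknown count_family {self.count_family!r}")
        if self.random_effects not in ("none", "shared_intercept", "correlated_intercepts"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if self.method not in ("laplace", "agq"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "agq" and (self.n_nodes < 1 or self.n_nodes % 2 == 0):
            raise ValueError("n_nodes must be odd and >= 1")
        if isinstance(self.lambda_binary, str) and self.lambda_binary != "free":
            raise ValueError("lambda_binary must be a number or 'free'")

    @property
    def effective_nodes(self) -> int:
        return 1 if self.method == "laplace" else int(self.n_nodes)


def _encode_terms(df: pd.DataFrame, terms: Sequence[str]):
    """Design matrix with intercept first; categoricals drop the last level."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in terms:
        if term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            for lv in levels[:-1]:
                cols.append((df[term].to_numpy(dtype=float) == lv).astype(float))
                names.append(f"{term}[{lv}]")
        else:
            cols.append(df[term].to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


@dataclass
class DesignBundle:
    """Aligned per-channel design matrices plus subject indexing."""

    y_count: np.ndarray
    X_count: np.ndarray
    subj_count: np.ndarray
    count_names: list
    y_binary: np.ndarray
    X_binary: np.ndarray
    subj_binary: np.ndarray
    binary_names: list
    subjects: np.ndarray
    spec: ModelSpec
    n_dropped: int = 0
    # warm-start cache for the inner Newton mode search; the per-subject
    # objective is strictly concave, so the start point cannot change the
    # converged mode, only how fast it is reached
    mode_cache: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_fixed(self) -> int:
        return len(self.count_names) + len(self.binary_names)


def build_design(stacked: pd.DataFrame, spec: ModelSpec) -> DesignBundle:
    """Turn a stacked frame into channel design matrices.

    Rows with a missing response or a missing value in any used covariate
    are dropped (available-case; run imputation upstream to avoid this).
    Columns with no variation raise :class:`SingularDesignError` naming the
    column.
    """
    used = sorted({*spec.count_terms, *spec.binary_terms})
    work = stacked.dropna(subset=[c for c in used if c in stacked.columns] + ["response"])
    n_dropped = len(stacked) - len(work)

    subjects, subj_codes = np.unique(work["patient_id"].to_numpy(), return_inverse=True)

    out = {}
    for channel, terms, key in (
        (CHANNEL_COUNT, spec.count_terms, "count"),
        (CHANNEL_BINARY, spec.binary_terms, "binary"),
    ):
        mask = (work["channel"] == channel).to_numpy()
        sub = work.loc[mask]
        y = sub["response"].to_numpy(dtype=float)
        if len(y) == 0:
            out[key] = (y, np.empty((0, 0)), subj_codes[mask], [])
            continue
        X, names = _encode_terms(sub, terms)
        if len(y) > 0:
            for j, name in enumerate(names):
                if name != "intercept" and np.ptp(X[:, j]) == 0.0:
                    raise SingularDesignError(
                        f"column {name!r} has no variation in the {channel} channel"
                    )
        if channel == CHANNEL_COUNT and spec.count_family == "gaussian-log":
            y = np.log1p(y)
        out[key] = (y, X, subj_codes[mask], names)

    return DesignBundle(
        y_count=out["count"][0], X_count=out["count"][1],
        subj_count=out["count"][2], count_names=out["count"][3],
        y_binary=out["binary"][0], X_binary=out["binary"][1],
        subj_binary=out["binary"][2], binary_names=out["binary"][3],
        subjects=subjects, spec=spec, n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# parameter packing

@dataclass
class ParamLayout:
    p_count: int
    p_binary: int
    has_sigma_e: bool
    structure: str
    free_lambda: bool

    @property
    def n_params(self) -> int:
        n = self.p_count + self.p_binary + int(self.has_sigma_e)
        if self.structure == "shared_intercept":
            n += 1 + int(self.free_lambda)
        elif self.structure == "correlated_intercepts":
            n += 3
        return n

    def unpack(self, theta: np.ndarray, spec: ModelSpec) -> dict:
        theta = np.asarray(theta, dtype=float)
        i = 0
        beta_c = theta[i:i + self.p_count]; i += self.p_count
        beta_b = theta[i:i + self.p_binary]; i += self.p_binary
        sigma_e = None
        if self.has_sigma_e:
            sigma_e = float(np.exp(theta[i])); i += 1
        out = {"beta_count": beta_c, "beta_binary": beta_b, "sigma_e": sigma_e}
        if self.structure == "shared_intercept":
            out["sigma_b"] = float(np.exp(theta[i])); i += 1
            if self.free_lambda:
                out["lambda"] = float(theta[i]); i += 1
            else:
                out["lambda"] = float(spec.lambda_binary)
        elif self.structure == "correlated_intercepts":
            out["sigma1"] = float(np.exp(theta[i])); i += 1
            out["sigma2"] = float(np.exp(theta[i])); i += 1
            out["rho"] = float(np.tanh(theta[i])); i += 1
        return out


def layout_for(bundle: DesignBundle) -> ParamLayout:
    spec = bundle.spec
    return ParamLayout(
        p_count=bundle.X_count.shape[1] if bundle.X_count.size else (
            len(bundle.count_names) if len(bundle.y_count) else 0),
        p_binary=bundle.X_binary.shape[1] if bundle.X_binary.size else (
            len(bundle.binary_names) if len(bundle.y_binary) else 0),
        has_sigma_e=(spec.count_family == "gaussian-log" and len(bundle.y_count) > 0),
        structure=spec.random_effects,
        free_lambda=(spec.random_effects == "shared_intercept"
                     and spec.lambda_binary == "free"),
    )


# ---------------------------------------------------------------------------
# conditional log-likelihood pieces (vectorised over rows, summed by subject)

def _count_terms(bundle, pars):
    """eta and helpers for the count channel; raises on non-finite eta."""
    if len(bundle.y_count) == 0:
        return None
    eta = bundle.X_count @ pars["beta_count"]
    if not np.all(np.isfinite(eta)):
        sid = bundle.subjects[bundle.subj_count[~np.isfinite(eta)][0]]
        raise FloatingPointError(f"non-finite count-channel linear predictor (subject {sid})")
    return eta


def _binary_terms(bundle, pars):
    if len(bundle.y_binary) == 0:
        return None
    eta = bundle.X_binary @ pars["beta_binary"]
    if not np.all(np.isfinite(eta)):
        sid = bundle.subjects[bundle.subj_binary[~np.isfinite(eta)][0]]
        raise FloatingPointError(f"non-finite binary-channel linear predictor (subject {sid})")
    return eta


def _channel_h(bundle, pars, eta_c, eta_b, b_c, b_b):
    """Per-subject sums of conditional log densities at offsets b_c / b_b.

    ``b_c`` / ``b_b`` are per-row random-effect contributions (already
    multiplied by their loadings).  Returns (h, g_c, g_b, negH_c, negH_b):
    per-subject conditional log-lik sums and the first/second derivative
    sums with respect to the raw random effect of each channel (loading
    applied by the caller for the binary side).
    """
    n = bundle.n_subjects
    h = np.zeros(n)
    g_c = np.zeros(n); negH_c = np.zeros(n)
    g_b = np.zeros(n); negH_b = np.zeros(n)
    if eta_c is not None:
        lin = eta_c + b_c
        if bundle.spec.count_family == "gaussian-log":
            se = pars["sigma_e"]
            resid = bundle.y_count - lin
            ll = -0.5 * np.log(2 * np.pi * se**2) - 0.5 * resid**2 / se**2
            gr = resid / se**2
            hr = np.full(len(ll), 1.0 / se**2)
        else:
            mu = np.exp(np.minimum(lin, _ETA_MAX))
            ll = bundle.y_count * lin - mu - gammaln(bundle.y_count + 1.0)
            gr = bundle.y_count - mu
            hr = mu
        h += np.bincount(bundle.subj_count, weights=ll, minlength=n)
        g_c += np.bincount(bundle.subj_count, weights=gr, minlength=n)
        negH_c += np.bincount(bundle.subj_count, weights=hr, minlength=n)
    if eta_b is not None:
        lin = eta_b + b_b
        p = expit(lin)
        ll = bundle.y_binary * lin - np.logaddexp(0.0, lin)
        gr = bundle.y_binary - p
        hr = p * (1.0 - p)
        h += np.bincount(bundle.subj_binary, weights=ll, minlength=n)
        g_b += np.bincount(bundle.subj_binary, weights=gr, minlength=n)
        negH_b += np.bincount(bundle.subj_binary, weights=hr, minlength=n)
    return h, g_c, g_b, negH_c, negH_b


# ---------------------------------------------------------------------------
# shared-intercept integral (1-D)

def _shared_h(bundle, pars, eta_c, eta_b, b):
    lam = pars["lambda"]
    sig = pars["sigma_b"]
    h, g_c, g_b, negH_c, negH_b = _channel_h(
        bundle, pars, eta_c, eta_b,
        b[bundle.subj_count] if eta_c is not None else None,
        lam * b[bundle.subj_binary] if eta_b is not None else None,
    )
    h = h - 0.5 * b**2 / sig**2 - np.log(sig) - 0.5 * np.log(2 * np.pi)
    g = g_c + lam * g_b - b / sig**2
    negH = negH_c + lam**2 * negH_b + 1.0 / sig**2
    return h, g, negH


def _shared_modes(bundle, pars, eta_c, eta_b, maxiter: int = 200):
    """Vectorised damped Newton for the per-subject posterior modes of b."""
    b = bundle.mode_cache.get("shared")
    if b is None or not np.all(np.isfinite(b)):
        b = np.zeros(bundle.n_subjects)
    h, g, negH = _shared_h(bundle, pars, eta_c, eta_b, b)
    if not np.all(np.isfinite(h)):
        b = np.zeros(bundle.n_subjects)
        h, g, negH = _shared_h(bundle, pars, eta_c, eta_b, b)
    evals = 0
    converged = False
    for _ in range(maxiter):
        step = np.clip(g / negH, -10.0, 10.0)
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
        b_new = b + step
        h_new, g_new, negH_new = _shared_h(bundle, pars, eta_c, eta_b, b_new)
        evals += 1
        # backtrack where the objective decreased (h is concave in b)
        for _ in range(15):
            worse = ~(h_new >= h - 1e-12)  # also catches NaN
            if not worse.any():
                break
            step = np.where(worse, 0.5 * step, step)
            b_new = b + step
            h_new, g_new, negH_new = _shared_h(bundle, pars, eta_c, eta_b, b_new)
            evals += 1
        b, h, g, negH = b_new, h_new, g_new, negH_new
        if np.max(np.abs(g) / negH) < 1e-11:
            converged = True
            break
        if evals > 120:  # absurd trial parameters: good enough for line search
            break
    bundle.mode_cache["shared"] = b.copy() if converged else None
    return b, h, negH


def _shared_loglik(bundle, pars, eta_c, eta_b, n_nodes: int):
    b_hat, h_hat, negH = _shared_modes(bundle, pars, eta_c, eta_b)
    if n_nodes == 1:
        ll = h_hat + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(negH)
        return float(np.sum(ll)), b_hat
    z, w = hermgauss(n_nodes)
    tau = 1.0 / np.sqrt(negH)
    vals = np.empty((n_nodes, bundle.n_subjects))
    for k in range(n_nodes):
        bk = b_hat + np.sqrt(2.0) * tau * z[k]
        hk, _, _ = _shared_h(bundle, pars, eta_c, eta_b, bk)
        vals[k] = hk + z[k] ** 2 + np.log(w[k])
    ll = logsumexp(vals, axis=0) + 0.5 * np.log(2.0) + np.log(tau)
    return float(np.sum(ll)), b_hat


# ---------------------------------------------------------------------------
# correlated-intercepts integral (2-D; count gets b1, binary gets b2)

def _corr_h(bundle, pars, eta_c, eta_b, b):
    s1, s2, rho = pars["sigma1"], pars["sigma2"], pars["rho"]
    det = (s1 * s2) ** 2 * (1.0 - rho**2)
    # precision matrix of the bivariate normal prior
    p11 = 1.0 / (s1**2 * (1 - rho**2))
    p22 = 1.0 / (s2**2 * (1 - rho**2))
    p12 = -rho / (s1 * s2 * (1 - rho**2))
    b1, b2 = b[:, 0], b[:, 1]
    h, g_c, g_b, negH_c, negH_b = _channel_h(
        bundle, pars, eta_c, eta_b,
        b1[bundle.subj_count] if eta_c is not None else None,
        b2[bundle.subj_binary] if eta_b is not None else None,
    )
    quad = p11 * b1**2 + 2 * p12 * b1 * b2 + p22 * b2**2
    h = h - 0.5 * quad - 0.5 * np.log(det) - np.log(2 * np.pi)
    g1 = g_c - (p11 * b1 + p12 * b2)
    g2 = g_b - (p12 * b1 + p22 * b2)
    H11 = negH_c + p11
    H22 = negH_b + p22
    H12 = np.full_like(H11, p12)
    return h, (g1, g2), (H11, H12, H22)


def _corr_modes(bundle, pars, eta_c, eta_b, maxiter: int = 200):
    b = bundle.mode_cache.get("corr")
    if b is None or not np.all(np.isfinite(b)):
        b = np.zeros((bundle.n_subjects, 2))
    h, g, H = _corr_h(bundle, pars, eta_c, eta_b, b)
    if not np.all(np.isfinite(h)):
        b = np.zeros((bundle.n_subjects, 2))
        h, g, H = _corr_h(bundle, pars, eta_c, eta_b, b)
    evals = 0
    converged = False
    for _ in range(maxiter):
        g1, g2 = g
        H11, H12, H22 = H
        det = H11 * H22 - H12**2
        s1 = (H22 * g1 - H12 * g2) / det
        s2 = (H11 * g2 - H12 * g1) / det
        step = np.clip(np.column_stack([s1, s2]), -10.0, 10.0)
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
        b_new = b + step
        h_new, g_new, H_new = _corr_h(bundle, pars, eta_c, eta_b, b_new)
        evals += 1
        for _ in range(15):
            worse = ~(h_new >= h - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            b_new = b + step
            h_new, g_new, H_new = _corr_h(bundle, pars, eta_c, eta_b, b_new)
            evals += 1
        b, h, g, H = b_new, h_new, g_new, H_new
        if evals > 150:
            break
    bundle.mode_cache["corr"] = b.copy() if converged else None
    return b, h, H


def _corr_loglik(bundle, pars, eta_c, eta_b, n_nodes: int):
    b_hat, h_hat, H = _corr_modes(bundle, pars, eta_c, eta_b)
    H11, H12, H22 = H
    detH = H11 * H22 - H12**2
    if n_nodes == 1:
        ll = h_hat + np.log(2 * np.pi) - 0.5 * np.log(detH)
        return float(np.sum(ll)), b_hat
    # per-subject Cholesky of the inverse curvature: inv(H) = L L^T
    inv11 = H22 / detH; inv12 = -H12 / detH; inv22 = H11 / detH
    L11 = np.sqrt(inv11)
    L21 = inv12 / L11
    L22 = np.sqrt(inv22 - L21**2)
    z, w = hermgauss(n_nodes)
    logw = np.log(w)
    vals = np.empty((n_nodes * n_nodes, bundle.n_subjects))
    r = 0
    for j in range(n_nodes):
        for k in range(n_nodes):
            d1 = np.sqrt(2.0) * L11 * z[j]
            d2 = np.sqrt(2.0) * (L21 * z[j] + L22 * z[k])
            bk = b_hat + np.column_stack([d1, d2])
            hk, _, _ = _corr_h(bundle, pars, eta_c, eta_b, bk)
            vals[r] = hk + z[j] ** 2 + z[k] ** 2 + logw[j] + logw[k]
            r += 1
    ll = logsumexp(vals, axis=0) + np.log(2.0) + np.log(L11 * L22)
    return float(np.sum(ll)), b_hat


# ---------------------------------------------------------------------------
# public likelihood / fitting

def _loglik_and_modes(theta, bundle: DesignBundle):
    spec = bundle.spec
    layout = layout_for(bundle)
    pars = layout.unpack(theta, spec)
    eta_c = _count_terms(bundle, pars)
    eta_b = _binary_terms(bundle, pars)
    if spec.random_effects == "none" or (
        spec.random_effects == "shared_intercept" and pars.get("sigma_b", 1.0) == 0.0
    ):
        b = np.zeros(bundle.n_subjects)
        h, *_ = _channel_h(
            bundle, pars, eta_c, eta_b,
            np.zeros(len(bundle.y_count)) if eta_c is not None else None,
            np.zeros(len(bundle.y_binary)) if eta_b is not None else None,
        )
        return float(np.sum(h)), b
    if spec.random_effects == "shared_intercept":
        return _shared_loglik(bundle, pars, eta_c, eta_b, spec.effective_nodes)
    return _corr_loglik(bundle, pars, eta_c, eta_b, spec.effective_nodes)


def marginal_loglik(theta, bundle: DesignBundle, spec: ModelSpec | None = None) -> float:
    """Marginal log-likelihood at packed parameters ``theta``.

    ``theta`` is ``[beta_count, beta_binary, (log sigma_e,) variance
    parameters]`` with variance parameters on the transformed scale
    (log sigma_b and free lambda for the shared intercept; log sigma1,
    log sigma2, atanh rho for correlated intercepts).
    """
    if spec is not None and spec is not bundle.spec:
        bundle = replace(bundle, spec=spec)
    ll, _ = _loglik_and_modes(np.asarray(theta, dtype=float), bundle)
    return ll


def posterior_modes(theta, bundle: DesignBundle) -> np.ndarray:
    """Per-subject posterior modes of the random effect(s) at ``theta``."""
    _, b = _loglik_and_modes(np.asarray(theta, dtype=float), bundle)
    return b


def _start_values(bundle: DesignBundle) -> np.ndarray:
    import statsmodels.api as sm

    layout = layout_for(bundle)
    spec = bundle.spec
    parts = []
    sigma_e_start = 0.3
    if layout.p_count:
        if spec.count_family == "gaussian-log":
            res = sm.OLS(bundle.y_count, bundle.X_count).fit()
            sigma_e_start = max(float(np.sqrt(res.mse_resid)), 1e-3)
            parts.append(res.params)
        else:
            try:
                res = sm.GLM(bundle.y_count, bundle.X_count,
                             family=sm.families.Poisson()).fit()
                parts.append(res.params)
            except Exception:
                beta = np.zeros(layout.p_count)
                beta[0] = np.log(max(bundle.y_count.mean(), 1e-3))
                parts.append(beta)
    if layout.p_binary:
        try:
            res = sm.GLM(bundle.y_binary, bundle.X_binary,
                         family=sm.families.Binomial()).fit()
            parts.append(np.clip(res.params, -10, 10))
        except Exception:
            beta = np.zeros(layout.p_binary)
            pbar = np.clip(bundle.y_binary.mean(), 1e-3, 1 - 1e-3)
            beta[0] = np.log(pbar / (1 - pbar))
            parts.append(beta)
    if layout.has_sigma_e:
        parts.append([np.log(sigma_e_start)])
    if layout.structure == "shared_intercept":
        parts.append([np.log(spec.sigma_b_start)])
        if layout.free_lambda:
            parts.append([1.0])
    elif layout.structure == "correlated_intercepts":
        parts.append([np.log(spec.sigma_b_start), np.log(spec.sigma_b_start), 0.0])
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _numeric_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; steps scaled to parameter magnitude."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    hstep = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hstep[i]
            ej = np.zeros(p); ej[j] = hstep[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f(x) + f(x - ei)) / hstep[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * hstep[i] * hstep[j])
    return H


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one maximum-likelihood fit."""

    coef: pd.DataFrame                     # channel, term, estimate, se, z, p
    random_effects: dict                   # variance parameters + SEs
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    message: str
    theta: np.ndarray
    vcov: np.ndarray | None
    posterior_modes: np.ndarray
    subjects: np.ndarray
    spec: ModelSpec
    n_obs: int
    flags: list = field(default_factory=list)

    @property
    def minus2_loglik(self) -> float:
        return -2.0 * self.loglik

    def coef_for(self, channel: str) -> pd.DataFrame:
        return self.coef.loc[self.coef["channel"] == channel].reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.to_dict(orient="list"),
            "random_effects": {
                k: (None if v is None or (np.isscalar(v) and not np.isfinite(v)) else v)
                for k, v in self.random_effects.items()
            },
            "loglik": self.loglik,
            "minus2_loglik": self.minus2_loglik,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "grad_norm": float(self.grad_norm),
            "message": self.message,
            "theta": np.asarray(self.theta).tolist(),
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
            "posterior_modes": np.asarray(self.posterior_modes).tolist(),
            "subjects": [str(s) for s in self.subjects],
            "n_obs": int(self.n_obs),
            "flags": list(self.flags),
            "spec": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                     for k, v in dataclasses.asdict(self.spec).items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _check_degenerate(bundle: DesignBundle) -> None:
    if bundle.n_subjects < 2:
        raise DegenerateDataError("need at least 2 subjects")
    if len(bundle.y_binary) > 0:
        m = bundle.y_binary.mean()
        if m == 0.0 or m == 1.0:
            raise DegenerateDataError(
                "binary channel is all-negative or all-positive (complete separation)"
            )


def fit_glmm(stacked: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood fit of the (possibly joint) GLMM.

    Maximises :func:`marginal_loglik` by BFGS with numerical gradients;
    standard errors come from the inverse observed information (central
    differences).  Deterministic given data, spec and starting values.
    Non-convergence is flagged on the result, never raised.
    """
    bundle = build_design(stacked, spec)
    _check_degenerate(bundle)
    layout = layout_for(bundle)
    theta0 = _start_values(bundle)

    def negll(theta):
        try:
            val = -marginal_loglik(theta, bundle)
        except FloatingPointError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        negll, theta0, method="BFGS",
        options={"gtol": spec.gtol, "maxiter": spec.maxiter},
    )
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))

    flags: list[str] = []
    H = _numeric_hessian(negll, theta)
    vcov = None
    try:
        vcov = np.linalg.inv(H)
        if not np.all(np.diag(vcov) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        if not np.all(np.diag(vcov) > 0):
            flags.append("information_not_pd")

    # BFGS often stops with "precision loss" at what is numerically the
    # optimum of an O(1e4) objective; call it converged when the Newton
    # decrement (expected remaining objective improvement) is negligible
    decrement = float(0.5 * res.jac @ vcov @ res.jac) if vcov is not None else np.inf
    converged = bool(res.success or (np.isfinite(decrement) and 0 <= decrement < 1e-4))
    if not converged:
        flags.append("non_convergence")

    pars = layout.unpack(theta, spec)
    se_all = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf)) if vcov is not None else np.full(len(theta), np.nan)

    if spec.scale_se_by_dispersion:
        fs = fit_statistics_from_bundle(theta, bundle)
        se_all = se_all * np.sqrt(max(fs["chi2_per_df"], 1.0))

    rows = []
    i = 0
    for channel, names in ((CHANNEL_COUNT, bundle.count_names if layout.p_count else []),
                           (CHANNEL_BINARY, bundle.binary_names if layout.p_binary else [])):
        for name in names:
            est, se = float(theta[i]), float(se_all[i])
            z = est / se if se > 0 else np.nan
            rows.append({"channel": channel, "term": name, "estimate": est,
                         "se": se, "z": z,
                         "p": float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan})
            i += 1
    coef = pd.DataFrame(rows)

    rand: dict = {}
    if layout.has_sigma_e:
        t_se = se_all[i]
        rand["sigma_e"] = pars["sigma_e"]
        rand["sigma_e_se"] = float(pars["sigma_e"] * t_se)  # delta method on log scale
        i += 1
    if layout.structure == "shared_intercept":
        sig = pars["sigma_b"]
        t_se = se_all[i]
        rand["sigma_b2"] = sig**2
        if sig < 1e-3:
            flags.append("boundary_sigma_b")
            rand["sigma_b2_se"] = np.nan
        else:
            rand["sigma_b2_se"] = float(2.0 * sig**2 * t_se)  # Var(e^{2t}) delta
        i += 1
        rand["lambda"] = pars["lambda"]
        if layout.free_lambda:
            rand["lambda_se"] = float(se_all[i]); i += 1
        else:
            rand["lambda_se"] = None
    elif layout.structure == "correlated_intercepts":
        for key in ("sigma1", "sigma2"):
            s = pars[key]
            rand[f"{key}2"] = s**2
            rand[f"{key}2_se"] = float(2.0 * s**2 * se_all[i])
            i += 1
        rho = pars["rho"]
        rand["rho"] = rho
        rand["rho_se"] = float((1.0 - rho**2) * se_all[i])  # d tanh(t)/dt
        i += 1

    _, modes = _loglik_and_modes(theta, bundle)
    return FitResult(
        coef=coef, random_effects=rand, loglik=float(-res.fun),
        converged=converged, n_iter=int(res.nit), grad_norm=grad_norm,
        message=str(res.message), theta=theta, vcov=vcov,
        posterior_modes=modes, subjects=bundle.subjects, spec=spec,
        n_obs=len(bundle.y_count) + len(bundle.y_binary), flags=flags,
    )


def fit_separate(stacked: pd.DataFrame, spec: ModelSpec):
    """Univariate random-intercept fits of each channel on its own rows.

    Returns ``(count_fit, binary_fit)``.  The loading is fixed at 1 in each
    univariate model (a free loading is not identified without the second
    channel).
    """
    random = spec.random_effects if spec.random_effects == "none" else "shared_intercept"
    count_spec = replace(spec, binary_terms=(), random_effects=random, lambda_binary=1.0)
    binary_spec = replace(spec, count_terms=(), random_effects=random, lambda_binary=1.0)
    count_fit = fit_glmm(stacked.loc[stacked["channel"] == CHANNEL_COUNT], count_spec)
    binary_fit = fit_glmm(stacked.loc[stacked["channel"] == CHANNEL_BINARY], binary_spec)
    return count_fit, binary_fit


def fitted_values(result: FitResult, stacked: pd.DataFrame,
                  spec: ModelSpec | None = None) -> pd.DataFrame:
    """Conditional means per stacked row, evaluated at the posterior modes."""
    spec = spec or result.spec
    bundle = build_design(stacked, spec)
    return _fitted_from_bundle(result.theta, bundle)


def _fitted_from_bundle(theta, bundle: DesignBundle) -> pd.DataFrame:
    layout = layout_for(bundle)
    pars = layout.unpack(np.asarray(theta, dtype=float), bundle.spec)
    _, b = _loglik_and_modes(np.asarray(theta, dtype=float), bundle)
    rows = []
    if len(bundle.y_count):
        eta = bundle.X_count @ pars["beta_count"]
        if bundle.spec.random_effects == "correlated_intercepts":
            eta = eta + b[bundle.subj_count, 0]
        elif bundle.spec.random_effects == "shared_intercept":
            eta = eta + b[bundle.subj_count]
        if bundle.spec.count_family == "gaussian-log":
            mu = eta
            var = np.full(len(eta), pars["sigma_e"] ** 2)
        else:
            mu = np.exp(eta)
            var = mu
        rows.append(pd.DataFrame({
            "channel": CHANNEL_COUNT, "subject": bundle.subjects[bundle.subj_count],
            "y": bundle.y_count, "mu": mu, "var": var,
        }))
    if len(bundle.y_binary):
        eta = bundle.X_binary @ pars["beta_binary"]
        if bundle.spec.random_effects == "correlated_intercepts":
            eta = eta + b[bundle.subj_binary, 1]
        elif bundle.spec.random_effects == "shared_intercept":
            eta = eta + pars["lambda"] * b[bundle.subj_binary]
        p = expit(eta)
        rows.append(pd.DataFrame({
            "channel": CHANNEL_BINARY, "subject": bundle.subjects[bundle.subj_binary],
            "y": bundle.y_binary, "mu": p, "var": p * (1.0 - p),
        }))
    return pd.concat(rows, ignore_index=True)


def fit_statistics_from_bundle(theta, bundle: DesignBundle) -> dict:
    fitted = _fitted_from_bundle(theta, bundle)
    resid2 = (fitted["y"] - fitted["mu"]) ** 2
    var = np.maximum(fitted["var"].to_numpy(), 1e-12)
    chi2 = float(np.sum(resid2.to_numpy() / var))
    df = len(fitted) - bundle.n_fixed
    if df <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")
    return {
        "pearson_chi2": chi2,
        "df": int(df),
        "chi2_per_df": chi2 / df,
        "n_obs": int(len(fitted)),
        "n_fixed_params": int(bundle.n_fixed),
    }


def fit_statistics(result: FitResult, stacked: pd.DataFrame,
                   spec: ModelSpec | None = None) -> dict:
    """Pearson generalized chi-square diagnostics of a converged fit.

    chi-square = sum over stacked rows of (y - mu_hat)^2 / V(mu_hat) with
    mu_hat conditional on the posterior modes; df = rows - fixed
    parameters.  A ratio near 1 indicates correct dispersion; values much
    larger indicate overdispersion relative to the assumed families.
    """
    spec = spec or result.spec
    bundle = build_design(stacked, spec)
    out = fit_statistics_from_bundle(result.theta, bundle)
    out["minus2_loglik"] = result.minus2_loglik
    return out
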