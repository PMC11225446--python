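"""Synthetic-cohort generator.

Generates HIV/ART cohorts with exactly the statistical structure the joint
model assumes: for patient *i* with shared random intercept
``b_i ~ Normal(0, sigma_b^2)`` and covariate row ``x_ij`` at visit *j*,

* CD4 count:  ``Y1_ij ~ Poisson(exp(x_ij . beta_count + b_i))``
* TB screen:  ``Y2_ij ~ Bernoulli(logit^-1(x_ij . beta_binary + lambda_binary * b_i))``

so the two channels are conditionally independent given ``b_i`` and the
cross-outcome association is carried entirely by the shared intercept.
Covariates are drawn from marginal distributions matched to the cohort the
model is meant for (a ~1,400-patient Ethiopian ART clinic population:
61% female, TB-screen-positive prevalence near 0.87, weight ~ N(57.3,
10.4) kg, etc.); weight and hemoglobin drift over visits as random walks,
everything else is time-constant.  Dropout is geometric: each retained
patient returns for the next visit with a fixed retention probability.

Two generator switches mirror the engine's options: a Gaussian-on-log-CD4
count channel (``count_family="gaussian-log"``) and negative-binomial
overdispersion (``count_dispersion=k`` mixes the Poisson rate with a
Gamma(k, 1/k) frailty) for misspecification experiments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .schema import CANONICAL_COLUMNS
from ._utils import check_rate

__all__ = ["SyntheticTruth", "default_truth", "simulate_cohort", "inject_missingness"]


#: marginal categorical frequencies (cohort proportions; normalised on use)
DEFAULT_CATEGORICAL_PROBS = {
    "gender": {0: 860, 1: 548},
    "marital_status": {1: 217, 2: 668, 3: 429, 4: 94},
    "religion": {1: 1078, 2: 197, 3: 45, 4: 88},
    "education": {0: 61, 1: 258, 2: 396, 3: 693},
    "occupation": {0: 283, 1: 87, 2: 62, 3: 328, 4: 238, 5: 106, 6: 304},
    "functional_status": {1: 1275, 2: 89, 3: 44},
    "who_stage": {1: 1190, 2: 108, 3: 67, 4: 12},
    "oi_status": {1: 49, 0: 1359},
    "adherence": {1: 1197, 2: 28, 3: 183},
    "regimen": {0: 70, 1: 70, 2: 140, 3: 140, 4: 848, 5: 140},
}

#: truncated-normal marginals: (mean, sd, min, max)
DEFAULT_CONTINUOUS_DISTS = {
    "age": (35.0, 10.0, 15.0, 70.0),
    "weight": (57.3, 10.4, 24.9, 88.0),
    "hemoglobin": (30.3, 83.8, 9.1, 888.0),
    "baseline_cd4": (293.0, 167.0, 65.0, 980.0),
}


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a simulated cohort.

    Fixed effects are dicts keyed by term: ``"intercept"``, a continuous
    column name, or ``"column[level]"`` for a categorical dummy (levels not
    listed get coefficient 0, so the omitted last level is the reference).
    ``lambda_binary`` is the binary channel's loading on the shared
    intercept; the count channel's loading is fixed at 1.
    """

    beta_count: dict = field(default_factory=dict)
    beta_binary: dict = field(default_factory=dict)
    sigma_b: float = 0.3415          # sqrt of a random-intercept variance of 0.1166
    lambda_binary: float = 1.0
    n_patients: int = 1400
    max_visits: int = 10
    retention: float = 0.9           # P(return for visit j+1 | seen at visit j)
    categorical_probs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORICAL_PROBS.items()}
    )
    continuous_dists: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS_DISTS)
    )
    rw_sd: dict = field(default_factory=lambda: {"weight": 0.5, "hemoglobin": 1.0})
    count_family: str = "poisson"    # or "gaussian-log"
    sigma_e: float = 0.35            # residual sd of the gaussian-log channel
    count_dispersion: float | None = None  # NB size k; None = pure Poisson
    seed: int = 0

    def __post_init__(self):
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if not (0.0 < self.retention <= 1.0):
            raise ValueError("retention must be in (0, 1]")
        if self.count_family not in ("poisson", "gaussian-log"):
            raise ValueError(f"unknown count_family {self.count_family!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_truth(**overrides) -> SyntheticTruth:
    """Truth with effect magnitudes anchored to the target cohort.

    The opportunistic-infection log-odds effect is 1.798 and the weight and
    hemoglobin log-odds effects are log(1.14) and log(1.05) per unit on the
    binary channel; the random-intercept variance is 0.1166.  Intercepts are
    set so the simulated marginal CD4 mean is near 396 cells/mm^3 and the
    TB-screen-positive fraction near 0.87.
    """
    beta_count = {
        "intercept": 5.30,
        "visit": 0.018,
        "weight": 0.003,
        "hemoglobin": 0.004,
    }
    beta_binary = {
        "intercept": -7.8,
        "oi_status": 1.798,
        "weight": 0.131,       # log(1.14) per kg
        "hemoglobin": 0.049,   # log(1.05) per g/dl
    }
    params = dict(beta_count=beta_count, beta_binary=beta_binary)
    params.update(overrides)
    return SyntheticTruth(**params)


def linear_predictor(df: pd.DataFrame, beta: dict) -> np.ndarray:
    """Evaluate ``x . beta`` rowwise for a term-keyed coefficient dict."""
    eta = np.zeros(len(df))
    for term, coef in beta.items():
        if term == "intercept":
            eta += coef
        elif "[" in term:
            col, level = term[:-1].split("[")
            eta += coef * (df[col].to_numpy() == float(level))
        else:
            eta += coef * df[term].to_numpy(dtype=float)
    return eta


def _draw_covariates(truth: SyntheticTruth, rng: np.random.Generator) -> pd.DataFrame:
    n = truth.n_patients
    cols = {"patient_id": [f"P{i:05d}" for i in range(1, n + 1)]}
    for col, probs in truth.categorical_probs.items():
        levels = np.array(sorted(probs), dtype=float)
        p = np.array([probs[k] for k in sorted(probs)], dtype=float)
        p = p / p.sum()
        cols[col] = rng.choice(levels, size=n, p=p)
    for col, (mean, sd, lo, hi) in truth.continuous_dists.items():
        a, b = (lo - mean) / sd, (hi - mean) / sd
        draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        if col == "baseline_cd4":
            draws = np.round(draws)
        cols[col] = draws
    return pd.DataFrame(cols)


def simulate_cohort(truth: SyntheticTruth, return_latent: bool = False):
    """Simulate a long-format cohort from ``truth``.

    Returns ``(cohort_frame, truth)`` — the truth is echoed back so callers
    can serialise generator parameters next to the data for recovery tests.
    With ``return_latent=True`` a third frame carries the per-row latent
    quantities (random intercept, conditional mean of each channel).
    """
    rng = np.random.default_rng(truth.seed)
    base = _draw_covariates(truth, rng)
    n = truth.n_patients
    b = rng.normal(0.0, truth.sigma_b, size=n)

    # geometric dropout: number of visits made, in 1..max_visits
    cont = rng.random(size=(n, truth.max_visits - 1)) < truth.retention
    n_visits = 1 + np.cumprod(cont, axis=1).sum(axis=1).astype(int)

    rows = []
    for j in range(1, truth.max_visits + 1):
        alive = n_visits >= j
        if not alive.any():
            break
        sub = base.loc[alive].copy()
        sub.insert(1, "visit", j)
        rows.append(sub)
    long = pd.concat(rows, ignore_index=True)

    # random-walk drift of the time-varying labs, applied visit over visit
    long = long.sort_values(["patient_id", "visit"], kind="stable").reset_index(drop=True)
    for col, sd in truth.rw_sd.items():
        steps = rng.normal(0.0, sd, size=len(long))
        steps[long["visit"].to_numpy() == 1] = 0.0
        offset = (
            pd.Series(steps).groupby(long["patient_id"].to_numpy()).cumsum().to_numpy()
        )
        lo = truth.continuous_dists.get(col, (0.0, 1.0, 0.1, np.inf))[2]
        long[col] = np.maximum(long[col].to_numpy() + offset, lo)

    b_row = b[pd.factorize(long["patient_id"], sort=False)[0]]
    eta_c = linear_predictor(long, truth.beta_count) + b_row
    eta_b = linear_predictor(long, truth.beta_binary) + truth.lambda_binary * b_row
    p_binary = expit(eta_b)

    if truth.count_family == "gaussian-log":
        logs = rng.normal(eta_c, truth.sigma_e)
        cd4 = np.round(np.expm1(np.maximum(logs, 0.0)))
        mu_c = np.expm1(eta_c + 0.5 * truth.sigma_e**2)
    else:
        rate = np.exp(eta_c)
        if truth.count_dispersion is not None:
            k = float(truth.count_dispersion)
            rate = rate * rng.gamma(shape=k, scale=1.0 / k, size=len(long))
        cd4 = rng.poisson(rate).astype(float)
        mu_c = np.exp(eta_c)
    tb = (rng.random(len(long)) < p_binary).astype(float)

    long["cd4_count"] = cd4
    long["tb_status"] = tb
    cohort = long[CANONICAL_COLUMNS].copy()
    if return_latent:
        latent = pd.DataFrame(
            {
                "patient_id": long["patient_id"],
                "visit": long["visit"],
                "b": b_row,
                "mu_count": mu_c,
                "p_binary": p_binary,
            }
        )
        return cohort, truth, latent
    return cohort, truth


def inject_missingness(
    records: pd.DataFrame,
    mechanism: str = "MCAR",
    rates: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Blank cells of the targeted columns at the given per-column rates.

    MCAR blanks each cell independently with its column's rate.  MAR makes
    the missingness of a cell depend on fully observed quantities: the cell's
    probability of being blanked is the column rate multiplied by a weight
    of 1.5 for TB-positive rows vs 0.5 for TB-negative rows (for ``weight``
    and ``hemoglobin``) or proportional to the visit index (other columns),
    normalised so the average probability stays at the nominal rate.
    Identifiers are never removed.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    rates = rates or {}
    for col, rate in rates.items():
        check_rate(rate, f"rates[{col!r}]")
        if col in ("patient_id", "visit"):
            raise ValueError(f"cannot inject missingness into {col}")
    rng = np.random.default_rng(seed)
    out = records.copy()
    for col, rate in rates.items():
        if mechanism == "MCAR":
            p = np.full(len(out), rate)
        else:
            if col in ("weight", "hemoglobin") and out["tb_status"].notna().all():
                w = np.where(out["tb_status"].to_numpy() == 1.0, 1.5, 0.5)
            else:
                w = out["visit"].to_numpy(dtype=float)
            p = np.clip(rate * w / w.mean(), 0.0, 1.0)
        mask = rng.random(len(out)) < p
        out.loc[mask, col] = np.nan
    return out
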