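"""Descriptive layer: cross-tabulations, continuous summaries, trajectories.

Cross-tabs follow the baseline-characteristics-table convention: one row
per patient (first visit) split by TB screening result, every cell expressed
as a percentage of the total number of patients, rounded half away from
zero to one decimal.  A per-visit counting mode is available for cohorts
where the table is meant over all visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CATEGORICAL_LEVELS
from ._utils import round_half_away

__all__ = ["CrossTab", "ContinuousSummary", "cross_tab", "continuous_summary",
           "trajectory_series"]


@dataclass
class CrossTab:
    """Counts and overall percentages of one categorical variable by TB status."""

    variable: str
    levels: list
    neg_counts: list
    pos_counts: list
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        neg = np.asarray(self.neg_counts, dtype=int)
        pos = np.asarray(self.pos_counts, dtype=int)
        tot = neg + pos
        pct = lambda c: round_half_away(100.0 * c / self.n_total, 1)
        return pd.DataFrame(
            {
                "variable": self.variable,
                "level": self.levels,
                "tb_negative_count": neg,
                "tb_negative_pct": pct(neg),
                "tb_positive_count": pos,
                "tb_positive_pct": pct(pos),
                "total_count": tot,
                "total_pct": pct(tot),
            }
        )

    def cell_pct(self, level, tb_positive: bool = True) -> float:
        """Overall percentage of one cell (count / N_total * 100, 1 dp)."""
        i = self.levels.index(level)
        count = (self.pos_counts if tb_positive else self.neg_counts)[i]
        return round_half_away(100.0 * count / self.n_total, 1)


@dataclass
class ContinuousSummary:
    variable: str
    n: int
    mean: float | None = None
    minimum: float | None = None
    maximum: float | None = None
    sd: float | None = None
    empty: bool = False


def _one_row_per_patient(records: pd.DataFrame) -> pd.DataFrame:
    first = records.sort_values(["patient_id", "visit"], kind="stable")
    return first.groupby("patient_id", sort=True).first().reset_index()


def cross_tab(records: pd.DataFrame, variable: str, mode: str = "baseline") -> CrossTab:
    """Cross-tabulate a categorical covariate against TB screening status.

    ``mode="baseline"`` counts one row per patient (first visit);
    ``mode="per_visit"`` counts every patient-visit row.  Rows with a
    missing value of the variable or of TB status are excluded from the
    cells but N_total is the number of counted rows with both observed.
    """
    if variable not in CATEGORICAL_LEVELS:
        raise ValueError(f"{variable!r} is not a categorical cohort variable")
    if mode == "baseline":
        df = _one_row_per_patient(records)
    elif mode == "per_visit":
        df = records
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df = df.loc[df[variable].notna() & df["tb_status"].notna()]
    levels = [lv for lv in CATEGORICAL_LEVELS[variable]]
    neg = [int(((df[variable] == lv) & (df["tb_status"] == 0.0)).sum()) for lv in levels]
    pos = [int(((df[variable] == lv) & (df["tb_status"] == 1.0)).sum()) for lv in levels]
    return CrossTab(variable, levels, neg, pos, n_total=len(df))


def continuous_summary(records: pd.DataFrame, variables: list[str]) -> list[ContinuousSummary]:
    """Mean / min / max / sample SD (n-1 denominator) per variable.

    Missing cells are excluded variable-by-variable; an all-missing column
    yields a summary flagged ``empty`` instead of NaN propagation.
    """
    out = []
    for var in variables:
        vals = pd.to_numeric(records[var], errors="coerce").dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            out.append(ContinuousSummary(var, n=0, empty=True))
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(
            ContinuousSummary(
                var,
                n=len(vals),
                mean=float(vals.mean()),
                minimum=float(vals.min()),
                maximum=float(vals.max()),
                sd=sd,
            )
        )
    return out


def summaries_to_frame(summaries: list[ContinuousSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [s.variable for s in summaries],
            "mean": [s.mean for s in summaries],
            "minimum": [s.minimum for s in summaries],
            "maximum": [s.maximum for s in summaries],
            "sd": [s.sd for s in summaries],
            "n": [s.n for s in summaries],
        }
    )


@dataclass
class TrajectoryData:
    """Plot-ready longitudinal series (rendering is optional and separate)."""

    per_patient: pd.DataFrame  # patient_id, visit, cd4_count, tb_status
    per_visit: pd.DataFrame    # visit, cd4_mean, tb_positive_fraction, n

    def plot(self, path=None):
        """Render the individual CD4 profiles and the per-visit means."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for _, grp in self.per_patient.groupby("patient_id"):
            axes[0].plot(grp["visit"], grp["cd4_count"], color="grey", alpha=0.2, lw=0.6)
        axes[0].set(xlabel="visit", ylabel="CD4 count", title="Individual profiles")
        ax2 = axes[1]
        ax2.plot(self.per_visit["visit"], self.per_visit["cd4_mean"], "o-", label="mean CD4")
        ax2.set(xlabel="visit", ylabel="mean CD4 count")
        ax3 = ax2.twinx()
        ax3.plot(
            self.per_visit["visit"], self.per_visit["tb_positive_fraction"],
            "s--", color="firebrick", label="TB+ fraction",
        )
        ax3.set_ylabel("TB-positive fraction")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def trajectory_series(records: pd.DataFrame) -> TrajectoryData:
    """Per-patient CD4/TB series plus per-visit mean CD4 and TB+ fraction."""
    per_patient = (
        records[["patient_id", "visit", "cd4_count", "tb_status"]]
        .sort_values(["patient_id", "visit"], kind="stable")
        .reset_index(drop=True)
    )
    grouped = records.groupby("visit", sort=True)
    per_visit = pd.DataFrame(
        {
            "visit": list(grouped.groups),
            "cd4_mean": grouped["cd4_count"].mean().to_numpy(),
            "tb_positive_fraction": grouped["tb_status"].mean().to_numpy(),
            "n": grouped.size().to_numpy(),
        }
    )
    return TrajectoryData(per_patient=per_patient, per_visit=per_visit)
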