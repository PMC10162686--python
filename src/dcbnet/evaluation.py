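"""Model evaluation: ROC/AUC and survival stratification.

ROC analysis scores patients by their predicted probability of durable
clinical benefit; the AUC equals the Mann–Whitney concordance probability
(ties counted 1/2).  Survival stratification splits the cohort by the
binary DCB prediction and compares progression-free survival between the
two predicted groups with Kaplan–Meier curves and a two-group log-rank
test (events precede censorings at tied times, the standard convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .cohort_io import BENEFIT, CLASS_VAR, CohortTable
from .inference import predict_label, predict_proba
from .models import FittedClassifier

__all__ = [
    "ROCResult",
    "SurvivalCurve",
    "LogRankResult",
    "StratificationResult",
    "roc_curve",
    "kaplan_meier",
    "log_rank_test",
    "stratify_by_prediction",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be nondecreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0
                and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must span (0,0) to (1,1)")
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SurvivalCurve:
    """Kaplan–Meier step function with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities outside [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival function must be nonincreasing")

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous)."""
        k = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if k < 0 else float(self.survival[k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    df: int = 1

    def __post_init__(self) -> None:
        if self.chi_square < 0:
            raise ValueError("chi-square must be >= 0")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class StratificationResult:
    groups: pd.Series
    curves: dict[str, SurvivalCurve]
    logrank: LogRankResult | None


def roc_curve(scores: Sequence[float], labels: Sequence[str] | Sequence[int],
              positive: str | int = BENEFIT) -> ROCResult:
    """ROC curve with thresholds at the unique scores (plus sentinels).

    The trapezoidal AUC equals the Mann–Whitney concordance probability
    with tied scores counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    # cut after each run of tied scores
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def kaplan_meier(
    times: Sequence[float], events: Sequence[float], label: str = ""
) -> SurvivalCurve:
    """Product-limit survival estimate S(t) = prod (1 - d_t / n_t)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    grid = tbl.index.values.astype(float)
    surv = kmf.survival_function_at_times(grid).values
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=tbl["at_risk"].values.astype(int),
        label=label,
    )


def log_rank_test(
    times: Sequence[float],
    events: Sequence[float],
    group: Sequence,
) -> LogRankResult:
    """Two-group log-rank test (chi-square statistic on 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    m0, m1 = group == levels[0], group == levels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("both groups must be nonempty")
    res = _lifelines_logrank(times[m0], times[m1], events[m0], events[m1])
    return LogRankResult(
        chi_square=float(res.test_statistic), p_value=float(res.p_value), df=1
    )


def stratify_by_prediction(
    model: FittedClassifier,
    cohort: CohortTable,
    threshold: float = 0.5,
) -> StratificationResult:
    """Split a cohort by the model's binary DCB call and compare survival.

    Patients with missing features are scored by exact conditional
    inference over the network.  Returns per-group Kaplan–Meier curves and
    the log-rank comparison; if every patient lands in one group a warning
    is issued and no test is run.
    """
    df = cohort.data
    has_surv = df["pfs_months"].notna() & df["pfs_event"].notna()
    if not has_surv.any():
        raise ValueError("cohort has no usable survival data")
    probs = predict_proba(model, cohort)
    calls = pd.Series(
        [predict_label(float(p), threshold) for p in probs],
        index=df.index,
        name="predicted_group",
    )
    sub = df[has_surv]
    sub_calls = calls[has_surv]
    curves = {
        g: kaplan_meier(
            sub.loc[sub_calls == g, "pfs_months"],
            sub.loc[sub_calls == g, "pfs_event"],
            label=g,
        )
        for g in sub_calls.unique()
    }
    if len(curves) < 2:
        warnings.warn("all patients predicted into one group; no log-rank test")
        logrank = None
    else:
        logrank = log_rank_test(
            sub["pfs_months"].values, sub["pfs_event"].values, sub_calls.values
        )
    return StratificationResult(groups=calls, curves=curves, logrank=logrank)
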