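"""Kaplan–Meier estimation, log-rank testing, and reference-survival
comparison for the class-stratified cohorts.

The product-limit estimator and its Greenwood variance are computed directly
because the reported confidence intervals use the plain-scale normal
approximation, S(t) ± 1.96·√var, clipped to [0, 1] (no log(−log) transform).
Deaths precede censorings at tied times, the standard KM convention.
Log-rank machinery (global K-group test and Bonferroni-corrected pairwise
tests) is delegated to lifelines.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import CalibrationError, ContractError


@dataclass(frozen=True)
class SurvivalInput:
    """One subject: follow-up time in years and a death indicator."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")


@dataclass
class SurvivalCurve:
    times: np.ndarray       # distinct event (death) times, increasing
    estimates: np.ndarray   # S(t) just after each event time
    variance: np.ndarray    # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray     # number at risk just before each event time
    n_subjects: int
    max_followup: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "estimate": self.estimates,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


@dataclass(frozen=True)
class SurvivalPoint:
    estimate: float
    ci: tuple[float, float]
    extrapolated: bool = False


def _split(inputs: Sequence[SurvivalInput]) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([s.time for s in inputs], dtype=float)
    events = np.asarray([s.event for s in inputs], dtype=bool)
    return times, events


def km_estimate(
    inputs: Sequence[SurvivalInput], alpha: float = 0.05
) -> SurvivalCurve:
    """Product-limit estimate with Greenwood variance and plain-scale CI."""
    if len(inputs) == 0:
        raise ContractError("km_estimate requires at least one subject")
    times, events = _split(inputs)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    death_times = np.unique(times[events])

    n = len(times)
    z = stats.norm.ppf(1 - alpha / 2)
    est, var_terms, at_risk_out = [], [], []
    surv = 1.0
    greenwood = 0.0
    for t in death_times:
        at_risk = int(np.sum(times >= t))  # deaths precede censorings at ties
        d = int(np.sum((times == t) & events))
        surv *= (at_risk - d) / at_risk
        if at_risk > d:
            greenwood += d / (at_risk * (at_risk - d))
        else:
            greenwood = np.inf  # S hits 0; variance term degenerates
        est.append(surv)
        var_terms.append(greenwood)
        at_risk_out.append(at_risk)

    est_arr = np.asarray(est)
    gw = np.asarray(var_terms)
    with np.errstate(invalid="ignore"):
        var = np.where(np.isfinite(gw), est_arr**2 * gw, 0.0)
    half = z * np.sqrt(var)
    return SurvivalCurve(
        times=death_times,
        estimates=est_arr,
        variance=var,
        ci_lower=np.clip(est_arr - half, 0.0, 1.0),
        ci_upper=np.clip(est_arr + half, 0.0, 1.0),
        at_risk=np.asarray(at_risk_out, dtype=np.int64),
        n_subjects=n,
        max_followup=float(times.max()),
    )


def survival_at(curve: SurvivalCurve, t: float) -> SurvivalPoint:
    """Right-continuous step evaluation: S at the largest event time ≤ t.

    Beyond the last follow-up the last estimate is returned with
    ``extrapolated=True``.
    """
    if t < 0:
        raise ContractError("t must be >= 0")
    extrapolated = t > curve.max_followup
    k = int(np.searchsorted(curve.times, t, side="right")) - 1
    if k < 0:
        return SurvivalPoint(1.0, (1.0, 1.0), extrapolated)
    return SurvivalPoint(
        float(curve.estimates[k]),
        (float(curve.ci_lower[k]), float(curve.ci_upper[k])),
        extrapolated,
    )


def _stack_groups(
    groups: Sequence[Sequence[SurvivalInput]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times, events, labels = [], [], []
    for g, inputs in enumerate(groups):
        if len(inputs) == 0:
            raise ContractError("log-rank groups must be non-empty")
        t, e = _split(inputs)
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), g))
    return np.concatenate(times), np.concatenate(events), np.concatenate(labels)


def logrank_test(
    groups: Sequence[Sequence[SurvivalInput]],
) -> tuple[float, int, float]:
    """K-group log-rank chi-square (hypergeometric tie handling).

    Returns (statistic, degrees of freedom, p-value); df = K − 1.
    """
    if len(groups) < 2:
        raise ContractError("log-rank needs >= 2 groups")
    times, events, labels = _stack_groups(groups)
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def pairwise_logrank(
    groups: Mapping[object, Sequence[SurvivalInput]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All unordered pairs, Bonferroni-adjusted decisions at alpha / n_pairs.

    The correction is applied as a threshold adjustment; decisions equal
    those from multiplying p-values by the pair count.
    """
    labels = list(groups)
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        stat, _, p = logrank_test([groups[a], groups[b]])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": stat,
                "p_value": p,
                "adjusted_threshold": alpha / m,
                "significant": p < alpha / m,
            }
        )
    return pd.DataFrame(rows)


class ReferenceSurvivalTable:
    """Published 2- and 5-year survival probabilities per fine TNM stage."""

    def __init__(self, table: Mapping[str, tuple[float, float]]):
        for stage, (s2, s5) in table.items():
            if not (0 <= s5 <= s2 <= 1):
                raise CalibrationError(
                    f"stage {stage}: need 0 <= 5-year <= 2-year <= 1, got ({s2}, {s5})"
                )
        self._table = dict(table)

    @classmethod
    def default(cls) -> "ReferenceSurvivalTable":
        """The packaged reference table (IASLC staging-project rates)."""
        with resources.files("stageinv.data").joinpath(
            "reference_survival.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
        return cls(
            {
                row.stage: (float(row.survival_2yr), float(row.survival_5yr))
                for row in df.itertuples()
            }
        )

    def survival(self, stage: str, years: int) -> float:
        s2, s5 = self._table[stage]
        if years == 2:
            return s2
        if years == 5:
            return s5
        raise KeyError("reference table carries 2- and 5-year rates only")

    def stages(self) -> list[str]:
        return list(self._table)


def compare_to_reference(
    curves: Mapping[int, SurvivalCurve],
    class_to_stages: Mapping[int, Sequence[str]],
    reference: ReferenceSurvivalTable,
) -> pd.DataFrame:
    """Per-class predicted 2-/5-year survival vs the reference stage rates.

    Classes mapping to several stages (surgery-only covers IA/IB/IIA) get one
    row per reference stage with no single signed difference; a class whose
    follow-up is shorter than 5 years has its 5-year cells flagged
    unavailable.
    """
    rows = []
    for class_id, curve in sorted(curves.items()):
        stages = list(class_to_stages[class_id])
        p2 = survival_at(curve, 2.0)
        p5 = survival_at(curve, 5.0)
        five_ok = curve.max_followup >= 5.0
        single = len(stages) == 1
        for stage in stages:
            r2 = reference.survival(stage, 2)
            r5 = reference.survival(stage, 5)
            rows.append(
                {
                    "class_id": class_id,
                    "n": curve.n_subjects,
                    "stage": stage,
                    "reference_2yr": r2,
                    "reference_5yr": r5,
                    "predicted_2yr": p2.estimate,
                    "predicted_2yr_lo": p2.ci[0],
                    "predicted_2yr_hi": p2.ci[1],
                    "predicted_5yr": p5.estimate if five_ok else np.nan,
                    "predicted_5yr_lo": p5.ci[0] if five_ok else np.nan,
                    "predicted_5yr_hi": p5.ci[1] if five_ok else np.nan,
                    "diff_2yr": p2.estimate - r2 if single else np.nan,
                    "diff_5yr": p5.estimate - r5 if single and five_ok else np.nan,
                    "five_year_available": five_ok,
                }
            )
    return pd.DataFrame(rows)
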