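"""Validation machinery: confusion matrix, one-vs-rest stage metrics, and
percentile-bootstrap confidence intervals.

All metrics are one-vs-rest constructions on the 4x4 coarse-stage confusion
matrix (rows = reference stage, columns = inferred stage).  For a hard
rule-based classifier no score axis exists, so the c-statistic is the
balanced accuracy (sensitivity + specificity)/2, which equals the
trapezoidal area under the two-point ROC.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedCIError, UndefinedMetricError
from .rounding import round_half_away
from .staging import COARSE_STAGES, StageLabel

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1", "c_statistic")


@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # rows = reference, columns = inferred
    n_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape must match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("cell sum must equal n_total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass
class MetricSet:
    """Point values in [0,1]; None where a denominator was zero.

    ``ci`` optionally maps metric name -> (lower, upper).
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    c_statistic: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def value(self, name: str) -> float | None:
        return getattr(self, name)


def _as_indices(
    pairs: Sequence[tuple[StageLabel, StageLabel]]
) -> tuple[np.ndarray, np.ndarray]:
    idx = {s: i for i, s in enumerate(COARSE_STAGES)}
    ref = np.empty(len(pairs), dtype=np.int64)
    inf = np.empty(len(pairs), dtype=np.int64)
    for k, (r, c) in enumerate(pairs):
        if not (r.is_coarse and c.is_coarse):
            raise ContractError("confusion matrix requires coarse labels")
        ref[k] = idx[r.value]
        inf[k] = idx[c.value]
    return ref, inf


def _counts_from_indices(ref: np.ndarray, inf: np.ndarray) -> np.ndarray:
    k = len(COARSE_STAGES)
    return np.bincount(ref * k + inf, minlength=k * k).reshape(k, k)


def confusion_matrix(
    pairs: Sequence[tuple[StageLabel, StageLabel]]
) -> ConfusionMatrix:
    """Count (reference, inferred) coarse-stage pairs into a 4x4 grid."""
    if len(pairs) == 0:
        zero = np.zeros((4, 4), dtype=np.int64)
        return ConfusionMatrix(COARSE_STAGES, zero, 0)
    ref, inf = _as_indices(pairs)
    return ConfusionMatrix(COARSE_STAGES, _counts_from_indices(ref, inf), len(pairs))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.n_total == 0:
        raise UndefinedMetricError("accuracy undefined on an empty matrix")
    return float(np.trace(cm.counts)) / cm.n_total


def one_vs_rest_counts(cm: ConfusionMatrix, stage: str) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) collapsing the matrix against ``stage``."""
    if stage not in cm.labels:
        raise ContractError(f"unknown stage {stage!r}")
    i = cm.labels.index(stage)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum() - tp)
    fn = int(cm.counts[i, :].sum() - tp)
    tn = int(cm.n_total - tp - fp - fn)
    return tp, fp, fn, tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def f1_score(sensitivity: float, ppv: float) -> float | None:
    """Harmonic mean of sensitivity (recall) and PPV (precision)."""
    if sensitivity + ppv == 0:
        return None
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def c_statistic(sensitivity: float, specificity: float) -> float:
    """Concordance of a hard binary classifier: balanced accuracy."""
    return (sensitivity + specificity) / 2


def one_vs_rest_metrics(cm: ConfusionMatrix, stage: str) -> MetricSet:
    """All six stage-vs-rest metrics; zero-denominator metrics come back None,
    the rest are still computed."""
    if cm.n_total == 0:
        raise UndefinedMetricError("metrics undefined on an empty matrix")
    tp, fp, fn, tn = one_vs_rest_counts(cm, stage)
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    f1 = f1_score(sens, ppv) if sens is not None and ppv is not None else None
    cstat = c_statistic(sens, spec) if sens is not None and spec is not None else None
    return MetricSet(sens, spec, ppv, npv, f1, cstat)


# ---------------------------------------------------------------------------
# named metric functions over (reference, inferred) index arrays, for the
# bootstrap (vectorized resampling needs array-level metrics)

def accuracy_metric() -> Callable[[np.ndarray, np.ndarray], float]:
    def fn(ref: np.ndarray, inf: np.ndarray) -> float:
        return float(np.mean(ref == inf))

    return fn


def ovr_metric(name: str, stage: str) -> Callable[[np.ndarray, np.ndarray], float]:
    """One-vs-rest metric ``name`` for ``stage`` as an array function.

    Returns NaN when the denominator is zero in a given (re)sample.
    """
    if name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {name!r}")
    i = COARSE_STAGES.index(stage)

    def fn(ref: np.ndarray, inf: np.ndarray) -> float:
        r = ref == i
        c = inf == i
        tp = int(np.sum(r & c))
        fp = int(np.sum(~r & c))
        fn_ = int(np.sum(r & ~c))
        tn = int(np.sum(~r & ~c))
        sens = tp / (tp + fn_) if tp + fn_ else math.nan
        spec = tn / (tn + fp) if tn + fp else math.nan
        ppv = tp / (tp + fp) if tp + fp else math.nan
        npv = tn / (tn + fn_) if tn + fn_ else math.nan
        if name == "sensitivity":
            return sens
        if name == "specificity":
            return spec
        if name == "ppv":
            return ppv
        if name == "npv":
            return npv
        if name == "f1":
            if math.isnan(sens) or math.isnan(ppv) or sens + ppv == 0:
                return math.nan
            return 2 * sens * ppv / (sens + ppv)
        return (sens + spec) / 2

    return fn


def bootstrap_ci(
    pairs: Sequence[tuple[StageLabel, StageLabel]],
    metric: Callable[[np.ndarray, np.ndarray], float],
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    redraw_cap: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval over patient-level resamples.

    Resamples with an undefined metric (NaN) are redrawn; after
    ``redraw_cap * B`` extra draws the CI is declared undefined.
    """
    if B < 1:
        raise ContractError("B must be >= 1")
    if len(pairs) == 0:
        raise ContractError("bootstrap requires a non-empty sample")
    ref, inf = _as_indices(pairs)
    n = len(ref)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    filled = 0
    redraws = 0
    while filled < B:
        idx = rng.integers(0, n, size=n)
        v = metric(ref[idx], inf[idx])
        if math.isnan(v):
            redraws += 1
            if redraws > redraw_cap * B:
                raise UndefinedCIError(redraws, redraw_cap * B)
            continue
        values[filled] = v
        filled += 1
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def metric_table(
    pairs: Sequence[tuple[StageLabel, StageLabel]],
    B: int = 1000,
    seed: int | None = None,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Formatted table of the six metrics by stage, "point (lower, upper)".

    Rows are metrics, columns are coarse stages (same shape as the published
    validation tables); raw values are available via ``one_vs_rest_metrics``.
    """
    cm = confusion_matrix(pairs)
    cells: dict[str, list[str]] = {}
    for k, stage in enumerate(COARSE_STAGES):
        ms = one_vs_rest_metrics(cm, stage)
        col = []
        for j, name in enumerate(METRIC_NAMES):
            v = ms.value(name)
            if v is None:
                col.append("NA")
                continue
            # one deterministic seed per (stage, metric) cell
            cell_seed = None if seed is None else seed + 101 * k + j
            lo, hi = bootstrap_ci(pairs, ovr_metric(name, stage), B=B, seed=cell_seed)
            col.append(
                f"{round_half_away(v, ndigits):.{ndigits}f} "
                f"({round_half_away(lo, ndigits):.{ndigits}f}, "
                f"{round_half_away(hi, ndigits):.{ndigits}f})"
            )
        cells[stage] = col
    out = pd.DataFrame(cells, index=list(METRIC_NAMES))
    out.index.name = "metric"
    return out.reset_index()
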