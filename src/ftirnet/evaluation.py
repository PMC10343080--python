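"""Diagnostic metrics with percentile-bootstrap confidence intervals.

The suite is F1, accuracy, precision, recall (from the 2x2 confusion table
against the immunoassay-strip reference) and AUROC on the continuous scores.
Confidence intervals are percentile bootstrap (2.5th/97.5th) over 10,000
resamples of (prediction, label) pairs; the model is not refit per resample.
A secondary analysis summarises fentanyl concentration among true positives
caught by the network but missed by a comparator detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "LowConcentrationSummary",
    "confusion",
    "metrics",
    "auroc",
    "bootstrap_ci",
    "metrics_report",
    "compare_detectors",
    "low_concentration_summary",
    "roc_curve_points",
    "format_report_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Point estimates (percent) and 95 % bootstrap CIs for the five
    diagnostics, plus the underlying confusion counts."""

    counts: ConfusionCounts
    f1: float | None
    accuracy: float
    precision: float | None
    recall: float | None
    auroc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_bootstrap: int = 0
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


@dataclass
class LowConcentrationSummary:
    n_caught_missed: int
    median_pct: float | None
    q1_pct: float | None
    q3_pct: float | None


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a).astype(int)
    if set(np.unique(a)) - {0, 1}:
        raise ValueError(f"{name} must be binary 0/1")
    return a


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """2x2 tally with truth == 1 as the positive class."""
    p = _check_binary(np.asarray(pred), "pred")
    t = _check_binary(np.asarray(truth), "truth")
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(t)} labels")
    if len(p) == 0:
        raise ValueError("empty input")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
    )


def metrics(
    counts: ConfusionCounts,
) -> tuple[float | None, float, float | None, float | None]:
    """(f1, accuracy, precision, recall) as fractions; ratios with a zero
    denominator are returned as None (undefined), never coerced to 0."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == 0 or recall == 0:
        f1 = 0.0
    else:
        f1 = None
    accuracy = (tp + tn) / counts.total
    return f1, accuracy, precision, recall


def auroc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative, ties
    half-credited (rank / Mann-Whitney formulation on continuous scores)."""
    s = np.asarray(scores, dtype=float)
    t = _check_binary(np.asarray(truth), "truth")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: need at least one of each class")
    ranks = rankdata(s)  # average ranks handle ties with half credit
    return float((ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_ci(
    values: np.ndarray,
    truth: np.ndarray,
    metric_fn: Callable[[np.ndarray, np.ndarray], float | None],
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a metric of paired (value, truth) data.

    Resamples pairs with replacement; resamples on which the metric is
    undefined (None or raises) are redrawn.  Reproducible from the seed.
    Raises if more than half of all draws are undefined.
    """
    v = np.asarray(values)
    t = np.asarray(truth)
    n = len(v)
    if n < 2 or len(t) != n:
        raise ValueError("need >= 2 aligned (value, truth) pairs")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    bad = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            m = metric_fn(v[idx], t[idx])
        except ValueError:
            m = None
        if m is None:
            bad += 1
            if bad > (n_boot + bad) / 2 and bad > 10:
                raise RuntimeError(
                    f"metric undefined on >50% of bootstrap resamples ({bad} redraws)"
                )
            continue
        stats[i] = m
        i += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


_METRIC_ORDER = ("f1", "accuracy", "precision", "recall", "auroc")


def _label_metric(name: str) -> Callable[[np.ndarray, np.ndarray], float | None]:
    def fn(pred: np.ndarray, truth: np.ndarray) -> float | None:
        c = confusion(pred, truth)
        f1, acc, prec, rec = metrics(c)
        return {"f1": f1, "accuracy": acc, "precision": prec, "recall": rec}[name]

    return fn


def metrics_report(
    pred: Sequence[int],
    truth: Sequence[int],
    scores: Sequence[float] | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MetricsReport:
    """Full diagnostic report in percent, with 95 % bootstrap CIs.

    AUROC (and its CI, resampling score/label pairs) is included when
    continuous scores are supplied.
    """
    p = np.asarray(pred).astype(int)
    t = np.asarray(truth).astype(int)
    c = confusion(p, t)
    f1, acc, prec, rec = metrics(c)
    point = {"f1": f1, "accuracy": acc, "precision": prec, "recall": rec}
    undefined = [k for k, v in point.items() if v is None]

    au = None
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        try:
            au = auroc(s, t)
        except ValueError:
            undefined.append("auroc")

    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        ss = np.random.SeedSequence(seed).spawn(len(_METRIC_ORDER))
        for name, sub in zip(_METRIC_ORDER, ss):
            sub_seed = int(sub.generate_state(1)[0] % (2**31))
            if name == "auroc":
                if au is None:
                    continue
                lo, hi = bootstrap_ci(
                    np.asarray(scores, dtype=float), t,
                    lambda sc, tr: auroc(sc, tr), n_boot, sub_seed,
                )
            else:
                if point[name] is None:
                    continue
                lo, hi = bootstrap_ci(p, t, _label_metric(name), n_boot, sub_seed)
            ci[name] = (100 * lo, 100 * hi)

    def pct(x: float | None) -> float | None:
        return None if x is None else 100 * x

    return MetricsReport(
        counts=c,
        f1=pct(f1),
        accuracy=pct(acc),  # type: ignore[arg-type]
        precision=pct(prec),
        recall=pct(rec),
        auroc=pct(au),
        ci=ci,
        n_bootstrap=n_boot,
        undefined=undefined,
    )


def compare_detectors(
    pred_a: Sequence[int],
    pred_b: Sequence[int],
    truth: Sequence[int],
    scores_a: Sequence[float] | None = None,
    scores_b: Sequence[float] | None = None,
    sample_ids_a: Sequence[str] | None = None,
    sample_ids_b: Sequence[str] | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[MetricsReport, MetricsReport]:
    """Side-by-side reports for two detectors against the same reference."""
    if sample_ids_a is not None and sample_ids_b is not None:
        if list(sample_ids_a) != list(sample_ids_b):
            raise ValueError("detector sample_ids are not aligned")
    if len(pred_a) != len(truth) or len(pred_b) != len(truth):
        raise ValueError("prediction/label lengths differ")
    rep_a = metrics_report(pred_a, truth, scores_a, n_boot=n_boot, seed=seed)
    rep_b = metrics_report(pred_b, truth, scores_b, n_boot=n_boot, seed=seed)
    return rep_a, rep_b


def low_concentration_summary(
    model_pred: Sequence[int],
    comparator_pred: Sequence[int],
    truth: Sequence[int],
    concentration_pct: Sequence[float],
) -> LowConcentrationSummary:
    """Concentration statistics among true positives the model caught but the
    comparator missed (truth == 1, model == 1, comparator == 0).

    Quartiles use linear interpolation between order statistics.
    """
    mp = _check_binary(np.asarray(model_pred), "model_pred")
    cp = _check_binary(np.asarray(comparator_pred), "comparator_pred")
    t = _check_binary(np.asarray(truth), "truth")
    conc = np.asarray(concentration_pct, dtype=float)
    if not len(mp) == len(cp) == len(t) == len(conc):
        raise ValueError("inputs must be aligned")
    sel = (t == 1) & (mp == 1) & (cp == 0)
    if np.any(sel & ~np.isfinite(conc)):
        raise ValueError("concentration missing for a selected sample")
    picked = conc[sel]
    if len(picked) == 0:
        return LowConcentrationSummary(0, None, None, None)
    q1, med, q3 = np.quantile(picked, [0.25, 0.5, 0.75])  # linear interpolation
    return LowConcentrationSummary(len(picked), float(med), float(q1), float(q3))


def roc_curve_points(
    scores: Sequence[float], truth: Sequence[int]
) -> np.ndarray:
    """(FPR, TPR) pairs over all score thresholds, for plotting/export."""
    s = np.asarray(scores, dtype=float)
    t = _check_binary(np.asarray(truth), "truth")
    order = np.argsort(-s, kind="stable")
    t_sorted = t[order]
    s_sorted = s[order]
    tps = np.cumsum(t_sorted)
    fps = np.cumsum(1 - t_sorted)
    # keep the last point of each run of tied scores
    distinct = np.append(np.diff(s_sorted) != 0, True)
    tps, fps = tps[distinct], fps[distinct]
    n_pos, n_neg = int(t.sum()), int(len(t) - t.sum())
    tpr = np.concatenate(([0.0], tps / max(n_pos, 1)))
    fpr = np.concatenate(([0.0], fps / max(n_neg, 1)))
    return np.column_stack([fpr, tpr])


def format_report_table(
    reports: dict[str, MetricsReport],
) -> str:
    """Human-readable comparison table: one column block per detector,
    one row per metric, percent with 95 % CI."""
    lines = []
    header = f"{'Metric':<12}" + "".join(f"{name:>32}" for name in reports)
    lines.append(header)
    lines.append("-" * len(header))
    for m in _METRIC_ORDER:
        row = f"{m:<12}"
        for rep in reports.values():
            val = getattr(rep, m)
            if val is None:
                cell = "undefined"
            elif m in rep.ci:
                lo, hi = rep.ci[m]
                cell = f"{val:5.1f}% ({lo:.1f}-{hi:.1f})"
            else:
                cell = f"{val:5.1f}%"
            row += f"{cell:>32}"
        lines.append(row)
    return "\n".join(lines)
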