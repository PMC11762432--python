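"""Test-set evaluation: classification metrics with percentile-bootstrap
confidence intervals, calibration tables, and stratified reports.

Metrics: Cohen's kappa, ROC-AUC, PR-AUC, precision and recall at a stated
threshold. Intervals are 95% percentile bootstrap over seeded resamples of
the test set; resamples containing a single outcome class are redrawn and
counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    cohen_kappa_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

METRIC_NAMES = ("cohens_kappa", "roc_auc", "pr_auc", "precision", "recall")
N_CALIBRATION_BINS = 20
DEFAULT_THRESHOLD = 0.5


def _binary(p: np.ndarray, threshold: float) -> np.ndarray:
    return (p >= threshold).astype(int)


def _metric_value(name: str, y: np.ndarray, p: np.ndarray, threshold: float) -> float:
    if name == "roc_auc":
        return float(roc_auc_score(y, p))
    if name == "pr_auc":
        return float(average_precision_score(y, p))
    yhat = _binary(p, threshold)
    if name == "cohens_kappa":
        return float(cohen_kappa_score(y, yhat))
    if name == "precision":
        return float(precision_score(y, yhat, zero_division=0))
    if name == "recall":
        return float(recall_score(y, yhat, zero_division=0))
    raise KeyError(f"unknown metric {name!r}")


def compute_metrics(
    y_true, p_pred, threshold: float = DEFAULT_THRESHOLD
) -> dict[str, Optional[float]]:
    """Point estimates of all five metrics; AUCs are None (with a reason
    entry) when only one class is present."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p_pred, dtype=float)
    if len(y) != len(p):
        raise ValueError("y_true and p_pred must have equal length")
    out: dict[str, Optional[float]] = {}
    single_class = len(np.unique(y)) < 2
    for name in METRIC_NAMES:
        if name in ("roc_auc", "pr_auc") and single_class:
            out[name] = None
        else:
            out[name] = _metric_value(name, y, p, threshold)
    if single_class:
        out["missing_reason"] = "single-class y_true: AUCs undefined"
    return out


@dataclass
class MetricCI:
    point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    missing_reason: Optional[str] = None

    def as_tuple(self):
        return (self.point, self.ci_low, self.ci_high)


@dataclass
class MetricsReport:
    metrics: dict[str, MetricCI]
    threshold: float
    n_bootstrap: int
    n: int
    stratum: Optional[str] = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_bootstrap": self.n_bootstrap,
            "n": self.n,
            "stratum": self.stratum,
            "flags": self.flags,
            "metrics": {
                k: {"point": v.point, "ci_low": v.ci_low, "ci_high": v.ci_high,
                    "missing_reason": v.missing_reason}
                for k, v in self.metrics.items()
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "point": v.point, "ci_low": v.ci_low, "ci_high": v.ci_high}
            for k, v in self.metrics.items()
        ]
        return pd.DataFrame(rows).set_index("metric")


def bootstrap_ci(
    y_true,
    p_pred,
    metric: str | Callable,
    n_bootstrap: int = 1000,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = 0.05,
) -> tuple[float, float, float, int]:
    """Percentile bootstrap CI for one metric.

    Returns (point, ci_low, ci_high, n_redrawn). Resamples with a single
    class are redrawn; the count of redraws is returned for logging.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p_pred, dtype=float)
    fn = (lambda yy, pp: _metric_value(metric, yy, pp, threshold)) if isinstance(metric, str) else metric
    needs_both = isinstance(metric, str) and metric in ("roc_auc", "pr_auc")
    if needs_both and len(np.unique(y)) < 2:
        raise ValueError(f"{metric} undefined on single-class sample")
    point = fn(y, p)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = np.empty(n_bootstrap)
    redrawn = 0
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, n)
            if not needs_both or len(np.unique(y[idx])) > 1:
                break
            redrawn += 1
        vals[b] = fn(y[idx], p[idx])
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(point), float(lo), float(hi), redrawn


def bootstrap_report(
    y_true,
    p_pred,
    threshold: float = DEFAULT_THRESHOLD,
    n_bootstrap: int = 1000,
    seed: int = 0,
    stratum: Optional[str] = None,
) -> MetricsReport:
    """All five metrics with 95% percentile-bootstrap CIs from shared resamples."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p_pred, dtype=float)
    single_class = len(np.unique(y)) < 2
    rng = np.random.default_rng(seed)
    n = len(y)
    flags = []
    names = [m for m in METRIC_NAMES
             if not (single_class and m in ("roc_auc", "pr_auc"))]
    vals = {m: np.empty(n_bootstrap) for m in names}
    redrawn = 0
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, n)
            if single_class or len(np.unique(y[idx])) > 1:
                break
            redrawn += 1
        for m in names:
            vals[m][b] = _metric_value(m, y[idx], p[idx], threshold)
    if redrawn:
        flags.append(f"{redrawn} single-class resamples redrawn")
    metrics: dict[str, MetricCI] = {}
    for m in METRIC_NAMES:
        if m not in names:
            metrics[m] = MetricCI(None, None, None,
                                  "single-class y_true: AUC undefined")
            continue
        point = _metric_value(m, y, p, threshold)
        lo, hi = np.percentile(vals[m], [2.5, 97.5])
        metrics[m] = MetricCI(point, float(lo), float(hi))
    return MetricsReport(metrics=metrics, threshold=threshold,
                         n_bootstrap=n_bootstrap, n=n, stratum=stratum,
                         flags=flags)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_table(y_true, p_pred) -> pd.DataFrame:
    """20 right-closed probability bins of width 0.05.

    Per bin: n, observed outcome proportion, positive and negative counts.
    p = 0 falls in the first bin, p = 1 in the last.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p_pred, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    width = 1.0 / N_CALIBRATION_BINS
    bins = np.clip(np.ceil(p / width).astype(int) - 1, 0, N_CALIBRATION_BINS - 1)
    rows = []
    for b in range(N_CALIBRATION_BINS):
        sel = bins == b
        n = int(sel.sum())
        pos = int(y[sel].sum())
        rows.append(
            {
                "bin": b,
                "p_low": b * width,
                "p_high": (b + 1) * width,
                "midpoint": (b + 0.5) * width,
                "n": n,
                "n_positive": pos,
                "n_negative": n - pos,
                "observed_proportion": pos / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def calibration_plot(table: pd.DataFrame, out_path: str | Path,
                     title: str = "Calibration") -> None:
    """Calibration curve plus per-class probability bars (one figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    mid = table["midpoint"].values
    total = max(int(table["n"].sum()), 1)
    ax.bar(mid - 0.008, table["n_negative"] / total, width=0.016,
           color="tab:blue", alpha=0.6, label="negative class")
    ax.bar(mid + 0.008, table["n_positive"] / total, width=0.016,
           color="tab:orange", alpha=0.6, label="positive class")
    ok = table["n"] > 0
    ax.plot(mid[ok.values], table.loc[ok, "observed_proportion"], "-o",
            color="teal", label="calibration curve")
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=1)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed proportion / class share")
    ax.set_title(title)
    ax.legend(loc="upper center", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# stratified reports
# ---------------------------------------------------------------------------

DEFAULT_AGE_EDGES = (65, 75, 85)


def age_strata(ages, edges=DEFAULT_AGE_EDGES) -> np.ndarray:
    """Label each age into configurable bands, e.g. 65-74, 75-84, 85+."""
    ages = np.asarray(ages, dtype=float)
    labels = np.empty(len(ages), dtype=object)
    for i, lo in enumerate(edges):
        hi = edges[i + 1] if i + 1 < len(edges) else None
        name = f"{lo}-{hi - 1}" if hi else f"{lo}+"
        sel = (ages >= lo) if hi is None else (ages >= lo) & (ages < hi)
        labels[sel] = name
    labels[ages < edges[0]] = f"<{edges[0]}"
    return labels


def stratified_report(
    y_true,
    p_pred,
    strata,
    threshold: float = DEFAULT_THRESHOLD,
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_n: int = 30,
) -> dict[str, MetricsReport]:
    """One full MetricsReport per stratum; empty strata omitted, small ones
    flagged."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p_pred, dtype=float)
    strata = np.asarray(strata)
    out: dict[str, MetricsReport] = {}
    for k, label in enumerate(pd.unique(strata)):
        sel = strata == label
        if sel.sum() == 0:
            continue
        rep = bootstrap_report(y[sel], p[sel], threshold=threshold,
                               n_bootstrap=n_bootstrap, seed=seed + k,
                               stratum=str(label))
        if sel.sum() < min_n:
            rep.flags.append(f"small stratum (n={int(sel.sum())} < {min_n})")
        out[str(label)] = rep
    return out
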