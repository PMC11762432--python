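"""Population- and patient-level attention maps.

Population maps average per-patient attention over the test set, masked
entries excluded, and rank variables by their overall mean contribution (mean
variable-level attention over real, recorded slots; a beta-weighted variant
is available behind a flag). Patient maps show, per year, the five most
contributing variables, min-max rescaled over the displayed values only —
the rescaling is display-only; raw weights are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PopulationMap:
    mean_alpha: np.ndarray            # (T, V), masked-mean over patients
    mean_beta: np.ndarray             # (T,)
    variable_scores: pd.Series        # per-variable overall mean contribution
    top_variables: list[str]
    weight_by_beta: bool = False
    tie_flag: bool = False

    def frame(self) -> pd.DataFrame:
        """Fig-3-style layout: top variables as columns, beta as last column,
        one row per year of history (most recent last)."""
        T = self.mean_alpha.shape[0]
        cols = {v: self.mean_alpha[:, self.variable_scores.index.get_loc(v)]
                for v in self.top_variables}
        cols["time_attention"] = self.mean_beta
        idx = [f"history_year_{t - T}" for t in range(T)]
        return pd.DataFrame(cols, index=idx)


@dataclass
class PatientMap:
    entries: pd.DataFrame             # period, variable_id, raw_alpha, scaled
    beta: np.ndarray                  # (T,)
    period_mask: np.ndarray
    k: int = 5

    def frame(self) -> pd.DataFrame:
        """Wide layout: displayed variables as columns, NaN where not shown."""
        if self.entries.empty:
            return pd.DataFrame()
        wide = self.entries.pivot(index="period", columns="variable_id",
                                  values="scaled")
        wide["time_attention"] = self.beta[wide.index.values]
        return wide


def population_map(
    alpha: np.ndarray,
    beta: np.ndarray,
    value_mask: np.ndarray,
    period_mask: np.ndarray,
    variable_index: list[str],
    top_k: int = 10,
    weight_by_beta: bool = False,
) -> PopulationMap:
    """Masked means of alpha and beta over patients, with top-k variable
    ranking (ties broken by schema order, flagged)."""
    if alpha.shape[0] == 0:
        raise ValueError("population map needs at least one patient")
    Mv = value_mask > 0
    Mt = period_mask > 0
    denom_a = np.maximum(Mv.sum(axis=0), 1)
    mean_alpha = (alpha * Mv).sum(axis=0) / denom_a              # (T, V)
    mean_alpha[Mv.sum(axis=0) == 0] = 0.0
    denom_b = np.maximum(Mt.sum(axis=0), 1)
    mean_beta = (beta * Mt).sum(axis=0) / denom_b
    mean_beta[Mt.sum(axis=0) == 0] = 0.0

    w = alpha * Mv
    if weight_by_beta:
        w = w * beta[:, :, None]
    cnt = Mv.sum(axis=(0, 1))
    scores = np.where(cnt > 0, w.sum(axis=(0, 1)) / np.maximum(cnt, 1), 0.0)
    series = pd.Series(scores, index=list(variable_index), name="mean_attention")

    k = min(top_k, len(series))
    order = np.lexsort((np.arange(len(series)), -series.values))
    top = [variable_index[i] for i in order[:k]]
    tie = bool(k < len(series)
               and series.values[order[k - 1]] == series.values[order[k]])
    return PopulationMap(mean_alpha=mean_alpha, mean_beta=mean_beta,
                         variable_scores=series, top_variables=top,
                         weight_by_beta=weight_by_beta, tie_flag=tie)


def patient_map(
    alpha: np.ndarray,
    beta: np.ndarray,
    value_mask: np.ndarray,
    period_mask: np.ndarray,
    variable_index: list[str],
    k: int = 5,
) -> PatientMap:
    """Top-k variables per real period (which need not repeat across years),
    min-max rescaled to [0, 1] over the displayed values only."""
    if period_mask.sum() < 1:
        raise ValueError("patient has no real periods")
    T, V = alpha.shape
    rows = []
    for t in range(T):
        if period_mask[t] <= 0:
            continue
        avail = np.flatnonzero(value_mask[t] > 0)
        if avail.size == 0:
            continue
        order = avail[np.lexsort((avail, -alpha[t, avail]))][:k]
        for j in order:
            rows.append({"period": t, "variable_id": variable_index[j],
                         "raw_alpha": float(alpha[t, j])})
    entries = pd.DataFrame(rows, columns=["period", "variable_id", "raw_alpha"])
    if len(entries):
        vals = entries["raw_alpha"].values
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            entries["scaled"] = (vals - lo) / (hi - lo)
        else:
            entries["scaled"] = np.where(vals > 0, 1.0, 0.0)
    else:
        entries["scaled"] = pd.Series(dtype=float)
    return PatientMap(entries=entries, beta=np.asarray(beta),
                      period_mask=np.asarray(period_mask), k=k)


def render_map(pmap: PopulationMap | PatientMap, out_path: str | Path,
               title: str = "Attention map") -> pd.DataFrame:
    """Heatmap (variables as columns, time attention as the final column)
    plus a CSV of the plotted values. Blank (not zero-coloured) cells mark
    slots outside a patient's observed history."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    frame = pmap.frame()
    if isinstance(pmap, PatientMap) and not frame.empty:
        # pad to full history length; unobserved periods stay all-NaN
        frame = frame.reindex(range(len(pmap.period_mask)))
        frame.loc[pmap.period_mask <= 0, "time_attention"] = np.nan
    frame.to_csv(out_path.with_suffix(".csv"))

    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * max(frame.shape[1], 1)), max(3, 0.4 * max(frame.shape[0], 1))))
    data = np.ma.masked_invalid(frame.values.astype(float)) if frame.size else np.zeros((1, 1))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad(color="white")
    im = ax.imshow(data, aspect="auto", cmap=cmap)
    ax.set_xticks(range(frame.shape[1]) if frame.size else [])
    ax.set_xticklabels(frame.columns if frame.size else [], rotation=90, fontsize=7)
    ax.set_yticks(range(frame.shape[0]) if frame.size else [])
    ax.set_yticklabels(frame.index if frame.size else [], fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path.with_suffix(".png"), dpi=120)
    plt.close(fig)
    return frame
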