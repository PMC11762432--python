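"""Cohort tensorization: cleaning, eligibility, annual aggregation, labels,
and the doubly-masked zero-padded feature tensor.

The tensor layout is ``[n_patients x T_max x V]`` with two masks: a period
mask marking real observed calendar years versus zero-padding, and a value
mask marking values actually recorded within an observed year. Histories are
right-aligned — the most recent year sits at the last slot, padding on the
left — so "years before the prediction" is a fixed index across patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .schema import COUNT, FLAG_CARRY, MEAN, MODE, OUT_OF_RANGE, FeatureSchema, drug_variable_for_atc

HOME_CARE_PREFIX = "Z74"
NURSING_HOME_CODE = "Z59.3"
LABEL_COLUMNS = ("mortality", "nursing_home", "home_care")


@dataclass
class EligibilityConfig:
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2019, 12, 31)
    min_age: int = 65
    max_age_at_start: int = 100        # exclusive upper bound on age at study start
    prediction_window: int = 1

    def __post_init__(self) -> None:
        if self.prediction_window not in (1, 5):
            raise ValueError("prediction_window must be 1 or 5")
        if self.min_age >= self.max_age_at_start:
            raise ValueError("min_age must be below max_age_at_start")

    @property
    def min_followup_years(self) -> int:
        # window years of outcome ascertainment + at least one history year
        return self.prediction_window + 1


@dataclass
class NormalizationStats:
    mean: np.ndarray               # (V,)
    std: np.ndarray                # (V,)
    numeric: np.ndarray            # (V,) bool — which variables are z-scored

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist(),
                "numeric": self.numeric.astype(int).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(np.asarray(d["mean"], float), np.asarray(d["std"], float),
                   np.asarray(d["numeric"], bool))


@dataclass
class FeatureTensor:
    X: np.ndarray                  # (n, T_max, V) float32
    period_mask: np.ndarray        # (n, T_max) float32 in {0,1}
    value_mask: np.ndarray         # (n, T_max, V) float32 in {0,1}
    S: np.ndarray                  # (n, V_static) float32
    variable_index: list[str]
    static_index: list[str]
    patient_ids: np.ndarray        # (n,)
    entry_year: np.ndarray         # (n,) first observed calendar year
    index_year: np.ndarray         # (n,) year at whose end the prediction is made
    schema_hash: str = ""
    normalization: Optional[NormalizationStats] = None

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def t_max(self) -> int:
        return self.X.shape[1]

    @property
    def n_variables(self) -> int:
        return self.X.shape[2]

    def period_calendar(self, i: int) -> list[int]:
        """Calendar years of patient i's real periods (oldest first)."""
        h = int(self.period_mask[i].sum())
        return list(range(int(self.index_year[i]) - h + 1, int(self.index_year[i]) + 1))

    def validate_masks(self) -> None:
        if not np.all(self.value_mask <= self.period_mask[:, :, None]):
            raise AssertionError("value mask exceeds period mask")
        if not np.all(self.X[self.value_mask == 0] == 0):
            raise AssertionError("values present at masked positions")

    def rows_for(self, patient_ids) -> np.ndarray:
        pos = {int(p): i for i, p in enumerate(self.patient_ids)}
        return np.array([pos[int(p)] for p in patient_ids], dtype=np.int64)

    # ------------------------------------------------------------------ io
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            X=self.X, period_mask=self.period_mask, value_mask=self.value_mask,
            S=self.S, patient_ids=self.patient_ids,
            entry_year=self.entry_year, index_year=self.index_year,
        )
        sidecar = {
            "variable_index": self.variable_index,
            "static_index": self.static_index,
            "schema_hash": self.schema_hash,
            "normalization": self.normalization.to_dict() if self.normalization else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTensor":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        norm = sidecar.get("normalization")
        return cls(
            X=arrays["X"], period_mask=arrays["period_mask"],
            value_mask=arrays["value_mask"], S=arrays["S"],
            variable_index=sidecar["variable_index"],
            static_index=sidecar["static_index"],
            patient_ids=arrays["patient_ids"],
            entry_year=arrays["entry_year"], index_year=arrays["index_year"],
            schema_hash=sidecar.get("schema_hash", ""),
            normalization=NormalizationStats.from_dict(norm) if norm else None,
        )


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_events(
    events: pd.DataFrame,
    statics: pd.DataFrame,
    sex_specific_codes: Optional[dict[str, str]] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove duplicate diagnoses, date-inconsistent events, and sex-specific
    diagnoses recorded on the wrong sex. Returns a cleaned copy and a
    removal-count log."""
    known = set(statics["patient_id"].tolist())
    unknown = set(events["patient_id"].unique()) - known
    if unknown:
        raise ValueError(f"events reference unknown patient ids: {sorted(unknown)[:5]}")
    log = {"duplicate_diagnosis": 0, "inconsistent_date": 0, "wrong_sex_code": 0}
    ev = events.copy()
    if ev.empty:
        return ev, log

    st = statics.set_index("patient_id")
    birth = ev["patient_id"].map(st["birth_date"]).values
    death = ev["patient_id"].map(st["death_date"]).values
    dates = pd.to_datetime(ev["date"]).values
    bad = (dates < birth) | (~pd.isna(death) & (dates > death))
    log["inconsistent_date"] = int(bad.sum())
    ev = ev.loc[~bad]

    if sex_specific_codes:
        sex = ev["patient_id"].map(st["sex"]).values
        allowed = ev["code"].map(sex_specific_codes).values
        bad = (ev["domain"].values == "diagnosis") & ~pd.isna(allowed) & (allowed != sex)
        log["wrong_sex_code"] = int(bad.sum())
        ev = ev.loc[~bad]

    is_dx = ev["domain"].values == "diagnosis"
    dup = np.zeros(len(ev), dtype=bool)
    dup[is_dx] = ev.loc[is_dx].duplicated(subset=["patient_id", "date", "code"]).values
    log["duplicate_diagnosis"] = int(dup.sum())
    ev = ev.loc[~dup].reset_index(drop=True)
    return ev, log


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def apply_eligibility(
    statics: pd.DataFrame,
    events: pd.DataFrame,
    cfg: EligibilityConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the dynamic-cohort eligibility rules.

    Returns a per-patient frame (patient_id, entry_year, end_year, index_year)
    for included patients, plus per-rule exclusion counts.
    """
    st = statics.copy()
    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    birth = pd.to_datetime(st["birth_date"])

    age_at_start = (start - birth).dt.days / 365.25
    b65 = birth + pd.DateOffset(years=cfg.min_age)
    entry = pd.concat(
        [pd.Series(start, index=st.index), b65,
         pd.to_datetime(st["registry_entry_date"])], axis=1
    ).max(axis=1)
    exit_candidates = pd.concat(
        [pd.Series(end, index=st.index),
         pd.to_datetime(st["registry_exit_date"]),
         pd.to_datetime(st["death_date"])], axis=1
    )
    followup_end = exit_candidates.min(axis=1, skipna=True)

    counts = {"no_events": 0, "no_visits": 0, "too_old_at_start": 0,
              "insufficient_followup": 0}
    has_events = st["patient_id"].isin(events["patient_id"].unique())
    visits = events.loc[events["domain"] == "visit"]
    in_window = (pd.to_datetime(visits["date"]) >= start) & (pd.to_datetime(visits["date"]) <= end)
    has_visits = st["patient_id"].isin(visits.loc[in_window, "patient_id"].unique())

    keep = pd.Series(True, index=st.index)
    rule = ~has_events
    counts["no_events"] = int((keep & rule).sum()); keep &= ~rule
    rule = ~has_visits
    counts["no_visits"] = int((keep & rule).sum()); keep &= ~rule
    rule = age_at_start >= cfg.max_age_at_start
    counts["too_old_at_start"] = int((keep & rule).sum()); keep &= ~rule

    entry_year = entry.dt.year
    end_year = followup_end.dt.year
    # a censored patient's partial final year cannot ascertain outcomes;
    # their last usable year is the preceding complete one
    exit_d = pd.to_datetime(st["registry_exit_date"])
    partial = (followup_end == exit_d) & ~(
        (exit_d.dt.month == 12) & (exit_d.dt.day == 31))
    end_year = end_year.where(~partial.fillna(False), end_year - 1)
    followup_years = end_year - entry_year + 1
    rule = (entry > followup_end) | (followup_years < cfg.min_followup_years)
    counts["insufficient_followup"] = int((keep & rule).sum()); keep &= ~rule

    out = pd.DataFrame(
        {
            "patient_id": st.loc[keep, "patient_id"].values,
            "entry_year": entry_year[keep].astype(int).values,
            "end_year": end_year[keep].astype(int).values,
        }
    )
    out["index_year"] = out["end_year"] - cfg.prediction_window
    return out.reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# annual aggregation
# ---------------------------------------------------------------------------

def _event_variable_assignment(events: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Explode events into (patient_id, year, variable_id, value) rows."""
    ev = events.copy()
    ev["year"] = pd.to_datetime(ev["date"]).dt.year
    is_drug = ev["domain"] == "drug"
    parts = []
    if is_drug.any():
        d = ev.loc[is_drug, ["patient_id", "year", "code", "value"]].copy()
        d["variable_id"] = d["code"].map(drug_variable_for_atc)
        parts.append(d[["patient_id", "year", "variable_id", "value"]])
    rest = ev.loc[~is_drug]
    mapped = rest["code"].map(lambda c: schema.code_map.get(c))
    keep = mapped.notna()
    rest = rest.loc[keep]
    mapped = mapped.loc[keep]
    if len(rest):
        e = rest[["patient_id", "year", "value"]].copy()
        e["variable_id"] = mapped.values
        e = e.explode("variable_id")
        parts.append(e[["patient_id", "year", "variable_id", "value"]])
    if not parts:
        return pd.DataFrame(columns=["patient_id", "year", "variable_id", "value"])
    return pd.concat(parts, ignore_index=True)


def aggregate_cohort(
    events: pd.DataFrame,
    schema: FeatureSchema,
    cohort: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate events annually over each patient's history window.

    ``cohort`` carries (patient_id, entry_year, index_year). Returns
    ``(values, recorded, years)`` where values/recorded have shape
    (n, Y, V) over the global calendar span ``years``; only events dated at or
    before each patient's index year contribute (prediction-window exclusion).
    """
    n = len(cohort)
    y_lo = int(cohort["entry_year"].min())
    y_hi = int(cohort["index_year"].max())
    years = np.arange(y_lo, y_hi + 1)
    Y, V = len(years), schema.total_dynamic
    row_of = {int(p): i for i, p in enumerate(cohort["patient_id"].values)}
    entry = cohort["entry_year"].values
    index = cohort["index_year"].values

    values = np.zeros((n, Y, V), dtype=np.float64)
    recorded = np.zeros((n, Y, V), dtype=bool)
    # observed (real) patient-years
    yr_grid = years[None, :]
    observed = (yr_grid >= entry[:, None]) & (yr_grid <= index[:, None])

    var_pos = {v.variable_id: j for j, v in enumerate(schema.variables)}
    kinds = np.array([v.aggregation for v in schema.variables])
    always_cols = np.array([v.always_recorded for v in schema.variables])
    range_lo = np.full(V, -np.inf)
    range_hi = np.full(V, np.inf)
    for v in schema.variables:
        if v.reference_range is not None:
            range_lo[var_pos[v.variable_id]] = v.reference_range[0]
            range_hi[var_pos[v.variable_id]] = v.reference_range[1]

    # known-zero variables (counts, out-of-range counts, carry flags) are
    # recorded in every observed year; means/modes only when data exist
    recorded[:, :, always_cols] = observed[:, :, None]

    ex = _event_variable_assignment(events, schema)
    ex = ex.loc[ex["patient_id"].isin(row_of.keys())]
    if len(ex):
        rows_all = ex["patient_id"].map(row_of).values.astype(int)
        yrs_all = ex["year"].values.astype(int)
        # prediction-window leakage guard: drop events after the index year
        keep = yrs_all <= index[rows_all]
        ex = ex.loc[keep]
        rows_all, yrs_all = rows_all[keep], yrs_all[keep]
        vj_all = ex["variable_id"].map(var_pos).values.astype(int)
        vals_all = ex["value"].values.astype(float)
        kind_all = kinds[vj_all]
        inside = (yrs_all >= y_lo) & (yrs_all <= y_hi)

        sel = (kind_all == COUNT) & inside
        np.add.at(values, (rows_all[sel], yrs_all[sel] - y_lo, vj_all[sel]), 1.0)

        sel = (kind_all == OUT_OF_RANGE) & inside
        sel &= (vals_all < range_lo[vj_all]) | (vals_all > range_hi[vj_all])
        np.add.at(values, (rows_all[sel], yrs_all[sel] - y_lo, vj_all[sel]), 1.0)

        # carry-forward flags: present from first occurrence onwards (also
        # carries from records predating cohort entry)
        sel = kind_all == FLAG_CARRY
        if sel.any():
            first = np.full((n, V), np.iinfo(np.int64).max)
            np.minimum.at(first, (rows_all[sel], vj_all[sel]), yrs_all[sel])
            flag_cols = np.flatnonzero(kinds == FLAG_CARRY)
            values[:, :, flag_cols] = (
                yr_grid[:, :, None] >= first[:, None, flag_cols]
            ).astype(float)

        sel = (kind_all == MEAN) & inside
        if sel.any():
            ssum = np.zeros((n, Y, V))
            scnt = np.zeros((n, Y, V))
            np.add.at(ssum, (rows_all[sel], yrs_all[sel] - y_lo, vj_all[sel]), vals_all[sel])
            np.add.at(scnt, (rows_all[sel], yrs_all[sel] - y_lo, vj_all[sel]), 1.0)
            present = scnt > 0
            values = np.where(present, ssum / np.maximum(scnt, 1.0), values)
            recorded |= present & observed[:, :, None]

        sel = (kind_all == MODE) & inside
        if sel.any():
            g = (pd.DataFrame({"row": rows_all[sel], "year": yrs_all[sel],
                               "vj": vj_all[sel], "value": vals_all[sel]})
                 .groupby(["row", "year", "vj", "value"]).size()
                 .reset_index(name="n")
                 .sort_values(["row", "year", "vj", "n", "value"],
                              ascending=[True, True, True, False, True], kind="stable")
                 .drop_duplicates(["row", "year", "vj"]))
            r = g["row"].values.astype(int)
            y = g["year"].values.astype(int) - y_lo
            c = g["vj"].values.astype(int)
            values[r, y, c] = g["value"].values.astype(float)
            recorded[r, y, c] |= observed[r, y]

    values *= recorded          # zero wherever unrecorded
    return values, recorded, years


def aggregate_annual(
    events: pd.DataFrame,
    schema: FeatureSchema,
    patient_id: int,
    year: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate one patient-year into (values, recorded_flags) over V.

    Carry-forward flags consider the patient's full record up to ``year``.
    """
    sub = events.loc[events["patient_id"] == patient_id]
    cohort = pd.DataFrame({"patient_id": [patient_id],
                           "entry_year": [year], "index_year": [year]})
    values, recorded, years = aggregate_cohort(sub, schema, cohort)
    yi = int(np.searchsorted(years, year))
    return values[0, yi], recorded[0, yi]


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def derive_labels(
    events: pd.DataFrame,
    statics: pd.DataFrame,
    cohort: pd.DataFrame,
    window: int,
) -> tuple[pd.DataFrame, int]:
    """Binary outcome labels over the window following each index year.

    mortality: death within (index_year end, index_year end + window];
    home_care: any diagnosis code with prefix Z74 in that interval;
    nursing_home: code Z59.3 in that interval. Patients whose follow-up cannot
    ascertain the window (no death, exited before window end) are omitted and
    counted.
    """
    st = statics.set_index("patient_id").loc[cohort["patient_id"].values]
    iy = cohort["index_year"].values.astype(int)
    lo = pd.to_datetime(pd.DataFrame({"year": iy, "month": 12, "day": 31}))
    hi = pd.to_datetime(pd.DataFrame({"year": iy + window, "month": 12, "day": 31}))
    death = pd.to_datetime(st["death_date"]).reset_index(drop=True)
    exit_d = pd.to_datetime(st["registry_exit_date"]).reset_index(drop=True)

    died_in = death.notna() & (death > lo) & (death <= hi)
    dead_before = death.notna() & (death <= lo)
    observed_until = exit_d.fillna(pd.Timestamp.max)
    ascertainable = died_in | (~dead_before & (observed_until >= hi))
    omitted = int((~ascertainable).sum())

    # window bounds per patient id, for the code-based outcomes
    bounds = pd.DataFrame({
        "patient_id": cohort["patient_id"].values,
        "_lo": lo, "_hi": hi, "_death": death,
    })
    dx = events.loc[(events["domain"] == "diagnosis")
                    & (events["code"].str.startswith(HOME_CARE_PREFIX)
                       | (events["code"] == NURSING_HOME_CODE)),
                    ["patient_id", "date", "code"]].copy()
    dx["date"] = pd.to_datetime(dx["date"])
    dx = dx.merge(bounds, on="patient_id", how="inner")
    valid = (dx["date"] > dx["_lo"]) & (dx["date"] <= dx["_hi"])
    valid &= dx["_death"].isna() | (dx["date"] <= dx["_death"])
    dx = dx.loc[valid]
    nh_ids = set(dx.loc[dx["code"] == NURSING_HOME_CODE, "patient_id"])
    hc_ids = set(dx.loc[dx["code"].str.startswith(HOME_CARE_PREFIX), "patient_id"])

    out = pd.DataFrame({
        "patient_id": cohort["patient_id"].values,
        "index_year": iy,
        "mortality": died_in.astype(int).values,
        "nursing_home": cohort["patient_id"].isin(nh_ids).astype(int).values,
        "home_care": cohort["patient_id"].isin(hc_ids).astype(int).values,
    })
    return out.loc[ascertainable.values].reset_index(drop=True), omitted


# ---------------------------------------------------------------------------
# tensor assembly
# ---------------------------------------------------------------------------

def _static_matrix(statics: pd.DataFrame, patient_ids: np.ndarray) -> np.ndarray:
    st = statics.set_index("patient_id").loc[patient_ids]
    sex = (st["sex"].values == "F").astype(np.float32)
    ses = st["ses_quintile"].values.astype(float)
    ses = np.where(np.isnan(ses), 0.0, ses).astype(np.float32)  # 0 encodes missing
    return np.stack([sex, ses], axis=1)


def build_tensor(
    values: np.ndarray,
    recorded: np.ndarray,
    years: np.ndarray,
    cohort: pd.DataFrame,
    statics: pd.DataFrame,
    schema: FeatureSchema,
) -> FeatureTensor:
    """Stack per-year aggregates into the right-aligned zero-padded tensor."""
    n = len(cohort)
    entry = cohort["entry_year"].values.astype(int)
    index = cohort["index_year"].values.astype(int)
    hist = index - entry + 1
    if np.any(hist < 1):
        raise ValueError("every patient needs at least one history year")
    t_max = int(hist.max())
    V = values.shape[2]
    X = np.zeros((n, t_max, V), dtype=np.float32)
    pm = np.zeros((n, t_max), dtype=np.float32)
    vm = np.zeros((n, t_max, V), dtype=np.float32)
    y_lo = int(years[0])
    for i in range(n):
        h = hist[i]
        src = slice(entry[i] - y_lo, index[i] - y_lo + 1)
        dst = slice(t_max - h, t_max)
        X[i, dst] = values[i, src]
        vm[i, dst] = recorded[i, src]
        pm[i, t_max - h:] = 1.0
    tensor = FeatureTensor(
        X=X, period_mask=pm, value_mask=vm,
        S=_static_matrix(statics, cohort["patient_id"].values),
        variable_index=schema.variable_ids,
        static_index=list(schema.static_variables),
        patient_ids=cohort["patient_id"].values.astype(np.int64),
        entry_year=entry.astype(np.int64),
        index_year=index.astype(np.int64),
        schema_hash=schema.content_hash(),
    )
    tensor.validate_masks()
    return tensor


def tensorize_cohort(
    events: pd.DataFrame,
    statics: pd.DataFrame,
    schema: FeatureSchema,
    cfg: EligibilityConfig,
) -> tuple[FeatureTensor, pd.DataFrame, dict]:
    """Full pipeline: clean -> eligibility -> aggregate -> labels -> tensor."""
    clean, clean_log = clean_events(events, statics, schema.sex_specific_codes)
    cohort, excl = apply_eligibility(statics, clean, cfg)
    labels, omitted = derive_labels(clean, statics, cohort, cfg.prediction_window)
    cohort = cohort.loc[cohort["patient_id"].isin(labels["patient_id"])].reset_index(drop=True)
    values, recorded, years = aggregate_cohort(clean, schema, cohort)
    tensor = build_tensor(values, recorded, years, cohort, statics, schema)
    labels = labels.set_index("patient_id").loc[tensor.patient_ids].reset_index()
    report = {"cleaning": clean_log, "exclusions": excl,
              "label_omitted": omitted, "n_final": tensor.n_patients}
    return tensor, labels, report


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def fit_normalizer(tensor: FeatureTensor, train_ids, schema: FeatureSchema) -> NormalizationStats:
    """Per-variable mean/sd over unmasked training entries only (population sd)."""
    rows = tensor.rows_for(train_ids)
    X = tensor.X[rows].astype(np.float64)
    M = tensor.value_mask[rows].astype(np.float64)
    cnt = M.sum(axis=(0, 1))
    safe = np.maximum(cnt, 1.0)
    mu = (X * M).sum(axis=(0, 1)) / safe
    var = ((X - mu) ** 2 * M).sum(axis=(0, 1)) / safe
    std = np.sqrt(var)
    mu[cnt == 0] = 0.0
    std[cnt == 0] = 0.0
    return NormalizationStats(mean=mu, std=std, numeric=np.asarray(schema.numeric_mask))


def apply_normalizer(tensor: FeatureTensor, stats: NormalizationStats) -> FeatureTensor:
    """Z-score unmasked numeric entries; masked entries stay exactly 0;
    categorical/binary variables pass through untouched. Zero-variance
    variables map to 0 (they carry no information)."""
    X = tensor.X.astype(np.float32).copy()
    M = tensor.value_mask
    safe_std = np.where(stats.std > 0, stats.std, 1.0).astype(np.float32)
    z = (X - stats.mean.astype(np.float32)) / safe_std
    z = np.where(stats.std.astype(np.float32) > 0, z, 0.0)
    norm = np.where(stats.numeric[None, None, :], z, X)
    X = np.where(M > 0, norm, 0.0).astype(np.float32)
    return FeatureTensor(
        X=X, period_mask=tensor.period_mask, value_mask=tensor.value_mask,
        S=tensor.S, variable_index=tensor.variable_index,
        static_index=tensor.static_index, patient_ids=tensor.patient_ids,
        entry_year=tensor.entry_year, index_year=tensor.index_year,
        schema_hash=tensor.schema_hash, normalization=stats,
    )
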