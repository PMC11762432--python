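"""Seeded synthetic cohort generator with planted, recoverable risk structure.

Emulates a dynamic primary-care cohort of adults aged 65+ over a ten-year
window: patients enter at the study start, at their 65th birthday, or (for a
configurable in-migrant fraction) at a simulated arrival date; per-patient
yearly visit intensity drives the recording of laboratory and clinical
measurements, so low-intensity patients produce the missingness the model's
masks must absorb; three binary outcomes (death, nursing-home admission coded
Z59.3, home-care need coded Z74*) are drawn from a logistic model on a small
set of planted variables with a configurable recency profile, so that signal
recovery by a downstream model is testable against known ground truth.

All randomness flows from a single integer seed; identical configurations
produce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from .schema import (
    COUNT,
    FLAG_CARRY,
    MEAN,
    FeatureSchema,
    build_default_schema,
    drug_variable_for_atc,
    event_code,
)

OUTCOMES = ("mortality", "nursing_home", "home_care")
NURSING_HOME_CODE = "Z59.3"
HOME_CARE_CODE = "Z74.0"

RECENCY_PROFILES = ("last_year_only", "uniform", "decaying")
DECAY_RATIO = 0.5

_EPOCH = np.datetime64("1970-01-01")

# ATC level-5 codes used for billed-drug events (cardiovascular / nervous
# system / other), with sampling weights.
_ATC_CODES = np.array(
    ["C03CA01", "C07AB02", "C09AA05", "N02BE01", "N05BA06",
     "A02BC01", "M01AE01", "B01AC06"]
)
_ATC_PROBS = np.array([0.12, 0.10, 0.12, 0.18, 0.10, 0.16, 0.10, 0.12])

_VISIT_TYPE_PROBS = np.array([0.40, 0.20, 0.12, 0.08, 0.06, 0.06, 0.05, 0.03])


@dataclass(frozen=True)
class PlantedEffect:
    variable_id: str
    effect_size: float
    recency_profile: str = "last_year_only"

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.recency_profile not in RECENCY_PROFILES:
            raise ValueError(f"unknown recency profile {self.recency_profile!r}")


def default_risk_spec() -> list[PlantedEffect]:
    """Three strong acute-event effects felt only through the most recent year."""
    return [
        PlantedEffect("event_00", 1.8, "last_year_only"),
        PlantedEffect("event_01", 1.5, "last_year_only"),
        PlantedEffect("event_02", 1.2, "last_year_only"),
    ]


@dataclass
class SyntheticConfig:
    n_patients: int = 2000
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2019, 12, 31)
    seed: int = 0
    visit_rate_range: tuple[float, float] = (0.5, 6.0)
    risk_spec: list[PlantedEffect] = field(default_factory=default_risk_spec)
    outcome_base_rates: dict[str, float] = field(
        default_factory=lambda: {"mortality": 0.12, "nursing_home": 0.06, "home_care": 0.10}
    )
    prediction_window: int = 1
    in_migrant_fraction: float = 0.10      # of those already >=65 at study start
    exit_hazard: float = 0.02              # per-year loss to follow-up
    planted_event_rate: float = 0.7        # yearly Poisson rate of planted acute events
    background_event_rate: float = 0.03

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for name, rate in self.outcome_base_rates.items():
            if not 0.0 < rate < 1.0:
                raise ValueError(f"base rate for {name} must lie in (0, 1)")
            if rate > 0.0 and len(self.risk_spec) == 0 and rate >= 0.5:
                raise ValueError(
                    "empty risk_spec cannot support a majority-class outcome signal"
                )
        for eff in self.risk_spec:
            PlantedEffect(eff.variable_id, eff.effect_size, eff.recency_profile)


@dataclass(frozen=True)
class PlantedTruth:
    """Echo of the generative risk structure, for recovery scoring."""
    risk_spec: tuple[PlantedEffect, ...]
    outcome_base_rates: dict[str, float]
    seed: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _days(ts) -> np.ndarray:
    """datetime64 array -> int days since epoch."""
    return np.asarray(ts, dtype="datetime64[D]").astype(np.int64)


def _to_dates(day_ints: np.ndarray) -> np.ndarray:
    return (_EPOCH + day_ints.astype("timedelta64[D]")).astype("datetime64[D]")


def _year_start(year: int) -> int:
    return _days(np.datetime64(f"{year:04d}-01-01"))[()]


def _year_end(year: int) -> int:
    return _days(np.datetime64(f"{year:04d}-12-31"))[()]


def recency_weights(profile: str, n_years: int) -> np.ndarray:
    """Weights over history years (oldest first), summing to 1, anchored on the
    year closest to the prediction."""
    if n_years <= 0:
        return np.zeros(0)
    if profile == "last_year_only":
        w = np.zeros(n_years)
        w[-1] = 1.0
    elif profile == "uniform":
        w = np.full(n_years, 1.0 / n_years)
    elif profile == "decaying":
        w = DECAY_RATIO ** np.arange(n_years - 1, -1, -1, dtype=float)
        w /= w.sum()
    else:
        raise ValueError(f"unknown recency profile {profile!r}")
    return w


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(
    cfg: SyntheticConfig, schema: FeatureSchema | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate (events, statics, planted_truth) for a synthetic dynamic cohort.

    Events are long-format rows (patient_id, date, domain, code, value);
    statics carry one row per patient. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    schema = schema or build_default_schema()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    y0, y1 = cfg.study_start.year, cfg.study_end.year
    years = np.arange(y0, y1 + 1)
    start_day = _days(np.datetime64(cfg.study_start))[()]
    end_day = _days(np.datetime64(cfg.study_end))[()]

    # ----- statics -------------------------------------------------------
    age_at_start = rng.integers(56, 100, n)
    birth_year = y0 - age_at_start
    birth_doy = rng.integers(0, 365, n)
    birth_day = np.array([_year_start(int(b)) for b in birth_year]) + birth_doy
    b65_day = np.array([_year_start(int(b) + 65) for b in birth_year]) + birth_doy

    sex = np.where(rng.random(n) < 0.56, "F", "M")
    ses = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.13, 0.30, 0.34, 0.19, 0.04]).astype(float)
    ses[rng.random(n) < 0.02] = np.nan

    migrant = (age_at_start >= 65) & (rng.random(n) < cfg.in_migrant_fraction)
    arrival = np.full(n, start_day, dtype=np.int64)
    arrival[migrant] = rng.integers(start_day, end_day + 1, migrant.sum())

    entry_day = np.maximum(np.maximum(arrival, b65_day), start_day)
    entry_year = _to_dates(entry_day).astype("datetime64[Y]").astype(int) + 1970

    # loss to follow-up (censoring); death is decided by the outcome model.
    # Censoring is year-granular (exit on Dec 31) so the final observed year
    # is always complete — annual aggregation cannot use partial years.
    exit_offset_years = rng.exponential(1.0 / max(cfg.exit_hazard, 1e-12), n)
    exit_day = entry_day + (exit_offset_years * 365.25).astype(np.int64)
    exit_year_arr = _to_dates(exit_day).astype("datetime64[Y]").astype(int) + 1970
    exit_day = np.array([_year_end(int(y)) for y in exit_year_arr])
    censored = exit_day < end_day
    followup_end_day = np.minimum(exit_day, end_day)
    end_year = _to_dates(followup_end_day).astype("datetime64[Y]").astype(int) + 1970

    lam = rng.uniform(cfg.visit_rate_range[0], cfg.visit_rate_range[1], n)

    # ----- yearly events -------------------------------------------------
    pid_parts: list[np.ndarray] = []
    day_parts: list[np.ndarray] = []
    dom_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    val_parts: list[np.ndarray] = []

    def emit(pids, days, domain, codes, values=None):
        m = len(pids)
        if m == 0:
            return
        pid_parts.append(np.asarray(pids, dtype=np.int64))
        day_parts.append(np.asarray(days, dtype=np.int64))
        dom_parts.append(np.full(m, domain, dtype=object))
        codes = np.asarray(codes, dtype=object)
        code_parts.append(codes if codes.shape else np.full(m, codes[()], dtype=object))
        if values is None:
            val_parts.append(np.full(m, np.nan))
        else:
            val_parts.append(np.asarray(values, dtype=float))

    n_event_types = sum(1 for v in schema.variables if v.family == "events")
    planted_codes = {
        schema.get(e.variable_id).source_code
        for e in cfg.risk_spec
        if e.variable_id in schema.variable_ids
    }

    lab_vars = [v for v in schema.variables if v.source_domain == "lab" and v.aggregation == MEAN]
    analyte_codes = [v.source_code for v in lab_vars]
    meas_num_codes = sorted({v.source_code for v in schema.variables
                             if v.source_domain == "measure" and v.source_code.startswith("MEAS")})
    meas_cat_codes = sorted({v.source_code for v in schema.variables
                             if v.source_domain == "measure" and v.source_code.startswith("CMEAS")})
    chronic_vars = [v for v in schema.variables if v.family == "chronic_disease"]
    frailty_vars = [v for v in schema.variables if v.family == "frailty"]
    visit_codes = sorted({v.source_code for v in schema.variables if v.source_domain == "visit"})
    adm_codes = sorted({v.source_code for v in schema.variables if v.source_domain == "admission"})

    # per (patient, year) visit counts, for missingness coupling
    visit_counts = np.zeros((n, len(years)), dtype=np.int64)

    for yi, year in enumerate(years):
        active = (entry_year <= year) & (end_year >= year)
        idx = np.flatnonzero(active)
        if idx.size == 0:
            continue
        lo = np.maximum(_year_start(int(year)), entry_day[idx])
        hi = np.minimum(_year_end(int(year)), followup_end_day[idx])

        def rand_days(owner_rows: np.ndarray) -> np.ndarray:
            """Uniform event day within each owner's observable span this year."""
            u = rng.random(owner_rows.size)
            span = (hi[owner_rows] - lo[owner_rows] + 1).astype(float)
            return lo[owner_rows] + np.floor(u * span).astype(np.int64)

        visits = rng.poisson(lam[idx])
        visit_counts[idx, yi] = visits
        has_visit = visits > 0

        # visit events, split over consultation types
        owners = np.repeat(np.arange(idx.size), visits)
        vtypes = rng.choice(len(visit_codes), size=owners.size, p=_VISIT_TYPE_PROBS)
        emit(idx[owners] if owners.size else owners, rand_days(owners), "visit",
             np.array([visit_codes[t] for t in vtypes], dtype=object))

        # laboratory results: only in years with >=1 visit
        p_test = np.where(has_visit, 1.0 - np.exp(-0.15 * visits), 0.0)
        for k, code in enumerate(analyte_codes):
            tested = np.flatnonzero(rng.random(idx.size) < p_test)
            counts = 1 + rng.poisson(0.25, tested.size)
            owners = np.repeat(tested, counts)
            values = rng.normal(100.0 + k, 15.0, owners.size)
            emit(idx[owners], rand_days(owners), "lab",
                 np.full(owners.size, code, dtype=object), values)

        # clinical measurements: numeric and categorical, same coupling
        p_meas = np.where(has_visit, 1.0 - np.exp(-0.25 * visits), 0.0)
        for k, code in enumerate(meas_num_codes):
            tested = np.flatnonzero(rng.random(idx.size) < p_meas)
            owners = tested
            values = rng.normal(50.0 + k, 10.0, owners.size)
            emit(idx[owners], rand_days(owners), "measure",
                 np.full(owners.size, code, dtype=object), values)
        for code in meas_cat_codes:
            tested = np.flatnonzero(rng.random(idx.size) < p_meas)
            values = rng.integers(0, 3, tested.size).astype(float)
            emit(idx[tested], rand_days(tested), "measure",
                 np.full(tested.size, code, dtype=object), values)

        # incident chronic diseases and frailty deficits (recorded at a visit)
        for j, v in enumerate(chronic_vars):
            haz = 0.004 + 0.0004 * j
            hit = has_visit & (rng.random(idx.size) < haz)
            allowed = schema.sex_specific_codes.get(v.source_code)
            if allowed is not None:
                hit &= sex[idx] == allowed
            rows = np.flatnonzero(hit)
            emit(idx[rows], rand_days(rows), "diagnosis",
                 np.full(rows.size, v.source_code, dtype=object))
        for j, v in enumerate(frailty_vars):
            haz = 0.006 + 0.0004 * j
            rows = np.flatnonzero(has_visit & (rng.random(idx.size) < haz))
            emit(idx[rows], rand_days(rows), "diagnosis",
                 np.full(rows.size, v.source_code, dtype=object))

        # hospital admissions
        adm = rng.poisson(0.08, idx.size)
        owners = np.repeat(np.arange(idx.size), adm)
        atypes = rng.integers(0, len(adm_codes), owners.size)
        emit(idx[owners], rand_days(owners), "admission",
             np.array([adm_codes[t] for t in atypes], dtype=object))

        # billed drugs (ATC level-5 codes)
        ndrg = rng.poisson(1.2, idx.size)
        owners = np.repeat(np.arange(idx.size), ndrg)
        codes = rng.choice(_ATC_CODES, size=owners.size, p=_ATC_PROBS)
        emit(idx[owners], rand_days(owners), "drug", codes.astype(object))

        # specific acute events; planted codes get a higher, i.i.d. yearly rate
        for k in range(n_event_types):
            code = event_code(k)
            rate = cfg.planted_event_rate if code in planted_codes else cfg.background_event_rate
            cnt = rng.poisson(rate, idx.size)
            owners = np.repeat(np.arange(idx.size), cnt)
            emit(idx[owners], rand_days(owners), "diagnosis",
                 np.full(owners.size, code, dtype=object))

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_parts) if pid_parts else np.array([], dtype=np.int64),
            "date": _to_dates(np.concatenate(day_parts)) if day_parts else np.array([], dtype="datetime64[D]"),
            "domain": np.concatenate(dom_parts) if dom_parts else np.array([], dtype=object),
            "code": np.concatenate(code_parts) if code_parts else np.array([], dtype=object),
            "value": np.concatenate(val_parts) if val_parts else np.array([], dtype=float),
        }
    )

    # ----- outcomes -------------------------------------------------------
    window = cfg.prediction_window
    index_year = end_year - window
    scorable = index_year >= entry_year

    planted_vals = _planted_value_matrices(events, schema, cfg.risk_spec, years, n)
    eta = {o: np.full(n, _logit(cfg.outcome_base_rates[o])) for o in OUTCOMES}
    for j, eff in enumerate(cfg.risk_spec):
        vals = planted_vals[j]                      # (n, n_years)
        contrib = np.zeros(n)
        for p in np.flatnonzero(scorable):
            h0, h1 = entry_year[p] - y0, index_year[p] - y0
            w = recency_weights(eff.recency_profile, h1 - h0 + 1)
            contrib[p] = float(w @ vals[p, h0:h1 + 1])
        # center so the intercept controls overall prevalence
        if scorable.any():
            contrib[scorable] -= contrib[scorable].mean()
        for o in OUTCOMES:
            eta[o] = eta[o] + eff.effect_size * contrib

    out = {o: np.zeros(n, dtype=bool) for o in OUTCOMES}
    for o in OUTCOMES:
        p_o = 1.0 / (1.0 + np.exp(-eta[o]))
        out[o] = scorable & (rng.random(n) < p_o)

    death_day = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    died = out["mortality"]
    if died.any():
        rows = np.flatnonzero(died)
        lo = np.array([_year_start(int(y)) for y in end_year[rows]])
        lo = np.maximum(lo, entry_day[rows])
        hi = np.array([min(_year_end(int(y)), int(d)) for y, d in
                       zip(end_year[rows], followup_end_day[rows])])
        death_day[rows] = lo + np.floor(rng.random(rows.size) * (hi - lo + 1)).astype(np.int64)

    extra_pid, extra_day, extra_code = [], [], []
    for o, code in (("nursing_home", NURSING_HOME_CODE), ("home_care", HOME_CARE_CODE)):
        rows = np.flatnonzero(out[o])
        if rows.size == 0:
            continue
        lo = np.array([_year_start(int(y) + 1) for y in index_year[rows]])
        hi = np.minimum(followup_end_day[rows], death_day[rows])
        hi = np.maximum(hi, lo)
        day = lo + np.floor(rng.random(rows.size) * (hi - lo + 1)).astype(np.int64)
        extra_pid.append(rows)
        extra_day.append(day)
        extra_code.append(np.full(rows.size, code, dtype=object))
    if extra_pid:
        extra = pd.DataFrame(
            {
                "patient_id": np.concatenate(extra_pid),
                "date": _to_dates(np.concatenate(extra_day)),
                "domain": "diagnosis",
                "code": np.concatenate(extra_code),
                "value": np.nan,
            }
        )
        events = pd.concat([events, extra], ignore_index=True)

    events = events.sort_values(
        ["patient_id", "date", "domain", "code"], kind="stable"
    ).reset_index(drop=True)

    statics = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "birth_date": _to_dates(birth_day),
            "sex": sex,
            "ses_quintile": ses,
            "registry_entry_date": _to_dates(np.where(migrant, arrival, start_day)),
            "registry_exit_date": pd.Series(
                np.where(censored, _to_dates(exit_day), np.datetime64("NaT"))
            ),
            "death_date": pd.Series(
                np.where(died, _to_dates(np.minimum(death_day, end_day)), np.datetime64("NaT"))
            ),
        }
    )

    truth = PlantedTruth(tuple(cfg.risk_spec), dict(cfg.outcome_base_rates), cfg.seed)
    return events, statics, truth


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _planted_value_matrices(
    events: pd.DataFrame,
    schema: FeatureSchema,
    risk_spec: list[PlantedEffect],
    years: np.ndarray,
    n_patients: int,
) -> list[np.ndarray]:
    """Per planted variable: (n_patients x n_years) matrix of yearly values.

    Supports yearly counts, carry-forward flags, and (centered) yearly means —
    the value kinds a risk specification may plant on.
    """
    mats = []
    if events.empty:
        return [np.zeros((n_patients, len(years))) for _ in risk_spec]
    ev_year = events["date"].values.astype("datetime64[Y]").astype(int) + 1970
    for eff in risk_spec:
        var = schema.get(eff.variable_id)
        mat = np.zeros((n_patients, len(years)))
        sel = (events["domain"].values == var.source_domain) & (
            events["code"].values == var.source_code
        )
        pid = events["patient_id"].values[sel]
        yr = ev_year[sel]
        inside = (yr >= years[0]) & (yr <= years[-1])
        pid, yr = pid[inside], yr[inside]
        if var.aggregation == COUNT:
            np.add.at(mat, (pid, yr - years[0]), 1.0)
        elif var.aggregation == FLAG_CARRY:
            np.add.at(mat, (pid, yr - years[0]), 1.0)
            mat = np.minimum(np.maximum.accumulate(mat, axis=1), 1.0)
        elif var.aggregation == MEAN:
            vals = events["value"].values[sel][inside]
            ssum = np.zeros_like(mat)
            scnt = np.zeros_like(mat)
            np.add.at(ssum, (pid, yr - years[0]), vals)
            np.add.at(scnt, (pid, yr - years[0]), 1.0)
            with np.errstate(invalid="ignore"):
                mean = np.where(scnt > 0, ssum / np.maximum(scnt, 1.0), 0.0)
            present = scnt > 0
            overall = mean[present].mean() if present.any() else 0.0
            mat = np.where(present, mean - overall, 0.0)
        else:
            raise ValueError(
                f"cannot plant risk on aggregation kind {var.aggregation!r}"
            )
        mats.append(mat)
    return mats


# ---------------------------------------------------------------------------
# signal-recovery scoring
# ---------------------------------------------------------------------------

def planted_signal_report(truth: PlantedTruth, variable_scores) -> dict:
    """Score how well a population attention map recovers the planted signal.

    ``variable_scores`` is a mapping / pandas Series of per-variable mean
    attention (e.g. ``PopulationMap.variable_scores``). Returns the fraction of
    planted variables inside the top decile of the attention ranking and the
    Spearman rank correlation between planted effect sizes and attention.
    """
    scores = pd.Series(variable_scores, dtype=float)
    planted = [e.variable_id for e in truth.risk_spec]
    if len(planted) == 0:
        return {"recovery_fraction": None, "rank_correlation": None,
                "flag": "no_planted_variables"}
    missing = [v for v in planted if v not in scores.index]
    if missing:
        raise KeyError(f"planted variables absent from attention map: {missing}")
    v = len(scores)
    k = max(1, math.ceil(0.1 * v))
    top = set(scores.sort_values(ascending=False, kind="stable").index[:k])
    recovery = sum(p in top for p in planted) / len(planted)
    if len(planted) >= 2:
        from scipy.stats import spearmanr
        effects = [e.effect_size for e in truth.risk_spec]
        rho = float(spearmanr(effects, scores.loc[planted].values).statistic)
    else:
        rho = None
    return {"recovery_fraction": recovery, "rank_correlation": rho,
            "top_decile_size": k, "flag": None}
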