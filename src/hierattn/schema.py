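"""Feature schema for annually-aggregated primary-care EHR data.

The default schema mirrors the structure of a primary-care feature set for
people aged 65+: eight dynamic variable families (chronic-disease occurrence
flags, frailty deficits, laboratory tests, clinical measurements, primary-care
consultations, hospital admissions, billed drugs, and specific acute events)
totalling 246 annually-aggregated variables, plus 2 static variables (sex and
socioeconomic quintile), i.e. 248 variables overall.

Variable names are synthetic (family prefix + index): the schema reproduces
family sizes and aggregation semantics, not a clinical code list.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

# Aggregation kinds
FLAG_CARRY = "flag_carry"        # once recorded, present in every later year
COUNT = "count"                  # events per calendar year (known-zero)
MEAN = "mean"                    # mean of numeric values in the year
MODE = "mode"                    # most frequent category in the year
OUT_OF_RANGE = "out_of_range"    # yearly count of values outside the reference range

NUMERIC_KINDS = {COUNT, MEAN, OUT_OF_RANGE}


@dataclass(frozen=True)
class Variable:
    variable_id: str
    family: str
    value_type: str                      # count | continuous | categorical | binary
    aggregation: str                     # one of the kinds above
    source_domain: str                   # event domain feeding this variable
    source_code: Optional[str] = None    # exact event code (None => family-level)
    reference_range: Optional[tuple[float, float]] = None

    @property
    def always_recorded(self) -> bool:
        """Counts and carry-forward flags are known-zero in any observed year."""
        return self.aggregation in (COUNT, OUT_OF_RANGE, FLAG_CARRY)


@dataclass(frozen=True)
class Family:
    name: str
    variable_count: int
    aggregation_kind: str


@dataclass
class FeatureSchema:
    families: list[Family]
    variables: list[Variable]
    static_variables: list[str] = field(default_factory=lambda: ["sex", "ses_quintile"])
    # event code -> list of variable ids it informs
    code_map: dict[str, list[str]] = field(default_factory=dict)
    # diagnosis codes restricted to one sex, e.g. {"C61.9": "M"}
    sex_specific_codes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [v.variable_id for v in self.variables]
        if len(set(ids)) != len(ids):
            raise ValueError("variable ids must be unique")
        by_family: dict[str, int] = {}
        for v in self.variables:
            by_family[v.family] = by_family.get(v.family, 0) + 1
        for fam in self.families:
            if by_family.get(fam.name, 0) != fam.variable_count:
                raise ValueError(
                    f"family {fam.name}: declared {fam.variable_count} variables, "
                    f"found {by_family.get(fam.name, 0)}"
                )
        for v in self.variables:
            if (v.reference_range is not None) != (v.aggregation == OUT_OF_RANGE):
                raise ValueError(
                    f"{v.variable_id}: reference_range must be present iff the "
                    "variable counts out-of-range tests"
                )

    # ------------------------------------------------------------------ sizes
    @property
    def total_dynamic(self) -> int:
        return len(self.variables)

    @property
    def total_static(self) -> int:
        return len(self.static_variables)

    @property
    def variable_ids(self) -> list[str]:
        return [v.variable_id for v in self.variables]

    def index_of(self, variable_id: str) -> int:
        try:
            return self.variable_ids.index(variable_id)
        except ValueError as err:
            raise KeyError(f"unknown variable_id {variable_id!r}") from err

    def get(self, variable_id: str) -> Variable:
        return self.variables[self.index_of(variable_id)]

    @property
    def numeric_mask(self):
        """Boolean list: True where the variable is z-scored (counts & means)."""
        return [v.value_type in ("count", "continuous") for v in self.variables]

    def content_hash(self) -> str:
        payload = json.dumps(
            [
                (v.variable_id, v.family, v.value_type, v.aggregation,
                 v.source_domain, v.source_code, v.reference_range)
                for v in self.variables
            ],
            default=list,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Default schema construction
# ---------------------------------------------------------------------------

N_CHRONIC = 60
N_FRAILTY = 37
N_LAB = 67          # 21 analytes x (count, mean, out-of-range) + 2 x (count, mean)
N_MEASURE = 50      # 16 numeric x (count, mean) + 9 categorical x (count, mode)
N_CONSULT = 8
N_ADMISSION = 9
N_DRUG = 3
N_EVENT = 12

N_LAB_ANALYTES = 23          # last two analytes have no reference range
N_LAB_RANGED = 21
N_MEAS_NUMERIC = 16
N_MEAS_CATEG = 9

# Synthetic diagnosis codes (dotted ICD-10-like form). Two chronic slots use
# recognisable sex-specific codes so the sex-consistency cleaning rule has a
# default target.
MALE_ONLY_CODE = "C61.9"     # prostate
FEMALE_ONLY_CODE = "C53.9"   # cervix


def chronic_code(k: int) -> str:
    if k == N_CHRONIC - 2:
        return MALE_ONLY_CODE
    if k == N_CHRONIC - 1:
        return FEMALE_ONLY_CODE
    return f"I{k:02d}.9"


def frailty_code(k: int) -> str:
    return f"R{k:02d}.8"


def event_code(k: int) -> str:
    return f"W{k:02d}.0"


# ATC level-1 groups mapped to the three billed-drug count variables
DRUG_GROUPS = {
    "drug_cardiovascular": ("C",),
    "drug_nervous_system": ("N",),
    "drug_other": None,          # fallback bucket
}


def build_default_schema() -> FeatureSchema:
    """Construct the default 248-variable schema (246 dynamic + 2 static)."""
    variables: list[Variable] = []
    code_map: dict[str, list[str]] = {}

    def add(var: Variable) -> None:
        variables.append(var)
        if var.source_code is not None:
            code_map.setdefault(var.source_code, []).append(var.variable_id)

    for k in range(N_CHRONIC):
        add(Variable(f"chronic_{k:02d}", "chronic_disease", "binary", FLAG_CARRY,
                     "diagnosis", chronic_code(k)))
    for k in range(N_FRAILTY):
        add(Variable(f"frailty_{k:02d}", "frailty", "binary", FLAG_CARRY,
                     "diagnosis", frailty_code(k)))

    for k in range(N_LAB_ANALYTES):
        code = f"LAB{k:02d}"
        has_range = k < N_LAB_RANGED
        add(Variable(f"lab_{k:02d}_count", "laboratory", "count", COUNT, "lab", code))
        add(Variable(f"lab_{k:02d}_mean", "laboratory", "continuous", MEAN, "lab", code))
        if has_range:
            lo, hi = 80.0 + k, 120.0 + k    # synthetic reference interval
            add(Variable(f"lab_{k:02d}_oor", "laboratory", "count", OUT_OF_RANGE,
                         "lab", code, reference_range=(lo, hi)))

    for k in range(N_MEAS_NUMERIC):
        code = f"MEAS{k:02d}"
        add(Variable(f"meas_{k:02d}_count", "measurement", "count", COUNT, "measure", code))
        add(Variable(f"meas_{k:02d}_mean", "measurement", "continuous", MEAN, "measure", code))
    for k in range(N_MEAS_CATEG):
        code = f"CMEAS{k:02d}"
        add(Variable(f"cmeas_{k:02d}_count", "measurement", "count", COUNT, "measure", code))
        add(Variable(f"cmeas_{k:02d}_mode", "measurement", "categorical", MODE, "measure", code))

    for k in range(N_CONSULT):
        add(Variable(f"consult_{k:02d}", "consultations", "count", COUNT, "visit", f"VIS{k}"))
    for k in range(N_ADMISSION):
        add(Variable(f"admission_{k:02d}", "admissions", "count", COUNT, "admission", f"ADM{k}"))
    for name in DRUG_GROUPS:
        add(Variable(name, "drugs", "count", COUNT, "drug", None))
    for k in range(N_EVENT):
        add(Variable(f"event_{k:02d}", "events", "count", COUNT, "diagnosis", event_code(k)))

    families = [
        Family("chronic_disease", N_CHRONIC, FLAG_CARRY),
        Family("frailty", N_FRAILTY, FLAG_CARRY),
        Family("laboratory", N_LAB, "count/mean/out_of_range"),
        Family("measurement", N_MEASURE, "count/mean/mode"),
        Family("consultations", N_CONSULT, COUNT),
        Family("admissions", N_ADMISSION, COUNT),
        Family("drugs", N_DRUG, COUNT),
        Family("events", N_EVENT, COUNT),
    ]
    return FeatureSchema(
        families=families,
        variables=variables,
        code_map=code_map,
        sex_specific_codes={MALE_ONLY_CODE: "M", FEMALE_ONLY_CODE: "F"},
    )


def drug_variable_for_atc(atc: str) -> str:
    """Map an ATC code to one of the three billed-drug count variables."""
    for name, prefixes in DRUG_GROUPS.items():
        if prefixes is not None and atc.startswith(prefixes):
            return name
    return "drug_other"
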