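"""Reading and writing the long-format event and static tables.

CSV with ISO-8601 dates, or columnar binary (parquet via pyarrow).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

EVENT_COLUMNS = ["patient_id", "date", "domain", "code", "value"]
STATIC_COLUMNS = ["patient_id", "birth_date", "sex", "ses_quintile",
                  "registry_entry_date", "registry_exit_date", "death_date"]
_STATIC_DATES = ["birth_date", "registry_entry_date", "registry_exit_date", "death_date"]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df = events[EVENT_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df[EVENT_COLUMNS]


def write_statics(statics: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df = statics[STATIC_COLUMNS].copy()
    for c in _STATIC_DATES:
        df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_statics(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    for c in _STATIC_DATES:
        df[c] = pd.to_datetime(df[c])
    return df[STATIC_COLUMNS]
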