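"""Delimited-text readers and writers for the pipeline's tables.

All files are UTF-8 CSV with '.' as the decimal mark.  Column names match
the field names of the corresponding domain types; diet dry matter is
written as % (as in the published tables) and converted to a fraction on
read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .balance import BalanceRecord, DietFormulation, EnergyPartition, GasTrace
from .difference import InclusionScheme

__all__ = [
    "read_diets", "write_diets",
    "read_balance_records", "write_balance_records",
    "read_gas_traces", "write_gas_traces",
    "read_partition_table", "write_partition_table",
    "read_ingredient_table", "write_ingredient_table",
    "read_schemes", "write_schemes",
    "read_config", "write_config",
]

_DIET_COLS = ["diet", "dm", "ash", "ee", "ndf", "adf", "cp", "ge"]
_RECORD_COLS = ["pig_id", "diet_id", "dmi", "ge_intake", "fecal_ge", "urinary_ge",
                "ch4_energy", "n_intake", "fecal_n", "urinary_n", "bw_start", "bw_end"]
_TRACE_COLS = ["pig_id", "time_min", "o2", "co2", "ch4", "state"]
_PARTITION_COLS = ["pig_id", "diet_id", "mei", "thp", "fhp", "hi", "re", "pd", "ld",
                   "pd_free_ne", "ne_density", "me_density", "de_density", "metabolic_bw"]
_INGREDIENT_COLS = ["name", "ge", "cp", "ee", "starch", "ndf", "adf", "ash", "pd", "ld"]


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def read_diets(path: str | Path) -> dict[str, DietFormulation]:
    """Diet nutrient levels (%, as-fed; dm in %; ge in MJ/kg as-fed)."""
    df = pd.read_csv(path)
    _require(df, _DIET_COLS, "diet table")
    out = {}
    for _, r in df.iterrows():
        out[str(r["diet"])] = DietFormulation(
            id=str(r["diet"]), dm=r["dm"] / 100.0, ash=r["ash"], ee=r["ee"],
            ndf=r["ndf"], adf=r["adf"], cp=r["cp"], ge=r["ge"],
        )
    return out


def write_diets(path: str | Path, diets: Iterable[DietFormulation]) -> None:
    rows = [{
        "diet": d.id, "dm": d.dm * 100.0, "ash": d.ash, "ee": d.ee,
        "ndf": d.ndf, "adf": d.adf, "cp": d.cp, "ge": d.ge,
    } for d in diets]
    pd.DataFrame(rows, columns=_DIET_COLS).to_csv(path, index=False)


def read_balance_records(path: str | Path) -> list[BalanceRecord]:
    df = pd.read_csv(path)
    _require(df, _RECORD_COLS, "balance records")
    return [
        BalanceRecord(**{c: (str(r[c]) if c in ("pig_id", "diet_id") else float(r[c]))
                         for c in _RECORD_COLS})
        for _, r in df.iterrows()
    ]


def write_balance_records(path: str | Path, records: Iterable[BalanceRecord]) -> None:
    pd.DataFrame([{c: getattr(r, c) for c in _RECORD_COLS} for r in records]).to_csv(
        path, index=False)


def read_gas_traces(path: str | Path) -> dict[str, GasTrace]:
    """Long-format 5-min traces: pig_id, time_min, o2, co2, ch4, state(fed|fasted)."""
    df = pd.read_csv(path)
    _require(df, _TRACE_COLS, "gas traces")
    out = {}
    for pig_id, g in df.groupby("pig_id", sort=False):
        out[str(pig_id)] = GasTrace(
            pig_id=str(pig_id),
            time_min=g["time_min"].to_numpy(float),
            o2=g["o2"].to_numpy(float),
            co2=g["co2"].to_numpy(float),
            ch4=g["ch4"].to_numpy(float),
            fed=(g["state"] == "fed").to_numpy(),
        )
    return out


def write_gas_traces(path: str | Path, traces: Iterable[GasTrace]) -> None:
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "pig_id": t.pig_id, "time_min": t.time_min, "o2": t.o2,
            "co2": t.co2, "ch4": t.ch4,
            "state": np.where(t.fed, "fed", "fasted"),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_partition_table(path: str | Path) -> list[EnergyPartition]:
    df = pd.read_csv(path)
    _require(df, _PARTITION_COLS, "partition table")
    return [
        EnergyPartition(**{c: (str(r[c]) if c in ("pig_id", "diet_id") else float(r[c]))
                           for c in _PARTITION_COLS})
        for _, r in df.iterrows()
    ]


def write_partition_table(path: str | Path, parts: Iterable[EnergyPartition]) -> None:
    pd.DataFrame([{c: getattr(p, c) for c in _PARTITION_COLS} for p in parts]).to_csv(
        path, index=False)


def read_ingredient_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, _INGREDIENT_COLS, "ingredient table")
    if df[[c for c in _INGREDIENT_COLS if c != "name"]].isna().any().any():
        raise ValueError("ingredient table contains missing values")
    return df


def write_ingredient_table(path: str | Path, df: pd.DataFrame) -> None:
    _require(df, _INGREDIENT_COLS, "ingredient table")
    df.to_csv(path, index=False)


def read_schemes(path: str | Path) -> dict[str, InclusionScheme]:
    """Substitution proportions per test diet: diet, r0, r1, r2[, basis]."""
    df = pd.read_csv(path)
    _require(df, ["diet", "r0", "r1", "r2"], "scheme table")
    out = {}
    for _, r in df.iterrows():
        out[str(r["diet"])] = InclusionScheme(
            r0=float(r["r0"]), r1=float(r["r1"]), r2=float(r["r2"]),
            basis=str(r.get("basis", "as_fed")) if "basis" in df.columns else "as_fed",
        )
    return out


def write_schemes(path: str | Path, schemes: dict[str, InclusionScheme]) -> None:
    pd.DataFrame([
        {"diet": k, "r0": s.r0, "r1": s.r1, "r2": s.r2, "basis": s.basis}
        for k, s in schemes.items()
    ]).to_csv(path, index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Plain-text key = value configuration; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(path: str | Path, values: dict[str, object],
                 comments: dict[str, str] | None = None) -> None:
    lines = []
    for k, v in values.items():
        c = f"  # {comments[k]}" if comments and k in comments else ""
        lines.append(f"{k} = {v}{c}")
    Path(path).write_text("\n".join(lines) + "\n")
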