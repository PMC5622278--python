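"""Tabular output: daily fluxes, harvests and catchment series as CSV."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .grid import CatchmentDay, DailyRecord, HarvestRecord


def records_frame(records: list[DailyRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def harvests_frame(harvests: list[HarvestRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(h) for h in harvests])


def write_outputs(out_dir, records, harvests, catchment) -> None:
    """Write fluxes.csv, harvest.csv and catchment.csv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_frame(records).to_csv(out / "fluxes.csv", index=False)
    harvests_frame(harvests).to_csv(out / "harvest.csv", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in catchment]).to_csv(
        out / "catchment.csv", index=False)


def read_fluxes(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])
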