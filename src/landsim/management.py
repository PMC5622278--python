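"""Management schedule: sowing, fertiliser, manure, cuts, grazing, harvest."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import pandas as pd

KINDS = {"sow", "fertilise_N", "fertilise_P", "apply_FYM", "cut",
         "graze_start", "graze_stop", "harvest", "fallow"}
N_FORMS = {"ammonium", "nitrate", "ammonium_nitrate"}
ANIMALS = {"beef", "dairy", "sheep"}


class ManagementError(ValueError):
    pass


@dataclass(frozen=True)
class ManagementEvent:
    date: Date
    kind: str
    amount: float = 0.0       # kg N ha-1, kg P ha-1 or t ha-1 fresh FYM
    n_form: str | None = None
    crop: str | None = None   # for sow events
    animal: str | None = None
    stocking: float = 0.0     # head ha-1

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ManagementError(f"unknown event kind {self.kind!r}")
        if self.amount < 0:
            raise ManagementError(f"{self.date}: negative amount")
        if self.kind == "fertilise_N":
            if self.n_form not in N_FORMS:
                raise ManagementError(
                    f"{self.date}: fertilise_N requires n_form in {N_FORMS}")
        elif self.n_form is not None:
            raise ManagementError(
                f"{self.date}: n_form only valid for fertilise_N")
        if self.kind == "graze_start" and self.animal not in ANIMALS:
            raise ManagementError(
                f"{self.date}: graze_start requires animal in {ANIMALS}")


def read_management(path) -> list[ManagementEvent]:
    """Read a management CSV (date,kind,amount,n_form,animal,stocking[,crop])."""
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        def get(col, default=None):
            v = row.get(col)
            return default if v is None or pd.isna(v) else v
        events.append(ManagementEvent(
            date=pd.to_datetime(row["date"]).date(),
            kind=str(row["kind"]),
            amount=float(get("amount", 0.0)),
            n_form=get("n_form"),
            crop=get("crop"),
            animal=get("animal"),
            stocking=float(get("stocking", 0.0)),
        ))
    return sorted(events, key=lambda e: e.date)


def write_management(events: list[ManagementEvent], path) -> None:
    pd.DataFrame([{
        "date": e.date.isoformat(), "kind": e.kind, "amount": e.amount,
        "n_form": e.n_form, "crop": e.crop, "animal": e.animal,
        "stocking": e.stocking} for e in events]).to_csv(path, index=False)
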