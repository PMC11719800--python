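"""CSV dialects for measurements, PFS records and Ct tables.

Measurement CSV: ``mouse_id,arm,day,length_mm,breadth_mm[,volume_mm3]``.
The day-0 row of each animal carries the enrollment volume V0 (the volume
at irradiation); rows with day > 0 are post-irradiation measurements.  When
``volume_mm3`` is absent it is derived from the caliper axes with the
ellipsoid formula.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .endpoints import SurvivalRecord
from .regrowth import GrowthMeasurement, MouseRecord, ellipsoid_volume

__all__ = [
    "read_measurements_csv",
    "write_measurements_csv",
    "read_pfs_csv",
    "write_pfs_csv",
]

_MEAS_REQUIRED = ("mouse_id", "arm", "day")


def read_measurements_csv(path, endpoint_multiple: float = 3.0,
                          followup_cap: float | None = None
                          ) -> list[MouseRecord]:
    """Parse a measurement CSV into MouseRecords (one per animal)."""
    # round_trip parsing keeps re-analysis of an emitted CSV bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_MEAS_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing column(s): {sorted(missing)}")
    has_vol = "volume_mm3" in df.columns
    has_axes = {"length_mm", "breadth_mm"} <= set(df.columns)
    if not (has_vol or has_axes):
        raise ValueError(
            "measurement CSV needs volume_mm3 or length_mm+breadth_mm columns"
        )

    def row_volume(row, idx):
        if has_vol and pd.notna(row.get("volume_mm3")):
            return float(row["volume_mm3"])
        if has_axes and pd.notna(row.get("length_mm")) and pd.notna(row.get("breadth_mm")):
            return ellipsoid_volume(float(row["length_mm"]), float(row["breadth_mm"]))
        raise ValueError(f"row {idx}: no volume and incomplete caliper axes")

    records = []
    for (mouse, arm), sub in df.groupby(["mouse_id", "arm"], sort=False):
        sub = sub.sort_values("day")
        day0 = sub[sub["day"] == 0]
        if day0.empty:
            raise ValueError(f"{mouse}: no day-0 row to define V0")
        v0 = row_volume(day0.iloc[0], day0.index[0])
        meas = []
        for idx, row in sub[sub["day"] > 0].iterrows():
            vol = row_volume(row, idx)
            length = float(row["length_mm"]) if has_axes and pd.notna(row.get("length_mm")) else None
            breadth = float(row["breadth_mm"]) if has_axes and pd.notna(row.get("breadth_mm")) else None
            meas.append(GrowthMeasurement(day=float(row["day"]),
                                          length_mm=length, breadth_mm=breadth,
                                          volume_mm3=vol))
        reached = bool(meas and meas[-1].volume_mm3 >= endpoint_multiple * v0)
        last = meas[-1].day if meas else 0.0
        if not reached and followup_cap is not None:
            last = max(last, followup_cap)
        records.append(
            MouseRecord(mouse_id=str(mouse), arm=str(arm), v0=v0,
                        measurements=meas, reached_endpoint=reached,
                        last_followup_day=last,
                        endpoint_multiple=endpoint_multiple)
        )
    return records


def write_measurements_csv(records: list[MouseRecord], path) -> None:
    rows = []
    for rec in records:
        rows.append({"mouse_id": rec.mouse_id, "arm": rec.arm, "day": 0.0,
                     "length_mm": np.nan, "breadth_mm": np.nan,
                     "volume_mm3": rec.v0})
        for m in rec.measurements:
            rows.append({"mouse_id": rec.mouse_id, "arm": rec.arm,
                         "day": m.day, "length_mm": m.length_mm,
                         "breadth_mm": m.breadth_mm,
                         "volume_mm3": m.volume_mm3})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pfs_csv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    missing = {"mouse_id", "arm", "time_days", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"PFS CSV missing column(s): {sorted(missing)}")
    return [
        SurvivalRecord(str(r.mouse_id), str(r.arm), float(r.time_days),
                       int(r.event))
        for r in df.itertuples()
    ]


def write_pfs_csv(records: list[SurvivalRecord], path) -> None:
    pd.DataFrame(
        [{"mouse_id": r.mouse_id, "arm": r.arm, "time_days": r.time,
          "event": r.event} for r in records]
    ).to_csv(path, index=False)
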