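"""CSV/JSON dialects for press logs, counting sheets and tidy result tables.

All floats in emitted CSVs are formatted at 6 significant digits so that
repeated runs with the same configuration and seed are byte-identical;
full-precision values go to companion JSON where needed.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .schedule import Event, EventKind, PressLog, Session
from .stereology import CountingSheet, GridGeometry, SectionRecord, StereoEstimate

__all__ = [
    "write_press_logs_csv",
    "read_press_logs_csv",
    "write_counting_sheets",
    "read_counting_sheets",
    "write_estimates_csv",
    "format_float",
    "write_tidy_csv",
]

PRESS_LOG_COLUMNS = ["animal_id", "group", "session_day", "time_s", "kind"]


def format_float(x: float, sig: int = 6) -> str:
    """Fixed 6-significant-digit representation for bit-stable CSV output."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if not np.isfinite(x):
        return str(x)
    return f"{x:.{sig}g}"


def write_press_logs_csv(logs: Iterable[PressLog], path: str | Path) -> None:
    """One row per event: animal_id, group, session_day, time_s, kind."""
    rows = []
    for log in logs:
        for sess in log.sessions:
            for ev in sess.events:
                rows.append((log.animal_id, log.group, sess.session_day,
                             format_float(ev.time_s, sig=10), ev.kind.value))
    df = pd.DataFrame(rows, columns=PRESS_LOG_COLUMNS)
    df.to_csv(path, index=False)


def read_press_logs_csv(path: str | Path) -> list[PressLog]:
    df = pd.read_csv(path)
    missing = set(PRESS_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"press-log CSV missing columns: {sorted(missing)}")
    logs: list[PressLog] = []
    for animal_id, adf in df.groupby("animal_id", sort=True):
        group = str(adf["group"].iloc[0])
        sessions = []
        for day, sdf in adf.groupby("session_day", sort=True):
            events = [
                Event(float(t), EventKind(k))
                for t, k in zip(sdf["time_s"], sdf["kind"])
            ]
            sessions.append(Session(session_day=int(day), events=events))
        logs.append(PressLog(animal_id=str(animal_id), group=group,
                             sessions=sessions))
    return logs


def write_counting_sheets(sheets: Iterable[CountingSheet],
                          csv_path: str | Path,
                          geometry_json_path: str | Path) -> None:
    """Counting-sheet CSV plus a companion geometry/mode JSON per animal-region."""
    rows = []
    geo: dict[str, dict] = {}
    for sh in sheets:
        key = f"{sh.animal_id}/{sh.region}/{sh.stain}"
        g = sh.geometry
        geo[key] = {
            "point_spacing_mm": g.point_spacing_mm,
            "frame_side_mm": g.frame_side_mm,
            "magnification": g.magnification,
            "t_mm": g.section_thickness_t_mm,
            "s": g.section_interval_s,
            "frame_sampling_interval": g.frame_sampling_interval,
            "counting_mode": sh.counting_mode,
        }
        for rec in sh.sections:
            rows.append((sh.animal_id, sh.group, sh.region, sh.stain,
                         rec.section_index, rec.points_P, rec.frames_F,
                         rec.disector_Q))
    pd.DataFrame(rows, columns=[
        "animal_id", "group", "region", "stain", "section_index",
        "points_P", "frames_F", "disector_Q",
    ]).to_csv(csv_path, index=False)
    Path(geometry_json_path).write_text(json.dumps(geo, indent=1, sort_keys=True))


def read_counting_sheets(csv_path: str | Path,
                         geometry_json_path: str | Path) -> list[CountingSheet]:
    df = pd.read_csv(csv_path)
    if df.empty:
        raise ValueError(f"empty counting-sheet file: {csv_path}")
    geo = json.loads(Path(geometry_json_path).read_text())
    sheets: list[CountingSheet] = []
    for (animal, region, stain), sdf in df.groupby(
        ["animal_id", "region", "stain"], sort=True
    ):
        key = f"{animal}/{region}/{stain}"
        if key not in geo:
            raise ValueError(f"no geometry entry for {key}")
        g = geo[key]
        geometry = GridGeometry(
            point_spacing_mm=g["point_spacing_mm"],
            frame_side_mm=g["frame_side_mm"],
            magnification=g["magnification"],
            section_thickness_t_mm=g["t_mm"],
            section_interval_s=g["s"],
            frame_sampling_interval=g["frame_sampling_interval"],
        )
        sdf = sdf.sort_values("section_index")
        sections = [
            SectionRecord(int(r.section_index), int(r.points_P),
                          int(r.frames_F), int(r.disector_Q))
            for r in sdf.itertuples()
        ]
        sheets.append(CountingSheet(
            animal_id=str(animal), group=str(sdf["group"].iloc[0]),
            region=str(region), stain=str(stain), geometry=geometry,
            sections=sections, counting_mode=g.get("counting_mode",
                                                   "unidirectional"),
        ))
    return sheets


def write_estimates_csv(estimates: Iterable[StereoEstimate],
                        path: str | Path) -> None:
    rows = []
    for e in estimates:
        rows.append({
            "animal_id": e.animal_id, "group": e.group, "region": e.region,
            "stain": e.stain,
            "Vref_mm3": format_float(e.Vref_mm3),
            "TSV_mm3": format_float(e.TSV_mm3),
            "Nv_per_mm3": format_float(e.Nv_per_mm3),
            "N_absolute": format_float(e.N_absolute),
            "ce_vref": format_float(e.ce_vref),
            "ce_nv": format_float(e.ce_nv),
            "ce_n": format_float(e.ce_n),
            "Vv_um3": "" if e.Vv_um3 is None else format_float(e.Vv_um3),
            "ce_vv": "" if e.ce_vv is None else format_float(e.ce_vv),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_tidy_csv(rows: list[Mapping], path: str | Path) -> None:
    """Write a tidy table with stable column order and 6-sig-digit floats."""
    df = pd.DataFrame(rows)
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(format_float)
    df.to_csv(path, index=False)
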