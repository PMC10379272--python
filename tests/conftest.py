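"""Shared fixtures: hand-built press logs and small counting sheets."""
from __future__ import annotations

import pytest

from operant_stereo.schedule import Event, EventKind, PressLog, ScheduleConfig, Session
from operant_stereo.stereology import CountingSheet, GridGeometry, SectionRecord


@pytest.fixture
def cfg() -> ScheduleConfig:
    return ScheduleConfig()


def build_session(day: int, fi_specs: list[list[float]],
                  ext_presses: list[float] | None = None,
                  fi_duration: float = 120.0,
                  reward_access: float = 3.0) -> Session:
    """Construct one session: one sequence of len(fi_specs) FI components.

    ``fi_specs[i]`` lists press times (seconds from that FI's start); each
    component is closed by a bare reward event at ``fi_duration`` so that
    hand-placed presses are the only presses counted.
    """
    events: list[Event] = [Event(0.0, EventKind.FI_SEQUENCE_START)]
    t = 0.0
    for presses in fi_specs:
        events.append(Event(t, EventKind.FI_START))
        for p in sorted(presses):
            events.append(Event(t + p, EventKind.PRESS_LEFT))
        events.append(Event(t + fi_duration, EventKind.REWARD))
        t += fi_duration + reward_access
    events.append(Event(t, EventKind.EXT_START))
    for p in sorted(ext_presses or []):
        events.append(Event(t + p, EventKind.PRESS_LEFT))
    return Session(session_day=day, events=events)


def make_log(fi_specs: list[list[float]], ext_presses: list[float] | None = None,
             days: range = range(23, 24), animal_id: str = "a1",
             group: str = "control") -> PressLog:
    sessions = [build_session(d, fi_specs, ext_presses) for d in days]
    return PressLog(animal_id=animal_id, group=group, sessions=sessions)


@pytest.fixture
def vta_geometry() -> GridGeometry:
    return GridGeometry(point_spacing_mm=25.0, frame_side_mm=50.0,
                        magnification=220.0, section_thickness_t_mm=0.005,
                        section_interval_s=20, frame_sampling_interval=2)


@pytest.fixture
def simple_sheet(vta_geometry) -> CountingSheet:
    return CountingSheet(
        animal_id="r1", group="control", region="VTA",
        geometry=vta_geometry,
        sections=[SectionRecord(i, points_P=25, frames_F=10, disector_Q=100)
                  for i in range(4)],
    )
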