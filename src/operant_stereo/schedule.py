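"""Domain types for multiple fixed-interval / extinction (FI-EXT) operant schedules.

The schedule modelled here is the classic Sagvolden-style multiple FI-EXT
schedule used to assay delay-of-reinforcement behaviour in rodents: sequences
of seven 2-min fixed intervals (house light on; the first left-lever press
after the interval elapses is rewarded) each followed by a 5-min extinction
component (house light off, no reward), repeated within daily sessions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class EventKind(str, Enum):
    PRESS_LEFT = "press_left"
    PRESS_RIGHT = "press_right"
    REWARD = "reward"
    FI_START = "fi_start"
    EXT_START = "ext_start"
    FI_SEQUENCE_START = "fi_sequence_start"


@dataclass(frozen=True)
class Event:
    time_s: float
    kind: EventKind

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"negative event time {self.time_s}")


@dataclass
class Session:
    """One daily session: an ordered stream of timestamped operant events."""

    session_day: int
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.session_day < 1:
            raise ValueError("session_day must be >= 1")
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"event times must be non-decreasing (session day {self.session_day})"
            )


@dataclass
class PressLog:
    """Per-animal event stream over daily sessions, with schedule annotations."""

    animal_id: str
    group: str  # "control" | "treated"
    sessions: list[Session] = field(default_factory=list)

    def sessions_in_days(self, day_range: tuple[int, int]) -> list[Session]:
        lo, hi = day_range
        return [s for s in self.sessions if lo <= s.session_day <= hi]


#: Inter-response-time duration bin edges (seconds).  Gap-free half-open
#: thirds-of-a-second partition; the final bin is open-ended.  An IRT of
#: exactly 1/3 s falls in the second bin.
DEFAULT_IRT_EDGES: tuple[float, ...] = (
    0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0, 4.0 / 3.0, 5.0 / 3.0, 2.0,
)


@dataclass(frozen=True)
class ScheduleConfig:
    """Schedule geometry and analysis-window parameters.

    Defaults encode the standard protocol: 120 s fixed intervals binned at
    10 s (12 bins), 300 s extinction binned at 60 s (5 bins), seven FIs per
    sequence, analysis restricted to testing days 23-32, and seven IRT
    duration bins of which the first three (< 1 s) enter the burst index.
    """

    fi_duration_s: float = 120.0
    fi_bin_s: float = 10.0
    ext_duration_s: float = 300.0
    ext_bin_s: float = 60.0
    fis_per_sequence: int = 7
    analysis_days: tuple[int, int] = (23, 32)
    irt_bin_edges_s: tuple[float, ...] = DEFAULT_IRT_EDGES
    burst_bins: tuple[int, ...] = (0, 1, 2)
    reward_access_s: float = 3.0

    def __post_init__(self) -> None:
        if self.fi_duration_s % self.fi_bin_s:
            raise ValueError("fi_duration_s must be divisible by fi_bin_s")
        if len(self.irt_bin_edges_s) != 7:
            raise ValueError("irt_bin_edges_s must define 7 bins (7 ascending edges, last bin open)")
        edges = self.irt_bin_edges_s
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("irt_bin_edges_s must be strictly ascending")
        if self.analysis_days[0] > self.analysis_days[1]:
            raise ValueError("empty analysis-day range")

    @property
    def n_fi_bins(self) -> int:
        return int(round(self.fi_duration_s / self.fi_bin_s))

    @property
    def n_ext_bins(self) -> int:
        return int(round(self.ext_duration_s / self.ext_bin_s))

    @property
    def n_irt_bins(self) -> int:
        return 7


def validate_events(events: Sequence[Event]) -> None:
    """Structural check: the session must carry schedule annotations."""
    kinds = {e.kind for e in events}
    if events and EventKind.FI_START not in kinds:
        raise ValueError("missing schedule annotations (no fi_start events)")
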