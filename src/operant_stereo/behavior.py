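"""Fixed-interval / extinction operant read-outs.

Turns raw press logs into the standard delay-of-reinforcement measures:

* within-FI response curves ("scallops") in 10 s bins, excluding the first
  FI of every sequence,
* group stability flags on the scallop (bin 1 vs bin 11 criteria),
* extinction response curves in 1 min bins,
* inter-response-time (IRT) distributions over 7 duration bins x 12 FI
  segments,
* the burst index: the excess of observed short-IRT (< 1 s) frequency over
  the frequency expected from a random (exponential) responder at the
  animal's overall press rate, a rate-independent impulsivity statistic,
* hyperactivity summaries (last-60 s pressing, 11th-bin pressing).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import Event, EventKind, PressLog, ScheduleConfig, Session, validate_events

__all__ = [
    "FiBinMatrix",
    "ExtBinVector",
    "IrtHistogram",
    "BurstIndexResult",
    "bin_fi_presses",
    "bin_ext_presses",
    "check_stability",
    "irt_distribution",
    "expected_irt_frequencies",
    "burst_index",
    "hyperactivity_metrics",
]


@dataclass
class FiBinMatrix:
    """Mean left presses per 10 s FI bin, averaged over included FIs."""

    animal_id: str
    per_bin_mean: np.ndarray  # shape (12,)
    n_fis_included: int

    def __post_init__(self) -> None:
        self.per_bin_mean = np.asarray(self.per_bin_mean, dtype=float)
        if self.per_bin_mean.shape != (12,):
            raise ValueError("per_bin_mean must have length 12")
        if (self.per_bin_mean < 0).any():
            raise ValueError("per_bin_mean entries must be >= 0")


@dataclass
class ExtBinVector:
    """Mean left presses per 1 min extinction bin."""

    animal_id: str
    per_bin_mean: np.ndarray  # shape (5,)

    def __post_init__(self) -> None:
        self.per_bin_mean = np.asarray(self.per_bin_mean, dtype=float)
        if self.per_bin_mean.shape != (5,):
            raise ValueError("per_bin_mean must have length 5")


@dataclass
class IrtHistogram:
    """IRT counts per (duration bin x 10 s FI segment), mean per analysis day.

    ``overall_rate_p`` is the animal's mean left-press rate (per second)
    across included FI time — the ``p`` of the burst-index formula.
    """

    animal_id: str
    counts: np.ndarray  # shape (7, 12), mean counts per day
    overall_rate_p: float
    n_days: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (7, 12):
            raise ValueError("counts must be 7 x 12")
        if self.overall_rate_p < 0:
            raise ValueError("overall_rate_p must be >= 0")

    @property
    def proportions(self) -> np.ndarray:
        """Relative frequency of IRTs per duration bin (marginal over segments)."""
        per_bin = self.counts.sum(axis=1)
        total = per_bin.sum()
        if total == 0:
            raise ValueError("no inter-response times")
        return per_bin / total


@dataclass
class BurstIndexResult:
    animal_id: str
    expected_freq: np.ndarray  # per short bin
    actual_freq: np.ndarray
    burst_index: float


# ---------------------------------------------------------------------------
# session parsing

@dataclass
class _FiComponent:
    start_s: float
    end_s: float  # closed by the rewarded press (or next annotation)
    is_first_of_sequence: bool
    press_times: list[float]


@dataclass
class _ExtComponent:
    start_s: float
    press_times: list[float]


def _parse_session(session: Session, cfg: ScheduleConfig) -> tuple[list[_FiComponent], list[_ExtComponent]]:
    """Split one session's event stream into FI and EXT components.

    An FI component opens at ``fi_start`` and stays open until the rewarded
    press (schedule semantics: the first press after the interval elapses is
    rewarded and closes the component), or until the next schedule
    annotation if no reward was earned.
    """
    validate_events(session.events)
    fis: list[_FiComponent] = []
    exts: list[_ExtComponent] = []
    current_fi: _FiComponent | None = None
    current_ext: _ExtComponent | None = None
    next_is_first = False

    def close_fi(at: float) -> None:
        nonlocal current_fi
        if current_fi is not None:
            current_fi.end_s = at
            fis.append(current_fi)
            current_fi = None

    for ev in session.events:
        k = ev.kind
        if k is EventKind.FI_SEQUENCE_START:
            close_fi(ev.time_s)
            next_is_first = True
        elif k is EventKind.FI_START:
            close_fi(ev.time_s)
            current_fi = _FiComponent(ev.time_s, np.inf, next_is_first, [])
            next_is_first = False
        elif k is EventKind.EXT_START:
            close_fi(ev.time_s)
            current_ext = _ExtComponent(ev.time_s, [])
            exts.append(current_ext)
        elif k is EventKind.REWARD:
            close_fi(ev.time_s)
        elif k is EventKind.PRESS_LEFT:
            if current_fi is not None:
                current_fi.press_times.append(ev.time_s)
            elif current_ext is not None and ev.time_s < current_ext.start_s + cfg.ext_duration_s:
                current_ext.press_times.append(ev.time_s)
    if session.events:
        close_fi(session.events[-1].time_s)
    return fis, exts


def _analysis_sessions(log: PressLog, cfg: ScheduleConfig) -> list[Session]:
    sessions = log.sessions_in_days(cfg.analysis_days)
    if not sessions:
        raise ValueError(
            f"animal {log.animal_id}: no sessions inside analysis days {cfg.analysis_days}"
        )
    return sessions


def _fi_bin_index(t_in_fi: float, cfg: ScheduleConfig) -> int:
    # Presses after the nominal FI has elapsed but before the rewarded press
    # still belong to the running component and accrue to the last bin.
    return min(int(t_in_fi // cfg.fi_bin_s), cfg.n_fi_bins - 1)


# ---------------------------------------------------------------------------
# operations

def bin_fi_presses(log: PressLog, cfg: ScheduleConfig | None = None) -> FiBinMatrix:
    """Mean left presses per 10 s FI bin over all non-first FIs of analysis days."""
    cfg = cfg or ScheduleConfig()
    counts = np.zeros(cfg.n_fi_bins)
    n_included = 0
    for session in _analysis_sessions(log, cfg):
        fis, _ = _parse_session(session, cfg)
        for fi in fis:
            if fi.is_first_of_sequence:
                continue
            n_included += 1
            for t in fi.press_times:
                counts[_fi_bin_index(t - fi.start_s, cfg)] += 1
    per_bin = counts / n_included if n_included else counts
    return FiBinMatrix(log.animal_id, per_bin, n_included)


def bin_ext_presses(log: PressLog, cfg: ScheduleConfig | None = None) -> ExtBinVector:
    """Mean left presses per 1 min extinction bin over analysis days."""
    cfg = cfg or ScheduleConfig()
    counts = np.zeros(cfg.n_ext_bins)
    n_ext = 0
    for session in _analysis_sessions(log, cfg):
        _, exts = _parse_session(session, cfg)
        for ext in exts:
            n_ext += 1
            for t in ext.press_times:
                b = min(int((t - ext.start_s) // cfg.ext_bin_s), cfg.n_ext_bins - 1)
                counts[b] += 1
    per_bin = counts / n_ext if n_ext else counts
    return ExtBinVector(log.animal_id, per_bin)


def check_stability(
    group: list[FiBinMatrix],
    bin1_max: float = 0.5,
    bin11_min: float = 1.5,
) -> bool:
    """Group-level stability of the scallop: mean bin 1 < 0.5 and mean bin 11 > 1.5.

    Both inequalities are strict; a group sitting exactly on a boundary is
    not stable.
    """
    if not group:
        raise ValueError("empty group")
    means = np.mean([m.per_bin_mean for m in group], axis=0)
    return bool(means[0] < bin1_max and means[10] > bin11_min)


def irt_distribution(log: PressLog, cfg: ScheduleConfig | None = None) -> IrtHistogram:
    """IRT counts per (duration bin x 10 s FI segment), averaged over analysis days.

    IRTs are times between consecutive left presses within the same FI
    component: the timer resets at each ``fi_start`` and at each reward, so
    no IRT spans reward consumption or a component boundary.  Each IRT is
    assigned to the duration bin by half-open edges and to the 10 s segment
    containing its terminating press.  First-of-sequence FIs are excluded,
    mirroring the press-curve exclusion.
    """
    cfg = cfg or ScheduleConfig()
    edges = np.asarray(cfg.irt_bin_edges_s)
    counts = np.zeros((cfg.n_irt_bins, cfg.n_fi_bins))
    total_presses = 0
    total_time = 0.0
    sessions = _analysis_sessions(log, cfg)
    for session in sessions:
        fis, _ = _parse_session(session, cfg)
        for fi in fis:
            if fi.is_first_of_sequence:
                continue
            dur = fi.end_s - fi.start_s
            if not np.isfinite(dur):
                dur = cfg.fi_duration_s
            total_time += dur
            total_presses += len(fi.press_times)
            times = fi.press_times
            for t_prev, t in zip(times, times[1:]):
                irt = t - t_prev
                # half-open bins [e_k, e_{k+1}); last bin open-ended
                k = int(np.searchsorted(edges, irt, side="right")) - 1
                k = max(0, min(k, cfg.n_irt_bins - 1))
                seg = _fi_bin_index(t - fi.start_s, cfg)
                counts[k, seg] += 1
    n_days = len(sessions)
    p = total_presses / total_time if total_time > 0 else 0.0
    return IrtHistogram(log.animal_id, counts / n_days, p, n_days)


def expected_irt_frequencies(
    p: float,
    cfg: ScheduleConfig | None = None,
    literal_sign: bool = False,
) -> np.ndarray:
    """Expected relative IRT frequency per short (< 1 s) bin for a random responder.

    Under random (exponential, rate ``p``) responding, the probability that
    an IRT falls in [t1, t2) is exp(-p*t1) - exp(-p*t2).  ``literal_sign``
    flips the sign to -exp(-p*t1) + exp(-p*t2) for compatibility with the
    historical printed form of the formula.
    """
    cfg = cfg or ScheduleConfig()
    if p < 0:
        raise ValueError("rate p must be >= 0")
    edges = np.asarray(cfg.irt_bin_edges_s)
    out = np.empty(len(cfg.burst_bins))
    for i, b in enumerate(cfg.burst_bins):
        t1, t2 = edges[b], edges[b + 1]
        out[i] = np.exp(-p * t1) - np.exp(-p * t2)
    return -out if literal_sign else out


def burst_index(h: IrtHistogram, cfg: ScheduleConfig | None = None) -> BurstIndexResult:
    """Observed-minus-expected short-IRT frequency, summed over the sub-1 s bins.

    ``actual`` frequencies are proportions of all recorded IRTs, making the
    index independent of total response rate; a positive index indicates
    bursty (impulsive) responding in excess of a random responder at the
    same overall rate.
    """
    cfg = cfg or ScheduleConfig()
    props = h.proportions  # raises on zero IRTs
    actual = props[list(cfg.burst_bins)]
    expected = expected_irt_frequencies(h.overall_rate_p, cfg)
    return BurstIndexResult(
        animal_id=h.animal_id,
        expected_freq=expected,
        actual_freq=actual,
        burst_index=float(np.sum(actual - expected)),
    )


def hyperactivity_metrics(m: FiBinMatrix) -> dict[str, float]:
    """Delay-of-reinforcement hyperactivity summaries.

    ``last60s_total``: mean presses over the last 60 s of the FI (bins 7-12).
    ``bin11``: mean presses in the 11th 10 s bin, the conventional terminal
    ordinate of the scallop.
    """
    return {
        "last60s_total": float(m.per_bin_mean[6:].sum()),
        "bin11": float(m.per_bin_mean[10]),
    }
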