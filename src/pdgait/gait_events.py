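"""Gait-cycle segmentation, contact-event detection and cycle validation.

A gait cycle (stride) of one foot runs between two successive initial
contacts of that foot.  Stance onset/offset is found by threshold crossings
of the foot's aggregate force; initial contact (IC, heel strike) and
terminal contact (TC, toe off) are located as force peaks of the heel and
toe sensors.  Because the two feet alternate, each left-referenced cycle
must show the event order

    IC_R < TC_L < IC_L(next) < TC_R        (and previous TC_R < IC_R)

— heel strike of the contralateral foot, then ipsilateral toe off, then the
ipsilateral heel strike that closes the cycle, then the contralateral toe
off.  Cycles violating the configured ordering rule are excluded from all
downstream feature computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .vgrf_io import VGRFRecord

logger = logging.getLogger("pdgait")

#: minimum credible duration of a stance or swing phase, seconds
MIN_PHASE_S = 0.05
#: default stance on/off threshold as a fraction of the aggregate-force max
DEFAULT_THRESHOLD_FRACTION = 0.05
#: default peak prominence as a fraction of the sensor's record max
DEFAULT_PROMINENCE_FRACTION = 0.10
#: IC is searched in the first, TC in the last, this fraction of stance
DEFAULT_EVENT_WINDOW_FRACTION = 0.40


class SegmentationError(ValueError):
    """Raised when a force trace cannot be segmented into gait cycles."""


@dataclass
class GaitCycle:
    """One stride of one foot, bounded by successive stance onsets."""

    foot: str                 # "LEFT" | "RIGHT"
    index: int
    t_start: float            # stance onset (s)
    t_end: float              # stance offset (s)
    t_next_start: float       # next stance onset (s)

    @property
    def stance_time(self) -> float:
        return self.t_end - self.t_start

    @property
    def swing_time(self) -> float:
        return self.t_next_start - self.t_end

    @property
    def gct(self) -> float:
        """Gait cycle (stride) time."""
        return self.t_next_start - self.t_start


@dataclass
class FootEventSeries:
    """Per-cycle initial/terminal contact times and force magnitudes.

    Missing events (no qualifying peak in the search window) are NaN; such
    cycles are dropped by :func:`validate_cycles`.
    """

    foot: str
    ic_times: np.ndarray
    ic_magnitudes: np.ndarray
    tc_times: np.ndarray
    tc_magnitudes: np.ndarray

    def __len__(self) -> int:
        return len(self.ic_times)

    @property
    def n_missing(self) -> int:
        return int(np.sum(np.isnan(self.ic_times) | np.isnan(self.tc_times)))


@dataclass
class CycleEvents:
    """Left-referenced aligned events of one validated cycle."""

    ic_l: float               # left initial contact opening the cycle
    tc_l: float               # left terminal contact (toe off)
    ic_r: float               # right initial contact within the cycle
    tc_r: float               # right terminal contact closing the cycle
    ic_l_next: float          # left initial contact of the next cycle
    prev_tc_r: float | None   # right toe off just after ic_l (None: 1st cycle)
    ic_l_mag: float
    tc_l_mag: float
    ic_r_mag: float
    tc_r_mag: float

    @property
    def gct_l(self) -> float:
        return self.ic_l_next - self.ic_l


@dataclass
class ValidatedCycleSet:
    """Cycles of both feet that passed the event-ordering validation."""

    cycles_left: list[GaitCycle]
    cycles_right: list[GaitCycle]
    events_left: FootEventSeries
    events_right: FootEventSeries
    aligned: list[CycleEvents]
    excluded_count: int
    total_count: int

    @property
    def retained_count(self) -> int:
        return self.total_count - self.excluded_count


def segment_gait_cycles(
    total_force: np.ndarray,
    sample_rate_hz: float,
    threshold: float = DEFAULT_THRESHOLD_FRACTION,
    relative: bool = True,
    foot: str = "LEFT",
    t0: float = 0.0,
) -> list[GaitCycle]:
    """Segment one foot's aggregate force into gait cycles.

    Stance onset is the sample where the force first reaches the threshold,
    stance offset the sample where it next drops below.  ``threshold`` is a
    fraction of the trace maximum when ``relative`` (default 5%), else
    absolute Newtons.  The leading and trailing partial cycles are
    discarded, as is any cycle with a stance or swing phase shorter than
    50 ms (logged).  Fewer than two complete cycles is an error.
    """
    f = np.asarray(total_force, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    thr = threshold * float(np.max(f)) if relative else float(threshold)
    if thr <= 0:
        raise SegmentationError("trace maximum is zero; fewer than 2 cycles found")
    above = f >= thr
    edges = np.diff(above.astype(np.int8))
    rises = np.flatnonzero(edges == 1) + 1
    falls = np.flatnonzero(edges == -1) + 1
    # drop the leading partial stance (signal already above at sample 0)
    falls = falls[falls > (rises[0] if rises.size else len(f))]
    n_runs = min(len(rises), len(falls))  # trailing unfinished stance dropped
    rises, falls = rises[:n_runs], falls[:n_runs]

    dt = 1.0 / sample_rate_hz
    cycles: list[GaitCycle] = []
    n_short = 0
    for k in range(n_runs - 1):
        t_start = t0 + rises[k] * dt
        t_end = t0 + falls[k] * dt
        t_next = t0 + rises[k + 1] * dt
        if (t_end - t_start) <= MIN_PHASE_S or (t_next - t_end) <= MIN_PHASE_S:
            n_short += 1
            continue
        cycles.append(GaitCycle(foot.upper(), len(cycles), t_start, t_end, t_next))
    if n_short:
        logger.info("%s: discarded %d cycles violating the 50 ms phase rule", foot, n_short)
    if len(cycles) < 2:
        raise SegmentationError(
            f"fewer than 2 complete gait cycles found ({len(cycles)}); "
            "check the stance threshold and record length"
        )
    return cycles


def detect_ic_tc(
    record: VGRFRecord,
    cycles: list[GaitCycle],
    foot: str,
    heel_sensor: int = 1,
    toe_sensor: int = 8,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    window_fraction: float = DEFAULT_EVENT_WINDOW_FRACTION,
) -> FootEventSeries:
    """Locate initial/terminal contact per cycle via heel/toe sensor peaks.

    IC is the first prominent local maximum of the heel sensor within the
    first ``window_fraction`` of stance; TC the last prominent local maximum
    of the toe sensor within the last ``window_fraction``.  Prominence must
    exceed ``prominence_fraction`` of that sensor's record-wide maximum.
    Cycles without a qualifying peak get NaN events (excluded later).
    """
    if not cycles:
        raise ValueError("cycles must be nonempty")
    foot = foot.upper()
    heel = record.sensor(foot, heel_sensor)
    toe = record.sensor(foot, toe_sensor)
    t_origin = float(record.time[0])
    sr = record.sample_rate_hz
    prom_ic = prominence_fraction * float(np.max(heel))
    prom_tc = prominence_fraction * float(np.max(toe))

    ic_t = np.full(len(cycles), np.nan)
    ic_m = np.full(len(cycles), np.nan)
    tc_t = np.full(len(cycles), np.nan)
    tc_m = np.full(len(cycles), np.nan)
    for j, cyc in enumerate(cycles):
        stance = cyc.stance_time
        i0 = int(round((cyc.t_start - t_origin) * sr))
        i1 = int(round((cyc.t_start + window_fraction * stance - t_origin) * sr))
        peak = _first_peak(heel, i0, i1 + 1, prom_ic, last=False)
        if peak is not None:
            ic_t[j] = t_origin + peak / sr
            ic_m[j] = heel[peak]
        i0 = int(round((cyc.t_end - window_fraction * stance - t_origin) * sr))
        i1 = int(round((cyc.t_end - t_origin) * sr))
        peak = _first_peak(toe, i0, i1 + 1, prom_tc, last=True)
        if peak is not None:
            tc_t[j] = t_origin + peak / sr
            tc_m[j] = toe[peak]
    return FootEventSeries(foot, ic_t, ic_m, tc_t, tc_m)


def _first_peak(trace: np.ndarray, i0: int, i1: int, prominence: float, last: bool) -> int | None:
    """Index of the first (or last) prominent local max of trace[i0:i1]."""
    i0 = max(i0, 0)
    i1 = min(i1, len(trace))
    if i1 - i0 < 3:
        return None
    seg = trace[i0:i1]
    peaks, _ = find_peaks(seg, prominence=max(prominence, 0.0) or None)
    if peaks.size == 0:
        # plateau-tolerant fallback: the segment max, if it is a true interior
        # local maximum of the full trace and prominent enough
        k = int(np.argmax(seg)) + i0
        if 0 < k < len(trace) - 1 and trace[k] >= prominence and \
                trace[k] >= trace[k - 1] and trace[k] >= trace[k + 1] and \
                (trace[k] > trace[k - 1] or trace[k] > trace[k + 1]):
            return k
        return None
    return int(peaks[-1 if last else 0]) + i0


def validate_cycles(
    cycles_left: list[GaitCycle],
    cycles_right: list[GaitCycle],
    events_left: FootEventSeries,
    events_right: FootEventSeries,
    mode: str = "FIG4_ORDER",
) -> ValidatedCycleSet:
    """Retain left-referenced cycles whose events occur in a realizable order.

    ``FIG4_ORDER`` (default) enforces, for cycle j,

        IC_R(j) < TC_L(j) < IC_L(j+1) < TC_R(j)   and   TC_R(j-1) < IC_R(j)

    i.e. alternating double-support / single-support phases.
    ``LITERAL_INEQUALITY`` applies the alternative printed rule
    ``IC_L(j) < TC_R(j-1) < IC_R(j) < TC_L(j)`` verbatim (cycle 0, which has
    no j-1 event, is then unverifiable and excluded).  Cycles with missing
    events are always excluded; counts are recorded.
    """
    if mode not in ("FIG4_ORDER", "LITERAL_INEQUALITY"):
        raise ValueError(f"unknown validation mode {mode!r}")
    if len(events_left) == 0 or len(events_right) == 0:
        raise ValueError("event series for both feet are required")

    total = len(cycles_left)
    kept_left: list[GaitCycle] = []
    kept_right: list[GaitCycle] = []
    aligned: list[CycleEvents] = []
    kept_idx: list[int] = []

    ic_r_all = events_right.ic_times
    for j, cyc in enumerate(cycles_left):
        if j + 1 >= len(events_left):
            continue  # no closing left contact: boundary cycle
        ic_l = events_left.ic_times[j]
        tc_l = events_left.tc_times[j]
        ic_l_next = events_left.ic_times[j + 1]
        if np.isnan(ic_l) or np.isnan(tc_l) or np.isnan(ic_l_next):
            continue
        # the right cycle whose initial contact falls inside this left cycle
        inside = np.flatnonzero((ic_r_all > ic_l) & (ic_r_all < ic_l_next))
        if inside.size != 1:
            continue
        k = int(inside[0])
        ic_r = ic_r_all[k]
        tc_r = events_right.tc_times[k]
        prev_tc_r = events_right.tc_times[k - 1] if k >= 1 else np.nan
        if np.isnan(ic_r) or np.isnan(tc_r):
            continue
        if not (ic_l < tc_l and ic_r < tc_r):
            continue  # would violate the event-series invariant

        if mode == "FIG4_ORDER":
            ok = ic_r < tc_l < ic_l_next < tc_r
            if ok and not np.isnan(prev_tc_r):
                ok = prev_tc_r < ic_r
        else:  # LITERAL_INEQUALITY
            ok = (not np.isnan(prev_tc_r)) and (ic_l < prev_tc_r < ic_r < tc_l)
        if not ok:
            continue

        kept_idx.append(j)
        kept_left.append(cyc)
        kept_right.append(cycles_right[k] if k < len(cycles_right) else cycles_right[-1])
        aligned.append(
            CycleEvents(
                ic_l=float(ic_l),
                tc_l=float(tc_l),
                ic_r=float(ic_r),
                tc_r=float(tc_r),
                ic_l_next=float(ic_l_next),
                prev_tc_r=None if np.isnan(prev_tc_r) else float(prev_tc_r),
                ic_l_mag=float(events_left.ic_magnitudes[j]),
                tc_l_mag=float(events_left.tc_magnitudes[j]),
                ic_r_mag=float(events_right.ic_magnitudes[k]),
                tc_r_mag=float(events_right.tc_magnitudes[k]),
            )
        )

    if not aligned:
        raise SegmentationError(
            "no gait cycle passed event-order validation; review the stance "
            "threshold and peak-prominence settings"
        )
    idx = np.array(kept_idx)
    sel = lambda a: np.asarray(a)[idx]
    ev_left = FootEventSeries(
        "LEFT",
        sel(events_left.ic_times), sel(events_left.ic_magnitudes),
        sel(events_left.tc_times), sel(events_left.tc_magnitudes),
    )
    ev_right = FootEventSeries(
        "RIGHT",
        np.array([c.ic_r for c in aligned]), np.array([c.ic_r_mag for c in aligned]),
        np.array([c.tc_r for c in aligned]), np.array([c.tc_r_mag for c in aligned]),
    )
    return ValidatedCycleSet(
        cycles_left=kept_left,
        cycles_right=kept_right,
        events_left=ev_left,
        events_right=ev_right,
        aligned=aligned,
        excluded_count=total - len(kept_left),
        total_count=total,
    )
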