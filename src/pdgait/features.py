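"""Spatiotemporal, asymmetry, fluctuation-magnitude and double-support features.

Two feature sets are produced:

* a 34-element **diagnosis** vector per record (aggregate normalized VGRF,
  per-sensor left/right fluctuation-magnitude variability, stride/stance/
  swing times and ratios, heel-strike and toe-off peak forces, their
  per-cycle statistics, step distance and a stride asymmetry index), used to
  separate Parkinson's disease from healthy gait;
* a **severity** set per record (initial/terminal double support, their sum
  and the limp asymmetry, plus spatiotemporal summaries), used to stage
  disease progression on the Hoehn & Yahr scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gait_events import GaitCycle, ValidatedCycleSet
from .preprocess import aggregate_force, normalize_force
from .vgrf_io import SubjectMeta, VGRFRecord

#: per-sample force floor (N) below which the left sensor is treated as
#: unloaded and the sample excluded from FMV (swing-phase division blow-up)
FMV_FLOOR_N = 1.0


# ---------------------------------------------------------------------------
# spatiotemporal cycle features
# ---------------------------------------------------------------------------

@dataclass
class SpatiotemporalCycleRow:
    """Per-cycle stride/stance/swing durations and their ratios."""

    foot: str
    cycle: int
    gct: float                    # gait-cycle (stride) time, s
    stance_time: float
    swing_time: float
    stance_ratio: float
    swing_ratio: float
    swing_stance_ratio: float
    stride_length: float | None = None   # m; needs walking speed


def spatiotemporal_features(
    cycles: list[GaitCycle],
    meta: SubjectMeta | None = None,
    ratio_convention: str = "CORRECTED",
) -> list[SpatiotemporalCycleRow]:
    """Durations and ratios per gait cycle.

    ``CORRECTED`` (default) uses stance/stride and swing/stride ratios, which
    sum to 1; ``PAPER_LITERAL`` keeps the alternative printed swing ratio
    stride/stance.  Stride length is walking speed x stride time when the
    subject's speed is known, otherwise absent (warned once per call).
    """
    if ratio_convention not in ("CORRECTED", "PAPER_LITERAL"):
        raise ValueError(f"unknown ratio convention {ratio_convention!r}")
    if not cycles:
        raise ValueError("at least one gait cycle is required")
    speed = meta.walking_speed_m_per_s if meta is not None else None
    if meta is not None and speed is None:
        warnings.warn(
            "walking speed unavailable; stride length omitted", stacklevel=2
        )
    rows = []
    for cyc in cycles:
        gct, stance, swing = cyc.gct, cyc.stance_time, cyc.swing_time
        if ratio_convention == "CORRECTED":
            r_swing = swing / gct
        else:
            r_swing = gct / stance
        rows.append(
            SpatiotemporalCycleRow(
                foot=cyc.foot,
                cycle=cyc.index,
                gct=gct,
                stance_time=stance,
                swing_time=swing,
                stance_ratio=stance / gct,
                swing_ratio=r_swing,
                swing_stance_ratio=swing / stance,
                stride_length=None if speed is None else gct * speed,
            )
        )
    return rows


def asymmetry_index(left_values, right_values) -> float:
    """Mean over cycles of |L(i) - R(i)| / L(i).

    Left/right sequences are paired by cycle index after truncation to the
    shorter one; a zero left value or an empty overlap is an error.
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    n = min(len(left), len(right))
    if n == 0:
        raise ValueError("empty left/right overlap")
    left, right = left[:n], right[:n]
    if np.any(left == 0):
        raise ValueError("zero left value: asymmetry ratio undefined")
    return float(np.mean(np.abs(left - right) / left))


# ---------------------------------------------------------------------------
# fluctuation magnitude variability (per-sensor left/right discrepancy)
# ---------------------------------------------------------------------------

def _loaded_mean(trace: np.ndarray, floor: float) -> float:
    """Mean force over the samples where the sensor is loaded (> floor N)."""
    m = trace > floor
    return float(np.mean(trace[m])) if np.any(m) else 0.0


def fmv_value(
    record: VGRFRecord,
    sensor: int,
    floor: float = FMV_FLOOR_N,
    window: slice | None = None,
) -> float:
    """Fluctuation magnitude variability of one sensor pair: |L_i - R_i| / L_i x 100.

    ``L_i`` and ``R_i`` are the sensor's mean forces over its own loaded
    samples (force above ``floor`` Newtons) — the two feet alternate, so a
    sample-by-sample difference would only compare stance against swing.
    NaN when the left sensor is never loaded in the window.
    """
    li = record.sensor("LEFT", sensor)
    ri = record.sensor("RIGHT", sensor)
    if window is not None:
        li, ri = li[window], ri[window]
    if not np.any(li > floor):
        return float("nan")
    m_l = _loaded_mean(li, floor)
    m_r = _loaded_mean(ri, floor)
    return abs(m_l - m_r) / m_l * 100.0


def fmv_cycle_series(
    record: VGRFRecord,
    slices: list[slice],
    sensor: int,
    floor: float = FMV_FLOOR_N,
) -> np.ndarray:
    """FMV of one sensor pair evaluated per gait cycle (for CoV/mean/std)."""
    return np.array([fmv_value(record, sensor, floor, s) for s in slices])


def fmv(record: VGRFRecord, floor: float = FMV_FLOOR_N) -> np.ndarray:
    """Record-level fluctuation magnitude variability of each of the 8 sensors.

    A sensor whose left trace never rises above ``floor`` yields NaN
    (missing) and is excluded from ranking.
    """
    return np.array([fmv_value(record, i, floor) for i in range(1, 9)])


def select_fmv_sensors(fmv_values, k: int = 2) -> list[int]:
    """Indices (1-based) of the k sensors with the largest FMV, descending.

    Ties break toward the lower sensor index; NaN (missing) sensors are
    excluded from the ranking, and fewer than k available is an error.
    """
    v = np.asarray(fmv_values, dtype=float)
    if v.shape != (8,):
        raise ValueError("expected 8 FMV values")
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    avail = [i for i in range(8) if not np.isnan(v[i])]
    if len(avail) < k:
        raise ValueError(f"only {len(avail)} sensors have a defined FMV, need {k}")
    order = sorted(avail, key=lambda i: (-v[i], i))
    return [i + 1 for i in order[:k]]


# ---------------------------------------------------------------------------
# diagnosis feature vector (34 features per record)
# ---------------------------------------------------------------------------

def diagnosis_feature_names(sensors: tuple[int, int] = (3, 7)) -> list[str]:
    """Canonical ordered names of the 34 diagnosis features."""
    a, b = sensors
    primary = [
        "norm_agg_vgrf_left",
        "norm_agg_vgrf_right",
        f"fmv_sensor{a}",
        f"fmv_sensor{b}",
    ]
    names = list(primary)
    for base in ("stance_time", "stride_time", "swing_time",
                 "swing_ratio", "stance_ratio", "swing_stance_ratio",
                 "max_ic_force", "max_tc_force"):
        names += [f"{base}_left", f"{base}_right"]
    for stat in ("cov", "mean", "std"):
        names += [f"{stat}_{p}" for p in primary]
    names += ["step_distance", "asymmetry_index"]
    assert len(names) == 34
    return names


@dataclass
class DiagnosisFeatures:
    """The 34-element per-record diagnosis feature vector."""

    subject_id: str
    values: dict[str, float]
    incomplete: bool = False
    imputed: list[str] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def _cycle_slices(record: VGRFRecord, cycles: list[GaitCycle]) -> list[slice]:
    t0 = float(record.time[0])
    sr = record.sample_rate_hz
    out = []
    for c in cycles:
        i0 = int(round((c.t_start - t0) * sr))
        i1 = int(round((c.t_next_start - t0) * sr))
        out.append(slice(max(i0, 0), min(i1, record.n_samples)))
    return out


def _cov_mean_std(per_cycle: np.ndarray) -> tuple[float, float, float]:
    m = float(np.nanmean(per_cycle))
    s = float(np.nanstd(per_cycle))
    cov = float(s / m * 100.0) if m != 0 else 0.0
    return cov, m, s


def diagnosis_feature_vector(
    record: VGRFRecord,
    validated: ValidatedCycleSet,
    meta: SubjectMeta,
    sensors: tuple[int, int] = (3, 7),
    normalization: str = "BODY_WEIGHT",
    ratio_convention: str = "CORRECTED",
    fmv_floor: float = FMV_FLOOR_N,
) -> DiagnosisFeatures:
    """Assemble the 34 diagnosis features from one validated record.

    The four primary elements are the record means of the normalized
    aggregate left/right VGRF and of the two selected sensors' per-sample
    FMV series; their per-cycle means additionally yield coefficient of
    variation (std/mean x 100), mean and standard deviation features.
    Missing body weight falls back to unit-peak normalization; missing
    walking speed leaves step distance unavailable and flags the vector
    incomplete.
    """
    imputed: list[str] = []
    incomplete = False
    if normalization == "BODY_WEIGHT" and meta.weight_kg is None:
        normalization = "MAX"
        imputed.append("norm_agg_vgrf_left")
        imputed.append("norm_agg_vgrf_right")

    agg = {
        side: normalize_force(aggregate_force(record, side), meta, normalization)
        for side in ("LEFT", "RIGHT")
    }
    slices = _cycle_slices(record, validated.cycles_left)
    # primary elements: record values and per-cycle series for the statistics
    primary: dict[str, tuple[float, np.ndarray]] = {
        "norm_agg_vgrf_left": (
            float(np.mean(agg["LEFT"])),
            np.array([np.mean(agg["LEFT"][s]) for s in slices]),
        ),
        "norm_agg_vgrf_right": (
            float(np.mean(agg["RIGHT"])),
            np.array([np.mean(agg["RIGHT"][s]) for s in slices]),
        ),
    }
    for sensor in sensors:
        primary[f"fmv_sensor{sensor}"] = (
            fmv_value(record, sensor, fmv_floor),
            fmv_cycle_series(record, slices, sensor, fmv_floor),
        )

    values: dict[str, float] = {}
    for name, (record_value, _) in primary.items():
        values[name] = record_value if np.isfinite(record_value) else 0.0

    rows = {
        "left": spatiotemporal_features(validated.cycles_left, meta, ratio_convention),
        "right": spatiotemporal_features(validated.cycles_right, meta, ratio_convention),
    }
    for base, attr in (
        ("stance_time", "stance_time"),
        ("stride_time", "gct"),
        ("swing_time", "swing_time"),
        ("swing_ratio", "swing_ratio"),
        ("stance_ratio", "stance_ratio"),
        ("swing_stance_ratio", "swing_stance_ratio"),
    ):
        for side in ("left", "right"):
            values[f"{base}_{side}"] = float(
                np.mean([getattr(r, attr) for r in rows[side]])
            )
    values["max_ic_force_left"] = float(np.nanmax(validated.events_left.ic_magnitudes))
    values["max_ic_force_right"] = float(np.nanmax(validated.events_right.ic_magnitudes))
    values["max_tc_force_left"] = float(np.nanmax(validated.events_left.tc_magnitudes))
    values["max_tc_force_right"] = float(np.nanmax(validated.events_right.tc_magnitudes))

    for name, (_, per_cycle) in primary.items():
        cov, m, s = _cov_mean_std(per_cycle)
        values[f"cov_{name}"] = cov
        values[f"mean_{name}"] = m
        values[f"std_{name}"] = s

    mean_gct = float(np.mean(
        [r.gct for r in rows["left"]] + [r.gct for r in rows["right"]]
    ))
    if meta.walking_speed_m_per_s is not None:
        # no positional data: distance = speed x time, step time ~ GCT / 2
        values["step_distance"] = meta.walking_speed_m_per_s * mean_gct / 2.0
    else:
        values["step_distance"] = np.nan
        imputed.append("step_distance")
        incomplete = True

    values["asymmetry_index"] = asymmetry_index(
        [r.gct for r in rows["left"]], [r.gct for r in rows["right"]]
    )

    ordered = {n: values[n] for n in diagnosis_feature_names(sensors)}
    if any(not np.isfinite(v) for v in ordered.values()) and not incomplete:
        incomplete = True
    return DiagnosisFeatures(record.subject_id, ordered, incomplete, imputed)


# ---------------------------------------------------------------------------
# severity feature set (double support, limp, spatiotemporal summaries)
# ---------------------------------------------------------------------------

SEVERITY_FEATURE_NAMES: list[str] = (
    ["ids_mean", "ids_std", "tds_mean", "tds_std",
     "ds_mean", "ds_std", "limp_mean", "limp_std"]
    + [f"{base}_{side}" for base in
       ("gct", "stance_time", "swing_time", "stance_ratio", "swing_ratio")
       for side in ("left", "right")]
)


@dataclass
class SeverityFeatures:
    """Per-record double-support and spatiotemporal summaries."""

    subject_id: str
    values: dict[str, float]
    ids: np.ndarray = field(default_factory=lambda: np.empty(0))
    tds: np.ndarray = field(default_factory=lambda: np.empty(0))

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def double_support_per_cycle(validated: ValidatedCycleSet) -> dict[str, np.ndarray]:
    """Per-cycle IDS, TDS, DS and Limp (% of the left gait cycle).

    Initial double support spans the left heel strike to the right toe-off
    immediately following it; terminal double support spans the right heel
    strike to the left toe-off.  Both are expressed as percent of the left
    stride time; DS is their sum and Limp their absolute difference.  Cycles
    lacking the preceding right toe-off (the first of a record) are skipped.
    """
    ids, tds = [], []
    for ev in validated.aligned:
        if ev.prev_tc_r is None:
            continue
        gct = ev.gct_l
        ids.append((ev.prev_tc_r - ev.ic_l) / gct * 100.0)
        tds.append((ev.tc_l - ev.ic_r) / gct * 100.0)
    if not ids:
        raise ValueError(
            "no cycle carries a full double-support event set "
            "(every cycle lacked its preceding contralateral toe-off)"
        )
    ids_a, tds_a = np.asarray(ids), np.asarray(tds)
    return {
        "ids": ids_a,
        "tds": tds_a,
        "ds": ids_a + tds_a,
        "limp": np.abs(ids_a - tds_a),
    }


def severity_feature_vector(
    validated: ValidatedCycleSet, subject_id: str = "", ratio_convention: str = "CORRECTED"
) -> SeverityFeatures:
    """Record means/stds of IDS, TDS, DS and Limp plus spatiotemporal means."""
    if len(validated.aligned) < 2:
        raise ValueError("at least 2 validated cycles are required")
    per = double_support_per_cycle(validated)
    values: dict[str, float] = {}
    for key in ("ids", "tds", "ds", "limp"):
        values[f"{key}_mean"] = float(np.mean(per[key]))
        values[f"{key}_std"] = float(np.std(per[key]))
    rows = {
        "left": spatiotemporal_features(validated.cycles_left, None, ratio_convention),
        "right": spatiotemporal_features(validated.cycles_right, None, ratio_convention),
    }
    for base, attr in (
        ("gct", "gct"),
        ("stance_time", "stance_time"),
        ("swing_time", "swing_time"),
        ("stance_ratio", "stance_ratio"),
        ("swing_ratio", "swing_ratio"),
    ):
        for side in ("left", "right"):
            values[f"{base}_{side}"] = float(
                np.mean([getattr(r, attr) for r in rows[side]])
            )
    ordered = {n: values[n] for n in SEVERITY_FEATURE_NAMES}
    return SeverityFeatures(subject_id, ordered, per["ids"], per["tds"])
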