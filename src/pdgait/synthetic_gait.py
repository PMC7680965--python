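"""Ground-truthed synthetic VGRF walking records.

Generates per-sensor vertical ground-reaction-force records of simulated
level walking in the same text dialect as the real acquisitions, together
with the exact stance/contact event times used to build them, so that every
stage of the pipeline (segmentation, event detection, features, classifiers)
can be tested against a known truth.

The stance waveform is a phenomenological template: a weighted sum of two
raised-cosine humps (weight-acceptance after heel strike, push-off before
toe off) over a small baseline, morphed toward a single central hump by the
``flatten`` parameter — reproducing the flat-foot, single-peak force profile
of parkinsonian gait versus the double-hump profile of healthy gait.
Disease severity lengthens the stride (up to the configured factor),
increases stride-time variability, double support and left/right timing
asymmetry.  Raised cosines have compact support, so the force is exactly
zero during swing and threshold segmentation is unambiguous on noise-free
records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .vgrf_io import SAMPLE_RATE_HZ, SubjectMeta, VGRFRecord, write_gaitpdb_record

G_M_PER_S2 = 9.81

#: stance-phase activation centers/amplitudes of the six arch/metatarsal
#: sensors (2..7); the heel (1) and toe (8) sensors use steep exponential
#: gates instead so their force peaks stay next to ground contact and
#: lift-off.  Plausible fixed constants — the acquisitions provide no
#: per-sensor force model.
MID_SENSOR_CENTER = np.array([0.18, 0.32, 0.45, 0.55, 0.68, 0.82])
MID_SENSOR_AMP = np.array([0.6, 0.8, 0.8, 0.8, 0.8, 0.6])
MID_SENSOR_WIDTH = 0.30
HEEL_TOE_GATE_SCALE = 0.15
#: smoothstep window at the stance boundaries (fraction of stance)
EDGE_RAMP = 0.06


@dataclass
class GaitSimParams:
    """Knobs of the gait simulator; defaults emulate healthy adult walking."""

    n_steps: int = 30                 # strides per foot
    base_gct: float = 1.1             # control mean stride time, s
    pd_gct_factor: float = 1.4        # stride-time multiplier at severity 1
    stance_fraction: float = 0.62     # stance / stride
    severity: float = 0.0             # 0 healthy .. 1 most affected
    gct_cv: float = 0.02              # stride-time coefficient of variation
    asymmetry: float = 0.0            # 0..1 left/right timing asymmetry
    peak_force_bw: float = 1.1        # stance peak in body weights
    flatten: float = 0.0              # 0 double hump .. 1 single narrow peak
    noise_sigma: float = 0.0          # additive sensor noise, N
    weight_kg: float = 72.0
    right_sensor_gain: tuple = (1.0,) * 8   # per-sensor right-foot gain
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        for name in ("severity", "flatten", "asymmetry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.base_gct <= 0 or self.n_steps < 3:
            raise ValueError("base_gct must be positive and n_steps >= 3")


@dataclass
class FootTruth:
    """Exact per-stride event times/magnitudes of one foot."""

    t_start: np.ndarray
    t_end: np.ndarray
    ic_time: np.ndarray
    ic_force: np.ndarray
    tc_time: np.ndarray
    tc_force: np.ndarray


@dataclass
class SyntheticRecord:
    record: VGRFRecord
    truth_left: FootTruth
    truth_right: FootTruth
    params: GaitSimParams
    label: str                      # "PD" | "CONTROL"
    hy_stage: float | None = None

    def truth_double_support(self) -> dict[str, float]:
        """Mean IDS/TDS/DS (% of left stride) from the exact truth events.

        Uses the same heel-peak-to-push-off-peak convention as the feature
        extractor, so it is the appropriate oracle for DS recovery.
        """
        tl, tr = self.truth_left, self.truth_right
        ids_vals, tds_vals = [], []
        for j in range(len(tl.ic_time) - 1):
            ic_l, ic_l_next = tl.ic_time[j], tl.ic_time[j + 1]
            gct = ic_l_next - ic_l
            prev_tc = tr.tc_time[(tr.tc_time > ic_l) & (tr.tc_time < ic_l_next)]
            ic_r = tr.ic_time[(tr.ic_time > ic_l) & (tr.ic_time < ic_l_next)]
            if len(prev_tc) != 1 or len(ic_r) != 1 or prev_tc[0] > ic_r[0]:
                continue
            ids_vals.append((prev_tc[0] - ic_l) / gct * 100.0)
            tds_vals.append((tl.tc_time[j] - ic_r[0]) / gct * 100.0)
        return {
            "ids": float(np.mean(ids_vals)),
            "tds": float(np.mean(tds_vals)),
            "ds": float(np.mean(ids_vals) + np.mean(tds_vals)),
        }


def _hump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised cosine on [center-width, center+width], zero elsewhere."""
    out = np.zeros_like(u)
    m = np.abs(u - center) < width
    out[m] = 0.5 * (1.0 + np.cos(np.pi * (u[m] - center) / width))
    return out


def _edge_window(u: np.ndarray) -> np.ndarray:
    """Smoothstep to zero at both stance boundaries (compact support)."""
    r = np.ones_like(u)
    a = u < EDGE_RAMP
    r[a] = np.sin(0.5 * np.pi * u[a] / EDGE_RAMP) ** 2
    b = u > 1.0 - EDGE_RAMP
    r[b] = np.sin(0.5 * np.pi * (1.0 - u[b]) / EDGE_RAMP) ** 2
    r[(u < 0) | (u > 1)] = 0.0
    return r


def _stance_total(u: np.ndarray, flatten: float) -> np.ndarray:
    """Unit-free total stance waveform over phase u in [0, 1].

    ``flatten`` 0 is the healthy double hump (weight acceptance and push-off
    peaks around 18% / 82% of stance, mid-stance valley at ~45% of peak);
    ``flatten`` 1 is a single broad central peak (flat-foot loading).
    """
    double = _hump(u, 0.14, 0.42) + _hump(u, 0.86, 0.42) + 0.42 * _hump(u, 0.5, 0.60)
    single = 1.15 * _hump(u, 0.5, 0.55)
    return ((1.0 - flatten) * double + flatten * single) * _edge_window(u)


def _sensor_shares(u: np.ndarray) -> np.ndarray:
    """(len(u), 8) rows summing to 1: the split of the total across sensors."""
    g = np.zeros((len(u), 8))
    g[:, 0] = 1.8 * np.exp(-(u / HEEL_TOE_GATE_SCALE) ** 2)
    g[:, 7] = 1.8 * np.exp(-(((1.0 - u) / HEEL_TOE_GATE_SCALE) ** 2))
    for i, (c, a) in enumerate(zip(MID_SENSOR_CENTER, MID_SENSOR_AMP)):
        g[:, i + 1] = a * _hump(u, c, MID_SENSOR_WIDTH)
    g += 0.02  # keep every row well-defined across the whole stance
    return g / g.sum(axis=1, keepdims=True)


def _stance_sensors(u: np.ndarray, flatten: float) -> np.ndarray:
    """(len(u), 8) unit-free per-sensor forces (they sum to the total)."""
    return _stance_total(u, flatten)[:, None] * _sensor_shares(u)


def simulate_record(params: GaitSimParams, subject_id: str = "sim") -> SyntheticRecord:
    """Simulate one walking record with exact ground-truth events.

    Stride durations are i.i.d. with mean
    ``base_gct * (1 + severity * (pd_gct_factor - 1))`` and the configured
    CV; right strides interleave at ~50% phase, perturbed cycle-by-cycle by
    ``asymmetry``; the validation event order (contralateral heel strike,
    ipsilateral toe off, closing heel strike, contralateral toe off) holds
    by construction.  Truth IC/TC are the heel/toe-sensor peaks of the
    noise-free traces within the standard search windows.
    """
    rng = np.random.default_rng(params.seed)
    mean_gct = params.base_gct * (1.0 + params.severity * (params.pd_gct_factor - 1.0))
    n = params.n_steps
    # same normal draws across severities (same seed) -> GCT monotone in severity
    z = rng.standard_normal(n + 2)
    gcts = mean_gct * np.clip(1.0 + params.gct_cv * z, 0.6, 1.4)

    sf_l = params.stance_fraction
    sf_r = params.stance_fraction * (1.0 - 0.03 * params.asymmetry)
    # alternating right-contact phase produces per-cycle stride asymmetry
    # while keeping both feet synchronized on average
    phases = 0.5 + 0.03 * params.asymmetry * np.where(np.arange(n + 1) % 2 == 0, 1.0, -1.0)

    t0 = 1.0
    ic_l = t0 + np.concatenate([[0.0], np.cumsum(gcts[:n])])      # n+1 contacts
    ic_r = ic_l[:n + 1] + phases * gcts[: n + 1]
    ic_r = np.concatenate([[ic_l[0] - (1.0 - phases[0]) * gcts[0]], ic_r])

    stance_l = sf_l * gcts[:n + 1]
    stance_r = sf_r * np.concatenate([[gcts[0]], gcts[: n + 1]])

    duration = ic_r[-1] + stance_r[-1] + 0.5
    n_samples = int(np.ceil(duration * SAMPLE_RATE_HZ)) + 1
    time = np.arange(n_samples) / SAMPLE_RATE_HZ
    peak_n = params.peak_force_bw * params.weight_kg * G_M_PER_S2

    template_max = float(np.max(_stance_total(np.linspace(0, 1, 201), params.flatten)))

    def render(starts, stances, gains):
        sensors = np.zeros((n_samples, 8))
        for ts, st in zip(starts, stances):
            i0 = max(int(np.ceil(ts * SAMPLE_RATE_HZ)), 0)
            i1 = min(int(np.floor((ts + st) * SAMPLE_RATE_HZ)), n_samples - 1)
            if i1 <= i0:
                continue
            u = (time[i0:i1 + 1] - ts) / st
            s = _stance_sensors(u, params.flatten) / template_max * peak_n
            sensors[i0:i1 + 1] += s * gains
        return sensors

    left = render(ic_l, stance_l, np.ones(8))
    right = render(ic_r, stance_r, np.asarray(params.right_sensor_gain))

    # check no same-foot stance overlap (swing must exist)
    for starts, stances in ((ic_l, stance_l), (ic_r, stance_r)):
        if np.any(starts[1:] - (starts[:-1] + stances[:-1]) <= 0.05):
            raise ValueError("parameters yield overlapping same-foot stances")

    truth_left = _truth_events(time, left, ic_l[:-1], stance_l[:-1])
    truth_right = _truth_events(time, right, ic_r[1:-1], stance_r[1:-1])

    if params.noise_sigma > 0:
        left = np.clip(left + rng.normal(0, params.noise_sigma, left.shape), 0, None)
        right = np.clip(right + rng.normal(0, params.noise_sigma, right.shape), 0, None)

    record = VGRFRecord(
        subject_id=subject_id,
        time=time,
        left=left,
        right=right,
        left_total=left.sum(axis=1),
        right_total=right.sum(axis=1),
    )
    label = "PD" if params.severity > 0 else "CONTROL"
    return SyntheticRecord(record, truth_left, truth_right, params, label)


def _truth_events(time, sensors, starts, stances) -> FootTruth:
    """Heel/toe peak times and magnitudes of the noise-free traces."""
    heel, toe = sensors[:, 0], sensors[:, 7]
    sr = SAMPLE_RATE_HZ
    ic_t, ic_f, tc_t, tc_f = [], [], [], []
    for ts, st in zip(starts, stances):
        i0, i1 = int(np.ceil(ts * sr)), int(np.floor((ts + 0.4 * st) * sr))
        k = i0 + int(np.argmax(heel[i0:i1 + 1]))
        ic_t.append(time[k]); ic_f.append(heel[k])
        i0, i1 = int(np.ceil((ts + 0.6 * st) * sr)), int(np.floor((ts + st) * sr))
        k = i0 + int(np.argmax(toe[i0:i1 + 1]))
        tc_t.append(time[k]); tc_f.append(toe[k])
    return FootTruth(
        t_start=np.asarray(starts),
        t_end=np.asarray(starts) + np.asarray(stances),
        ic_time=np.asarray(ic_t),
        ic_force=np.asarray(ic_f),
        tc_time=np.asarray(tc_t),
        tc_force=np.asarray(tc_f),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: H&Y stage -> mean severity; progression is linear with fixed offsets, and
#: effect sizes at the defaults are large relative to the within-stage jitter
#: stage 3 sits closer to stage 2.5 than 2.5 does to 2: late-stage gait
#: changes saturate, so the under-represented top stage is also the hardest
#: to separate from its neighbour
STAGE_SEVERITY = {2.0: 0.32, 2.5: 0.62, 3.0: 0.80}
#: within-stage severity spread; neighbouring stages overlap moderately,
#: as in clinical staging where adjacent stages share gait patterns
SEVERITY_JITTER = 0.10
#: per-sensor scale of the left/right loading imbalance in patients
#: (medial-arch sensor 3 and lateral forefoot sensor 7 most variable)
SENSOR_IMBALANCE_SCALE = np.array(
    [0.01, 0.005, 0.08, 0.02, 0.05, 0.04, 0.07, 0.015]
)


def simulate_cohort(
    n_control: int,
    n_pd_by_stage: Mapping[float, int],
    base_params: GaitSimParams | None = None,
    seed: int = 0,
) -> tuple[list[SyntheticRecord], list[SubjectMeta]]:
    """Simulate a labelled cohort with stage-monotone gait effects.

    Per subject, the base parameters are perturbed around the cohort
    defaults; severity (0 for controls, stage-dependent for patients)
    drives stride time, stride-time CV, double support (via the stance
    fraction), timing asymmetry and waveform flattening, all monotone in
    stage.  Walking speed decreases with severity.  Deterministic per seed.
    """
    base = base_params or GaitSimParams()
    rng = np.random.default_rng(seed)
    records: list[SyntheticRecord] = []
    metas: list[SubjectMeta] = []

    def one(subject_id: str, severity: float, stage: float | None):
        weight = float(np.clip(rng.normal(72.4, 11.8), 45.0, 110.0))
        height = float(np.clip(rng.normal(1.67, 0.08), 1.45, 1.95))
        age = float(np.clip(rng.normal(66.0, 9.0), 40.0, 90.0))
        base_gct = float(np.clip(rng.normal(base.base_gct, 0.04), 0.8, 1.5))
        # patients load the two feet unevenly, most variably on sensors 3/7
        gains = np.clip(
            1.0 - severity * np.abs(rng.normal(0.0, SENSOR_IMBALANCE_SCALE)), 0.5, 1.0
        )
        params = replace(
            base,
            base_gct=base_gct,
            severity=severity,
            gct_cv=base.gct_cv * (1.0 + 2.0 * severity),
            stance_fraction=min(base.stance_fraction + 0.08 * severity, 0.8),
            asymmetry=min(0.5 * severity, 1.0),
            flatten=min(0.6 * severity, 1.0),
            weight_kg=weight,
            right_sensor_gain=tuple(gains),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        rec = simulate_record(params, subject_id=subject_id)
        rec.hy_stage = stage
        speed = float(np.clip(rng.normal(1.2 * (1.0 - 0.25 * severity), 0.05), 0.4, 2.0))
        meta = SubjectMeta(
            subject_id=subject_id,
            group="PD" if stage is not None else "CONTROL",
            hy_stage=stage,
            weight_kg=weight,
            height_m=height,
            age_years=age,
            sex="M" if rng.uniform() < 0.55 else "F",
            walking_speed_m_per_s=speed,
        )
        records.append(rec)
        metas.append(meta)

    for i in range(n_control):
        one(f"Co{i + 1:03d}", 0.0, None)
    for stage in sorted(n_pd_by_stage):
        for i in range(n_pd_by_stage[stage]):
            sev = float(np.clip(
                STAGE_SEVERITY[float(stage)] + rng.normal(0, SEVERITY_JITTER),
                0.05, 1.0,
            ))
            one(f"Pt{stage:g}_{i + 1:03d}", sev, float(stage))
    return records, metas


def write_cohort(
    records: list[SyntheticRecord],
    metas: list[SubjectMeta],
    directory: str | Path,
) -> Path:
    """Write record files, truth-event sidecars and a demographics CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, meta in zip(records, metas):
        write_gaitpdb_record(rec.record, directory / f"{meta.subject_id}.txt")
        sidecar = {
            "label": rec.label,
            "hy_stage": rec.hy_stage,
            "left": {k: getattr(rec.truth_left, k).tolist()
                     for k in ("t_start", "t_end", "ic_time", "tc_time")},
            "right": {k: getattr(rec.truth_right, k).tolist()
                      for k in ("t_start", "t_end", "ic_time", "tc_time")},
        }
        (directory / f"{meta.subject_id}.truth.json").write_text(json.dumps(sidecar))
        rows.append({
            "id": meta.subject_id,
            "group": meta.group,
            "hy": "" if meta.hy_stage is None else meta.hy_stage,
            "weight": meta.weight_kg,
            "height": meta.height_m,
            "age": meta.age_years,
            "sex": meta.sex,
            "speed": meta.walking_speed_m_per_s,
        })
    import pandas as pd

    pd.DataFrame(rows).to_csv(directory / "demographics.csv", index=False)
    return directory
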