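"""Reading and writing VGRF walking records and subject metadata.

The on-disk record dialect is the one used by the public gait-in-Parkinson's
force-record collections: plain whitespace-delimited text, no header, one row
per 10 ms sample, 19 numeric columns in the order

    time  L1..L8  R1..R8  left_total  right_total

where ``L1..L8``/``R1..R8`` are the eight insole force sensors of each foot
(Newtons) and the two trailing columns are the per-foot sensor sums recorded
by the acquisition system.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pdgait")

SAMPLE_RATE_HZ = 100.0
#: minimum record length (samples) — anything shorter cannot hold a full cycle
MIN_SAMPLES = 200
#: tolerated |total - sum(sensors)| as a fraction of the total's maximum
TOTAL_SUM_RTOL = 0.01

SUPPORTED_HY_STAGES = (2.0, 2.5, 3.0)

#: default demographics column-name map (keys are our field names, values the
#: column headers expected in the file); override any entry via config
DEFAULT_DEMOGRAPHICS_COLUMNS: dict[str, str] = {
    "subject_id": "id",
    "group": "group",
    "hy_stage": "hy",
    "weight_kg": "weight",
    "height_m": "height",
    "age_years": "age",
    "sex": "sex",
    "walking_speed_m_per_s": "speed",
}


class VGRFParseError(ValueError):
    """Malformed record file (wrong field count, non-numeric token...)."""


class VGRFFormatError(ValueError):
    """Well-formed file violating the record contract (timing, totals...)."""


@dataclass
class VGRFRecord:
    """One walking record: time-aligned per-sensor and total force traces."""

    subject_id: str
    time: np.ndarray            # (n,) seconds, uniform 0.01 s step
    left: np.ndarray            # (n, 8) N, sensor index 1..8 -> column 0..7
    right: np.ndarray           # (n, 8) N
    left_total: np.ndarray      # (n,) N
    right_total: np.ndarray     # (n,) N
    sample_rate_hz: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.left_total = np.asarray(self.left_total, dtype=float)
        self.right_total = np.asarray(self.right_total, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def sensor(self, foot: str, index: int) -> np.ndarray:
        """Return one sensor trace; ``index`` uses the 1..8 insole numbering."""
        if not 1 <= index <= 8:
            raise ValueError(f"sensor index must be 1..8, got {index}")
        arr = self.left if foot.upper() == "LEFT" else self.right
        return arr[:, index - 1]

    def validate(self) -> None:
        """Raise ``VGRFFormatError`` on any contract violation."""
        n = self.n_samples
        if n < 2:
            raise VGRFFormatError("record must hold at least 2 samples")
        for name, a, shape in (
            ("left", self.left, (n, 8)),
            ("right", self.right, (n, 8)),
            ("left_total", self.left_total, (n,)),
            ("right_total", self.right_total, (n,)),
        ):
            if a.shape != shape:
                raise VGRFFormatError(f"{name} has shape {a.shape}, expected {shape}")
            if not np.all(np.isfinite(a)):
                raise VGRFFormatError(f"{name} contains non-finite values")
        step = 1.0 / self.sample_rate_hz
        dt = np.diff(self.time)
        if dt.size and (np.any(dt <= 0) or np.max(np.abs(dt - step)) > 1e-6):
            raise VGRFFormatError(
                f"time must increase in uniform {step:.4f} s steps (tolerance 1e-6 s)"
            )
        for side, sensors, total in (
            ("left", self.left, self.left_total),
            ("right", self.right, self.right_total),
        ):
            ref = float(np.max(total)) if np.max(total) > 0 else 1.0
            err = float(np.max(np.abs(sensors.sum(axis=1) - total)))
            if err > TOTAL_SUM_RTOL * ref:
                raise VGRFFormatError(
                    f"{side}_total deviates from the sensor sum by {err:.3g} N "
                    f"(> {TOTAL_SUM_RTOL:.0%} of its {ref:.3g} N maximum)"
                )


@dataclass
class SubjectMeta:
    """Demographics and severity labels for one subject."""

    subject_id: str
    group: str                                   # "PD" | "CONTROL"
    hy_stage: float | None = None                # 2.0 | 2.5 | 3.0, PD only
    weight_kg: float | None = None
    height_m: float | None = None
    age_years: float | None = None
    sex: str | None = None
    walking_speed_m_per_s: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "CONTROL"):
            raise ValueError(f"group must be PD or CONTROL, got {self.group!r}")
        if self.group == "CONTROL" and self.hy_stage is not None:
            raise ValueError("control subjects carry no H&Y stage")
        if self.hy_stage is not None and self.hy_stage not in SUPPORTED_HY_STAGES:
            raise ValueError(
                f"H&Y stage {self.hy_stage} outside the supported range 2-3 "
                f"(stages {SUPPORTED_HY_STAGES})"
            )
        for attr in ("weight_kg", "height_m", "age_years", "walking_speed_m_per_s"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValueError(f"{attr} must be positive when present, got {v}")


def read_gaitpdb_record(path: str | Path, subject_id: str | None = None) -> VGRFRecord:
    """Parse one whitespace-delimited 19-column walking record.

    Negative sensor readings (acquisition noise; force sensors cannot pull)
    are clamped to zero with a logged count.  Raises :class:`VGRFParseError`
    naming the offending line on malformed input, :class:`VGRFFormatError` on
    timing/consistency violations, and rejects records shorter than 2 s.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 19:
                raise VGRFParseError(
                    f"{path}: line {lineno}: expected 19 fields, got {len(fields)}"
                )
            try:
                rows.append([float(tok) for tok in fields])
            except ValueError as exc:
                raise VGRFParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
    data = np.asarray(rows, dtype=float)
    if data.shape[0] < MIN_SAMPLES:
        raise VGRFFormatError(
            f"{path}: record too short ({data.shape[0]} samples < {MIN_SAMPLES}; "
            "at least 2 s of walking is required)"
        )
    forces = data[:, 1:]
    n_neg = int(np.sum(forces < 0))
    if n_neg:
        logger.info("%s: clamped %d negative force samples to 0", path, n_neg)
        forces = np.clip(forces, 0.0, None)
    rec = VGRFRecord(
        subject_id=subject_id,
        time=data[:, 0],
        left=forces[:, 0:8],
        right=forces[:, 8:16],
        left_total=forces[:, 16],
        right_total=forces[:, 17],
    )
    rec.validate()
    return rec


def write_gaitpdb_record(record: VGRFRecord, path: str | Path) -> None:
    """Emit a record in the 19-column text dialect (3-decimal forces)."""
    data = np.column_stack(
        [
            record.time,
            record.left,
            record.right,
            record.left_total,
            record.right_total,
        ]
    )
    np.savetxt(path, data, fmt="%.3f", delimiter="\t")


def _get(row: pd.Series, colmap: Mapping[str, str], key: str):
    col = colmap.get(key, DEFAULT_DEMOGRAPHICS_COLUMNS[key])
    if col not in row.index:
        return None
    v = row[col]
    if pd.isna(v) or (isinstance(v, str) and not v.strip()):
        return None
    return v


def read_demographics(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SubjectMeta]:
    """Read the per-subject demographics/severity table (CSV or TSV).

    ``column_map`` renames our canonical fields to the file's headers; any
    field absent from the file becomes ``None`` on the metadata, never zero.
    A PD row with a blank severity column yields a warning and a missing
    stage; a stage outside 2-3 or a duplicated subject id is an error.
    """
    path = Path(path)
    colmap = dict(DEFAULT_DEMOGRAPHICS_COLUMNS)
    if column_map:
        colmap.update(column_map)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    id_col = colmap["subject_id"]
    group_col = colmap["group"]
    for col in (id_col, group_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dupes}")

    subjects: list[SubjectMeta] = []
    for _, row in df.iterrows():
        sid = str(row[id_col])
        group = str(row[group_col]).strip().upper()
        if group in ("PD", "PATIENT", "PARKINSON"):
            group = "PD"
        elif group in ("CONTROL", "CO", "HC", "HEALTHY"):
            group = "CONTROL"
        else:
            raise ValueError(f"{path}: subject {sid}: unknown group {row[group_col]!r}")
        hy = _get(row, colmap, "hy_stage")
        if group == "PD":
            if hy is None:
                warnings.warn(
                    f"PD subject {sid} has no H&Y stage; stage left absent",
                    stacklevel=2,
                )
            else:
                hy = float(hy)
                if hy not in SUPPORTED_HY_STAGES:
                    raise ValueError(
                        f"{path}: subject {sid}: H&Y stage {hy} outside the "
                        "supported range 2-3"
                    )
        else:
            hy = None
        sex = _get(row, colmap, "sex")
        meta = SubjectMeta(
            subject_id=sid,
            group=group,
            hy_stage=hy,
            weight_kg=_f(_get(row, colmap, "weight_kg")),
            height_m=_f(_get(row, colmap, "height_m")),
            age_years=_f(_get(row, colmap, "age_years")),
            sex=str(sex) if sex is not None else None,
            walking_speed_m_per_s=_f(_get(row, colmap, "walking_speed_m_per_s")),
        )
        subjects.append(meta)
    return subjects


def _f(v) -> float | None:
    return None if v is None else float(v)


def group_counts(subjects: Sequence[SubjectMeta]) -> dict[str, int]:
    """Summary helper: number of subjects per group label."""
    out: dict[str, int] = {}
    for s in subjects:
        out[s.group] = out.get(s.group, 0) + 1
    return out


def write_feature_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write feature records as CSV (header always present, 12 sig digits).

    All rows must share one column set.  An empty row list yields a
    header-only file (``columns`` supplies the header in that case).
    """
    rows = list(rows)
    if not rows:
        pd.DataFrame(columns=list(columns or [])).to_csv(path, index=False)
        return
    cols = list(columns) if columns is not None else list(rows[0].keys())
    for i, r in enumerate(rows):
        if set(r.keys()) != set(cols):
            raise ValueError(
                f"row {i} columns {sorted(r.keys())} differ from {sorted(cols)}"
            )
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path)
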