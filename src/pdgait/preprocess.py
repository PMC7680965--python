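"""Signal conditioning: median filtering, force aggregation, normalization.

Raw insole traces carry single-sample spikes from the force-resistive
sensors; a short running median removes them without smearing heel-strike
transients the way a low-pass filter would.  Aggregated per-foot force is
then normalized so features are comparable across subjects of different
body mass.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.ndimage import median_filter as _ndi_median

from .vgrf_io import SubjectMeta, VGRFRecord

G_M_PER_S2 = 9.81

#: default running-median window, samples (30 ms at 100 Hz)
DEFAULT_MEDIAN_WINDOW = 3


def median_filter_trace(trace: np.ndarray, window: int) -> np.ndarray:
    """Running median with edge replication (``window`` odd, in samples)."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"median window must be a positive odd integer, got {window}")
    if window > trace.shape[-1] // 2:
        raise ValueError(
            f"median window {window} too large for trace of length {trace.shape[-1]}"
        )
    if window == 1:
        return np.array(trace, dtype=float)
    # mode="nearest" replicates the edge sample, matching the contract
    return _ndi_median(np.asarray(trace, dtype=float), size=window, mode="nearest")


def median_filter_record(record: VGRFRecord, window: int = DEFAULT_MEDIAN_WINDOW) -> VGRFRecord:
    """Apply the running median to all 18 force traces; time is untouched."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"median window must be a positive odd integer, got {window}")
    if window > record.n_samples // 2:
        raise ValueError(
            f"median window {window} too large for record of {record.n_samples} samples"
        )
    flt = lambda a: _ndi_median(a, size=(window, 1), mode="nearest") if a.ndim == 2 else \
        _ndi_median(a, size=window, mode="nearest")
    return replace(
        record,
        left=flt(record.left),
        right=flt(record.right),
        left_total=flt(record.left_total),
        right_total=flt(record.right_total),
    )


def aggregate_force(record: VGRFRecord, side: str, source: str = "SUM_SENSORS") -> np.ndarray:
    """Per-foot aggregate vertical force (N).

    ``source="SUM_SENSORS"`` sums the 8 sensor traces elementwise;
    ``source="TOTAL_COLUMN"`` returns the total recorded by the acquisition
    system (the two agree within the record's 1% consistency contract).
    """
    side = side.upper()
    if side not in ("LEFT", "RIGHT"):
        raise ValueError(f"side must be LEFT or RIGHT, got {side!r}")
    if source == "SUM_SENSORS":
        arr = record.left if side == "LEFT" else record.right
        return arr.sum(axis=1)
    if source == "TOTAL_COLUMN":
        return np.array(record.left_total if side == "LEFT" else record.right_total)
    raise ValueError(f"unknown aggregate source {source!r}")


def normalize_force(
    trace: np.ndarray, meta: SubjectMeta | None = None, mode: str = "BODY_WEIGHT"
) -> np.ndarray:
    """Normalize a force trace to a dimensionless scale.

    ``BODY_WEIGHT`` divides by the subject's weight force (kg x 9.81 m/s^2),
    so a value of 1.0 means one body weight — the field-standard basis for
    comparing VGRF across subjects.  ``MAX`` divides by the trace maximum
    (unit peak); an all-zero trace is returned unchanged under ``MAX``.
    """
    trace = np.asarray(trace, dtype=float)
    if mode == "BODY_WEIGHT":
        if meta is None or meta.weight_kg is None:
            raise ValueError(
                "BODY_WEIGHT normalization needs the subject's weight; "
                "fall back to mode='MAX' when weight is unavailable"
            )
        return trace / (meta.weight_kg * G_M_PER_S2)
    if mode == "MAX":
        peak = float(np.max(trace))
        if peak <= 0:
            return np.zeros_like(trace)
        return trace / peak
    raise ValueError(f"unknown normalization mode {mode!r}")
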