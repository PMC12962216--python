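"""Echo-time-shifting bias correction, run-time filters, precision metrics.

Segmented 3D-EPI with echo time shifting (ETS) leaves shot-dependent eddy
currents that bias the navigator parameter predictions with a pattern
repeating every S shots (S = in-plane segmentation factor).  The bias is
estimated by averaging the uncorrected predictions of the last four
partitions per in-plane shot index (so genuine motion and field
fluctuations average out), subtracted from subsequent predictions at run
time, and recomputed every new partition in a sliding-window fashion.

Only the zero-mean (periodic) part of the per-index averages is
subtracted at application time: the common mean over the S indices is the
current true motion/field level, not an acquisition bias, and removing it
would absorb sustained real motion into the bias table.  This is the
window arithmetic behind the characteristic transient a rapid motion
event leaves in the corrected trace (it decays within one full window,
4 partitions, after the event ends).

Precision is quantified as the standard deviation of a parameter trace
after high-pass filtering at 1/(TR x S) -- low enough to keep the ETS
band, high enough to reject drifts and slow motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ParameterVector, PARAM_NAMES

__all__ = [
    "BiasTable",
    "PrecisionReport",
    "init_bias",
    "slide_bias",
    "apply_bias_correction",
    "moving_average",
    "highpass_std",
    "precision_report",
    "apparent_shift",
]

WINDOW_PARTITIONS = 4  # sliding-window length of the bias estimator
MOTION_FILTER_WINDOW = 10  # shots; run-time moving average, motion parameters
FIELD_FILTER_WINDOW = 14  # shots; run-time moving average, field parameters


def _as_2d(pred) -> np.ndarray:
    """Coerce predictions to an (n, d) float array (ParameterVectors allowed)."""
    if isinstance(pred, (list, tuple)) and len(pred) and isinstance(pred[0], ParameterVector):
        return np.stack([p.as_array() for p in pred])
    a = np.asarray(pred, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


@dataclass(frozen=True)
class BiasTable:
    """Per-in-plane-shot-index bias estimates with their sliding window.

    table : (S, d) raw per-index means over the buffered partitions;
    buffer : (w, S, d) ring of the last w <= 4 partitions of *uncorrected*
    predictions (oldest first).
    """

    table: np.ndarray
    buffer: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        b = np.asarray(self.buffer, dtype=float)
        if b.ndim != 3 or b.shape[1:] != t.shape:
            raise ValueError(f"buffer {b.shape} inconsistent with table {t.shape}")
        if b.shape[0] > WINDOW_PARTITIONS:
            raise ValueError("buffer holds more than 4 partitions")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite bias entries")
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "buffer", b)

    @property
    def S(self) -> int:
        return self.table.shape[0]

    @property
    def centered(self) -> np.ndarray:
        """Zero-mean (periodic) part of the table, the part that is subtracted."""
        return self.table - self.table.mean(axis=0, keepdims=True)


def init_bias(predictions, S: int) -> BiasTable:
    """Initial bias table from the first four partitions of predictions.

    ``predictions`` must hold exactly 4 x S per-shot parameter rows in shot
    order; bias[s] is the mean over the four partitions at in-plane index s.
    """
    a = _as_2d(predictions)
    if a.shape[0] != WINDOW_PARTITIONS * S:
        raise ValueError(
            f"need exactly {WINDOW_PARTITIONS} x {S} = {WINDOW_PARTITIONS * S} "
            f"predictions, got {a.shape[0]}"
        )
    buf = a.reshape(WINDOW_PARTITIONS, S, -1)
    return BiasTable(buf.mean(axis=0), buf)


def slide_bias(table: BiasTable, new_partition) -> BiasTable:
    """Advance the window by one partition of uncorrected predictions."""
    a = _as_2d(new_partition)
    if a.shape[0] != table.S or a.shape[1] != table.table.shape[1]:
        raise ValueError(
            f"partition shape {a.shape} does not match table (S={table.S}, "
            f"d={table.table.shape[1]})"
        )
    buf = np.concatenate([table.buffer, a[None]], axis=0)
    if buf.shape[0] > WINDOW_PARTITIONS:
        buf = buf[-WINDOW_PARTITIONS:]
    return BiasTable(buf.mean(axis=0), buf)


def apply_bias_correction(pred, table: BiasTable, s: int):
    """Subtract the (centered) shot-specific bias for in-plane index s.

    Returns the same type as ``pred`` (ParameterVector or array).
    """
    if not 0 <= s < table.S:
        raise IndexError(f"in-plane index {s} out of range [0, {table.S})")
    bias = table.centered[s]
    if isinstance(pred, ParameterVector):
        return ParameterVector.from_array(pred.as_array() - bias)
    a = np.asarray(pred, dtype=float)
    return a - (bias if a.ndim else float(bias[0]))


def moving_average(series, window: int) -> np.ndarray:
    """Trailing (causal) moving average along axis 0.

    output[n] = mean(series[max(0, n-window+1) .. n]); the first window-1
    outputs use the available prefix mean, so a constant series is
    unchanged from the first sample.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    a = np.asarray(series, dtype=float)
    squeeze = a.ndim == 1
    if squeeze:
        a = a[:, None]
    csum = np.cumsum(a, axis=0)
    out = np.empty_like(a)
    n = a.shape[0]
    w = min(window, n)
    counts = np.minimum(np.arange(1, n + 1), window)[:, None].astype(float)
    out[:w] = csum[:w]
    if n > window:
        out[window:] = csum[window:] - csum[:-window]
    out = out / counts
    return out[:, 0] if squeeze else out


def highpass_std(series, f_threshold: float, fs: float) -> np.ndarray:
    """Standard deviation after zero-phase high-pass filtering.

    Second-order Butterworth high-pass at ``f_threshold`` (Hz), applied
    forward-backward (zero phase), then sample std along axis 0.  Removes
    drifts and slow motion while keeping the ETS periodicity band.
    """
    if not f_threshold < fs / 2:
        raise ValueError(
            f"threshold {f_threshold} Hz must be below Nyquist {fs / 2} Hz"
        )
    a = np.asarray(series, dtype=float)
    sos = sps.butter(2, f_threshold, btype="highpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, a, axis=0)
    return filtered.std(axis=0)


@dataclass(frozen=True)
class PrecisionReport:
    """Stage-wise high-pass-filtered parameter standard deviations.

    stds maps processing stage ('raw', 'bias_corrected', 'filtered') to an
    (11,) array in native units (deg, mm, rad, Hz, uT/m); improvement
    factors are elementwise std ratios between stages.
    """

    stds: dict
    improvement: dict
    threshold_hz: float
    param_names: tuple = PARAM_NAMES

    def to_dict(self) -> dict:
        return {
            "threshold_hz": self.threshold_hz,
            "stds": {k: dict(zip(self.param_names, v.tolist())) for k, v in self.stds.items()},
            "improvement": {
                k: dict(zip(self.param_names, v.tolist())) for k, v in self.improvement.items()
            },
        }

    def to_dataframe(self):
        """Tidy frame: one row per (parameter, quantity)."""
        import pandas as pd

        rows = []
        for kind, table in (("std", self.stds), ("improvement", self.improvement)):
            for stage, values in table.items():
                for name, value in zip(self.param_names, values):
                    rows.append(
                        dict(parameter=name, kind=kind, stage=stage, value=float(value))
                    )
        return pd.DataFrame(rows)


def precision_report(traces, protocol) -> PrecisionReport:
    """Per-parameter precision at each processing stage of a loop run.

    ``traces`` must expose (n, 11) arrays ``raw``, ``bias_corrected`` and
    ``filtered`` (see servo.LoopTraces) covering at least 8 partitions;
    ``protocol`` supplies TR and S.  Stds are computed after high-pass
    filtering at 1/(TR x S).  The first 4 partitions (the bias-table
    initialization window, during which the corrected stages run
    uncorrected) are excluded from every stage so the comparison reflects
    steady-state operation.
    """
    s_factor, tr_ms = protocol.segmentation, protocol.tr_ms
    raw = np.asarray(traces.raw, float)
    if raw.shape[0] < 8 * s_factor:
        raise ValueError(
            f"traces too short for a precision report: {raw.shape[0]} shots "
            f"< 8 partitions x {s_factor}"
        )
    fs = 1000.0 / tr_ms
    f_thr = 1000.0 / (tr_ms * s_factor)
    skip = WINDOW_PARTITIONS * s_factor
    stages = {
        "raw": raw[skip:],
        "bias_corrected": np.asarray(traces.bias_corrected, float)[skip:],
        "filtered": np.asarray(traces.filtered, float)[skip:],
    }
    stds = {k: highpass_std(v, f_thr, fs) for k, v in stages.items()}
    with np.errstate(divide="ignore", invalid="ignore"):
        improvement = {
            "raw_over_bias_corrected": stds["raw"] / stds["bias_corrected"],
            "bias_corrected_over_filtered": stds["bias_corrected"] / stds["filtered"],
            "raw_over_filtered": stds["raw"] / stds["filtered"],
        }
    return PrecisionReport(stds, improvement, f_thr)


def apparent_shift(f0_offset: float, pe_bandwidth: float) -> float:
    """Apparent image shift (mm) caused by a frequency offset.

    A global frequency offset displaces the image along the low-bandwidth
    phase-encoding direction by f0 / (PE bandwidth per mm).
    """
    if not pe_bandwidth > 0:
        raise ValueError(f"PE bandwidth must be positive, got {pe_bandwidth}")
    return f0_offset / pe_bandwidth
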