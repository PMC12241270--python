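"""Signal cleaning, derivatives, windowing and beat-wise BP extraction.

Pipeline order is fixed: band-pass filter the raw trace, compute the first
(vPPG) and second (aPPG) derivatives on the full filtered record, then cut
15-second windows with 66.67 % overlap.  Derivatives are taken before
segmentation so shared samples of overlapping windows agree exactly and no
per-window edge artifacts appear at window boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from ppgbp.config import ConfigurationError, FilterSpec
from ppgbp.simulate import SignalRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 15.0
DEFAULT_OVERLAP = 2.0 / 3.0


class InputError(ValueError):
    """The input data violates an operation precondition."""


@dataclass
class BeatBP:
    """Per-cardiac-cycle systolic/diastolic pressure from an ABP waveform."""

    beat_index: int
    sbp: float
    dbp: float
    peak_time: float
    trough_time: float


@dataclass
class SegmentWindow:
    """A fixed-duration slice of PPG + derivatives with window-level labels."""

    window_id: str
    ppg: np.ndarray
    vppg: np.ndarray
    appg: np.ndarray
    sampling_rate: float
    start_time: float
    sbp_label: float
    dbp_label: float
    record_id: str
    subject_id: str


def butter_sos(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Second-order-section coefficients of the band-pass design."""
    spec.validate(sampling_rate)
    return signal.butter(
        spec.order,
        [spec.lowcut, spec.highcut],
        btype="bandpass",
        output="sos",
        fs=sampling_rate,
    )


def bandpass_filter(
    samples: Sequence[float], sampling_rate: float, spec: Optional[FilterSpec] = None
) -> np.ndarray:
    """Butterworth band-pass via cascaded second-order sections.

    Zero-phase mode applies the cascade forward and backward (no net phase
    shift, squared magnitude response); single-pass mode applies it once.
    """
    spec = spec or FilterSpec()
    x = np.asarray(samples, dtype=float)
    sos = butter_sos(spec, sampling_rate)
    if len(x) < 3 * spec.order * 2:
        raise InputError(
            f"signal of length {len(x)} too short for order-{spec.order} filtering"
        )
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def derivative(samples: Sequence[float], sampling_rate: float, order: int = 1) -> np.ndarray:
    """Time derivative: central differences inside, one-sided at the edges.

    ``order=2`` applies the first-order operator twice.  Output units are
    input units per second (per second squared for order 2).
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 5:
        raise InputError("need at least 5 samples for a derivative estimate")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    dt = 1.0 / sampling_rate
    out = np.gradient(x, dt)
    if order == 2:
        out = np.gradient(out, dt)
    return out


def segment(
    n_samples: int,
    sampling_rate: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> List[Tuple[int, int]]:
    """Start/stop index ranges of overlapping windows.

    Window length ``W = round(window_s * fs)``, hop ``S = round(W * (1 -
    overlap_frac))``; trailing samples that do not fill a window are
    dropped.  A signal shorter than one window yields an empty list.
    """
    if not 0 <= overlap_frac < 1:
        raise ConfigurationError("overlap_frac must lie in [0, 1)")
    w = int(round(window_s * sampling_rate))
    hop = int(round(w * (1.0 - overlap_frac)))
    hop = max(hop, 1)
    if n_samples < w:
        logger.warning(
            "signal of %d samples shorter than one %d-sample window; no windows",
            n_samples,
            w,
        )
        return []
    n_windows = (n_samples - w) // hop + 1
    return [(i * hop, i * hop + w) for i in range(n_windows)]


def abp_to_beats(
    abp: Sequence[float],
    sampling_rate: float,
    min_peak_distance_s: float = 0.3,
    min_prominence: float = 10.0,
) -> List[BeatBP]:
    """Beat-wise SBP/DBP from an arterial-pressure waveform.

    Cardiac cycles are delimited by systolic peaks (minimum inter-peak
    distance 0.3 s, prominence >= 10 mmHg); per cycle SBP is the maximum and
    DBP the minimum pressure between successive peaks.
    """
    x = np.asarray(abp, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("ABP contains non-finite values")
    if sampling_rate < 25:
        raise InputError("ABP sampling rate must be >= 25 Hz")
    peaks, _ = signal.find_peaks(
        x,
        distance=max(1, int(round(min_peak_distance_s * sampling_rate))),
        prominence=min_prominence,
    )
    if len(peaks) < 2:
        raise InputError("no complete cardiac cycle: fewer than 2 systolic peaks")
    beats = []
    for i, (p0, p1) in enumerate(zip(peaks[:-1], peaks[1:])):
        cycle = x[p0 : p1 + 1]
        i_max = int(np.argmax(cycle))
        i_min = int(np.argmin(cycle))
        beats.append(
            BeatBP(
                beat_index=i,
                sbp=float(cycle[i_max]),
                dbp=float(cycle[i_min]),
                peak_time=(p0 + i_max) / sampling_rate,
                trough_time=(p0 + i_min) / sampling_rate,
            )
        )
    return beats


def make_windows(
    record: SignalRecord,
    filter_spec: Optional[FilterSpec] = None,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
    beats: Optional[List[BeatBP]] = None,
) -> List[SegmentWindow]:
    """Filter -> derivatives -> segment, carrying window-level BP labels.

    Labels are the record-level references, or — when ``beats`` from an
    ABP-style waveform are supplied — the mean of beat values whose systolic
    peak falls inside the window (windows with no complete beat are dropped
    and logged).
    """
    filter_spec = filter_spec or FilterSpec()
    clean = bandpass_filter(record.samples, record.sampling_rate, filter_spec)
    vppg = derivative(clean, record.sampling_rate, order=1)
    appg = derivative(clean, record.sampling_rate, order=2)

    windows: List[SegmentWindow] = []
    ranges = segment(len(clean), record.sampling_rate, window_s, overlap_frac)
    for w_idx, (start, stop) in enumerate(ranges):
        t0 = start / record.sampling_rate
        t1 = stop / record.sampling_rate
        if beats is None:
            sbp, dbp = record.sbp_ref, record.dbp_ref
        else:
            inside = [b for b in beats if t0 <= b.peak_time < t1]
            if not inside:
                logger.info(
                    "%s window %d: no complete beat inside; dropped",
                    record.record_id,
                    w_idx,
                )
                continue
            sbp = float(np.mean([b.sbp for b in inside]))
            dbp = float(np.mean([b.dbp for b in inside]))
        windows.append(
            SegmentWindow(
                window_id=f"{record.record_id}_w{w_idx:03d}",
                ppg=clean[start:stop],
                vppg=vppg[start:stop],
                appg=appg[start:stop],
                sampling_rate=record.sampling_rate,
                start_time=t0,
                sbp_label=sbp,
                dbp_label=dbp,
                record_id=record.record_id,
                subject_id=record.subject_id,
            )
        )
    return windows


__all__ = [
    "InputError",
    "BeatBP",
    "SegmentWindow",
    "butter_sos",
    "bandpass_filter",
    "derivative",
    "segment",
    "abp_to_beats",
    "make_windows",
    "DEFAULT_WINDOW_S",
    "DEFAULT_OVERLAP",
]
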