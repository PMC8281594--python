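"""Signal conditioning ahead of the classifier.

Two stages, applied to whole records in this order:

1. **Wavelet denoising** — an 8-level discrete wavelet transform with
   the Sym5 mother wavelet.  High-frequency noise is removed by soft-
   thresholding the finest detail bands at the universal threshold
   sigma * sqrt(2 ln n) (sigma estimated from the finest band's median
   absolute deviation / 0.6745); baseline wander is removed by zeroing
   the deepest approximation band.  Both switches are configurable.

2. **Fixed-length segmentation** — non-overlapping 2700-sample windows
   on the record's native sampling grid (the pipeline never resamples:
   fs anywhere in 100-500 Hz is accepted as-is).  A trailing remainder
   of at least half a window is zero-padded at the tail to full length;
   a shorter remainder is dropped.  A record shorter than one window
   yields exactly one zero-padded episode.  At any supported fs a
   2700-sample window spans 5.4-27 s, enough for the three beats / two
   R-R intervals an AF call needs.

R-peak detection (a Pan-Tompkins-style band-pass + adaptive threshold
scheme) supports quality control and R-R-interval statistics; QC is
reporting-only and never silently removes data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .records import EPISODE_LENGTH, ECGRecord, Episode

logger = logging.getLogger(__name__)

__all__ = [
    "WaveletPlan",
    "RPeakSet",
    "denoise",
    "segment",
    "detect_r_peaks",
    "episode_qc",
    "episodes_to_frame",
    "frame_to_episodes",
]


@dataclass
class WaveletPlan:
    """Configuration of the DWT denoiser.

    ``detail_threshold_levels`` counts from the finest scale: level 1 is
    the highest-frequency detail band.  ``drop_approximation`` zeroes
    the deepest approximation band (baseline wander).
    """

    wavelet_name: str = "sym5"
    levels: int = 8
    detail_threshold_levels: tuple[int, ...] = (1, 2)
    drop_approximation: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if any(l < 1 for l in self.detail_threshold_levels):
            raise ValueError("detail levels count from 1 (finest)")


@dataclass
class RPeakSet:
    """Detected R-peak sample indices and the derived R-R intervals."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive R-R intervals in seconds (length = n_peaks - 1)."""
        return np.diff(self.indices) / self.fs

    @property
    def rr_cv(self) -> float:
        """Coefficient of variation of the R-R intervals (nan if < 2 intervals)."""
        rr = self.rr_intervals
        if rr.size < 2:
            return float("nan")
        return float(np.std(rr, ddof=1) / np.mean(rr))

    def __len__(self) -> int:
        return len(self.indices)


def denoise(record: ECGRecord, plan: WaveletPlan | None = None) -> ECGRecord:
    """Wavelet-denoise a record; fs and label are unchanged.

    If the record is too short for the requested decomposition depth the
    level count is reduced (with a logged warning), never the signal.
    """
    plan = plan or WaveletPlan()
    x = np.asarray(record.samples, dtype=float)
    n = len(x)
    wavelet = pywt.Wavelet(plan.wavelet_name)
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    levels = min(plan.levels, max_level)
    if levels < plan.levels:
        logger.warning(
            "signal of %d samples supports only %d DWT levels; reduced from %d",
            n, levels, plan.levels,
        )
    if levels < 1:
        return ECGRecord(samples=x.copy(), fs=record.fs, label=record.label,
                         subject_id=record.subject_id, source=record.source)

    coeffs = pywt.wavedec(x, wavelet, level=levels)
    # coeffs[0] is the deepest approximation; coeffs[-1] the finest detail.
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest)) / 0.6745)
    threshold = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    if threshold > 0:
        for lvl in plan.detail_threshold_levels:
            if lvl <= levels:
                coeffs[-lvl] = pywt.threshold(coeffs[-lvl], threshold, mode="soft")
    if plan.drop_approximation:
        coeffs[0] = np.zeros_like(coeffs[0])
    y = pywt.waverec(coeffs, wavelet)[:n]
    return ECGRecord(samples=y, fs=record.fs, label=record.label,
                     subject_id=record.subject_id, source=record.source)


def segment(record: ECGRecord, length: int = EPISODE_LENGTH, record_id: str | None = None) -> list[Episode]:
    """Cut a record into consecutive non-overlapping fixed-length episodes.

    Windowing rule: full windows of ``length`` samples; a final partial
    window of at least ``length / 2`` samples is zero-padded at the tail,
    a shorter remainder is dropped; a record shorter than ``length``
    yields exactly one zero-padded episode.  Episode count is therefore
    ``max(1, floor(n / L) + [n mod L >= L / 2])``.
    """
    x = np.asarray(record.samples, dtype=float)
    n = len(x)
    rid = record_id if record_id is not None else (record.source or record.subject_id)
    episodes: list[Episode] = []
    n_full = n // length
    remainder = n - n_full * length
    for w in range(n_full):
        episodes.append(Episode(
            values=x[w * length:(w + 1) * length],
            label=record.label, parent_record=rid, window_index=w,
            pad_length=0, subject_id=record.subject_id,
        ))
    keep_partial = (remainder >= length / 2) or (n_full == 0)
    if keep_partial and remainder > 0:
        tail = np.zeros(length)
        tail[:remainder] = x[n_full * length:]
        episodes.append(Episode(
            values=tail, label=record.label, parent_record=rid,
            window_index=n_full, pad_length=length - remainder,
            subject_id=record.subject_id,
        ))
    return episodes


def detect_r_peaks(record: ECGRecord) -> RPeakSet:
    """Detect R-peaks: local maxima of the 5-15 Hz band-passed signal
    above an adaptive amplitude threshold, with a 0.2 s refractory
    period.  Records shorter than 1 s yield an empty set."""
    x = np.asarray(record.samples, dtype=float)
    fs = record.fs
    if len(x) < fs:  # < 1 s
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)
    nyq = fs / 2.0
    hi = min(15.0, 0.95 * nyq)
    b, a = sps.butter(3, [5.0 / nyq, hi / nyq], btype="band")
    y = sps.filtfilt(b, a, x)
    peak_amp = float(np.max(np.abs(y)))
    if peak_amp <= 0:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)
    height = max(0.40 * peak_amp, 1e-6)
    distance = max(1, int(round(0.2 * fs)))
    idx, _ = sps.find_peaks(np.abs(y), height=height, distance=distance)
    # Snap each band-passed peak to the raw-signal maximum nearby, so the
    # reported index is the actual R sample, not the filter's.
    half = max(1, int(round(0.05 * fs)))
    snapped = []
    for i in idx:
        lo, hi_i = max(0, i - half), min(len(x), i + half + 1)
        snapped.append(lo + int(np.argmax(x[lo:hi_i])))
    snapped = sorted(set(snapped))
    return RPeakSet(indices=np.array(snapped, dtype=int), fs=fs)


def episode_qc(episode: Episode, fs: float) -> bool:
    """True iff the unpadded portion contains at least three detected
    R-peaks (i.e. two R-R intervals).  Reporting only — segmentation is
    unconditional and QC never removes data."""
    unpadded = episode.unpadded
    if unpadded.size < fs:
        return False
    rec = ECGRecord(samples=unpadded, fs=fs)
    return len(detect_r_peaks(rec)) >= 3


# ---------------------------------------------------------------------------
# Episode store: one table per dataset, 2700 value columns + metadata.
# ---------------------------------------------------------------------------

def episodes_to_frame(episodes: list[Episode], fs: float):
    """Tabulate episodes: metadata columns (parent_record, window_index,
    label, subject_id, pad_length, fs_hz) followed by v0000..v2699."""
    import pandas as pd

    meta = pd.DataFrame({
        "parent_record": [e.parent_record for e in episodes],
        "window_index": [e.window_index for e in episodes],
        "label": [e.label for e in episodes],
        "subject_id": [e.subject_id for e in episodes],
        "pad_length": [e.pad_length for e in episodes],
        "fs_hz": fs,
    })
    values = pd.DataFrame(
        np.stack([e.values for e in episodes]) if episodes else np.empty((0, EPISODE_LENGTH)),
        columns=[f"v{i:04d}" for i in range(EPISODE_LENGTH)],
    )
    return pd.concat([meta, values], axis=1)


def frame_to_episodes(frame) -> tuple[list[Episode], float]:
    """Inverse of :func:`episodes_to_frame`."""
    vcols = [f"v{i:04d}" for i in range(EPISODE_LENGTH)]
    episodes = []
    for _, row in frame.iterrows():
        label = row["label"]
        if isinstance(label, float) and np.isnan(label):
            label = None
        episodes.append(Episode(
            values=row[vcols].to_numpy(dtype=float),
            label=label,
            parent_record=str(row["parent_record"]),
            window_index=int(row["window_index"]),
            pad_length=int(row["pad_length"]),
            subject_id=str(row["subject_id"]),
        ))
    fs = float(frame["fs_hz"].iloc[0]) if len(frame) else float("nan")
    return episodes, fs
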