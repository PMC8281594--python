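"""Core in-memory containers: a labeled single-lead ECG recording and a
fixed-length classifier input episode.

All amplitudes are millivolts everywhere in the package; readers apply
any format gain on ingest so no other module needs to think about units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed label vocabulary: normal sinus rhythm, atrial fibrillation,
#: and every other arrhythmia collapsed into one class.
LABEL_N = "N"
LABEL_AF = "AF"
LABEL_NON_AF = "NON_AF"
LABELS = (LABEL_N, LABEL_AF, LABEL_NON_AF)

#: Fixed model-input length in samples, independent of sampling frequency.
EPISODE_LENGTH = 2700

#: Sampling-frequency range (Hz) the pipeline is designed around.
FS_MIN = 100.0
FS_MAX = 500.0


@dataclass
class ECGRecord:
    """One single-lead ECG recording.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples in mV.
    fs : float
        Sampling frequency in Hz (> 0).
    label : str or None
        Rhythm label from :data:`LABELS`, or ``None`` if unlabeled.
    subject_id : str
        Opaque subject identity; drives inter-patient splitting.
    source : str
        Dataset tag (free text).
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    subject_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"label must be one of {LABELS} or None, got {self.label!r}"
            )

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Episode:
    """One fixed-length (2700-sample) model input with provenance.

    ``pad_length`` counts trailing zeros appended to reach the fixed
    length; zeros only ever occupy the tail.
    """

    values: np.ndarray
    label: str | None = None
    parent_record: str = ""
    window_index: int = 0
    pad_length: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (EPISODE_LENGTH,):
            raise ValueError(
                f"episode must hold exactly {EPISODE_LENGTH} samples, "
                f"got {self.values.shape}"
            )
        if not 0 <= self.pad_length < EPISODE_LENGTH:
            raise ValueError(
                f"pad_length must lie in [0, {EPISODE_LENGTH}), got {self.pad_length}"
            )

    @property
    def unpadded(self) -> np.ndarray:
        """The signal portion, excluding trailing zero padding."""
        n = EPISODE_LENGTH - self.pad_length
        return self.values[:n]
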