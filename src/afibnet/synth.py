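"""Synthetic single-lead ECG generator.

Produces labeled ECG-like records with the rhythm structure an AF
classifier must discriminate:

* **N** (normal sinus rhythm): near-constant R-R intervals and a visible
  P-wave before each QRS complex.
* **AF** (atrial fibrillation): irregularly irregular R-R intervals
  (i.i.d. log-normal with a configurable coefficient of variation),
  no P-wave, and a low-amplitude 6-8 Hz fibrillatory (f-wave) baseline.
* **NON_AF**: coarse variants of other arrhythmias (bradycardia,
  tachycardia, ectopic beats) that are neither sinus-regular at a
  normal rate nor AF-irregular.

Beat morphology is a sum of Gaussian P/QRS/T bumps placed at R-peak
times drawn from the rhythm's R-R model (an ECGSYN-style template
simplification).  R-R intervals are drawn in continuous time, so the
same seed yields the same beat times at any sampling frequency; the
discrete grids differ only by quantization.

All randomness flows from a single counter-based (Philox) stream keyed
by the config seed, so inserting new draw sites cannot silently shift
existing outputs drawn earlier in the stream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import LABELS, LABEL_AF, LABEL_N, LABEL_NON_AF, ECGRecord

__all__ = [
    "RhythmParams",
    "NoiseParams",
    "SynthConfig",
    "generate_record",
    "generate_dataset",
    "NON_AF_VARIANTS",
]

NON_AF_VARIANTS = ("bradycardia", "tachycardia", "ectopic")

# Gaussian bump template: (center offset from R in s, amplitude in mV, width in s).
# P and the f-wave are handled separately because they carry the class signal.
_QRS_T_TEMPLATE = (
    (-0.030, -0.12, 0.012),  # Q
    (0.000, 1.00, 0.013),    # R
    (0.032, -0.20, 0.012),   # S
    (0.230, 0.30, 0.060),    # T
)
_P_OFFSET = -0.180
_P_WIDTH = 0.030

_F_WAVE_FREQ = 7.0  # Hz, within the conventional 6-8 Hz fibrillatory band


@dataclass
class RhythmParams:
    """Parameters of the R-R interval model and atrial activity.

    ``rr_cv`` is the coefficient of variation (sd/mean) of the R-R
    intervals; AF requires rr_cv >= 0.15 and no P-wave, N requires
    rr_cv <= 0.05 and a visible P-wave.
    """

    rhythm_class: str
    mean_hr: float = 75.0
    rr_cv: float = 0.03
    p_wave_amplitude: float = 0.15
    f_wave_amplitude: float = 0.0
    variant: str = ""

    def __post_init__(self) -> None:
        if self.rhythm_class not in LABELS:
            raise ValueError(f"rhythm_class must be one of {LABELS}")
        if not self.mean_hr > 0:
            raise ValueError("mean_hr must be positive")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        if self.p_wave_amplitude < 0 or self.f_wave_amplitude < 0:
            raise ValueError("wave amplitudes must be non-negative")
        if self.rhythm_class == LABEL_AF:
            if self.p_wave_amplitude != 0:
                raise ValueError("AF rhythm must have p_wave_amplitude = 0")
            if self.rr_cv < 0.15:
                raise ValueError("AF rhythm requires rr_cv >= 0.15")
        if self.rhythm_class == LABEL_N:
            if self.rr_cv > 0.05:
                raise ValueError("N rhythm requires rr_cv <= 0.05")
            if not self.p_wave_amplitude > 0:
                raise ValueError("N rhythm requires a positive P-wave amplitude")

    @classmethod
    def normal_sinus(cls, mean_hr: float = 75.0, rr_cv: float = 0.03) -> "RhythmParams":
        return cls(LABEL_N, mean_hr=mean_hr, rr_cv=rr_cv)

    @classmethod
    def atrial_fibrillation(
        cls, mean_hr: float = 95.0, rr_cv: float = 0.25, f_wave_amplitude: float = 0.10
    ) -> "RhythmParams":
        return cls(
            LABEL_AF,
            mean_hr=mean_hr,
            rr_cv=rr_cv,
            p_wave_amplitude=0.0,
            f_wave_amplitude=f_wave_amplitude,
        )

    @classmethod
    def non_af(cls, variant: str = "bradycardia") -> "RhythmParams":
        if variant == "bradycardia":
            return cls(LABEL_NON_AF, mean_hr=45.0, rr_cv=0.04, variant=variant)
        if variant == "tachycardia":
            return cls(LABEL_NON_AF, mean_hr=125.0, rr_cv=0.04, variant=variant)
        if variant == "ectopic":
            return cls(LABEL_NON_AF, mean_hr=75.0, rr_cv=0.05, variant=variant)
        raise ValueError(f"unknown Non-AF variant {variant!r}; use one of {NON_AF_VARIANTS}")


@dataclass
class NoiseParams:
    """Additive artifact model: baseline wander (< 0.5 Hz sinusoid),
    50 Hz powerline interference, and white measurement noise."""

    baseline_wander_amplitude: float = 0.0
    baseline_wander_freq: float = 0.30
    powerline_amplitude: float = 0.0
    powerline_freq: float = 50.0
    white_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.baseline_wander_amplitude, self.powerline_amplitude, self.white_noise_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0 < self.baseline_wander_freq < 0.5:
            raise ValueError("baseline wander frequency must lie in (0, 0.5) Hz")

    @classmethod
    def realistic(cls) -> "NoiseParams":
        """Mild ambulatory-recording artifact mix."""
        return cls(
            baseline_wander_amplitude=0.08,
            powerline_amplitude=0.02,
            white_noise_sd=0.03,
        )


@dataclass
class SynthConfig:
    """Full generator configuration; ``seed`` determines the output exactly."""

    fs: float = 250.0
    duration: float = 10.0
    rhythm: RhythmParams = field(default_factory=RhythmParams.normal_sinus)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        min_duration = 3.0 * 60.0 / self.rhythm.mean_hr
        if self.duration < min_duration:
            raise ValueError(
                f"duration {self.duration:.2f} s holds fewer than 3 beats at "
                f"{self.rhythm.mean_hr:g} bpm; minimum is {min_duration:.2f} s"
            )


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed))


def _draw_beat_times(rng: np.random.Generator, rhythm: RhythmParams, duration: float) -> np.ndarray:
    """R-peak times in seconds, drawn in continuous time (fs-independent)."""
    mean_rr = 60.0 / rhythm.mean_hr
    times = []
    t = 0.45 * mean_rr  # first beat clear of the record start
    # Ectopic variant: mostly regular, with premature beats and a
    # compensatory pause afterwards.
    ectopic = rhythm.variant == "ectopic"
    pending_pause = 0.0
    while t < duration:
        times.append(t)
        if rhythm.rr_cv > 0:
            sigma2 = np.log1p(rhythm.rr_cv**2)
            mu = np.log(mean_rr) - sigma2 / 2.0
            rr = float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))
        else:
            rr = mean_rr
        if ectopic:
            if pending_pause > 0:
                rr += pending_pause
                pending_pause = 0.0
            elif rng.random() < 0.15:
                pause = 0.40 * rr
                rr -= pause
                pending_pause = pause
        t += rr
    return np.asarray(times)


def generate_record(config: SynthConfig) -> ECGRecord:
    """Generate one labeled synthetic ECG record.

    Returns exactly ``round(fs * duration)`` samples.  Deterministic:
    the same config (including seed) always yields the same array, and
    the same seed at two sampling frequencies yields beat times that
    agree within one sample of the coarser grid.
    """
    rng = _rng(config.seed)
    rhythm, noise = config.rhythm, config.noise
    n = int(round(config.fs * config.duration))
    t = np.arange(n) / config.fs

    beat_times = _draw_beat_times(rng, rhythm, config.duration)
    x = np.zeros(n)

    bumps = list(_QRS_T_TEMPLATE)
    if rhythm.p_wave_amplitude > 0:
        bumps.append((_P_OFFSET, rhythm.p_wave_amplitude, _P_WIDTH))
    for offset, amp, width in bumps:
        centers = beat_times + offset
        # Each Gaussian is negligible beyond 5 widths; build per-beat windows.
        half = 5.0 * width
        for c in centers:
            lo = max(0, int(np.ceil((c - half) * config.fs)))
            hi = min(n, int(np.floor((c + half) * config.fs)) + 1)
            if hi <= lo:
                continue
            seg = t[lo:hi]
            x[lo:hi] += amp * np.exp(-0.5 * ((seg - c) / width) ** 2)

    if rhythm.f_wave_amplitude > 0:
        # Fibrillatory baseline: fixed-frequency sinusoid with a slowly
        # drifting random phase, a standard coarse f-wave surrogate.
        phase0 = rng.uniform(0, 2 * np.pi)
        drift = np.cumsum(rng.normal(0.0, 0.08, size=n)) / np.sqrt(max(config.fs, 1.0))
        x += rhythm.f_wave_amplitude * np.sin(2 * np.pi * _F_WAVE_FREQ * t + phase0 + drift)

    if noise.baseline_wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += noise.baseline_wander_amplitude * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + phase
        )
    if noise.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += noise.powerline_amplitude * np.sin(2 * np.pi * noise.powerline_freq * t + phase)
    if noise.white_noise_sd > 0:
        x += rng.normal(0.0, noise.white_noise_sd, size=n)

    return ECGRecord(
        samples=x,
        fs=config.fs,
        label=rhythm.rhythm_class,
        source="synthetic",
    )


def _default_rhythm(label: str, variant: str, rng: np.random.Generator) -> RhythmParams:
    """Per-record rhythm parameters with mild heart-rate variation across
    records, so the dataset is not a single repeated waveform."""
    if label == LABEL_N:
        return RhythmParams.normal_sinus(mean_hr=float(rng.uniform(60, 90)))
    if label == LABEL_AF:
        return RhythmParams.atrial_fibrillation(mean_hr=float(rng.uniform(85, 110)))
    return RhythmParams.non_af(variant)


def generate_dataset(
    n_per_class: int,
    subjects: int,
    classes: tuple[str, ...] = (LABEL_N, LABEL_AF),
    fs: float = 250.0,
    duration: float = 10.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    out_dir=None,
    rr_cv_by_class: dict[str, float] | None = None,
):
    """Generate a labeled dataset with subjects assigned round-robin.

    Parameters
    ----------
    n_per_class : int
        Records per rhythm class (exact).
    subjects : int
        Number of distinct subject ids; records are dealt to subjects
        round-robin so that inter-patient splitting is meaningful.
    classes : tuple of str
        Which rhythm classes to generate.
    out_dir : path-like, optional
        When given, each record is written as a two-column CSV
        (time_s, amplitude_mV) under this directory and the manifest
        ``path`` column points at the files; otherwise paths are
        symbolic ids.
    rr_cv_by_class : dict, optional
        Override the per-class R-R coefficient of variation.

    Returns
    -------
    (records, manifest) : (list of ECGRecord, pandas.DataFrame)
        Manifest columns: path, fs_hz, label, subject_id, split.
    """
    if n_per_class < 1 or subjects < 1:
        raise ValueError("n_per_class and subjects must both be >= 1")
    for c in classes:
        if c not in LABELS:
            raise ValueError(f"unknown class {c!r}")
    noise = noise if noise is not None else NoiseParams()
    if out_dir is not None:
        import os

        os.makedirs(str(out_dir), exist_ok=True)
    root = _rng(seed)

    records: list[ECGRecord] = []
    rows = []
    idx = 0
    for label in classes:
        for j in range(n_per_class):
            rec_seed = int(root.integers(0, 2**31 - 1))
            variant = NON_AF_VARIANTS[j % len(NON_AF_VARIANTS)]
            rhythm = _default_rhythm(label, variant, root)
            if rr_cv_by_class and label in rr_cv_by_class:
                kwargs = {"rr_cv": rr_cv_by_class[label]}
                rhythm = replace(rhythm, **kwargs)
            cfg = SynthConfig(fs=fs, duration=duration, rhythm=rhythm, noise=noise, seed=rec_seed)
            rec = generate_record(cfg)
            subject = f"S{idx % subjects:04d}"
            rec.subject_id = subject
            # Manifest paths are relative to the manifest's own directory,
            # so a dataset is relocatable and seed-reproducible bytewise.
            path = f"{label}_{j:04d}.csv"
            if out_dir is not None:
                from . import io as ecg_io

                ecg_io.save_record_csv(rec, f"{out_dir}/{path}")
            rows.append(
                {"path": path, "fs_hz": fs, "label": label, "subject_id": subject, "split": "unassigned"}
            )
            records.append(rec)
            idx += 1

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from . import io as ecg_io

        ecg_io.save_manifest(manifest, f"{out_dir}/manifest.csv")
    return records, manifest
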