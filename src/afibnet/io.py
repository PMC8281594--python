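"""Readers and writers for ECG records and dataset manifests.

Supported formats:

* two-column CSV ``(time_s, amplitude_mV)`` with an optional single
  header line (comma separator, '.' decimal, UTF-8);
* a minimal subset of the WFDB (PhysioNet) convention: format-16
  ``.hea``/``.dat`` record pairs and MIT-format annotation files,
  implemented here directly (signed 16-bit little-endian samples,
  per-signal gain/baseline applied on read so everything downstream
  is mV);
* manifest CSV with columns ``path, fs_hz, label, subject_id, split``.

Label taxonomy: the many named non-AF arrhythmias found in public
annotation sets (bundle-branch blocks, premature beats, flutter,
tachy-/bradycardias, ...) collapse to the single ``NON_AF`` class via
:data:`NON_AF_LABEL_MAP`; atrial flutter deliberately maps to NON_AF,
not AF.
"""

from __future__ import annotations

import logging
import os
import struct

import numpy as np
import pandas as pd

from .records import LABELS, LABEL_AF, LABEL_N, LABEL_NON_AF, ECGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_record_csv",
    "save_record_csv",
    "read_record_wfdb",
    "write_record_wfdb",
    "read_annotations",
    "write_annotations",
    "load_manifest",
    "save_manifest",
    "NON_AF_LABEL_MAP",
]

MANIFEST_COLUMNS = ("path", "fs_hz", "label", "subject_id", "split")
SPLITS = ("train", "val", "test", "unassigned")

#: Annotation-string -> class-label mapping covering the common rhythm
#: vocabulary of public ECG databases. Anything absent stays unlabeled.
NON_AF_LABEL_MAP: dict[str, str] = {
    "(N": LABEL_N, "(NSR": LABEL_N, "SR": LABEL_N, "N": LABEL_N,
    "(AFIB": LABEL_AF, "AFIB": LABEL_AF, "AF": LABEL_AF,
    # Everything else named below is Non-AF, including atrial flutter.
    "(AFL": LABEL_NON_AF, "AFL": LABEL_NON_AF,
    "I-AVB": LABEL_NON_AF, "LBBB": LABEL_NON_AF, "RBBB": LABEL_NON_AF,
    "PAC": LABEL_NON_AF, "PVC": LABEL_NON_AF, "STD": LABEL_NON_AF,
    "STE": LABEL_NON_AF, "SB": LABEL_NON_AF, "ST": LABEL_NON_AF,
    "SI": LABEL_NON_AF, "SVT": LABEL_NON_AF, "AT": LABEL_NON_AF,
    "AVNRT": LABEL_NON_AF, "AVRT": LABEL_NON_AF, "SAAWR": LABEL_NON_AF,
    "(B": LABEL_NON_AF, "(T": LABEL_NON_AF, "(SVTA": LABEL_NON_AF,
}


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------

def read_record_csv(
    path,
    fs: float | None = None,
    label: str | None = None,
    subject_id: str = "",
    source: str = "",
) -> ECGRecord:
    """Read a two-column (time_s, amplitude_mV) CSV record.

    The sampling frequency is the reciprocal of the time column's
    median step; an explicit ``fs`` argument overrides it (with a
    logged warning if the two disagree by more than 1%).
    """
    path = str(path)
    try:
        raw = pd.read_csv(path, header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty record file: {path}") from None
    # Optional single header line: drop it if the first row is non-numeric.
    first = pd.to_numeric(raw.iloc[0], errors="coerce")
    if first.isna().any():
        raw = raw.iloc[1:]
    if raw.shape[0] < 2:
        raise ValueError(f"record file {path} has fewer than 2 data rows")
    if raw.shape[1] < 2:
        raise ValueError(f"record file {path} must have two columns (time_s, amplitude_mV)")
    data = raw.iloc[:, :2].astype(float).to_numpy()
    time, amp = data[:, 0], data[:, 1]
    steps = np.diff(time)
    if np.any(steps <= 0):
        raise ValueError(f"time column in {path} is not strictly increasing")
    inferred = 1.0 / float(np.median(steps))
    if fs is None:
        fs_out = inferred
    else:
        fs_out = float(fs)
        if abs(inferred - fs_out) / fs_out > 0.01:
            logger.warning(
                "explicit fs=%g Hz overrides inconsistent time column (inferred %g Hz) in %s",
                fs_out, inferred, path,
            )
    return ECGRecord(samples=amp, fs=fs_out, label=label, subject_id=subject_id, source=source or path)


def save_record_csv(record: ECGRecord, path) -> None:
    """Write a record as (time_s, amplitude_mV) CSV with a header line."""
    t = np.arange(len(record.samples)) / record.fs
    df = pd.DataFrame({"time_s": t, "amplitude_mV": record.samples})
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Minimal WFDB (format 16)
# ---------------------------------------------------------------------------

def write_record_wfdb(
    record: ECGRecord,
    record_name,
    gain: float = 200.0,
    channel_names: tuple[str, ...] | None = None,
    extra_channels: list[np.ndarray] | None = None,
) -> None:
    """Write a record as a WFDB format-16 .hea/.dat pair.

    Samples are quantized to signed 16-bit integers at ``gain`` ADC
    units per mV (default 200, i.e. 5 uV resolution).
    """
    record_name = str(record_name)
    base = os.path.basename(record_name)
    signals = [np.asarray(record.samples, dtype=float)]
    if extra_channels:
        signals.extend(np.asarray(s, dtype=float) for s in extra_channels)
    nsig = len(signals)
    n = len(signals[0])
    if any(len(s) != n for s in signals):
        raise ValueError("all channels must have the same length")
    names = channel_names or tuple(f"ch{i}" for i in range(nsig))
    adc = np.stack([np.clip(np.round(s * gain), -32768, 32767) for s in signals], axis=1)
    adc = adc.astype("<i2")
    with open(record_name + ".dat", "wb") as fh:
        fh.write(adc.tobytes())  # sample-interleaved frames
    lines = [f"{base} {nsig} {record.fs:g} {n}"]
    for i in range(nsig):
        checksum = int(np.sum(adc[:, i], dtype=np.int64) & 0xFFFF)
        if checksum >= 0x8000:
            checksum -= 0x10000
        lines.append(f"{base}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0, i])} {checksum} 0 {names[i]}")
    with open(record_name + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_gain(token: str) -> tuple[float, float]:
    """Parse a WFDB gain token like ``200``, ``200/mV`` or ``200(0)/mV``
    into (gain, baseline)."""
    baseline = 0.0
    if "/" in token:
        token = token.split("/", 1)[0]
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(token) if token else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline


def read_record_wfdb(
    record_name,
    channel: int | None = None,
    annotation_ext: str | None = None,
    symbol_map: dict[str, str] | None = None,
    subject_id: str = "",
) -> ECGRecord:
    """Read a WFDB format-16 record.

    ``channel`` picks the signal channel; if omitted, a channel whose
    description names Lead II is preferred, else channel 0.  When
    ``annotation_ext`` is given, the rhythm label is taken from the
    record's annotation file through ``symbol_map`` (annotation symbol
    or aux string -> label); unmapped symbols leave the record
    unlabeled rather than raising.
    """
    record_name = str(record_name)
    hea = record_name + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"missing WFDB header: {hea}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    nsig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else -1
    sig_lines = lines[1 : 1 + nsig]
    specs = []
    for ln in sig_lines:
        toks = ln.split()
        fmt = toks[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB format {fmt!r} (only format 16 is supported)")
        gain, baseline = _parse_gain(toks[2]) if len(toks) > 2 else (200.0, 0.0)
        desc = " ".join(toks[8:]) if len(toks) > 8 else ""
        specs.append((toks[0], gain, baseline, desc))
    dat = os.path.join(os.path.dirname(record_name), specs[0][0])
    raw = np.fromfile(dat, dtype="<i2")
    frames = raw.reshape(-1, nsig)
    if nsamp > 0:
        frames = frames[:nsamp]
    if channel is None:
        channel = 0
        for i, (_, _, _, desc) in enumerate(specs):
            d = desc.upper().replace(" ", "")
            if d in ("II", "LEADII", "MLII"):
                channel = i
                break
    if not 0 <= channel < nsig:
        raise ValueError(f"channel {channel} out of range for {nsig}-signal record")
    _, gain, baseline, _ = specs[channel]
    samples = (frames[:, channel].astype(float) - baseline) / gain

    label = None
    if annotation_ext is not None:
        mapping = symbol_map or NON_AF_LABEL_MAP
        anns = read_annotations(record_name, annotation_ext)
        for _, symbol, aux in anns:
            key = aux if aux else symbol
            if key in mapping:
                label = mapping[key]
                break
        if label is None and anns:
            logger.info("no annotation symbol in %s.%s mapped to a label; record left unlabeled",
                        record_name, annotation_ext)
    return ECGRecord(samples=samples, fs=fs, label=label,
                     subject_id=subject_id or os.path.basename(record_name),
                     source=record_name)


# MIT annotation code table (the subset this package writes/reads).
_ANN_CODES = {1: "N", 5: "V", 8: "A", 28: "+", 13: "J", 9: "a"}
_ANN_SYMBOLS = {v: k for k, v in _ANN_CODES.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def write_annotations(record_name, ext: str, annotations) -> None:
    """Write MIT-format annotations: iterable of (sample, symbol, aux)."""
    out = bytearray()
    prev = 0
    for sample, symbol, aux in annotations:
        code = _ANN_SYMBOLS.get(symbol)
        if code is None:
            raise ValueError(f"unsupported annotation symbol {symbol!r}")
        delta = int(sample) - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if delta >= 1023:
            # SKIP word, then the full interval as a PDP-11 long
            # (high 16 bits first, each word little-endian).
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        if aux:
            data = aux.encode()
            out += struct.pack("<H", (_AUX << 10) | len(data))
            out += data
            if len(data) % 2:
                out += b"\x00"
        prev = int(sample)
    out += struct.pack("<H", 0)  # EOF
    with open(f"{record_name}.{ext}", "wb") as fh:
        fh.write(out)


def read_annotations(record_name, ext: str):
    """Read MIT-format annotations -> list of (sample, symbol, aux)."""
    path = f"{record_name}.{ext}"
    with open(path, "rb") as fh:
        buf = fh.read()
    anns = []
    pos = 0
    time = 0
    pending_skip = 0
    while pos + 2 <= len(buf):
        (word,) = struct.unpack_from("<H", buf, pos)
        pos += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", buf, pos)
            pos += 4
            pending_skip = (hi << 16) | lo
        elif code == _AUX:
            nbytes = delta
            aux = buf[pos : pos + nbytes].decode(errors="replace")
            pos += nbytes + (nbytes % 2)
            if anns:
                anns[-1] = (anns[-1][0], anns[-1][1], aux)
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            time += delta + pending_skip
            pending_skip = 0
            anns.append((time, _ANN_CODES.get(code, "?"), ""))
    return anns


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def save_manifest(manifest: pd.DataFrame, path) -> None:
    """Write a manifest CSV; extra columns beyond the mandatory five are
    preserved."""
    _validate_manifest(manifest)
    manifest.to_csv(path, index=False)


def load_manifest(path) -> pd.DataFrame:
    """Load and validate a manifest CSV.

    A missing ``split`` column is filled with ``unassigned``; a missing
    mandatory column or a duplicate path is rejected.
    """
    df = pd.read_csv(path)
    if "split" not in df.columns:
        df["split"] = "unassigned"
    _validate_manifest(df)
    return df


def _validate_manifest(df: pd.DataFrame) -> None:
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest is missing mandatory column {col!r}")
    if df["path"].duplicated().any():
        dup = df.loc[df["path"].duplicated(), "path"].iloc[0]
        raise ValueError(f"manifest contains duplicate path {dup!r}")
    bad = set(df["split"].unique()) - set(SPLITS)
    if bad:
        raise ValueError(f"manifest split column contains unknown values {sorted(bad)}")
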