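"""Record I/O, segmentation, and global analysis configuration.

The universal in-memory container is :class:`EcgRecord`: a single-lead sampled
waveform with its sampling rate.  Records can be read from plain one-column
CSV/TSV files or from WFDB records in the PhysioNet dialect (``.hea`` header
plus ``.dat`` signal file, formats 16 and 212).  A matching writer exists so
that fixtures and simulated records round-trip through the same code paths.

All tunable thresholds of the assessment pipeline live in
:class:`AnalysisConfig`; every module takes (or defaults to) one of these so a
whole analysis is reproducible from a single object.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EcgRecord",
    "AnalysisConfig",
    "UndefinedIndexError",
    "InputTooShortError",
    "read_csv",
    "write_csv",
    "read_wfdb",
    "write_wfdb",
    "segment",
]


class UndefinedIndexError(ValueError):
    """A signal-quality index is undefined for the given input.

    Raised e.g. when both R-peak detectors return nothing (qSQI has a zero
    denominator), when a spectrum carries no power, or when a constant signal
    makes the standardized moments meaningless.  Callers that grade segments
    treat the affected index as "unqualified" instead of aborting.
    """


class InputTooShortError(ValueError):
    """The record is too short for the requested operation."""


@dataclass(frozen=True)
class EcgRecord:
    """A sampled single-lead ECG trace.

    Parameters
    ----------
    samples:
        Amplitude samples.  Stored as a float64 array; the scale is
        irrelevant to the quality indices (they are all ratios or
        standardized moments) so no unit normalization is applied.
    fs:
        Sampling rate in Hz, strictly positive.
    lead_name:
        Display label of the lead (e.g. ``"II"``).
    source_id:
        Provenance string (file stem, synthesis tag, window index...).
    units:
        Amplitude unit label, carried for display only.
    """

    samples: np.ndarray
    fs: float
    lead_name: str = "ECG"
    source_id: str = ""
    units: str = "mV"

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not (self.fs > 0) or not math.isfinite(self.fs):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self)) / self.fs


# pSQI grading limits (hr_low, hr_high, l1, l2, l3) per heart-rate band.
DEFAULT_PSQI_LIMITS = (
    (60.0, 130.0, 0.5, 0.8, 0.4),
    (130.0, 160.0, 0.4, 0.7, 0.3),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the quality-assessment pipeline, with defaults.

    The defaults are the published operating point: 9000-sample analysis
    windows, 150 ms beat-matching tolerance, the per-index grading
    breakpoints, fuzzy weights W = (0.4, 0.4, 0.1, 0.1) over
    (qSQI, pSQI, kSQI, basSQI) and decision thresholds v = 1.50 / 2.40.
    """

    segment_length_samples: int = 9000
    match_tolerance_s: float = 0.15
    psqi_limits_by_hr: tuple = DEFAULT_PSQI_LIMITS
    qsqi_grade_bounds: tuple[float, float] = (60.0, 90.0)
    csqi_thresholds: tuple[float, float] = (0.45, 0.64)
    ksqi_threshold: float = 5.0
    bassqi_grade_bounds: tuple[float, float] = (0.90, 0.95)
    weights: tuple[float, float, float, float] = (0.4, 0.4, 0.1, 0.1)
    decision_thresholds: tuple[float, float] = (1.50, 2.40)
    membership_mode: str = "continuity_corrected"  # or "literal"
    acceptable_levels: frozenset = frozenset({"E", "B"})
    interpolate_nans: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for band in self.psqi_limits_by_hr:
            _, _, l1, l2, l3 = band
            if not (l3 < l1 < l2):
                raise ValueError(f"pSQI limits must satisfy l3 < l1 < l2, got {band}")
        v1, v2 = self.decision_thresholds
        if not (v1 < v2):
            raise ValueError("decision thresholds must satisfy v_th1 < v_th2")
        if self.membership_mode not in ("continuity_corrected", "literal"):
            raise ValueError(f"unknown membership_mode {self.membership_mode!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be four non-negative values summing to 1")

    def with_(self, **kw) -> "AnalysisConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


def _postprocess(samples: np.ndarray, interpolate_nans: bool, where: str) -> np.ndarray:
    samples = np.asarray(samples, dtype=np.float64)
    bad = ~np.isfinite(samples)
    if bad.any():
        if not interpolate_nans:
            raise ValueError(f"{where}: record contains {int(bad.sum())} non-finite samples")
        if bad.all():
            raise ValueError(f"{where}: record is entirely non-finite")
        idx = np.arange(samples.size)
        samples = samples.copy()
        samples[bad] = np.interp(idx[bad], idx[~bad], samples[~bad])
    return samples


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv(path: str | os.PathLike, fs: float, *, lead_name: str = "ECG",
             interpolate_nans: bool = False) -> EcgRecord:
    """Read a one-column CSV/TSV of amplitude samples.

    An optional single header line is skipped.  Non-numeric rows after the
    header raise a parse error that names the offending line number.
    """
    if not fs > 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip().strip(",")
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(f"{path}: non-numeric value {text!r} on line {lineno}")
    if not values:
        raise ValueError(f"{path}: no numeric samples found")
    samples = _postprocess(np.array(values), interpolate_nans, str(path))
    return EcgRecord(samples, fs=float(fs), lead_name=lead_name, source_id=path.stem)


def write_csv(record: EcgRecord, path: str | os.PathLike, *, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("ecg\n")
        for v in record.samples:
            fh.write(f"{v:.9g}\n")


# ---------------------------------------------------------------------------
# WFDB (PhysioNet dialect, formats 16 and 212)
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise IOError(f"{hea_path}: empty header")
    rec_tokens = lines[0].split()
    name = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = 250.0
    n_samp = 0
    if len(rec_tokens) >= 3:
        fs = float(rec_tokens[2].split("/")[0])
    if len(rec_tokens) >= 4:
        n_samp = int(rec_tokens[3])
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname = tok[0]
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) >= 3:
            gspec = tok[2]
            if "/" in gspec:
                gspec, units = gspec.split("/", 1)
            if "(" in gspec:
                gspec, base = gspec[:-1].split("(")
                baseline = int(base)
            gain = float(gspec) if float(gspec) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) >= 5 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) >= 9 else f"ch{len(signals)}"
        signals.append(dict(file=fname, fmt=fmt, gain=gain, baseline=baseline,
                            units=units, description=desc))
    if len(signals) != n_sig:
        raise IOError(f"{hea_path}: header declares {n_sig} signals, found {len(signals)}")
    return name, fs, n_samp, signals


def _read_dat(path: Path, fmt: str, n_sig: int) -> np.ndarray:
    """Read an interleaved multiplexed signal file; returns (n_samples, n_sig)."""
    raw = path.read_bytes()
    if fmt == "16":
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (len(b) // 3)]
        b = b.reshape(-1, 3).astype(np.int32)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 0x7FF, first - 0x1000, first)
        second = np.where(second > 0x7FF, second - 0x1000, second)
        flat = np.empty(2 * len(b), dtype=np.int32)
        flat[0::2] = first
        flat[1::2] = second
    else:
        raise IOError(f"{path}: unsupported WFDB format {fmt!r}")
    flat = flat[: n_sig * (len(flat) // n_sig)]
    return flat.reshape(-1, n_sig)


def read_wfdb(path: str | os.PathLike, lead: str | int | None = None, *,
              interpolate_nans: bool = False) -> EcgRecord:
    """Read one channel of a WFDB record (``.hea`` + ``.dat``).

    ``path`` may be the record stem or the header path.  ``lead`` selects the
    channel by index or by its description string; ``None`` selects channel 0.
    ADC values are converted to physical units using the header gain/baseline.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"WFDB header not found: {hea}")
    name, fs, n_samp, signals = _parse_header(hea)

    if lead is None:
        chan = 0
    elif isinstance(lead, int):
        chan = lead
    else:
        descs = [s["description"] for s in signals]
        if lead not in descs:
            raise LookupError(f"lead {lead!r} not in record {name} (has {descs})")
        chan = descs.index(lead)
    if not 0 <= chan < len(signals):
        raise LookupError(f"channel {chan} out of range for record {name}")

    fmts = {s["fmt"] for s in signals}
    files = {s["file"] for s in signals}
    if len(fmts) != 1 or len(files) != 1:
        raise IOError(f"{hea}: mixed formats/files are not supported")
    dat = hea.parent / signals[0]["file"]
    if not dat.exists():
        raise IOError(f"WFDB signal file not found: {dat}")
    data = _read_dat(dat, signals[0]["fmt"], len(signals))
    if n_samp and data.shape[0] < n_samp:
        raise IOError(f"{dat}: expected {n_samp} samples, found {data.shape[0]}")
    if n_samp:
        data = data[:n_samp]
    sig = signals[chan]
    phys = (data[:, chan].astype(np.float64) - sig["baseline"]) / sig["gain"]
    phys = _postprocess(phys, interpolate_nans, str(dat))
    return EcgRecord(phys, fs=fs, lead_name=sig["description"],
                     source_id=name, units=sig["units"])


def write_wfdb(record: EcgRecord, directory: str | os.PathLike,
               name: str | None = None, *, fmt: str = "16",
               gain: float = 1000.0) -> Path:
    """Write a single-channel WFDB record; returns the header path.

    Amplitudes are quantized as ``round(x * gain)``, so the round-trip is
    exact to 1/gain of the amplitude unit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or (record.source_id or "record")
    adc = np.round(record.samples * gain).astype(np.int32)
    if fmt == "16":
        if np.any(np.abs(adc) > 32767):
            raise ValueError("amplitude exceeds int16 range at this gain")
        (directory / f"{name}.dat").write_bytes(adc.astype("<i2").tobytes())
    elif fmt == "212":
        if np.any(adc > 2047) or np.any(adc < -2048):
            raise ValueError("amplitude exceeds 12-bit range at this gain")
        vals = adc.astype(np.int32)
        if vals.size % 2:
            vals = np.append(vals, 0)
        u = np.where(vals < 0, vals + 0x1000, vals).astype(np.uint32)
        first, second = u[0::2], u[1::2]
        packed = np.empty((first.size, 3), dtype=np.uint8)
        packed[:, 0] = first & 0xFF
        packed[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
        packed[:, 2] = second & 0xFF
        (directory / f"{name}.dat").write_bytes(packed.tobytes())
    else:
        raise ValueError(f"unsupported write format {fmt!r}")
    fs_txt = f"{record.fs:g}"
    header = (f"{name} 1 {fs_txt} {len(record)}\n"
              f"{name}.dat {fmt} {gain:g}(0)/{record.units} 16 0 "
              f"{int(adc[0])} 0 0 {record.lead_name}\n")
    hea = directory / f"{name}.hea"
    hea.write_text(header)
    return hea


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(record: EcgRecord, length: int) -> list[EcgRecord]:
    """Split a record into consecutive non-overlapping windows of ``length``.

    A trailing remainder shorter than ``length`` is dropped.  A record shorter
    than one window yields an empty list.
    """
    if length < 1:
        raise ValueError(f"segment length must be >= 1, got {length}")
    n = len(record) // length
    out = []
    for i in range(n):
        chunk = record.samples[i * length:(i + 1) * length]
        out.append(EcgRecord(chunk, fs=record.fs, lead_name=record.lead_name,
                             source_id=f"{record.source_id}#w{i}", units=record.units))
    return out


def results_to_json(rows: Sequence[dict], path: str | os.PathLike | None = None) -> str:
    """Serialize per-segment result dicts to JSON (one object per segment)."""
    text = json.dumps(list(rows), indent=2, default=_json_default)
    if path is not None:
        Path(path).write_text(text)
    return text


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
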