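"""Synthetic single-lead ECG generator with ground-truth beats and labels.

Clean records are quasi-periodic trains of Gaussian bumps, one P-QRS-T
complex per beat, at a configurable heart rate with optional RR jitter; the
exact R-peak sample positions are recorded at construction time.  Four
additive noise classes emulate the disturbances a real single-lead recording
suffers:

* baseline wander — a sum of slow sinusoids (0.05-0.5 Hz, random phases);
* powerline interference — a 50/60 Hz tone;
* EMG-like noise — white noise band-passed to 20-40 Hz, inside the
  analysis ceiling of 40 Hz so it perturbs the spectral indices the way
  muscle noise does;
* Gaussian white noise.

Noise amplitudes are fractions of the R amplitude (peak amplitude for the
deterministic tones, RMS for the stochastic classes).  Each record carries a
construction-time intended quality label E/B/U, downgraded per noise class
when its amplitude crosses the per-class bands in ``QUALITY_BANDS``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import EcgRecord

__all__ = ["SynthesisSpec", "LabeledRecord", "generate_clean", "add_noise",
           "generate_dataset", "QUALITY_BANDS"]

NOISE_CLASSES = ("baseline_wander", "powerline", "emg", "gaussian")

# (amp, time offset s, width s) of each Gaussian bump, relative to the beat
# time; amplitudes relative to an R amplitude of 1.
BEAT_MORPHOLOGY = {
    "P": (0.12, -0.22, 0.025),
    "Q": (-0.08, -0.035, 0.010),
    "R": (1.00, 0.000, 0.012),
    "S": (-0.12, 0.030, 0.010),
    "T": (0.28, 0.300, 0.055),
}

# Per-noise-class (barely, unacceptable) amplitude bands for the intended
# label: amp <= lo -> E, lo < amp <= hi -> B, amp > hi -> U.  The bands are
# set from a power argument: the ECG bump train has a low duty cycle (total
# power about 0.03 of the squared R amplitude), so a drift sinusoid of 5 %
# of the R amplitude already carries ~5 % of the record power and noise at a
# quarter of the R amplitude dominates it outright.
QUALITY_BANDS = {
    "baseline_wander": (0.05, 0.20),
    "powerline": (0.10, 0.30),
    "emg": (0.05, 0.25),
    "gaussian": (0.05, 0.25),
}


@dataclass(frozen=True)
class SynthesisSpec:
    """Parameters of one synthetic record."""

    fs: float = 300.0
    duration_s: float = 30.0
    heart_rate_bpm: float = 60.0
    hr_jitter_frac: float = 0.0  # coefficient of variation of RR
    noise_amplitudes: dict = field(default_factory=dict)
    powerline_hz: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.fs < 100:
            raise ValueError(f"fs must be >= 100 Hz, got {self.fs}")
        if self.duration_s < 5:
            raise ValueError(f"duration must be >= 5 s, got {self.duration_s}")
        if not 30 <= self.heart_rate_bpm <= 220:
            raise ValueError(f"heart rate must be in [30, 220] bpm, got {self.heart_rate_bpm}")
        if self.hr_jitter_frac < 0:
            raise ValueError("hr_jitter_frac must be >= 0")
        for name, amp in self.noise_amplitudes.items():
            if name not in NOISE_CLASSES:
                raise ValueError(f"unknown noise class {name!r}")
            if amp < 0:
                raise ValueError(f"noise amplitude must be >= 0, got {name}={amp}")

    def intended_label(self) -> str:
        """Construction-time quality label from the noise amplitude bands."""
        worst = "E"
        rank = {"E": 0, "B": 1, "U": 2}
        for name, amp in self.noise_amplitudes.items():
            lo, hi = QUALITY_BANDS[name]
            lbl = "E" if amp <= lo else ("B" if amp <= hi else "U")
            if rank[lbl] > rank[worst]:
                worst = lbl
        return worst


@dataclass(frozen=True)
class LabeledRecord:
    record: EcgRecord
    true_rpeaks: np.ndarray
    intended_label: str
    spec: SynthesisSpec

    def __post_init__(self):
        idx = np.asarray(self.true_rpeaks, dtype=np.int64)
        object.__setattr__(self, "true_rpeaks", idx)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0
                         or idx[-1] >= len(self.record)):
            raise ValueError("true_rpeaks must be strictly increasing and in range")


def generate_clean(spec: SynthesisSpec) -> LabeledRecord:
    """Noise-free quasi-periodic ECG with exact ground-truth R positions."""
    rng = np.random.default_rng(spec.seed)
    fs, dur = spec.fs, spec.duration_s
    mean_rr = 60.0 / spec.heart_rate_bpm

    beat_times = []
    t = 0.5  # lead-in before the first beat
    while t <= dur - 0.3:
        beat_times.append(t)
        jitter = spec.hr_jitter_frac * rng.standard_normal()
        t += mean_rr * (1.0 + float(np.clip(jitter, -0.3, 0.3)))
    beat_times = np.asarray(beat_times)

    n = int(round(dur * fs))
    tgrid = np.arange(n) / fs
    x = np.zeros(n)
    for amp, off, width in BEAT_MORPHOLOGY.values():
        for bt in beat_times:
            mu = bt + off
            lo = max(0, int((mu - 5 * width) * fs))
            hi = min(n, int((mu + 5 * width) * fs) + 1)
            x[lo:hi] += amp * np.exp(-0.5 * ((tgrid[lo:hi] - mu) / width) ** 2)

    rpeaks = np.round(beat_times * fs).astype(np.int64)
    rpeaks = rpeaks[rpeaks < n]
    rec = EcgRecord(x, fs=fs, lead_name="synthetic",
                    source_id=f"synth-{spec.seed}")
    return LabeledRecord(rec, rpeaks, "E", spec)


def add_noise(labeled: LabeledRecord, spec: SynthesisSpec | None = None) -> LabeledRecord:
    """Add the four noise classes of ``spec`` on top of an existing record.

    Amplitudes are relative to the R amplitude (1 in clean records): peak
    amplitude for baseline-wander sinusoids and the powerline tone, RMS for
    the EMG and Gaussian classes.  The intended label is downgraded (never
    upgraded) according to ``QUALITY_BANDS``.
    """
    spec = spec or labeled.spec
    rng = np.random.default_rng(spec.seed + 1)  # independent of morphology jitter
    rec = labeled.record
    fs, n = rec.fs, len(rec)
    t = np.arange(n) / fs
    x = rec.samples.copy()
    amps = {k: float(spec.noise_amplitudes.get(k, 0.0)) for k in NOISE_CLASSES}

    a = amps["baseline_wander"]
    if a > 0:
        k = 5
        freqs = rng.uniform(0.05, 0.5, size=k)
        phases = rng.uniform(0, 2 * np.pi, size=k)
        drift = np.sum([np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)],
                       axis=0)
        x += a * drift / np.sqrt(k)  # RMS equals that of one sinusoid of amplitude a

    a = amps["powerline"]
    if a > 0:
        x += a * np.sin(2 * np.pi * spec.powerline_hz * t + rng.uniform(0, 2 * np.pi))

    a = amps["emg"]
    if a > 0:
        hi = min(40.0, 0.45 * fs)
        sos = butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
        w = sosfiltfilt(sos, rng.standard_normal(n))
        x += a * w / np.std(w)

    a = amps["gaussian"]
    if a > 0:
        x += a * rng.standard_normal(n)

    rank = {"E": 0, "B": 1, "U": 2}
    label = max((labeled.intended_label, spec.intended_label()), key=rank.get)
    rec2 = EcgRecord(x, fs=fs, lead_name=rec.lead_name,
                     source_id=rec.source_id, units=rec.units)
    return LabeledRecord(rec2, labeled.true_rpeaks, label, spec)


def generate(spec: SynthesisSpec) -> LabeledRecord:
    """Clean morphology plus the noise mix requested by ``spec``."""
    return add_noise(generate_clean(dataclasses.replace(spec)), spec)


# Per-class noise recipes for dataset generation.  The U-class recipe is a
# heavy composite artifact (muscle noise plus drift plus broadband noise),
# the kind of disturbance that corrupts both the waveform and the spectrum.
def _class_spec(label: str, rng: np.random.Generator, fs: float,
                duration_s: float) -> SynthesisSpec:
    hr = float(rng.uniform(60.0, 100.0))
    cv = float(rng.uniform(0.02, 0.06))
    seed = int(rng.integers(2 ** 31))
    if label == "E":
        noise = {"gaussian": float(rng.uniform(0.0, 0.02)),
                 "baseline_wander": float(rng.uniform(0.0, 0.03))}
    elif label == "B":
        kind = rng.choice(["baseline_wander", "gaussian", "emg"])
        noise = {str(kind): float(rng.uniform(0.07, 0.15))}
    elif label == "U":
        noise = {"emg": float(rng.uniform(1.0, 2.0)),
                 "baseline_wander": float(rng.uniform(0.3, 0.8)),
                 "gaussian": float(rng.uniform(0.15, 0.3))}
    else:
        raise ValueError(f"unknown class {label!r}")
    return SynthesisSpec(fs=fs, duration_s=duration_s, heart_rate_bpm=hr,
                         hr_jitter_frac=cv, noise_amplitudes=noise, seed=seed)


def generate_dataset(n_per_class: int, seed: int, *,
                     classes: tuple[str, ...] = ("E", "U"),
                     fs: float = 300.0, duration_s: float = 30.0
                     ) -> list[LabeledRecord]:
    """Balanced labeled dataset with randomized per-record specs.

    Deterministic for a fixed seed.  By default two classes (clean Excellent
    records and heavily corrupted Unacceptable ones) mirroring a balanced
    acceptable/unacceptable study set; pass ``classes=("E", "B", "U")`` for
    three.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[LabeledRecord] = []
    for label in classes:
        for _ in range(n_per_class):
            spec = _class_spec(label, rng, fs, duration_s)
            rec = generate(spec)
            # construction recipe decides the class; assert consistency
            out.append(LabeledRecord(rec.record, rec.true_rpeaks, label, spec))
    return out
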