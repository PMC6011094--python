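"""The six signal-quality indices and their three-level grading.

Indices
-------
qSQI    agreement of two R-peak detectors, 100 * 2N/(Na+Nb), in percent;
pSQI    fraction of 5-40 Hz spectral power in the QRS band 5-15 Hz;
cSQI    coefficient of variation (SD/mean) of the RR intervals;
sSQI    third standardized moment (skewness) of the amplitude distribution;
kSQI    fourth standardized moment (kurtosis, Gaussian = 3, non-excess);
basSQI  one minus the fraction of 0-40 Hz power below 1 Hz.

Each index has a grading function mapping it to one of
``optimal`` / ``suspicious`` / ``unqualified`` (kSQI has no suspicious
level).  Skewness is computed and reported but never graded or fused: it is
markedly less robust to noise than kurtosis, which already separates
Gaussian-like noise (kurtosis near 3 or below) from the spiky amplitude
distribution of a clean ECG (kurtosis above 5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import welch

from .io import AnalysisConfig, EcgRecord, InputTooShortError, UndefinedIndexError
from .rpeaks import RPeakMatch, RPeakSet, detect_rpeaks_dwt, detect_rpeaks_hilbert, match_rpeaks

__all__ = [
    "SqiVector", "SqiGradeVector", "PowerSpectrum",
    "compute_qsqi", "grade_qsqi",
    "estimate_spectrum", "compute_psqi", "grade_psqi",
    "compute_csqi", "grade_csqi",
    "compute_moments", "grade_ksqi",
    "compute_bassqi", "grade_bassqi",
    "compute_all_sqis",
]

log = logging.getLogger(__name__)

OPTIMAL, SUSPICIOUS, UNQUALIFIED = "optimal", "suspicious", "unqualified"


@dataclass(frozen=True)
class SqiVector:
    """The six numeric indices for one segment (NaN marks "undefined")."""

    qsqi: float
    psqi: float
    csqi: float
    ssqi: float
    ksqi: float
    bassqi: float
    heart_rate_bpm: float

    def as_dict(self) -> dict:
        return dict(qsqi=self.qsqi, psqi=self.psqi, csqi=self.csqi,
                    ssqi=self.ssqi, ksqi=self.ksqi, bassqi=self.bassqi,
                    heart_rate_bpm=self.heart_rate_bpm)


@dataclass(frozen=True)
class SqiGradeVector:
    """Per-index grades; kSQI admits only optimal/unqualified."""

    qsqi: str
    psqi: str
    csqi: str
    ksqi: str
    bassqi: str

    def __post_init__(self):
        for name in ("qsqi", "psqi", "csqi", "bassqi"):
            if getattr(self, name) not in (OPTIMAL, SUSPICIOUS, UNQUALIFIED):
                raise ValueError(f"bad grade for {name}: {getattr(self, name)!r}")
        if self.ksqi not in (OPTIMAL, UNQUALIFIED):
            raise ValueError(f"kSQI grade must be optimal/unqualified, got {self.ksqi!r}")

    def as_dict(self) -> dict:
        return {f"grade_{k}": v for k, v in vars(self).items()}

    def subset(self, names: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(getattr(self, n) for n in names)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on a non-negative frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)
        if f.ndim != 1 or f.shape != p.shape:
            raise ValueError("freqs and power must be matching 1-D arrays")
        if np.any(np.diff(f) <= 0) or f[0] < 0:
            raise ValueError("freqs must be non-negative and increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")

    def band_power(self, lo: float, hi: float) -> float:
        """Trapezoidal integral of the density over [lo, hi] Hz."""
        f, p = self.freqs, self.power
        lo = max(lo, f[0])
        hi = min(hi, f[-1])
        if hi <= lo:
            return 0.0
        grid = f[(f > lo) & (f < hi)]
        grid = np.concatenate([[lo], grid, [hi]])
        vals = np.interp(grid, f, p)
        return float(np.trapezoid(vals, grid))


# ---------------------------------------------------------------------------
# qSQI
# ---------------------------------------------------------------------------

def compute_qsqi(match: RPeakMatch) -> float:
    """Detector agreement in percent: 100 * 2N / (Na + Nb)."""
    denom = match.n_a + match.n_b
    if denom == 0:
        raise UndefinedIndexError("qSQI undefined: neither detector found any beat")
    return float(np.clip(100.0 * 2.0 * match.n_matched / denom, 0.0, 100.0))


def grade_qsqi(q: float, bounds: tuple[float, float] = (60.0, 90.0)) -> str:
    if not 0 <= q <= 100:
        raise ValueError(f"qSQI must be in [0, 100], got {q}")
    lo, hi = bounds
    if q > hi:
        return OPTIMAL
    if q >= lo:
        return SUSPICIOUS
    return UNQUALIFIED


# ---------------------------------------------------------------------------
# Spectrum, pSQI, basSQI
# ---------------------------------------------------------------------------

def estimate_spectrum(record: EcgRecord, *, window_s: float = 8.0,
                      overlap: float = 0.5) -> PowerSpectrum:
    """Averaged-periodogram (Welch) PSD with Hann taper.

    8 s windows with 50 % overlap give a 0.125 Hz grid, fine enough to
    resolve the 0-1 Hz numerator of basSQI.  Shorter records fall back to a
    single full-length window.
    """
    n = len(record)
    if n < 1024:
        raise InputTooShortError(f"need >= 1024 samples for a spectrum, got {n}")
    nperseg = min(int(round(window_s * record.fs)), n)
    f, p = welch(record.samples, fs=record.fs, window="hann",
                 nperseg=nperseg, noverlap=int(nperseg * overlap),
                 detrend="constant")
    return PowerSpectrum(f, p)


def compute_psqi(spectrum: PowerSpectrum) -> float:
    """QRS-band power concentration: P[5,15] / P[5,40]."""
    if spectrum.freqs[-1] < 40.0:
        raise ValueError("spectrum must cover [0, 40] Hz")
    denom = spectrum.band_power(5.0, 40.0)
    if denom <= 0:
        raise UndefinedIndexError("pSQI undefined: no power in 5-40 Hz")
    return float(np.clip(spectrum.band_power(5.0, 15.0) / denom, 0.0, 1.0))


def grade_psqi(p: float, heart_rate_bpm: float,
               limits_by_hr=AnalysisConfig().psqi_limits_by_hr) -> str:
    """Grade pSQI against heart-rate dependent limits (l1, l2, l3).

    Only bands 60-130 and 130-160 bpm are defined; a rate outside them uses
    the nearest band (with a logged warning), and an undefined rate (NaN)
    uses the first band.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"pSQI must be in [0, 1], got {p}")
    if math.isnan(heart_rate_bpm):
        band = limits_by_hr[0]
    else:
        band = None
        for b in limits_by_hr:
            if b[0] <= heart_rate_bpm <= b[1]:
                band = b
                break
        if band is None:
            band = min(limits_by_hr,
                       key=lambda b: min(abs(heart_rate_bpm - b[0]),
                                         abs(heart_rate_bpm - b[1])))
            log.warning("heart rate %.0f bpm outside graded bands; using %s",
                        heart_rate_bpm, band[:2])
    _, _, l1, l2, l3 = band
    if l1 <= p <= l2:
        return OPTIMAL
    if l3 <= p < l1:
        return SUSPICIOUS
    return UNQUALIFIED


def compute_bassqi(spectrum: PowerSpectrum) -> float:
    """Baseline relative power: 1 - P[0,1] / P[0,40]."""
    if spectrum.freqs[-1] < 40.0:
        raise ValueError("spectrum must cover [0, 40] Hz")
    denom = spectrum.band_power(0.0, 40.0)
    if denom <= 0:
        raise UndefinedIndexError("basSQI undefined: zero total power")
    return float(np.clip(1.0 - spectrum.band_power(0.0, 1.0) / denom, 0.0, 1.0))


def grade_bassqi(b: float, bounds: tuple[float, float] = (0.90, 0.95)) -> str:
    if not 0 <= b <= 1:
        raise ValueError(f"basSQI must be in [0, 1], got {b}")
    lo, hi = bounds
    if b >= hi:
        return OPTIMAL
    if b >= lo:
        return SUSPICIOUS
    return UNQUALIFIED


# ---------------------------------------------------------------------------
# cSQI
# ---------------------------------------------------------------------------

def compute_csqi(rpeaks: RPeakSet) -> float:
    """Coefficient of variation of the RR intervals (sample SD / mean)."""
    if len(rpeaks) < 3:
        raise UndefinedIndexError(
            f"cSQI needs >= 3 peaks (2 RR intervals), got {len(rpeaks)}")
    rr = rpeaks.rr_intervals_s()
    return float(np.std(rr, ddof=1) / np.mean(rr))


def grade_csqi(c: float, thresholds: tuple[float, float] = (0.45, 0.64)) -> str:
    if c < 0:
        raise ValueError(f"cSQI must be >= 0, got {c}")
    lo, hi = thresholds
    if c < lo:
        return OPTIMAL
    if c <= hi:
        return SUSPICIOUS
    return UNQUALIFIED


# ---------------------------------------------------------------------------
# Moments: sSQI, kSQI
# ---------------------------------------------------------------------------

def compute_moments(record: EcgRecord) -> tuple[float, float]:
    """Third and fourth standardized moments (skewness, Pearson kurtosis)."""
    x = record.samples
    if x.size < 2 or np.std(x) == 0:
        raise UndefinedIndexError("moments undefined for a constant signal")
    ssqi = float(stats.skew(x, bias=True))
    ksqi = float(stats.kurtosis(x, fisher=False, bias=True))
    return ssqi, ksqi


def grade_ksqi(k: float, threshold: float = 5.0) -> str:
    return OPTIMAL if k > threshold else UNQUALIFIED


# ---------------------------------------------------------------------------
# Full per-segment extraction
# ---------------------------------------------------------------------------

def compute_all_sqis(record: EcgRecord,
                     config: AnalysisConfig | None = None
                     ) -> tuple[SqiVector, SqiGradeVector]:
    """Run detectors, matching, spectrum and all six index computations.

    Any index undefined on the input (flatline, zero power, too few beats)
    is reported as NaN and graded ``unqualified``; the heart rate comes from
    the Hilbert detector's RR series.
    """
    config = config or AnalysisConfig()
    nan = float("nan")

    try:
        peaks_a = detect_rpeaks_hilbert(record)
        peaks_b = detect_rpeaks_dwt(record)
    except InputTooShortError:
        raise
    match = match_rpeaks(peaks_a, peaks_b, config.match_tolerance_s)

    try:
        qsqi = compute_qsqi(match)
        g_q = grade_qsqi(qsqi, config.qsqi_grade_bounds)
    except UndefinedIndexError as e:
        log.info("segment %s: %s", record.source_id, e)
        qsqi, g_q = nan, UNQUALIFIED

    if len(peaks_a) >= 2:
        hr = 60.0 / float(np.mean(peaks_a.rr_intervals_s()))
    else:
        hr = nan

    try:
        csqi = compute_csqi(peaks_a)
        g_c = grade_csqi(csqi, config.csqi_thresholds)
    except UndefinedIndexError as e:
        log.info("segment %s: %s", record.source_id, e)
        csqi, g_c = nan, UNQUALIFIED

    try:
        spec = estimate_spectrum(record)
        psqi = compute_psqi(spec)
        g_p = grade_psqi(psqi, hr, config.psqi_limits_by_hr)
        bassqi = compute_bassqi(spec)
        g_b = grade_bassqi(bassqi, config.bassqi_grade_bounds)
    except (UndefinedIndexError, InputTooShortError) as e:
        log.info("segment %s: %s", record.source_id, e)
        psqi = bassqi = nan
        g_p = g_b = UNQUALIFIED

    try:
        ssqi, ksqi = compute_moments(record)
        g_k = grade_ksqi(ksqi, config.ksqi_threshold)
    except UndefinedIndexError as e:
        log.info("segment %s: %s", record.source_id, e)
        ssqi = ksqi = nan
        g_k = UNQUALIFIED

    return (SqiVector(qsqi, psqi, csqi, ssqi, ksqi, bassqi, hr),
            SqiGradeVector(g_q, g_p, g_c, g_k, g_b))
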