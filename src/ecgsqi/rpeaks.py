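"""Two independent R-peak detectors and cross-detector beat matching.

The agreement rate between two structurally different QRS detectors run on
the same segment is itself a quality index (qSQI): on a clean trace both find
the same beats, while noise makes them disagree.  The two pipelines here are

* ``detect_rpeaks_hilbert`` — band-pass, differentiate, Hilbert-transform
  envelope, dynamic adaptive threshold with refractory period and search-back;
* ``detect_rpeaks_dwt`` — stationary wavelet decomposition; R peaks located
  at zero-crossings between paired positive/negative modulus maxima of the
  detail coefficients at the QRS-dominant scale.

``match_rpeaks`` counts one-to-one agreements within a time tolerance,
producing the (N, Na, Nb) triple that feeds qSQI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

from .io import EcgRecord, InputTooShortError

__all__ = [
    "RPeakSet",
    "RPeakMatch",
    "detect_rpeaks_hilbert",
    "detect_rpeaks_dwt",
    "match_rpeaks",
]

REFRACTORY_S = 0.2  # minimum physiological beat separation


@dataclass(frozen=True)
class RPeakSet:
    """Detector output: strictly increasing R-peak sample positions."""

    indices: np.ndarray
    detector_id: str
    fs: float

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.times_s)


@dataclass(frozen=True)
class RPeakMatch:
    """Cross-detector match counts: N matched pairs out of Na and Nb peaks."""

    n_matched: int
    n_a: int
    n_b: int
    tolerance_s: float

    def __post_init__(self):
        if not 0 <= self.n_matched <= min(self.n_a, self.n_b):
            raise ValueError("need 0 <= N <= min(Na, Nb)")


def _check_length(record: EcgRecord, min_s: float = 2.0) -> None:
    if record.duration_s < min_s:
        raise InputTooShortError(
            f"record is {record.duration_s:.2f} s; need >= {min_s} s")


def _bandpass(x: np.ndarray, fs: float, lo: float = 5.0, hi: float = 20.0,
              order: int = 3) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _refine(x: np.ndarray, idx: int, half: int) -> int:
    """Snap a candidate to the local absolute extremum of x within +-half."""
    lo = max(0, idx - half)
    hi = min(len(x), idx + half + 1)
    seg = np.abs(x[lo:hi] - np.median(x[lo:hi]))
    return lo + int(np.argmax(seg))


def detect_rpeaks_hilbert(
    record: EcgRecord,
    *,
    band: tuple[float, float] = (5.0, 20.0),
    refractory_s: float = REFRACTORY_S,
    init_frac: float = 0.6,
    thr_frac: float = 0.3,
    searchback_frac: float = 0.4,
    searchback_rr: float = 1.66,
) -> RPeakSet:
    """Hilbert-envelope QRS detector with a dynamic adaptive threshold.

    Pipeline: zero-phase band-pass (default 5-20 Hz), first difference,
    analytic-signal envelope, light smoothing, then candidate peaks are
    accepted against a threshold initialized at ``init_frac`` times the 98th
    percentile of the first 2 s of envelope and updated after each beat to
    ``thr_frac`` times the running mean of the last 8 accepted peak
    amplitudes.  If no beat is accepted for ``searchback_rr`` times the median
    RR, the largest rejected candidate in the gap is accepted at the reduced
    threshold ``searchback_frac * threshold`` (search-back).
    """
    _check_length(record)
    fs = record.fs
    bp = _bandpass(record.samples, fs, *band)
    env = np.abs(hilbert(np.diff(bp, prepend=bp[0])))
    win = max(1, int(round(0.08 * fs)))
    env = np.convolve(env, np.ones(win) / win, mode="same")

    refr = max(1, int(round(refractory_s * fs)))
    cand, props = find_peaks(env, distance=refr)
    if cand.size == 0:
        return RPeakSet(np.empty(0, dtype=np.int64), "hilbert_adaptive", fs)
    amps = env[cand]

    head = env[: int(2 * fs)]
    thr = init_frac * np.percentile(head, 98)
    if thr <= 0:
        return RPeakSet(np.empty(0, dtype=np.int64), "hilbert_adaptive", fs)

    accepted: list[int] = []
    recent: list[float] = []
    rejected: list[int] = []  # candidate positions rejected since last beat

    def _accept(pos_i: int) -> None:
        accepted.append(int(cand[pos_i]))
        recent.append(float(amps[pos_i]))
        if len(recent) > 8:
            recent.pop(0)

    for i in range(cand.size):
        if amps[i] >= thr:
            # search-back first: did we skip beats in a long gap?
            if len(accepted) >= 3 and rejected:
                rrs = np.diff(accepted) / fs
                med_rr = float(np.median(rrs))
                gap = (cand[i] - accepted[-1]) / fs
                if gap > searchback_rr * med_rr:
                    best = max(rejected, key=lambda j: amps[j])
                    if amps[best] >= searchback_frac * thr and \
                            cand[best] - accepted[-1] >= refr:
                        _accept(best)
            rejected.clear()
            _accept(i)
            thr = thr_frac * float(np.mean(recent))
        else:
            rejected.append(i)

    half = max(1, int(round(0.04 * fs)))
    refined = sorted({_refine(bp, p, half) for p in accepted})
    # enforce refractory after refinement
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refr:
            if np.abs(bp[p]) > np.abs(bp[out[-1]]):
                out[-1] = p
        else:
            out.append(p)
    return RPeakSet(np.asarray(out, dtype=np.int64), "hilbert_adaptive", fs)


def _qrs_level(fs: float, max_level: int = 4) -> int:
    """Decomposition level whose detail band best covers 10 Hz.

    Level l of a dyadic decomposition spans [fs/2^(l+1), fs/2^l]; the level
    with band center nearest 10 Hz (capped at ``max_level``) carries most of
    the QRS energy.
    """
    best, best_d = 1, np.inf
    for lvl in range(1, max_level + 1):
        center = 0.75 * fs / 2 ** lvl  # midpoint of [fs/2^(l+1), fs/2^l]
        d = abs(center - 10.0)
        if d < best_d:
            best, best_d = lvl, d
    return best


def detect_rpeaks_dwt(
    record: EcgRecord,
    *,
    wavelet: str = "haar",
    max_level: int = 4,
    mod_frac: float = 0.3,
    noise_gate: float = 4.5,
    refractory_s: float = REFRACTORY_S,
    pair_window_s: tuple[float, float] = (0.015, 0.12),
) -> RPeakSet:
    """Wavelet modulus-maxima QRS detector.

    The signal is decomposed with an undecimated (stationary) wavelet
    transform up to four levels; the detail scale whose passband best covers
    10 Hz behaves as a smoothed derivative of the QRS complex, so each R peak
    produces a positive/negative modulus-maximum pair with a zero-crossing at
    the peak.  Pairs must exceed ``mod_frac`` times the 95th percentile of
    the modulus and ``noise_gate`` robust standard deviations of the detail
    coefficients (a MAD-based noise floor: QRS complexes are sparse outliers
    of the detail distribution, while broadband noise is not, so this
    detector abstains rather than free-running on noise), and must straddle
    a QRS-scale support: extrema closer together than 15 ms (as produced by
    mains interference) are rejected.
    """
    _check_length(record)
    fs = record.fs
    x = record.samples - np.mean(record.samples)
    level = _qrs_level(fs, max_level)

    step = 2 ** level
    pad = (-len(x)) % step
    xp = np.pad(x, (0, pad), mode="edge")
    coeffs = pywt.swt(xp, wavelet, level=level, trim_approx=True, norm=True)
    d = np.asarray(coeffs[1])[: len(x)]  # deepest detail scale

    mod = np.abs(d)
    sigma_rob = 1.4826 * np.median(np.abs(d - np.median(d)))
    thr = max(mod_frac * np.percentile(mod, 95), noise_gate * sigma_rob)
    if thr <= 0:
        return RPeakSet(np.empty(0, dtype=np.int64), "dwt_modmax", fs)

    min_gap = max(1, int(round(pair_window_s[0] * fs)))
    max_gap = max(min_gap + 1, int(round(pair_window_s[1] * fs)))
    pos, _ = find_peaks(d, height=thr)
    neg, _ = find_peaks(-d, height=thr)
    extrema = np.sort(np.concatenate([pos, neg]))

    cands: list[tuple[int, float]] = []
    for i in range(len(extrema) - 1):
        a, b = int(extrema[i]), int(extrema[i + 1])
        if np.sign(d[a]) == np.sign(d[b]):
            continue
        gap = b - a
        if not (min_gap <= gap <= max_gap):
            continue
        # zero-crossing of the detail between the paired extrema
        seg = d[a:b + 1]
        zc = np.nonzero(np.diff(np.sign(seg)) != 0)[0]
        loc = a + (int(zc[0]) if zc.size else gap // 2)
        cands.append((loc, float(min(np.abs(d[a]), np.abs(d[b])))))

    half = max(1, int(round(0.04 * fs)))
    refr = max(1, int(round(refractory_s * fs)))
    scored = sorted({(_refine(x, loc, half), m) for loc, m in cands})
    out: list[int] = []
    best_mod: list[float] = []
    for p, m in scored:
        if out and p - out[-1] < refr:
            if m > best_mod[-1]:
                out[-1], best_mod[-1] = p, m
        else:
            out.append(p)
            best_mod.append(m)
    return RPeakSet(np.asarray(out, dtype=np.int64), "dwt_modmax", fs)


def match_rpeaks(a: RPeakSet, b: RPeakSet, tolerance_s: float = 0.15) -> RPeakMatch:
    """Greedy one-to-one beat matching within ``tolerance_s``.

    Candidate pairs within the tolerance are accepted smallest
    time-difference first, each peak used at most once.  For peak trains that
    respect the cardiac refractory period (successive peaks separated by more
    than twice the tolerance) this greedy matching attains the optimum of the
    bipartite assignment problem, and is symmetric in its arguments.
    """
    if a.fs != b.fs:
        raise ValueError(f"sampling rates differ: {a.fs} vs {b.fs}")
    if tolerance_s <= 0:
        raise ValueError("tolerance must be positive")
    ta, tb = a.times_s, b.times_s
    pairs: list[tuple[float, int, int]] = []
    j0 = 0
    for i, t in enumerate(ta):
        lo = np.searchsorted(tb, t - tolerance_s, side="left")
        hi = np.searchsorted(tb, t + tolerance_s, side="right")
        for j in range(lo, hi):
            pairs.append((abs(t - tb[j]), i, j))
    pairs.sort()
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    n = 0
    for _, i, j in pairs:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            n += 1
    return RPeakMatch(n, len(a), len(b), tolerance_s)
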