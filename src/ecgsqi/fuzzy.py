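"""Fuzzy comprehensive evaluation of ECG segment quality.

Four retained indices (qSQI, pSQI, kSQI, basSQI) are each mapped to a degree
of membership in the three quality levels V = {Excellent, Barely acceptable,
Unacceptable} by Cauchy, trapezoidal and rectangular membership functions,
forming a 4x3 fuzzy matrix R.  A weight vector W (default 0.4/0.4/0.1/0.1,
summing to 1) synthesizes the rows with the bounded operator M(., (+)):

    s_j = min(1, sum_i w_i * r_ij)

and the weighted-membership score

    v = sum_j j * s_j^2 / sum_j s_j^2      (j = 1, 2, 3 for E, B, U)

decides the label: E if v <= 1.50, B if 1.50 < v < 2.40, else U.  A
follow-up recommendation is attached: accept Excellent segments; for
Unacceptable segments suggest de-noising when the noise-sensitive indices
(kSQI, basSQI) are unqualified and re-collection when the waveform indices
(qSQI, pSQI) are; Barely acceptable segments are flagged for reassessment.

Membership parameters
---------------------
qSQI (percent q):
    E: 0 for q<=80; rising half-Cauchy 1/{1+[0.3(q-80)]^-2} on 80<q<90;
       q/100 on [90, 100]   (alpha = 0.3 enforces continuity at 90).
    B: full Cauchy centered at 75, scale 7.5.
    U: 1 for q<=55; falling Cauchy 1/{1+[(q-55)/5]^2} above.
pSQI (fraction p): trapezoids with breakpoints 0.15 / 0.18 / 0.22 / 0.25 /
    0.28 / 0.32 / 0.35.  The E and U ramps are printed with slope 0.1 over a
    width-0.1 interval, which leaves them discontinuous (jumping from 0.01
    to 1); the default ``continuity_corrected`` mode uses slope 10 so the
    ramps actually connect their plateaus, the ``literal`` mode keeps the
    printed digits.
kSQI: rectangular — (1,0,0) if k > 5 else (0,0,1).
basSQI (percent b = 100 * basSQI):
    E: 0 for b<=90; rising half-Cauchy with alpha = 0.8718 on 90<b<95;
       b/100 on [95, 100]   (alpha chosen for continuity at 95).
    B: full Cauchy centered at 92, scale 2.5.
    U: 1 for b<=85; falling Cauchy with center 85, scale 5 above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AnalysisConfig, EcgRecord, UndefinedIndexError
from .sqi import SqiGradeVector, SqiVector, UNQUALIFIED, compute_all_sqis

__all__ = [
    "QualityResult",
    "membership_qsqi", "membership_psqi", "membership_ksqi", "membership_bassqi",
    "build_fuzzy_matrix", "synthesize", "decide", "recommend",
    "evaluate_segment",
]

log = logging.getLogger(__name__)

FACTOR_ORDER = ("qsqi", "psqi", "ksqi", "bassqi")
LEVELS = ("E", "B", "U")


@dataclass(frozen=True)
class QualityResult:
    """Decision score v in [1, 3], quality label, and follow-up advice.

    When produced by :func:`evaluate_segment`, the intermediate quantities
    (index values, grades, fuzzy matrix and synthesis vector) are attached.
    """

    v: float
    label: str
    recommendation: str
    sqis: SqiVector | None = None
    grades: SqiGradeVector | None = None
    matrix: np.ndarray | None = field(default=None, repr=False)
    synthesis: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        out = dict(v=self.v, label=self.label, recommendation=self.recommendation)
        if self.sqis is not None:
            out.update(self.sqis.as_dict())
        if self.grades is not None:
            out.update(self.grades.as_dict())
        if self.synthesis is not None:
            out.update(s1=float(self.synthesis[0]), s2=float(self.synthesis[1]),
                       s3=float(self.synthesis[2]))
        return out


def _rising_half_cauchy(x: float, a: float, alpha: float, beta: float = 2.0) -> float:
    # 1 / {1 + [alpha (x - a)]^(-beta)}; 0 at x = a by continuity
    if x <= a:
        return 0.0
    t = (alpha * (x - a)) ** beta
    return t / (1.0 + t)


def _falling_cauchy(x: float, a: float, scale: float, beta: float = 2.0) -> float:
    if x <= a:
        return 1.0
    return 1.0 / (1.0 + ((x - a) / scale) ** beta)


def _full_cauchy(x: float, a: float, scale: float) -> float:
    return 1.0 / (1.0 + ((x - a) / scale) ** 2)


def membership_qsqi(q: float) -> tuple[float, float, float]:
    """Memberships (E, B, U) of the detector-agreement index q in [0, 100]."""
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"qSQI must be in [0, 100], got {q}")
    if q <= 80.0:
        r_e = 0.0
    elif q < 90.0:
        r_e = _rising_half_cauchy(q, 80.0, 0.3)
    else:
        r_e = q / 100.0
    r_b = _full_cauchy(q, 75.0, 7.5)
    r_u = _falling_cauchy(q, 55.0, 5.0)
    return r_e, r_b, r_u


def _ramp(x: float, x0: float, x1: float, rising: bool) -> float:
    """Unit ramp between x0 and x1 (continuity-corrected trapezoid edge)."""
    t = (x - x0) / (x1 - x0)
    t = min(1.0, max(0.0, t))
    return t if rising else 1.0 - t


def membership_psqi(p: float, mode: str = "continuity_corrected"
                    ) -> tuple[float, float, float]:
    """Memberships (E, B, U) of the QRS band-power fraction p in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"pSQI must be in [0, 1], got {p}")
    # B: printed slopes (25) already connect the plateaus, both modes agree
    if p < 0.18 or p >= 0.32:
        r_b = 0.0
    elif p < 0.22:
        r_b = 25.0 * (p - 0.18)
    elif p < 0.28:
        r_b = 1.0
    else:
        r_b = 25.0 * (0.32 - p)

    if mode == "continuity_corrected":
        r_e = _ramp(p, 0.25, 0.35, rising=True)
        r_u = _ramp(p, 0.15, 0.25, rising=False)
    elif mode == "literal":
        if p <= 0.25:
            r_e = 0.0
        elif p < 0.35:
            r_e = 0.1 * (p - 0.25)
        else:
            r_e = 1.0
        if p < 0.15:
            r_u = 1.0
        elif p <= 0.25:
            r_u = 0.1 * (0.25 - p)
        else:
            r_u = 0.0
    else:
        raise ValueError(f"unknown membership mode {mode!r}")
    return r_e, r_b, r_u


def membership_ksqi(k: float, threshold: float = 5.0) -> tuple[float, float, float]:
    """Rectangular memberships of kurtosis: fully E above 5, fully U below."""
    return (1.0, 0.0, 0.0) if k > threshold else (0.0, 0.0, 1.0)


def membership_bassqi(b: float) -> tuple[float, float, float]:
    """Memberships (E, B, U) of baseline relative power on the percent scale.

    ``b`` is 100 times the basSQI fraction.
    """
    if not 0.0 <= b <= 100.0:
        raise ValueError(f"basSQI percent value must be in [0, 100], got {b}")
    if b <= 90.0:
        r_e = 0.0
    elif b < 95.0:
        r_e = _rising_half_cauchy(b, 90.0, 0.8718)
    else:
        r_e = b / 100.0
    r_b = _full_cauchy(b, 92.0, 2.5)
    r_u = _falling_cauchy(b, 85.0, 5.0)
    return r_e, r_b, r_u


def build_fuzzy_matrix(sqis: SqiVector,
                       mode: str = "continuity_corrected") -> np.ndarray:
    """Stack the four membership rows (qSQI, pSQI, kSQI, basSQI) into R (4x3)."""
    vals = (sqis.qsqi, sqis.psqi, sqis.ksqi, sqis.bassqi)
    if any(np.isnan(v) for v in vals):
        bad = [n for n, v in zip(FACTOR_ORDER, vals) if np.isnan(v)]
        raise UndefinedIndexError(f"cannot build fuzzy matrix, undefined: {bad}")
    rows = [
        membership_qsqi(sqis.qsqi),
        membership_psqi(sqis.psqi, mode),
        membership_ksqi(sqis.ksqi),
        membership_bassqi(100.0 * sqis.bassqi),
    ]
    return np.asarray(rows, dtype=float)


def synthesize(weights, matrix: np.ndarray) -> np.ndarray:
    """Bounded-operator synthesis S = W o R: s_j = min(1, sum_i w_i r_ij).

    With the weights summing to 1 and memberships bounded by 1 the bound
    never bites and S equals the plain weighted mean of the rows.
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(matrix, dtype=float)
    if w.shape != (r.shape[0],):
        raise ValueError(f"weights {w.shape} do not match matrix rows {r.shape}")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("memberships must lie in [0, 1]")
    return np.minimum(1.0, w @ r)


def decide(s, thresholds: tuple[float, float] = (1.50, 2.40)) -> tuple[float, str]:
    """Weighted-membership decision: v = sum j s_j^2 / sum s_j^2, then label.

    An all-zero synthesis vector (possible only in literal membership mode)
    is reported as Unacceptable with v = 3 and a logged warning.
    """
    s = np.asarray(s, dtype=float)
    v1, v2 = thresholds
    w = s ** 2
    if w.sum() == 0:
        log.warning("all-zero synthesis vector; reporting Unacceptable")
        return 3.0, "U"
    v = float(np.dot(np.arange(1, 4), w) / w.sum())
    if v <= v1:
        label = "E"
    elif v < v2:
        label = "B"
    else:
        label = "U"
    return v, label


def recommend(label: str, grades: SqiGradeVector) -> str:
    """Follow-up advice from the label and which indices failed.

    Excellent segments are accepted as-is.  For Unacceptable segments, an
    unqualified kSQI or basSQI points to removable noise (de-noise, then
    reassess), while an unqualified qSQI or pSQI points to an unusable
    waveform (re-collect).  Barely acceptable segments get a second
    assessment pass.
    """
    if label == "E":
        return "accept"
    if label == "B":
        return "reassess"
    if grades.ksqi == UNQUALIFIED or grades.bassqi == UNQUALIFIED:
        return "denoise_and_reassess"
    return "recollect"


def evaluate_segment(record: EcgRecord,
                     config: AnalysisConfig | None = None) -> QualityResult:
    """Full chain: indices -> memberships -> synthesis -> decision -> advice."""
    config = config or AnalysisConfig()
    sqis, grades = compute_all_sqis(record, config)
    try:
        matrix = build_fuzzy_matrix(sqis, config.membership_mode)
    except UndefinedIndexError as e:
        log.warning("segment %s: %s; reporting Unacceptable", record.source_id, e)
        return QualityResult(3.0, "U", recommend("U", grades),
                             sqis=sqis, grades=grades)
    s = synthesize(config.weights, matrix)
    v, label = decide(s, config.decision_thresholds)
    return QualityResult(v, label, recommend(label, grades),
                         sqis=sqis, grades=grades, matrix=matrix, synthesis=s)
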