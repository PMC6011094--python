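# Methods

This note documents the models and procedures implemented in `ecgsqi`, the
parameters that matter, the numerical choices made where the design was
open, what the synthetic data does and does not emulate, and the known
limitations of the approach.

## Analysis pipeline

Each record is processed per segment (default 9000 samples, the
conventional fixed window for this task; at 300 Hz that is 30 s). The
pipeline is: run both R-peak detectors → match their peak sets → compute
the six indices → grade them → fuse (rule tables and/or fuzzy engine) →
decide E/B/U and a follow-up recommendation. All indices are ratios,
band-power fractions or standardized moments, so the pipeline is invariant
to amplitude scaling; no unit normalization is performed and ADC gain only
matters for display.

## R-peak detectors

**Hilbert / adaptive threshold.** Zero-phase Butterworth band-pass 5–20 Hz
(order 3), first difference, analytic-signal envelope, 80 ms moving-average
smoothing. Candidate envelope peaks (0.2 s refractory) are accepted against
a threshold initialized at 0.6 × the 98th percentile of the first 2 s of
envelope and updated after each accepted beat to 0.3 × the running mean of
the last 8 accepted peak amplitudes. If no beat is accepted for 1.66 × the
median RR, the largest rejected candidate in the gap is re-examined at
0.4 × the threshold (search-back). Accepted positions are refined to the
local absolute extremum of the band-passed signal within ±40 ms, which
makes reported positions polarity-insensitive. All constants are keyword
arguments.

**Wavelet modulus-maxima.** Undecimated (stationary) wavelet transform,
Haar by default, up to four levels; the detail scale whose dyadic band
[fs/2^(l+1), fs/2^l] has center nearest 10 Hz is used (level 4 at both
300 Hz and 500 Hz). The detail behaves as a smoothed derivative, so a QRS
complex produces an adjacent pair of opposite-sign modulus maxima with a
zero-crossing at the R peak. A pair is accepted when

* both moduli exceed `max(0.3 × p95(|d|), 4.5 × σ̂)` where σ̂ is the
  MAD-based robust standard deviation of the detail coefficients, and
* the extrema are 15–120 ms apart (QRS-scale support).

The MAD noise floor is the key robustness device: QRS complexes are sparse
outliers of the detail distribution, whereas broadband noise raises σ̂ in
proportion to itself, so under heavy muscle-band noise this detector
*abstains* instead of free-running at the refractory rate. The two
detectors therefore degrade very differently under noise — the Hilbert
detector over-fires while the wavelet detector under-fires — and their
agreement ratio qSQI collapses on corrupted segments, which is exactly the
behaviour the index needs. The 15 ms minimum pair support also rejects
mains interference (50 Hz extrema are 10 ms apart) without any absolute
amplitude threshold, preserving scale invariance.

**Matching.** One-to-one greedy matching, smallest time difference first,
within a ±150 ms tolerance (the PhysioNet beat-matching convention; the
choice is configurable). For peak trains whose intra-train spacing respects
the cardiac refractory period (> 2 × tolerance), each peak has at most one
feasible partner, so the greedy matching equals the optimal bipartite
assignment; this equivalence is verified in the tests against
`scipy.optimize.linear_sum_assignment` on random beat trains.

## Indices and grading

* **qSQI** = 100·2N/(Na+Nb). Grades: optimal > 90, suspicious 60–90,
  unqualified < 60 (boundaries at the closed ends as printed in the source
  criteria; every breakpoint is configurable).
* **pSQI** = P[5,15]/P[5,40]. Heart-rate dependent limits (l1, l2, l3):
  (0.5, 0.8, 0.4) for 60–130 bpm, (0.4, 0.7, 0.3) for 130–160 bpm; rates
  outside those bands use the nearest band with a logged warning. The heart
  rate is taken from the Hilbert detector's mean RR (configurable choice;
  the criteria do not say which detector feeds it).
* **cSQI** = sample SD / mean of the RR intervals (n−1 estimator; the
  conventional reading of "empirical estimates"). Optimal < 0.45,
  suspicious 0.45–0.64, unqualified > 0.64.
* **sSQI, kSQI** — third and fourth standardized moments, population
  estimators, non-excess kurtosis (Gaussian → 3). kSQI is two-level:
  optimal > 5, else unqualified. Skewness is computed and reported but not
  fused: it is far less noise-robust than kurtosis (symmetric broadband
  noise leaves skewness near zero while collapsing kurtosis).
* **basSQI** = 1 − P[0,1]/P[0,40]. Optimal ≥ 0.95, suspicious 0.90–0.95,
  unqualified < 0.90.

**Spectra** are Welch averaged periodograms: Hann taper, 8 s windows, 50 %
overlap, constant detrend, giving a 0.125 Hz grid — fine enough to resolve
the 0–1 Hz numerator of basSQI (a resolution coarser than 0.25 Hz would
alias the drift band into the first bin). Band powers are trapezoidal
integrals of the density with interpolated band edges.

Any index that is undefined on a degenerate input (flatline, zero spectral
power, fewer than three beats) is reported as NaN and graded unqualified;
the segment is never dropped.

## Heuristic fusion

The rule tables for 2–5 entered SQIs act on the counts of optimal /
suspicious / unqualified grades; the Excellent clause is checked first,
then Unacceptable, with Barely-acceptable as the catch-all (for the
two-SQI table the catch-all is Unacceptable, following the printed layout).
Exhaustive enumeration over all grade tuples confirms totality, agreement
with an independent clause-by-clause transcription, and monotonicity
(upgrading any single grade never worsens the four-SQI label).

## Fuzzy comprehensive evaluation

Factors `U = {qSQI, pSQI, kSQI, basSQI}`, levels `V = {E, B, U}` with
indices j = 1, 2, 3. Membership families:

* qSQI (percent): E — zero up to 80, rising half-Cauchy
  `1/{1+[0.3(q−80)]⁻²}` on (80, 90), `q/100` on [90, 100]; α = 0.3 is the
  unique value joining the two branches at 0.9. B — full Cauchy, center 75,
  scale 7.5. U — one up to 55, falling Cauchy `1/{1+[(q−55)/5]²}` above
  (value 0.5 at q = 60).
* pSQI (fraction): trapezoids with breakpoints 0.15/0.18/0.22/0.25/0.28/
  0.32/0.35. The E and U ramps are printed with slope 0.1 over a 0.1-wide
  interval, which cannot reach 1 and leaves jumps of 0.99 at the plateau
  edges; the default `continuity_corrected` mode uses slope 10 so the ramps
  join their plateaus (the same continuity argument that fixes α = 0.3
  above), and a `literal` mode keeps the printed digits for comparison.
* kSQI: rectangular, (1,0,0) above 5 else (0,0,1).
* basSQI (percent scale, b = 100·basSQI): E — zero up to 90, rising
  half-Cauchy with α = 0.8718 on (90, 95) (α again forced by continuity:
  both branches give 0.95 at b = 95), `b/100` above. B — full Cauchy,
  center 92, scale 2.5. U — one up to 85, falling Cauchy with scale 5.

Synthesis uses the bounded operator `M(·, ⊕)`: `sⱼ = min(1, Σ wᵢ rᵢⱼ)`.
Because the weights sum to 1 and memberships are bounded by 1, the bound
never truncates and S is algebraically the weighted mean of the rows (this
equivalence is property-tested). The alternative operators (max–min and
mixtures) are deliberately not offered as defaults: they discard most of
the membership information.

Decision: `v = Σ j sⱼ² / Σ sⱼ²` (squares emphasize the dominant level),
labels at v ≤ 1.50 / < 2.40 / ≥ 2.40. An all-zero synthesis vector — only
possible in literal membership mode — is reported as U with a warning.
Follow-up: E → accept; U with kSQI or basSQI unqualified →
de-noise and reassess (the failure is removable noise); U otherwise →
re-collect (the waveform itself is unusable); B → reassess.

Weights default to (0.4, 0.4, 0.1, 0.1) over (qSQI, pSQI, kSQI, basSQI) —
the operating point reported for this method — and the harness's
`weight_sweep` compares alternatives by cross-validated accuracy.

## Synthetic data

Clean records are trains of five Gaussian bumps per beat (P, Q, R, S, T
with amplitudes 0.12/−0.08/1.0/−0.12/0.28 relative to R, widths 10–55 ms,
offsets −220…+300 ms), beat times from RR = 60/HR × (1 + jitter) with
i.i.d. Gaussian jitter at a configurable coefficient of variation. R-peak
sample positions are recorded exactly at construction. Noise classes:

* baseline wander — five sinusoids with random frequencies 0.05–0.5 Hz and
  phases, scaled so the ensemble RMS equals that of a single sinusoid at
  the requested amplitude;
* powerline — 50/60 Hz tone at the requested peak amplitude;
* EMG — white noise band-passed 20–40 Hz at the requested RMS (inside the
  40 Hz analysis ceiling, where muscle noise actually perturbs pSQI);
* Gaussian white noise at the requested RMS.

Amplitudes are fractions of the R amplitude. Intended labels follow fixed
per-class bands (`QUALITY_BANDS`), set from a power argument: the bump
train carries only ≈ 0.03 R² of total power, so a noise amplitude of 5 %
of R is already a few percent of the record's power and 25 % dominates it.
Dataset generation draws heart rates uniformly from 60–100 bpm, RR
jitter 2–6 %, and per-class noise recipes: near-clean for E, a single mild
noise source for B, and a heavy composite artifact (EMG 1–2 × R RMS plus
drift plus broadband noise — the profile of a motion-corrupted mobile
recording) for U.

What the generator does **not** emulate: real QRS morphology variation,
ectopy and arrhythmia, electrode pop/step artifacts, amplifier saturation,
bursty (non-stationary) muscle noise, and recording dropouts. Passing the
synthetic end-to-end tests therefore shows that the indices and the fusion
machinery respond correctly to the canonical noise classes at controlled
levels; it does not certify performance on clinical data, for which the
harness's external-data mode (point it at local WFDB records) should be
used.

## Problem sizes and numerical choices

Tests and the harness default to 30 s records at 300 Hz and balanced
datasets of 20–30 records with 10 × stratified 10-fold scoring — ample for
a rule-based classifier with no trainable parameters, where
cross-validation measures only sampling variability of the accuracy.
Classes with fewer than 10 members reduce the fold count with a warning.
All randomness (synthesis, CV partitions) flows from explicit integer
seeds. Grade boundaries follow the printed inequalities exactly (e.g.
q = 90 is suspicious, not optimal; k = 5 is unqualified); all breakpoints
are configurable in `AnalysisConfig`. NaN samples are rejected at load
time by default, with an opt-in linear interpolation for isolated gaps.

## Known limitations

* **Pure baseline wander and pure mains pickup cannot drive the fuzzy
  label to U.** Drift (< 1 Hz) and 50/60 Hz tones lie outside the 5–40 Hz
  analysis band and outside both detectors' passbands, so only basSQI
  and/or kSQI respond — a combined weight of 0.2, which caps v well below
  the 2.40 threshold. Such segments come back E or B with basSQI (or kSQI)
  graded unqualified; the recommendation logic still flags them for
  de-noising when they fail, and real-world heavy drift (which arrives with
  broadband motion artifact) is classified U via the other indices. This is
  an intrinsic property of the published weighting, not an implementation
  artifact.
* The pSQI membership breakpoints (0.15–0.35) sit well below the pSQI
  grading limits (0.3–0.8); both are implemented as printed in their
  respective pathways. One visible consequence: a segment drowned in
  *white* noise has pSQI ≈ 0.3 and receives a high E-membership from the
  trapezoid while its grade is suspicious/unqualified.
* qSQI saturates near 100 for any segment where both detectors lock onto
  the same periodicity, and the ±150 ms tolerance lets dense spurious
  detections match by chance; the asymmetric failure modes of the two
  detectors (see above) are what keeps the index informative.
* The heuristic tables and all thresholds are fixed as printed; no
  threshold optimization is performed or offered.
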