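# Methods

This note records the models, numerical choices and limitations behind
`ecgkit`, in the package's own terms.

## Signal model and the synthetic generator

A beat is modelled as five Gaussian bumps (P, Q, R, S, T) anchored on the
R time; a record is a train of such beats at R times laid down by a
jittered RR process (`RR_k = 60/HR + N(0, σ_RR)`, floored at 0.3 s), plus
three additive artifacts: a low-frequency sinusoid for baseline wander, a
50/60 Hz sinusoid for mains interference, and white Gaussian noise. The
sum-of-Gaussians choice (over a dynamical-system beat model) is deliberate:
wave extrema are analytically known, so ground truth for R, Q and S
positions is exact and every downstream stage can be scored against it.

Default template (amplitude mV / offset s / width s): P 0.12/−0.20/0.030,
Q −0.15/−0.035/0.022, R 1.0/0/0.018, S −0.20/+0.035/0.022,
T 0.30/+0.30/0.060. The Q/S widths were set so that the trough-to-trough
width of a clean beat, as measured by the package's own Q/S localiser,
comes out at ≈0.097 s — the closest achievable value on a 360 Hz sample
lattice to the 0.099 s standard QRS width that the interval rule uses.
Because the Q and R Gaussians overlap, the trough of the superposition
sits outside the Q center; the width target therefore governs the
*measured* width, not the nominal offsets.

Cohorts: regular records use σ_RR = 0.02 s; irregular records use
σ_RR = 0.12 s and widen the QRS of a random 30 % of beats by a factor 1.8.
The irregular mechanism is timing/interval irregularity only — no
pathology-specific morphologies (AF f-waves, PVC shapes) are attempted, so
passing tests demonstrate interval-statistics separation, not clinical
arrhythmia discrimination. Noise defaults are zero; tests that need noise
size it explicitly (e.g. white noise at 10 dB SNR against the clean-signal
RMS). Per-record seeds derive deterministically from the base seed.

What the generator does not emulate: nonstationary heart rate, electrode
motion transients, muscle (EMG) noise, multi-lead geometry, and beat-to-beat
morphology variability beyond the widened-QRS mechanism.

## Filtering

All filters are designed directly in the digital domain
(`scipy.signal.butter` / `firwin`); analog-style reference transfer
functions are kept only as evaluation fixtures, with a bilinear-transform
utility for discretising them, because exact digital coefficients cannot be
recovered from printed analog forms. Forward-only application is the
library default; the pipeline applies every stage zero-phase
(forward-backward) so detected indices stay aligned with the raw record.

* **Baseline high-pass** — linear-phase FIR, cutoff 0.5 Hz. The tap vector
  is mean-corrected after the windowed-sinc design so DC is rejected
  *exactly* (a baseline filter must null the signal mean even when its
  order cannot realise the nominal cutoff). The pipeline default order is
  `2·round(10·fs/3)` (2400 at 360 Hz, impulse response ≈6.7 s): a Hamming
  windowed-sinc needs a transition band of roughly `3.3·fs/(order+1)` Hz,
  and suppressing a 0.3 Hz wander by ≥90 % behind a 0.5 Hz cutoff needs a
  transition ≲0.5 Hz. A fixed order of 60 (transition ≈20 Hz at 360 Hz)
  cannot do this — it leaves >90 % of a 0.3 Hz wander in place — but
  remains available through `baseline_order` for comparison runs.
* **QRS band-pass** — Butterworth order 2, 5–15 Hz: the classic QRS
  emphasis band.
* **Mains band-stop** — Butterworth order 6 around 49–51 Hz (59–61 Hz when
  the mains frequency is 60 Hz). Together with the band-pass this forms
  the 16th-degree IIR prototype that the reduction stage condenses.
* **Power-line FIR notch** — 101 taps, default band = mains ±5 Hz. A
  ±1 Hz band at this tap count is below the achievable transition width
  (measured |H(50 Hz)| ≈ 0.71 at 360 Hz); ±5 Hz reaches |H(50)| ≈ 0.04
  (≈29 dB) while leaving the 10 Hz response above 0.999. The half-width is
  configurable.
* A 150 Hz low-pass corner is applied only when `fs > 300` Hz; at lower
  sampling rates it is skipped with a logged warning rather than silently
  aliased.

## Minimax order reduction

The objective is the worst-case magnitude-response deviation from the
prototype over a log-spaced 256-point grid from 0.1 Hz to just below
Nyquist (log spacing weights the physiologically dense low-frequency
decades). The reduced filter is parameterised by its raw coefficients,
constrained to the box `[0, 50]` — nonnegativity is a structural
requirement, not a by-product — and the default target shape is numerator
degree 1 over a degree-0 denominator, i.e. reported order 2 (coefficient
count of the longest polynomial).

Numerics: the inner maximisation is exact (full grid scan per candidate).
The outer search is coefficient-sequential: numerator degree is grown one
at a time, each stage warm-starting from the previous stage's best solution
zero-padded on the high-degree side, then polished by Nelder–Mead from
three starts (a least-squares magnitude fit with unit denominator, the
warm start, and one seeded random start), with parameters clipped into the
box inside the objective and candidates with unstable denominators
penalised. The best candidate ever evaluated is kept, which makes the
achieved deviation provably non-increasing in the target order and never
worse than the initial candidate. Ties in the Nelder–Mead polish resolve
toward whatever was evaluated first, which the seeding makes deterministic.

Interpretation: condensing a band-pass-shaped 16th-order response to order
2 necessarily flattens the band structure; the achieved minimax deviation
on the default prototype is ≈0.5 (the response surface oscillates between
0 and ~1 while a 2-tap filter is nearly flat). The value of the stage is
the nonnegative compact smoother, not band-shape preservation — the
sign-preservation guarantee (nonnegative input ⇒ nonnegative output)
holds exactly for the FIR-numerator/constant-denominator default and is
*not* claimed for reduced filters with a nontrivial denominator.

## Peak detection

The analytic signal is built in the frequency domain (negative-frequency
zeroing); the principal-value convolution form of the Hilbert transform is
retained as an independent test oracle (cell-exact discretisation gives
the classic 2/(πk) odd-lag kernel). R candidates are envelope maxima at
least 0.2 s apart that exceed 0.5 × an exponentially weighted running
amplitude (update weight 0.125 per accepted beat, initialised from the
first two seconds); each detection is snapped to the raw-signal maximum
within ±50 ms. Q/S are signal minima within a ±60 ms window around R;
beats at record edges or with non-physiologic trough spacing (outside
(0, 0.25) s) are dropped with a warning. The comparator detector keeps its
textbook structure (5–15 Hz band-pass, five-point derivative, squaring,
150 ms integration window, dual adaptive thresholds with 1.66·RR
search-back).

## HRV conventions

SDNN is the population standard deviation of RR (ms). RMSSD is implemented
in both conventions — denominator = number of differences (standard) and
denominator = interval count (the package default, matching the convention
of the analyses this package reproduces) — and every report names the one
used. NN50 counts successive differences exceeding 50 ms; counting raw
intervals above 50 ms would flag essentially every beat and is deliberately
not implemented. Poincaré SD1 is the RMS of `(RR_{n+1}−RR_n)/√2` measured
about the identity line itself (hence exactly RMSSD_standard/√2); SD2 is
the centered SD of `(RR_n+RR_{n+1})/√2`.

## Classification

The positive class is *irregular*. The evaluation formulas are implemented
verbatim in their nonstandard form (sensitivity = Tp/(Tp+Tn), specificity
= precision = Tp/(Tp+Fn), accuracy = (Tp+Tn)/total, all ×100), with the
textbook definitions behind `convention="standard"`; under the default
convention precision and specificity are the same expression and always
agree.

Open design points resolved here: the interval rule treats its tolerance
band as closed (a record exactly on the boundary is regular); the
nearest-centroid rule standardises features by the training-set SD and
breaks ties (and sub-margin decisions) toward regular; the fuzzy rule base
is a package design — membership knees at 0.02/0.05 s for QRS deviation,
0/1 standardised units for the centroid margin, beat-count terms centered
on the training median — since only the rule inputs, not the table, are
externally specified. All of it is configurable.

## Problem sizes and tolerances in the test suite

Synthetic records in tests are 30–90 s at 360 Hz (100-beat records for
sensitivity checks, ~500-beat records for SDNN parameter recovery);
the brute-force cross-check of the reduction stage uses a 50³ coefficient
lattice on a 32-point grid. Detection sensitivity is scored with a 50 ms
matching window; envelope recovery at 1 %; the SD1/RMSSD identity at
1e-9 ms; printed-example metric rows at 4 decimal places.

## Known limitations

* WFDB support covers storage formats 212 and 16 with `(raw−baseline)/gain`
  scaling; multi-segment records, annotation (.atr) parsing and other
  storage formats are out of scope.
* The reduction stage matches magnitude response only; phase is ignored.
* Classification thresholds and the fuzzy rule table are calibrated on the
  synthetic cohort's feature distributions; real recordings will need the
  centroid/fuzzy rules re-fit on labelled data, which the estimators'
  `fit` supports directly.
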