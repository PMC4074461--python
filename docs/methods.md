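# Methods

## Problem and scope

`posturo` turns raw recordings from a four-load-cell balance board into
center-of-pressure (COP) sway metrics and measurement-reliability statistics.
The intended workflow is the standard instrument-validation design for such
boards: 20 subjects perform four stance tasks (two-leg and one-leg, eyes open
and closed), three trials each, across four measurement sessions — rater 1 on
day 1 (A1), rater 2 on day 1 (B), rater 1 on day 2 (A2), and a laboratory
force platform on day 3 (A3) — and the analysis reports inter-rater (A1 vs
B), intra-rater (A1 vs A2) and concurrent-validity (A1 vs A3) agreement.
Live acquisition from hardware is out of scope: data enters as CSV.

## COP reconstruction

The board is a rigid rectangle (default 45 × 26.5 cm) with vertical-load
sensors at the corners. A moment balance about the center gives, per sample
with corner loads f_tl, f_tr, f_bl, f_br and total F:

    x = (W/2) · [(f_tr + f_br) − (f_tl + f_bl)] / F
    y = (D/2) · [(f_tl + f_tr) − (f_bl + f_br)] / F

Axis convention (a documented choice — board vendors state none): x is
medio-lateral along the long edge, positive right; y is antero-posterior,
positive forward; origin at the center. Forces are unit-agnostic (N or
kg-equivalent) because the COP is invariant to uniform scaling.

Samples whose total load is below 5% of the trial's median (`min_load_fraction`)
are treated as step-on/step-off or dropouts: leading/trailing runs are cut,
interior ones linearly interpolated. The inverse map (`forces_from_cop`) uses
bilinear corner weighting, the unique separable decomposition, so
reconstruction∘decomposition is the identity to floating-point precision;
the simulator relies on this to materialise raw recordings.

## Preprocessing

The pipeline resamples (linear interpolation) onto a uniform grid at the
design rate — 50 Hz by default, matching the board's acquisition rate — and
then applies a 4th-order Butterworth low-pass at 12 Hz. Resampling always
precedes filtering because the digital design assumes uniform sampling.

Filter application mode is a genuine design freedom: a literal single
forward pass (`causal`) has the textbook magnitude response (gain 1/√2 at
the cutoff) but introduces phase lag; posturography pipelines conventionally
use a forward-backward pass instead, which has zero phase lag and the
squared magnitude (gain 1/2 at the cutoff). The default is `zero_phase`;
`causal` is available for strict single-pass conformance. Zero-phase edge
handling uses odd-reflection padding of length 3 × order, which suppresses
startup transients on 10 s one-leg trials; the causal mode initialises the
filter state at the signal's first value so a constant signal passes
unchanged (unit DC gain holds exactly in both modes). Signals must exceed
the 3 × order warm-up length.

## Sway metrics

Path length PL = Σ √(Δx² + Δy²) over consecutive samples (cm); average
velocity VA = PL / T with T = (N−1)/fs the elapsed recorded duration (cm/s),
so VA·T ≡ PL exactly. No trimming is applied by default (`trim_s=0`,
configurable). The per-condition value is the arithmetic mean of the three
trial repetitions; trials that fail preprocessing are dropped from the mean
with a reason-coded warning rather than failing the condition.

Published tables for this instrument class print VA values ≈6% above PL/T
(e.g. 36.03 cm over 30 s printed against 1.27 cm/s); the cause (trimming? a
different denominator?) is not recoverable from the published description,
so this package uses the clean definition and does not attempt to match
those VA cells.

## Reliability statistics

**ICC.** Published analyses of this design rarely state the ICC form. This
package defaults to ICC(2,1) — two-way random, absolute agreement, single
measures — for inter-rater and validity comparisons, because absolute
agreement is the assumption SEM and Bland–Altman also make; ICC(3,1)
(consistency) is additionally reported for intra-rater comparisons, and all
four form combinations (agreement/consistency × single/average) are
selectable. Estimates come from the standard two-way mean-squares
decomposition; confidence intervals use the F constructions of the
McGraw–Wong conventions (Satterthwaite df for the agreement form). CI bounds
are clipped to [−1, 1]; on degenerate tables where the Satterthwaite df
collapses, the error df is substituted and non-finite bounds widen to ±1.
A matrix with zero total variance raises an explicit undefined-ICC error.

Coverage of the agreement-form interval is near-nominal when the shared
session/rater effect is a modest share of the non-subject variance, but
with k = 2 raters only one degree of freedom estimates the rater variance,
so when raters carry half the noise the interval undercovers mildly (~92%
instead of 95% at n = 20). This is a property of the F approximation, not
of the implementation; the test suite demonstrates both regimes.

**SEM.** SEM = SD · √(1 − ICC), multiplied by √(n_repeats) for repeated
measures. Reports use the pooled SD of the two compared conditions,
√((SD_a² + SD_b²)/2) — published SEM columns in this literature are not
reproducible from any printed SD/ICC pair, so the pooled choice is
documented rather than reverse-engineered. Because the three trials are
averaged before analysis, `n_repeats` defaults to 1 and the correction is
exposed, never silently applied. Negative ICC estimates are clamped to 0
with a warning.

**Banding.** ICC ≥ 0.80 is "high", 0.60 ≤ ICC < 0.80 "moderate", below
"low". Published band definitions leave [0.79, 0.80) ambiguous; edges here
are half-open at the lower bound.

**Differences and agreement.** The difference column is second condition
minus first (b − a), with SD on the n−1 denominator and a two-sided paired
t-test; table flags are * for p < 0.05 and ** for p < 0.01 (an assumption —
such flags are often left undefined in print). Bland–Altman analysis plots
(mean, difference) pairs with bias ± 1.96 · SD limits of agreement; the
multiplier is fixed at 1.96 (no small-sample t substitute).

## Simulator

**Trajectories.** Quiet-stance sway is modelled per axis as a discrete
Ornstein–Uhlenbeck process, x_{t+1} = x_t − θ·x_t·Δt + σ·√Δt·ε, started from
the stationary distribution and clipped to the board rectangle. Defaults
θ = 0.8 s⁻¹ and σ = 0.15 cm/√s give stationary sway of ~1–2 mm RMS with
path lengths of tens of cm per trial — the magnitudes healthy adults show.
The OU model is a phenomenological stand-in: it is stationary and
band-limited like real sway but has no inverted-pendulum mechanics, no
intermittent control, and a flat high-frequency velocity spectrum, so
passing tests demonstrate pipeline correctness, not biomechanical fidelity.

With `target_pl_cm` set, the path is rescaled about its mean so the raw
path length equals the target exactly (path length is homogeneous of degree
one under scaling). For materialising study trials, the calibration is done
against the *filtered* path length instead: the OU velocity spectrum is
nearly flat, so a 12 Hz low-pass removes a large share of the raw path
length, and calibrating after the (linear, unit-DC-gain) preprocessing chain
makes the pipeline reproduce the tabulated value exactly rather than within
a filter-dependent tolerance.

**Studies.** Trial values follow an additive variance-components model:
y_ijk = μ_i + r_j + e_ijk with subject scores μ_i ~ N(task mean, σ_subject²),
a session effect r_j ~ N(0, σ_session²) shared across subjects, and trial
error e_ijk ~ N(0, σ_error²), floored at 0 (truncation probability ≪ 10⁻⁶
at the defaults). The platform session instead applies a fixed affine
distortion (default scale 0.92, bias 0 — laboratory platforms read several
percent shorter than the board). The single-trial ground truth
ICC = σ_s²/(σ_s² + σ_sess² + σ_e²) is emitted per task in `truth.json`,
alongside the trial-mean variant with σ_e²/n_trials.

Default task conditions (mean PL, between-subject SD, in cm): STOE 36.0/7.9,
STCE 39.8/6.4, SOOE 44.4/8.5, SOCE 81.0/18.0 — the observed scale for
healthy adults on 30 s two-leg and 10 s one-leg trials. Session and error
SDs are fixed fractions of the subject SD (0.2 for two-leg tasks, 0.45 for
SOOE, 0.28 for SOCE), giving true single-trial ICCs of ≈0.93/0.93/0.71/0.86:
high reliability on two-leg stances, moderate on the one-leg eyes-open task,
mirroring what such studies find. Velocities in simulated tables are PL/T by
construction. The same master seed yields byte-identical CSVs.

## Problem sizes in tests and the acceptance script

ICC parameter recovery uses 200 replicate 500×2 studies (mean estimate
within ±0.02 of a true 0.85) and CI coverage 500 replicate 20×2 studies;
limits-of-agreement coverage uses 10⁴ normal pairs; the end-to-end pipeline
tests use a 4-subject, 2-trial raw-materialised study. These sizes give
Monte-Carlo error comfortably below the asserted tolerances while keeping
the whole suite around ten seconds.

## Known limitations

* The OU sway generator reproduces magnitudes and reliability structure,
  not the spectral or mechanistic detail of human sway.
* The agreement-ICC CI undercovers when rater variance is large and k is
  small (see above).
* Minimal detectable change, kappa, regression-based agreement and
  multiple-testing correction across table cells are deliberately out of
  scope.
* Calibration-curve estimation per load cell and shear forces are not
  modelled; corner loads are taken as calibrated vertical forces.
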