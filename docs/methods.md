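# Methods

## The measurement problem

A third-instar larva sits on a force platform under a coverslip tilted
by about 3°, forming a wedge ("cleft") that narrows towards a slit.
After a 5 s ramp brings the confinement force to a set baseline
(25/50/75/100 mN) the platform is locked, so every subsequent change in
the vertical force comes from the animal. Trials last 120 s and are
truncated if the force falls below 5 mN (loss of mechanical
engagement). Time is trial-relative: t = 0 at ramp onset.

Each peristaltic wave produces a force wave — a rise to a peak followed
by partial relaxation. Forward waves advance the animal into the wedge
and leave the resting force higher (≈ +3 mN per wave); backward waves
retreat and leave it lower (≈ −7 mN). Behaviour arrives as an event
table (wave id, direction, start, end) scored externally; this package
never touches video.

## Wave detection

Peaks are strict local maxima filtered by topographic prominence
(default minimum 5 mN) with minimum peak distance 3 s; where candidates
crowd closer, the highest survives (ties go to the earlier). Troughs
are peaks of the negated trace. The 5 s analysis window slides by half
a window and only gathers candidate maxima; prominence is always
evaluated on the full trace, so window placement cannot change the
result and the detector is equivalent to a global enumeration — a
property the tests assert against an independent O(n²) oracle.

Wave periods:

- **Start** — the trough between the previous peak and the current
  peak, read noise-robustly as the last sample of that region whose
  smoothed value stays within a tolerance of the region minimum. The
  tolerance is 3·σ̂/√w, with σ̂ a median-absolute-difference noise
  estimate and w the smoothing window length; on a noiseless flat
  plateau it degenerates to the sample just before the rise, i.e. the
  last local minimum preceding the peak (the later, tighter, of the
  two natural candidates). For the first wave the search region starts
  after the compression ramp (plus one smoothing window), since the
  ramp's zero-force origin is not a wave boundary.
- **End** — the earliest post-peak time from which the slope magnitude
  stays below 0.5 mN s⁻¹ for at least 0.5 s. The brief zero-slope
  crossing at the peak itself cannot qualify because the dwell demands
  sustained quiet.
- **Overlap** — adjacent periods overlapping by ≥ 10% of the shorter
  one are resolved by pulling the earlier wave's end back to the later
  wave's start (zero overlap), never past its own peak.

Numerical choices: boundaries are computed on a 0.2 s moving-average
smoothing of the trace; the end-rule slope is a central difference over
a 0.5 s span of that smoothed trace. The wider differentiation span is
deliberate — at 100 Hz with 0.5 mN sensor noise a 0.2 s span gives
slope noise ≈ 0.8 mN s⁻¹, which would swamp the 0.5 mN s⁻¹ settling
criterion, while 0.5 s brings it to ≈ 0.3 mN s⁻¹ and still sits at the
dwell scale. The detector is sampling-rate-agnostic; all windows are
specified in seconds.

Matching to behaviour: a force wave (widened by the ±0.5 s
synchronisation slack) is assigned the behaviour event with the
greatest temporal overlap, provided the overlap covers at least half
the force-wave period; each event matches at most one force wave
(greatest overlap wins, earlier wave on ties), and unmatched is a valid
outcome. Bouts are maximal runs of same-direction waves with
end-to-next-start gaps under 30 s; unmatched waves break bouts and
belong to none.

## Per-wave parameters

For each wave of a bout: (1) peak change vs the previous wave;
(2) peak change vs the bout's first wave; (3) amplitude = peak − end
value; (4) duration = period; (5) inter-wave delay = previous end to
current start; (6) elastic work `W = (f_max² − f_min²)/(2k)` with
`f_max`/`f_min` the extreme trace values within the wave's own period
and `k` the elastic coefficient of the body (mN/mm; mN²·mm/mN = µJ).
The work formula is exactly the integral of force over displacement
along the linear-elastic loading path `f = k·x`, which the tests verify
by numerical integration. Parameters (1) and (5) are undefined — NaN,
never zero — for a bout's first wave; (1) is computed within bouts
only, never across bout boundaries. A trace value marginally below
zero from sensor noise is clamped to zero before entering the work
formula.

Per-bout rescaling maps a parameter series to
`P_re[n] = (Para[n] − Para[1])/|Para[1]|`, so the first wave is 0 and
later values are relative changes; dividing by the absolute value
keeps the sign of the change meaningful for negative-valued series.
The series is flagged undefined when `Para[1] = 0`.

Direction-effect fractions summarise parameter (1): the share of
forward waves with a positive peak change and of backward waves with a
negative one; ties count against direction-consistency, and a
direction with no eligible wave yields NaN rather than 0.

## Behaviour–force coupling

Per-sample state codes are 1 (forward), 0 (static), −1 (backward),
with half-open event membership. The pipeline is: baseline
subtraction (mean of the first 5 s) → clock alignment → state coding →
point-biserial correlation per active state,

    r_pb = ((M1 − M0)/S) · sqrt(n1·n0 / n²)

with M1/M0 the mean force over active/static samples, S the population
(divide-by-n) standard deviation of force over the included samples,
and n = n1 + n0. Samples carrying the *other* active code are excluded
so each r_pb is a clean two-group statistic; with the population
normalisation, r_pb is exactly the Pearson correlation between force
and the 0/1 activity indicator, which the tests assert to 1e-12.
Whole-sample rather than by-group pooling of S is the choice that
yields that identity. Undefined cases (no active samples, no static
samples, S = 0) are flagged, not raised. Baseline subtraction is a
constant shift and therefore cannot change r_pb; it is kept for
comparability of the force summaries (M1, M0). In synthetic trials the
first 5 s is the compression ramp, so the subtracted reference is
baseline/2 — harmless for the correlation for the same reason.

Clock alignment estimates a global offset by cross-correlating the 0/1
wave-state indicator with a like-shaped 0/1 force-activity series
(samples whose smoothed slope magnitude exceeds 0.5 mN s⁻¹, ramp
masked out). Two boxcar-like series over near-identical intervals peak
at the true lag; the residual shape bias is ≲ 0.05 s, and estimated
offsets below half the smoothing window snap to zero, making alignment
idempotent. Offsets beyond the 0.5 s tolerance are an error — the
tolerance is treated both as the correction range and the acceptance
bound. Both series are truncated at the last valid index of either
dataset; subtraction precedes truncation.

## The synthetic virtual larva

The generator emulates the statistical structure the analysis assumes,
not larval physiology:

| parameter | default | why |
|---|---|---|
| elastic coefficient k | 100 mN/mm | order-of-magnitude for a mm-scale hydrostat; with the 3° tilt it gives a ≈ 5 mN/mm force gradient so one ≈ 0.6 mm forward step yields ≈ +3 mN |
| forward / backward net increment | +3 / −7 mN (SD 1 / 1.5) | the empirical per-wave force changes |
| wave peak excursion | 12 mN (SD 1) | transient push well above the 5 mN prominence threshold, giving amplitudes near the observed ≈ 10 mN |
| forward / backward wave duration | 4 / 3 s (SD 0.5 / 0.4) | forward peristalsis is slower under load |
| inter-wave delay | 6 s (SD 1.5, floor 0.5 s) | spacings comfortably above the 3 s minimum peak distance |
| sensor noise | 0 (trials typically use 0.5 mN) | clean ground truth by default; 0.5 mN ≈ 10% of the prominence threshold |
| policy | p_forward 0.6, p_pause 0.1 | forward-dominated locomotion at low baseline force |
| sampling rate | 100 Hz | wave dynamics are ≳ 1 s; the detector is rate-agnostic, so desk-scale tests need not carry 5 kHz |

A trial is: linear 5 s ramp to baseline → wave slots drawn i.i.d. from
the policy, each a truncated-normal delay plus a wave profile —
raised-cosine rise over the first 60% of the wave to the peak
excursion, exponential relaxation (renormalised to hit the net offset
exactly at the wave end) over the remainder — with plateaus in
between, Gaussian noise added last. Net increments are truncated so
the resting force stays ≥ 0; the trial is cut and flagged when it
falls below 5 mN. All draws come from one seeded generator in a fixed
order, so trials are bit-reproducible. Position in the wedge is
tracked through the linear force field (force falls linearly with
distance from the slit, clamped at zero; gradient = k·tan(tilt) unless
set explicitly).

What the generator does **not** model — and hence what passing tests
cannot show about real recordings: wave directions are i.i.d. (no
behavioural autocorrelation or pressure-dependent retreat), there is
no between-wave drift from persistent body deformation, noise is white
Gaussian, and both directions share the same transient-excursion
distribution. That last choice keeps backward waves detectable, but it
means the per-sample backward coupling r_pb(backward) on synthetic
data is usually *positive* (backward waves still carry a transient
push), unlike in real recordings where backward epochs track declining
force. Only r_pb(forward) > 0 is construction-guaranteed. Likewise the
direction-consistency fractions emerge near 94% (forward) and 100%
(backward) rather than matching any particular empirical pair.

With the default SDs the detector can legitimately miss a wave whose
drawn net increment erodes its prominence below 5 mN (a +7 mN step
behind a 12 mN excursion leaves < 5 mN of relief). The deterministic
"noiseless" parameter set (all SDs zero, 8 s delays) therefore defines
the fixtures for exact-recovery and strict-monotonicity checks;
normal draws with positive SD cannot guarantee strict monotone peak
staircases.

## Training simulation

The controller is modelled exactly: commanded force starts at 100 mN;
in pro-forward mode each forward wave subtracts 20 mN and each
backward wave adds 20 mN (pro-backward mirrors this; naive applies no
feedback); the session ends at 0 mN (clamped; a safety cap of 600 s
catches inactive animals) and is repeated twice, each session
restarting from the initial force. Commanded changes settle linearly
over the 0.2 s controller response; with the 0.5 s minimum inter-wave
delay every wave sees a settled value. Exclusions: no peristaltic
activity (both training modes), or — pro-forward only — a run of ≥ 5
consecutive backward waves, each driving the commanded force up, with
no intervening forward wave; the run threshold fires at exactly 5.
Excluded larvae are replaced by fresh seeds so group size stays fixed
(10 per group by default). Naive animals run no feedback sessions, so
their policy cannot change. The test session is a 120 s no-feedback
trial at 25 mN in which forward and backward waves are counted.

The larva's learning rule is a simulator assumption, not biology: the
policy keeps a forward-vs-backward preference logit (pause probability
fixed); a commanded-force *drop* immediately after a wave nudges the
logit towards that wave's direction by the reward-sensitivity gain,
bounded at ±4; force increases leave the policy unchanged (a minimal,
reward-only mechanism). With the gain at 0 trained and naive groups
are distributionally identical — the null the tests check with a rank
test — and with gain 0.5 two pro-forward sessions move the test-session
forward count from ≈ 7.4 to ≈ 10.6 waves per 120 s.

## Problem sizes

The test-suite and acceptance script use desk-scale sizes chosen as
the package's own defaults: 100 random traces (≤ 2000 samples) for
detector-oracle equivalence; 50 seeded trials each for noiseless and
noisy recovery; ≥ 200 consecutive-wave pairs per direction for
increment recovery (forward-rich trials at 25 mN, backward-rich at
100 mN so backward bouts are not cut short by the 5 mN termination);
1000 random triples for the work oracle; 40 trials for the
direction-consistency fractions; 20 trials for coupling; 50–100
replicate experiments of 10 larvae per group for the training effect.
The whole suite runs in well under a minute on one CPU.

## Known limitations

- The delimitation rules (noise-tolerant trough start, slope-dwell
  end) are exercised against the generator's wave family; pathological
  real-world shapes (double-humped waves, slow drifts) may delimit
  differently.
- The elastic coefficient k has no literature default here; it scales
  the work estimate only and must be supplied for real preparations.
- The clock-offset estimator assumes waves are the dominant source of
  force activity; traces dominated by non-behavioural transients could
  mis-align within the ±0.5 s budget.
- Group-level significance testing of metric differences is out of
  scope; export the tidy CSVs and use standard statistics tooling.
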