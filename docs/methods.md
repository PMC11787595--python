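# Methods

This note documents the models implemented in `somnocal`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
can and cannot establish.

## Chamber gas dynamics and deconvolution

Each gas in the whole-room calorimeter follows the well-mixed balance
V·dC/dt = F·(C_in − C) + S, with chamber volume V = 14,490 L, ventilation
F = 80 L/min (110 L/min supported), and subject source S in L/min. The
forward model integrates this exactly for piecewise-constant minute
sources (a one-pole recursion, implemented as an IIR filter), and can add
i.i.d. Gaussian analyser noise with SD 2×10⁻⁵ in fraction units (0.002
percentage points, the repeatability of a process mass spectrometer on a
calibration mixture). Inlet composition is not part of the emulated
instrument's published description, so atmospheric defaults (20.93% O₂,
0.04% CO₂) are configurable parameters. All gas volumes are litres at one
common reference condition; no STPD/ATPS layer exists because the
synthetic data are generated in the same convention.

Recovery of minute sources is ill-conditioned: the time constant
V/F ≈ 181 min means a minute's metabolism changes the outlet fraction by
only (1−e^(−F/V))·S/F ≈ 6.9×10⁻⁵·S, comparable to sensor noise. The
inversion therefore solves

  min_s ‖K s − b‖² + λ‖D₂ s‖²

where K is the sampled impulse-response matrix of the mixing ODE, b the
observed trace minus the decay of its initial condition, and D₂ the
second-difference operator. λ is chosen by the Morozov discrepancy
principle with the customary safety factor: the largest weight whose
residual RMS stays below 1.05σ. At a bare 1.0σ target the crossing
occasionally lands at a severely under-smoothed weight (observed: a
9% RMSE night among otherwise 3–4% recoveries); the 5% margin removes
that failure mode at the cost of a few tenths of a percentage point in
typical accuracy. A noise-free trace short-circuits to the exact one-step
inversion of the recursion, which round-trips to machine precision.

Achievable accuracy is information-limited, not algorithm-limited: with
0.002-pp sensor noise, minute-VO₂ RMSE on a realistic night is 3–5% of
the mean for a male-athlete metabolic level, and the error grows as the
metabolic rate falls (the signal shrinks while sensor noise does not). An
edge-preserving total-variation penalty was evaluated and did not beat
the curvature penalty on stage-structured profiles with drift, so the
linear scheme was kept. Recovered rates are not clipped at zero; a
recovery dipping more than 25% of the series scale below zero sets a
conditioning flag.

## Energy expenditure and protocol segments

EE uses the Weir equation with coefficients 3.941 (VO₂), 1.106 (VCO₂) and
2.17 (urinary nitrogen, g/min; daily nitrogen is spread uniformly over
1440 min). The coefficients are explicit configuration
(`WeirCoefficients`) so protein-free variants can be swapped in;
kcal→kJ is fixed at 4.184. RER is undefined (NaN) where VO₂ = 0; EE is
still computed there.

Protocol segments are labelled half-open minute intervals anchored at
lights off. The sleep segment is exactly 480 min (960 30-s epochs); the
supine RMR segment is 30 min of which minutes 5–24 are averaged (the
first and last 5 min are discarded as unstable). The overnight time
course is the 16 means of consecutive 30-min bins of the sleep segment.

Participant-level QC excludes a night when the subject was awake more
than one third of the sleep period or the sleep-segment RER exceeds 1.00.
"Exceeds" is evaluated on the mean RER over the 8 h, not on single
minutes, because minute spikes are noise-dominated; with more than 20% of
sleep minutes lacking an RER the decision is reported as indeterminate
rather than guessed.

## Sleep metrics and sleep-period rates

Sleep onset is the first epoch of any sleep stage (AASM-consistent); last
awakening is the end of the last sleep epoch; SPT spans the two including
interior wake; TST = SPT − WASO; efficiency = 100·TST/SPT; the
sleep-quality ratio is 100·(N3+R)/TST. mSMR scans all 180-min windows at
1-min steps (301 candidates over 480 min), ties resolving to the earliest
window; mOMR is the full-night mean; both scale to kJ/day. Windows
containing missing minutes are skipped; a night missing more than 5% of
minutes has no mOMR. Stage-specific EE admits minute k for stage s only
when epochs 2k and 2k+1 both carry s; stages with no qualifying minutes
are reported absent, never as zero. Whether the 60-s continuity rule
should instead key on epoch runs spanning minute boundaries is not
determinable from the emulated protocol; the epoch-pair convention was
chosen for determinism and is fixed here.

## Reference rates

The three estimation equations (tissue-organ RMR; 77·FFM+1815 for SMR;
the FFM/FM/sex regression for OMR, sex coded 1 = male / 2 = female) are
pinned coefficient-by-coefficient in tests. Energy deficiency is strict:
ratio < 0.94 deficient, exactly 0.94 not deficient. Energy availability
uses the standard (intake − exercise EE)/FFM definition. PAL divides
total EE (here mRMR + activity EE) by mRMR.

## Synthetic cohort

The generator emulates a five-group design — 9 male runners, 8
amenorrheic runners, 9 menstruating runners, 10 female controls, 10 male
controls — with group FFM/FM/height means and SDs, sleep-stage duration
targets, wake-after-onset and sleep-period-time targets, and group-level
measured/estimated SMR ratios taken from the published group summaries.
FFM and FM are drawn independently per subject (normal, truncated at
physiologic floors) and body mass closes as their sum; tissue masses
partition FFM by fixed fractions (brain 2%, skeletal muscle 50%, bone 7%,
residual the remainder) with adipose tissue equal to FM. These fractions
are invented plumbing — configurable, documented, and not a claim about
any subject population. One published sleep-architecture column is
internally inconsistent (its stage durations sum to 454.4 min against a
printed total sleep time of 460.6 min); the generator targets the stage
sums, which are self-consistent with the printed SPT and WASO.

Hypnograms are built semi-Markov-style: nightly stage totals are drawn
around the group targets (CV 6%), split over five ~95-min ultradian
cycles with N3 front-loaded and REM back-loaded, each cycle laid out
N1–N2–N3–N2–wake–REM. Sleep-onset latency absorbs the gap between the
SPT target and the 8-h opportunity; a schedule overrunning the window is
shrunk proportionally rather than truncated (truncation biased REM, the
final-cycle-heavy stage, low). Cohort-mean stage durations land within
~2% of targets, comfortably inside the 10% generator contract.

True minute EE is basal × stage multiplier × drift × noise. The basal
level is the group's SMR ratio times the FFM-based SMR estimate, times a
between-subject log-normal factor (CV 6%); mRMR is a fixed 1.11 multiple
of basal, consistent with the published mRMR/mSMR gap. Stage multipliers
default to W 1.15, N1 1.05, N2 1.00, N3 0.95, R 1.08 — invented values
whose one anchored property is the ordering with slow-wave sleep lowest.
Drift is a slow sinusoidal dip (amplitude 4%, minimum mid-night); no
published within-night trajectory is machine-readable, so the amplitude
is a free parameter. Noise is multiplicative log-normal (mean exactly 1)
at two scales: minute-to-minute (CV 5% default) and night-to-night
(CV 3.3% default, set at the reported repeatability of sleeping metabolic
rate). Menstruating subjects can be simulated in both cycle phases; the
luteal night multiplies every minute by 1.027 (the configured +2.7%
elevation), reusing the same subject and hypnogram with fresh noise — a
within-subject design. Gas exchange is produced by inverting the Weir
equation at a target RER, which makes the generator the exact inverse of
the measurement chain and enables machine-precision recovery checks.

What the generator does *not* emulate: EEG waveforms, arousals and stage
fragmentation beyond the cycle layout, hormones, core temperature, meal
timing and diet-induced thermogenesis, and any within-group covariance
between body composition and sleep architecture. Passing tests therefore
show that the measurement chain recovers what the model puts in — not
that the model captures human nights.

## Statistics

Group comparisons: one-way ANOVA (any number of groups ≥ 2); identical
group means return F = 0, p = 1 rather than NaN. ANCOVA fits
value ~ group + FFM + FM by OLS and tests the group effect with type-II
sums of squares; covariates with zero variation are dropped so the test
reduces exactly to the unadjusted ANOVA; adjusted means are evaluated at
covariate grand means; a design-matrix condition number above 1e8 flags
collinearity. The 16-bin time course uses a univariate split-plot
decomposition: the group test runs on subject means (covariate-adjusted
when FFM/FM are supplied); time and time×group are tested against the
within-subject residual under sphericity (ε = 1, matching the design
computation). Per-bin post-hoc t tests are available and deliberately
unadjusted for multiplicity, with a note in the output. Paired phase
comparisons use the two-sided paired t test; zero-variance nonzero
differences are flagged undefined rather than given an infinite statistic.

The a-priori sample size inverts noncentral-F power for the
within-between interaction, λ = N·f²·m·ε/(1−ρ), df₁ = (g−1)(m−1)ε,
df₂ = (N−g)(m−1)ε, searching N upward in multiples of g from the smallest
size with positive error df. At the design settings (f = 0.4, α = 0.05,
power 0.95, ρ = 0.5, ε = 1, g = 2, m = 16) this yields N = 8 total, 4 per
group, with achieved power 0.988 — and 0.924 at N = 6, confirming
minimality. This noncentrality convention is the one used by the G*Power
program for this test family.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (generators refuse to
run without one), and identical seeds reproduce cohorts, hypnograms and
series byte-for-byte. The study-level checks use: full nights of 480 min
at 1-min resolution through the chamber; 1000 replicates of the
seven-pair phase comparison for parameter recovery and another 1000 for
type-I-error calibration (noise-free chamber leg, where deconvolution is
exact and cheap); 100 random nights for the window-scan oracle; and
20-replicate toy tables for the linear-model oracles. The noisy-chamber
accuracy checks run on single seeded nights because each regularized
inversion solves a 480-unknown penalized system with a λ search.

## Known limitations

- Deconvolution accuracy degrades for low-metabolism subjects; the 5%
  VO₂ bound holds for athlete-level nights but not universally.
- The split-plot time-course test assumes sphericity; no
  Greenhouse–Geisser correction is implemented (the emulated design used
  ε = 1).
- The QC RER rule is a mean-over-night interpretation; a single-minute
  reading above 1.00 does not exclude a night.
- Estimated rates take whatever body-composition values they are given;
  the package does not model the systematic offset between impedance- and
  DXA-derived composition, though the generator can emit an offset
  variant for sensitivity checks.
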