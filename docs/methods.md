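# Methods

This note documents the models, the synthetic-data assumptions, and the
numerical choices behind `exertvalue`, in the package's own terms.

## Conditioning controller and session simulator

The controller maps instantaneous heart rate to the sweet fraction of a
fixed 2 ml/min oral infusion:

    sweet_rate(HR) = total_rate · (HR − HR_b)² / (f·HRmax − HR_b)²,

with HR_b the heart rate at the participant's self-selected baseline speed,
HRmax = 220 − age, and threshold fraction f = 0.85. The stated endpoints
are 0% sweetness at HR_b and 100% at f·HRmax; behaviour outside that band
is not otherwise constrained, so the implementation clamps to [0,
total_rate] — the only physically realizable choice for a pump pair whose
rates must be non-negative and sum to the total. The curve between the
endpoints is the pure quadratic above. A baseline at or above the
threshold makes the denominator degenerate and raises a configuration
error rather than producing unbounded commands.

Interval sessions hold six cycles with peak targets 60–85 %HRmax in 5%
steps: 10 s ramp up, 120 s hold, 10 s ramp down, 90 s at baseline, with
180 s warm-up/cool-down bookends (~29 min total, matching the protocol's
~30 min). The simulated heart rate relaxes first-order toward the current
segment target with time constant `tau_sec` = 30 s — a typical
cardio-acceleration time scale; it is configurable because no value is
prescribed — plus optional per-second Gaussian noise (default SD 1 bpm).
Pump commands are sampled at 1 Hz (consumer HR-monitor cadence). One
pairing event per cycle is logged when the controller is on; its
`peak_sweet_fraction` is the controller output at the cycle's peak heart
rate. Three sessions per week for three weeks yields 9 × 6 = 54 pairings.

## Cohort generator

Each participant carries latent truth: age (normal 24.3 ± 5.2 y, clipped
18–50), HR/Speed at baseline (normal 22.3 ± 3.5 bpm per km/h — the
inverse-fitness index), a fractional training gain on HR/Speed at T1
(normal 8.5 ± 4%, zero in the NTR arm), a detraining fraction returning
most of that gain by T2 (normal 0.80 ± 0.15), log-normal per-day
discount constants for money/food/exercise (medians 0.02 / 0.25 / 0.17,
log-SD 1.1 — money discounted roughly an order of magnitude slower, all
right-skewed), an effort constant k_eff (log-normal, median 0.204, log-SD
0.15), and — in the COTR arm only — an additive conditioned reward
ΔM (normal 1.2 ± 0.3 on the generator's reward scale, see below). These
are conventions calibrated to the magnitudes a study of this design
reports, not claims about any particular sample; the joint distribution is
taken independent for want of better information.

### Speed selection model

A trial record is generated by maximizing model pleasantness over a speed
grid (3–16 km/h, 0.1 km/h resolution — treadmill walking-to-running
range):

    Vp(s) = R · [γ · g(f) + ΔM · f²] / (1 + k_eff · RPE(f)),

where f = (HR − 60)/(HRmax − 60) is the heart-rate reserve fraction at
speed s (HR = HR/Speed · s, clamped at HRmax), RPE(f) = 6 + 14f is the
affine exertion model on the reserve (RPE is strongly heart-rate coupled;
no exact form is prescribed, so the simplest monotone map onto the 6–20
scale is used), g(f) = f(2f_p − f)/f_p² is a concave reward-availability
curve peaking at reserve fraction f_p = 0.5, γ = HR/Speed(T0) /
HR/Speed(t) is the fitness-relative reward (rises with training), ΔM
applies only at T2 in the conditioned arm, weighted f² because the
conditioned reward was learned under a controller whose unconditioned
stimulus grows quadratically with heart rate, and R = 2.8 scales Vp so
that 5·Vp lands on the observed Feeling Scale range (~+4 at the optimum).

Why a concave g rather than a speed-constant reward: with M constant over
the grid, Vp is monotone decreasing in speed and the argmax degenerates to
the slowest speed for every participant and time point — no training or
conditioning effect on selected speed could exist. A single-peaked reward
in strain is the minimal structure under which (i) training (lower
HR/Speed) moves the optimal *speed* up while leaving the optimal heart
rate unchanged, (ii) full detraining restores the baseline optimum
exactly, and (iii) a positive ΔM moves the optimal *strain* itself up —
each a weakly monotone shift by an argmax-with-increasing-addend argument,
and each verified by test. With f_p = 0.5 and k_eff = 0.204 the
deterministic optimum sits at f* ≈ 0.40 (HR ≈ 114 bpm, RPE ≈ 11.6,
speed ≈ 5.1 km/h for average fitness), in the observed range for
self-paced exercise in non-athletes. Observation noise: Gaussian on heart
rate (SD 3 bpm) and on FS/RPE before rounding (SD 0.7 scale units),
with FS = round(5·Vp + ε) clipped to −5..+5 and RPE clipped to 6..20.

A 200-cohort Monte-Carlo of this generator puts the sampling distribution
of the 24-participant mean T0 speed at 5.23 ± 0.18 km/h; the calibration
test asserts a fresh cohort lands within two of those standard errors of
the 5.25 km/h reference value.

### Choices

A binary intertemporal choice values the immediate option at its amount
and the delayed one at A/(1+kD) with the profile's commodity-specific k;
with zero choice noise the larger value wins (seeded fair coin at exact
equality — avoids order bias), otherwise the immediate option is chosen
with logistic probability of the value difference over the noise
temperature (default 1.0, in commodity units).

## Adjusting-amount task

Per non-zero delay (1, 7, 30, 60, 180 days; delay 0 only frames the
immediate option and is never fitted), the delayed reward is anchored at
the menu maximum and the immediate amount follows bisection on
[0, max]: an immediate choice lowers the top of the bracket, a delayed
choice raises the bottom. Stopping: six choice reversals or bracket
narrower than one menu step (the smallest gap between adjacent menu
amounts: £3 for money, 5 for food/exercise), whichever first; the IP is
the final bracket midpoint. Two boundary conventions: a staircase in which
the delayed (resp. immediate) option was never declined resolves to the
anchor amount (resp. zero), since the data then bound the IP only from one
side. For any noise-free hyperbolic responder this recovers A/(1+kD)
within one menu step at every delay, and the recovered IP is a monotone
function of the true one, so delay-monotonicity is inherited exactly.
Delay order is shuffled per seed and distractor trials (re-presentations
of earlier questions, default 15% rate) are interleaved; both are verified
to leave deterministic-responder IPs unchanged. A staircase exceeding the
trial budget flags the curve instead of failing.

## Mazur fit, exclusion, transforms

Fits minimize Σ_D (IP_D/A − 1/(1+kD))² over k ≥ 0. Normalizing by the
anchor A puts the three commodity scales on one axis and renders k
scale-invariant (tested). The optimizer is a log-spaced coarse scan
(k = 0 plus 201 points over 1e-8..100) followed by bounded Brent
refinement between the bracketing neighbours; the scan guards against the
flat tails of the objective, and tests hold the result to within 1e-3 of
a 20 001-point dense-grid oracle. R² uses the standard 1 − SS_res/SS_tot
on normalized IPs about their mean. A constant curve has SS_tot = 0: R²
is reported as NaN and inclusion reduces to whether the k = 0 hyperbola
fits exactly (it does iff the constant is A). Exclusion removes fits with
R² strictly below 0.7 (R² = 0.7 is retained). Pre-statistics transforms
are the natural log for k (base immaterial for rank or linear-model
conclusions; recorded in output metadata) and the square for RPE.

## Effort model

Observables map to Vp = FS/5 (plain scale-maximum division — the value of
a neutral rating is 0 and negative pleasantness is allowed to carry
negative value; this convention is what makes pooled group FS means of
4.27 and 4.335 correspond to normalized values 0.854 and 0.867), C = raw
RPE, and M = ref/(HR/Speed) + ΔM with ref the cohort baseline mean
HR/Speed (the mapping is a named, swappable strategy; the pipeline's
fitter always uses ΔM = 0 — it must not know about conditioning, that
is the point of the diagnostic). The shared k per condition minimizes
Σ (vp_i − M_i/(1+kC_i))² with the same multi-start bounded scalar scheme
(grid-oracle-tested), and the fit carries an exact two-sided sign test of
measured-minus-model Vp (binomial null p = ½, zeros dropped and counted);
a Wilcoxon signed-rank statistic is attached alongside when n ≤ 25, since
"sign test" naming is ambiguous between the two in parts of the
literature. Degenerate inputs (all costs and rewards identical) return a
flat-objective flag rather than an error. The central property, verified
on noise-free synthetic cohorts: the fitted k strictly decreases as an
unmodeled reward surplus ΔM grows — lower k in a conditioned arm is the
signature of a learned reward the model's M omits, not of cheaper effort.

## Pipeline

Stage order: cohort → conditioning sessions (controller on for COTR,
neutral-only for TR) → trial records (NTR assessed at T0/T1 only) →
discounting tasks (money at T0; food and exercise at every assessment) →
Mazur fits and exclusion → shared-k effort fits for conditions T0, T1,
T2-TR, T2-COTR → CSV bundle and text report. Summary tables use the n−1
SD (NaN for singletons) and linear-interpolation quantiles (conventions
recorded here because none are prescribed); rows are sorted on the group
keys, so summaries are invariant to input row order. Randomness descends
from a single root seed through spawned child sequences per participant
and stage, and every output embeds the config hash and seed, making the
bundle byte-reproducible (tested). Group inferential statistics (mixed
ANOVA/ANCOVA, multiple regression) are deliberately not reimplemented:
the tidy CSVs are the interface to any standard stats package.

## Problem sizes and limitations

Default sizes — 58 participants (10/24/24), nine 29-minute sessions at
1 Hz for the 48 trained participants, ~12 staircase trials per delay —
run the full pipeline in about a second; the test suite's recovery checks
use 100–200 simulated curves per claim.

The generator emulates group-level structure (training gain and
detraining of HR/Speed, skewed discount constants, an additive
conditioned reward expressed at follow-up) but not: correlations between
latent traits, sex- or age-dependent response structure, session-to-session
learning or fatigue, dropout, or time-varying discount constants (the
transient post-training dip in exercise discounting a real cohort can show
is absent — each profile carries one k per commodity). Passing recovery
tests therefore demonstrates the estimators are consistent under the
stated generative assumptions, not that those assumptions exhaust real
behaviour. The effort fit's reward mapping is one deliberately simple
convention; fitted shared-k magnitudes depend on it, so only
within-convention contrasts (between time points or arms) are
interpretable — the direction and relative size of the conditioned-arm
drop, not the absolute k, is the robust quantity.
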