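# Methods

## Coordinate and epoch conventions

Position is ingress-positive millimetres; zero is the instrument origin,
not the behavioural baseline. Every trial is re-baselined by subtracting
the mean position over a configurable pre-stimulus window (default 1 s
immediately before stimulus onset). The baseline-window duration is a
free parameter because the quantity "change in burrow position with
respect to baseline" does not pin one down; 1 s covers two full breathing
cycles at the 2 Hz default, which makes the per-trial baseline mean
essentially phase-invariant.

Epochs are half-open `[start, end)` and convert to sample indices with
`floor(t·fs)` on both bounds. Equivalently, sample *i* (covering
`[i/fs, (i+1)/fs)`) belongs to an epoch iff its period's right edge falls
in `(start, end]`. This is deterministic, off-by-one-free, and identical
at 1 kHz and 10 kHz; all operations are sample-rate-parametric and the
suite exercises both rates. The default analysis rate is 1 kHz.

## The virtual mouse

The simulator emits the assay's phenomenology as a sum of components:

* **Breathing** — downward-only half-rectified sine pulses at
  `breathing_rate` (default 2 Hz) and `breathing_amp` (0.3 mm). The
  rectification matches the observation that breathing deflects the
  burrow downward from rest, and concentrates power in the 1–4 Hz band.
* **Ingress** — a logistic rise to `ingress_amp` (15 mm) whose 5%→95%
  rise takes `ingress_rise_time` (50 ms). The drawn onset latency is a
  zero-truncated Gaussian with mean 18.5 ms and cv 0.07 (only moments are
  known, so a truncated Gaussian is the minimal choice). The waveform is
  aligned so displacement crosses 5% of amplitude exactly at the drawn
  latency — the movement-onset reference that, at the default amplitude,
  coincides with the detector's 0.75 mm onset criterion. Because a
  whole-body ingress physically overrides breathing micro-deflections,
  the breathing component fades out in proportion to the ingress wave as
  it passes that reference; without this, breathing-phase jitter at the
  threshold crossing would corrupt latency estimates with variance that
  the real movement onset does not have.
* **Flinch** — one full sine cycle (`flinch_amp` 1 mm, 200 ms): a
  biphasic transient with exactly zero net displacement at its end.
* **Trembling** — a Hann-enveloped sinusoid at `tremble_freq` (default
  20 Hz; the phenomenon is only described as "high-frequency", so this is
  an exposed placeholder, not a measured value).
* **Egress bout** — a smooth downward pulse of depth `egress_bout_depth`
  (22 mm) and duration ~1 s.
* **Sensor noise** — white Gaussian, `noise_sd` 0.02 mm (a laser
  displacement sensor's noise floor is far below the behavioural scale;
  the exact value is a placeholder).

Response emission is Bernoulli with per-stimulus habituation
`p_n = p0·exp(−decay·(n−1))`, counted separately per stimulus id so a
novel stimulus resets to `p0`. Only early-versus-late response rates are
known empirically; exponential decay is the simplest law consistent with
them, and the decay rate is exposed.

In closed loop the realised position is the mouse's desired position
clipped by the actuator command (the tether constrains ingress, never
pushes). When the tether is taut the mouse pulls with force
`resist_force_amp·(1−e^(−t/τ_rise))·e^(−t/resist_decay)` (defaults 700 mN,
0.1 s, 5 s) — a bout that rises quickly and decays as the animal gives
up, always ending below any positive quiet threshold. Bouts survive slack
flickers shorter than 0.2 s so intermittent tautness does not restart
them at full amplitude. All ingress aspirations have finite durations
(evoked ingress holds `ingress_hold`, spontaneous attempts
`spont_ingress_duration`, the naive animal's initial struggle
`initial_ingress_duration`), which bounds every pullback struggle and
guarantees the trial machine's liveness with a compliant animal.
Spontaneous ingress attempts arrive as a Poisson hazard
(`spont_ingress_rate`, default 0.02 Hz, matching >30 s inter-ingress
intervals in acclimated animals).

What the simulator does **not** emulate: limb kinematics and posture,
platform-variant physics, sensory adaptation distinct from habituation,
slow drifts in motivation, and any coupling between neural activity and
behaviour (spike trains for the regression analyses are generated
independently of the behaviour channels). Passing tests therefore show
that the pipeline recovers what the generative model puts in — they do
not validate the generative model against real animals.

## Controller

The trial machine has phases RETRACTING → WAIT_FORCE_QUIET → ADVANCING →
ARMED → STIMULUS_OPEN_LOOP → POST_OPEN_LOOP, with ARMED → ABORTED →
RETRACTING on spontaneous ingress. Numeric gate defaults (force-quiet
50 mN, θ_p 2 mm, SD threshold 0.5 mm over a 2 s window, hold 5 s) are
user-specified quantities in the real instrument; the defaults here are
consistent with the behavioural scales (sub-millimetre quiescence,
tens-of-mN resistance tails) and everything is configurable. The hold
gate and the SD gate run **concurrently** — both must hold at the moment
of delivery; whether the original instrument ran them sequentially is not
documented, so this interpretation is flagged here. The rolling SD is
causal (window ending at the current sample) with the population
denominator, for determinism and online computability. The actuator is a
rate-limited follower (`actuator_speed`, default 100 mm/s); only its part
number is documented, not its dynamics. Armed periods carry a timeout
(default 60 s) so liveness holds even for a pathological mouse.

`replay_gate_check` is an independent auditor: it recomputes every gate
directly from the recorded channels (position below θ_p over the full
hold window, trailing-window population SD below threshold, a
sub-threshold force sample between pullback and stimulus) without
consulting the state machine, with a 1e-6 numerical tolerance.

## Detection

Thresholding is applied to raw re-baselined samples — no smoothing —
because the onset definition names the *first sample* exceeding 0.75 mm.
The onset search runs from stimulus onset to the end of the post epoch
(bounded for determinism; pre-onset crossings are excluded by
construction). Ingress takes precedence over flinch; trembling is an
independent flag scored on the pre-ingress portion of the stimulus epoch,
since the ingress step itself would dominate the spectrum and trembling
is observed to precede ingress on the same trial. Flinch thresholds
(peak ≥ 0.3 mm, |net| ≤ 0.2 mm at +500 ms) are operational inventions for
a qualitatively described behaviour. Spectral scores use a detrended,
Hann-windowed periodogram; the analytic band-power oracle in the tests is
the contract, not the method choice. Force integration uses a left
Riemann sum at the sample period, stopping when force stays below the
quiet threshold for a configurable consecutive duration (0.5 s default);
agreement within 1% of 10×-oversampled trapezoidal quadrature is tested.

## Statistics

The two-proportion z-test uses the pooled variance, no continuity
correction, and an upper-tail p for the one-sided alternative. This
triple is canonical here because it is the unique combination that makes
published ingress-count contrasts exactly recomputable from the counts;
the suite pins five such values at printed precision. Counts are
recovered from printed proportions via the unique k with
round(100·k/n) matching the printed percentage; one published contrast
whose counts cannot be recovered unambiguously is excluded. The normal
kernel is `erfc(z/√2)/2` (relative error ~1e-15 over the relevant range,
checked against arbitrary-precision evaluation).

The rank-sum test uses average ranks for ties and dispatches on combined
sample size: full enumeration of rank assignments for n ≤ 12, otherwise a
tie-corrected normal approximation with continuity correction. At n ≤ 12
the exact two-sided p-lattice is coarse (steps well above 0.01), so the
exact path is the only one that can meet a 0.01 agreement bar against a
permutation oracle; the approximation is reserved for sizes where it is
accurate. Spearman correlation uses average ranks, a t-distribution
approximation for n > 10, and exact permutation below.

## Study sizes used by the acceptance script and tests

Chosen once, as the package's own experiment designs:

* latency recovery: 500 strong-puff trials at 2 kHz (quantization bias
  +0.25 ms ≈ 1.4% of the 18.5 ms mean, well inside the 5% band);
* detected-rate checks: 150 trials per condition at p = 0.72 / 0.26;
* controller audit: 1000 sessions at 1 kHz, one trial each, with mouse
  and gate parameters randomized per session (resistance decay 0.3–1.5 s,
  spontaneous-ingress hazard up to 0.3 Hz, hold 1–2.5 s) — short
  resistance bouts keep each session a few seconds long without touching
  the gate logic being audited;
* habituation replicates: 5 mice × 15 trials, p₀ = 0.67, decay 0.5;
* extinction replicates: 20 mice × 12 trials with high-latency
  probability rising linearly 0.05 → 0.45. The cohort is sized by a power
  analysis: detecting a positive Spearman trend at α = 0.05 in ≥ 90% of
  replicates needs ~20 animals' worth of per-trial fractions at this
  effect size (9 animals give only ~75% power);
* calibration: 20,000 null count pairs at n = 50, p = 0.5.

## Known limitations

* The generative model is phenomenological; amplitudes and time constants
  not reported numerically (tremble frequency, flinch shape, noise floor)
  are placeholders and clearly exposed as parameters.
* The closed-loop mouse's "give-up" dynamics (finite aspiration
  durations) are a modelling convenience; real acclimation dynamics are
  slower and history-dependent.
* Force and position are noiseless in their interaction (no tether
  elasticity); the force channel is a pure bout waveform.
* Empirical values that derive from real animals (e.g. median
  conditioned-response latencies, specific ingress likelihoods) are used
  as default simulator parameters, not as quantities this package claims
  to reproduce from scratch.
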