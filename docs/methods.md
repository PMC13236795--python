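# Methods

This note documents the models, algorithms and numerical choices behind
`stepinit`, and what its synthetic-data validation does and does not show.

## Experimental design model

The paradigm is a go/no-go forward single-step task. Each trial shows a
fixation cross for 2 s, then a face for 1 s; face onset is therefore at 2.0 s
on the trial clock. Two conditions are modelled per participant, each with
exactly 30 go and 10 no-go trials in a seeded random order:

* **neutral-versus-emotional** — 10 identities (5 male, 5 female) × the three
  emotional expressions (fearful, angry, happy) as go trials, plus each
  identity once with a neutral expression as no-go.
* **face-gender** — go/no-go depends only on face gender. Go: the 5
  same-gender identities × 3 expressions, shown twice. No-go: 3
  opposite-gender identities × 3 expressions plus one identity showing anger
  only. Which identities serve as the 3+1 no-go faces is not dictated by the
  counts; the package picks them deterministically in lowest-label order.

Half the participants are go-men, half go-women (seeded assignment, exact
split); condition order is randomized per participant from a derived
sub-seed. The inter-trial interval beyond the fixed visual sequence is a
configurable constant (default 3 s) and plays no role in the analysis.

## Measurement model (kinematics)

All channels are filtered with a 10 Hz low-pass 4th-order Butterworth applied
forward and backward (`scipy.signal.filtfilt`, reflective padding of 3× the
filter polynomial length). "4th order" is the per-pass design order — the
biomechanics convention — so the effective magnitude response is the squared
single-pass response and the gain at 10 Hz is exactly 0.5. Filtering is
applied to the raw force/moment channels *before* the CP division; a config
switch (`FilterConfig.filter_before_cop`) flips the order, which matters only
in the third decimal at these noise levels.

Axis convention: +y is forward (toward the stimulus), so APA excursions of the
CP are negative. The plate origin is taken on the surface (`z_offset = 0`,
configurable for real hardware where the CP formula needs the origin-to-surface
term `−Fy·z_offset`).

CM acceleration uses Newton's law with the quiet-stance bias removed — the
mean Fy over the same 500 ms pre-onset window used for initial posture — which
enforces the modelling assumption that `y″G = 0` at rest. CM velocity is the
trapezoidal integral started at the detected movement onset with
`y′G(t0y) = 0`; samples before onset are zero.

## Event detection

`t0y` is the time at which CP velocity first reaches 10 % of its first
qualifying backward peak. A peak qualifies when it exceeds a noise floor
(5 × the pre-onset SD of `y′P`, with an absolute floor of 0.005 m/s so the
rule is defined for noiseless data) **and** reaches at least 30 % of the
largest backward velocity in the search window. The second clause is a
robustness guard: with band-limited channel noise, an isolated noise bump can
clear a pure SD-based floor (~1 trial in 300 at default noise), which would
produce spuriously early onsets; requiring the peak to be commensurate with
the trial's real APA removes these without affecting omission detection
(an omitted step has no large backward peak, so the floor still governs).
The 10 % crossing is searched *backward* from the peak, so late baseline
wiggles cannot trigger onset, and is located with linear interpolation
between samples (sub-millisecond resolution at 1000 Hz).

The APA peak is the first local minimum of `yP` after `t0y` with at least
0.5 cm prominence (an order of magnitude below typical APA amplitudes). The
amplitude is referenced to `yP(t0y)`; a switch references it to the initial
posture instead. `tV` is referenced to face onset, not to `t0y`: observed tV
values (~950–990 ms) equal RT plus ~350 ms only on that reading; this too is
switchable (`EventConfig.t_v_from_onset`). Ties at equal velocity maxima
resolve to the earliest sample. The onset search horizon is 2.5 s after face
onset.

QC applies rules a–d in order and reports the first failure, so a trial with
both an out-of-range RT and baseline motion is counted under the RT rule. RT
bounds are inclusive. "Considerable" pre-onset CP movement is not a published
number; the default threshold is 1 cm peak-to-peak over the 500 ms window.
Wrong-limb detection is metadata-based: AP-only channels cannot reveal the
stepping limb physically.

## Synthetic-data generator

The generator inverts the measurement chain. Latent per-trial outcomes follow

    y = mu(emotion, condition) + u_participant + w_face + eps

with independent Gaussian crossed intercepts and residuals, drawn per outcome
(outcomes are mutually independent at the latent level — a simplification;
real outcomes are correlated within trial). Default cell means reproduce the
reference estimates for this paradigm: RT 604/637 ms, initial posture
−44/−43.9 cm, APA duration 265/250 ms, APA amplitude −4.57/−3.97 cm, tV
948/994 ms, V 0.563 m/s (face-gender / neutral-versus-emotional). Emotion
structure within condition is flat except where the paradigm shows it: under
neutral-versus-emotional, APA duration 238 (angry) / 260 (fearful) / 252
(happy) ms, amplitude −3.55 / −4.25 / −4.11 cm, tV 1010 / 961 / 1011 ms —
free cells chosen once so the condition marginals above are preserved.
Trial-level SDs are *plausible*, not published: participant SDs are
back-solved from the reference standard errors (SE·√24), face SDs are set
small, residual SDs at typical trial-to-trial variability (e.g. 80 ms for RT,
0.8 cm for amplitude). Body mass ~ N(70, 10²) kg, g = 9.81 m/s².

Waveforms are chosen for stability under the 10 Hz zero-lag filter, since the
physiology fixes no analytic shape:

* **CP descent** — velocity lobe `g(τ) = τ²(1−τ)`: C¹ at the start (no
  acceleration jump for the filter to smear into the onset region) and a
  *transversal* velocity zero at the backward extremum, so the extremum is a
  sharp quadratic minimum that survives filtering at the sample level.
* **CP forward rise** — velocity lobe `σ(1−σ)²`, acceleration-matched at the
  extremum, ending on a forward plateau.
* **CM acceleration** — one full sine period starting at `t0y`: the positive
  lobe integrates to exactly V at its midpoint tV (again a transversal
  maximum), the negative lobe models the braking after push-off.

Because the latents are *defined* as what the standard measurement chain
reports, the generator calibrates the CP construction targets against that
chain (filter → velocity → 10 % criterion → extremum) with a two-iteration
fixed-point correction; the uncorrected discrepancy is up to ~1.5 ms / 0.05 cm
at the shortest APAs and an order of magnitude smaller after calibration.
Channel noise is additive white Gaussian (Fy and Fz 0.5 N, Mx 0.3 N·m); Mx is
built from the noisy Fz so the recovered CP is exact at zero noise and
unbiased under noise. Latents are clipped to a feasibility box (e.g. RT
230–1900 ms, tV ≥ RT + 150 ms) that essentially never binds at default SDs.

Artifact trials for QC validation: `no_step` (flat CP and force after onset),
`wrong_limb` (clean step, mismatched limb flag), `early_rt`/`late_rt` (latent
RT 150/2100 ms), `baseline_motion` (a smooth 2 cm CP excursion inside the
pre-onset window followed by a clean step).

**What passing tests show** — that the pipeline recovers the truth of records
whose structure it assumes: single clean APA, stationary baseline, white
channel noise. Real recordings add tremor, drift, multi-peaked APAs, cross-talk
and outcome correlations the generator does not emulate; recovery there is an
empirical question the synthetic validation cannot answer.

## Mixed-model estimation and inference

Per outcome the model is `value ~ emotion*condition + (1|participant) +
(1|face)` with sum-to-zero factor coding (Type-III-style marginal tests;
treatment-coded readouts can be obtained by recoding the input). REML
estimation profiles out the residual variance and the fixed effects and
maximizes over the two variance ratios γ = σ²_g/σ²_e, parameterized as
θ² ≥ 0 and searched by Nelder-Mead (criterion tolerance 1e-8) from five fixed
starting points (one when warm-started in simulation loops). All linear
algebra runs through the q×q capacitance matrix (q = participants + faces)
via the Woodbury identity, making a fit on the full 1440-trial design a few
tens of milliseconds. Ratios below 1e-8 snap to the boundary and are flagged;
a zero-variance response flags the residual component instead of failing.

Satterthwaite df for a contrast ℓ: df = 2f²/(gᵀAg) with f = ℓᵀC(ϑ̂)ℓ, g the
central-difference gradient of f in the variance components ϑ, and A the
asymptotic covariance of ϑ̂ (2 × the inverse numeric Hessian of the REML
deviance; relative step 1e-4). Components at the boundary are excluded from
ϑ. Multi-df terms follow the lmerTest recipe: eigendecompose ℓCℓᵀ into
independent 1-df contrasts, Satterthwaite each, and pool via
df = 2E/(E−q), E = Σ νᵢ/(νᵢ−2). With both random components at zero the df is
returned analytically as N−p (the OLS collapse). Agreement with R's
`lmerTest` is at the fourth decimal on crossed designs (see
`tests/test_lmm.py`).

EMMs are fixed-effect predictions on the factor grid with equal weights; SEs
come from σ̂²(XᵀV̂⁻¹X)⁻¹. Pairwise contrasts use the studentized-range
distribution (`scipy.stats.studentized_range`) with family size k and the
contrast's Satterthwaite df; for k = 2 this reduces to the unadjusted t test.
Effect sizes use the Edwards semi-partial mapping
R² = (q·F/df)/(1 + q·F/df) with the Satterthwaite df standing in for the
Kenward-Roger value — exact KR covariance inflation is out of scope, and on
designs this size the two df agree to well under 1 %.

## Power procedure

`power_simulation` mirrors the simr approach: draw responses from the crossed
generative model with a standardized effect injected (a shift of the fearful
cells by `effect × sd_residual`), refit, test the emotion term with the
Satterthwaite F at α = 0.05, and report the rejection fraction with a
Clopper–Pearson 95 % interval. At effect 0 this is a calibration run and
lands inside the exact binomial interval around α; power is non-decreasing in
effect size and in participant count.

Simulation studies use a balanced emotion×condition grid with rotating face
assignment (`simulation_design`), by default 24 participants × 10 faces with
4 trials per participant×condition×emotion (N = 576) — the crossed structure
of the real design at reduced trial counts, which keeps hundreds of refits
cheap while preserving the df regime of the full design.

## Known limitations

* Mediolateral mechanics are not modelled; the wrong-limb rule is
  metadata-only.
* The generator's outcomes are latently independent; covariance between RT,
  APA metrics and tV in real data is not emulated.
* Exact Kenward-Roger machinery (covariance inflation) is approximated by
  Satterthwaite df throughout.
* Heel-off/foot-contact events and double-support decomposition are out of
  scope; `tV` is the only motor-performance timing computed.
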