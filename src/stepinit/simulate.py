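"""Synthetic force-plate trials with a known crossed-random-effects truth.

The generator plays the role of the laboratory: it draws latent per-trial
outcomes from a cell-mean + crossed-random-intercept model

    y = mu(emotion, condition) + u_participant + w_face + eps,

then *inverts* the measurement chain, writing force-plate channels (Fy, Fz,
Mx) whose derived kinematics reproduce those latents. Because the onset
detector defines t0y as the 10 %-of-first-peak crossing of CP velocity, the
CP waveform is calibrated so that the crossing, the first backward extremum
and the CP drop between them land exactly on the latent reaction time, APA
duration and APA amplitude; likewise the CM acceleration pulse integrates to
exactly V at tV. A zero-noise record therefore round-trips through the
pipeline to within a sample.

Waveforms (chosen for filter stability, the physiology fixes no shape):

* CP descent — velocity lobe g(tau) = tau^2 (1 - tau): smooth (C1) at the
  start so the 10 Hz zero-lag filter does not bias the onset crossing, but
  with a transversal velocity zero at the backward extremum so the extremum
  survives filtering as a sharp quadratic minimum.
* CP forward rise — velocity lobe sigma (1 - sigma)^2, acceleration-matched
  at the extremum, ending on a forward plateau.
* CM acceleration — one full sine period starting at t0y: the forward lobe
  integrates to V at the midpoint tV (a transversal velocity maximum), the
  trailing negative lobe brings the modelled push-off back to zero.

Channel noise is additive Gaussian (white); Mx is built from the *noisy* Fz
so the CP recovered by the pipeline is unbiased under noise and exact
without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .design import EMOTIONS_GO, Schedule
from .events import OUTCOME_NAMES, EventDetectionError, apa_phase, detect_t0y
from .kinematics import GRAVITY, differentiate, lowpass_zero_lag

# ---------------------------------------------------------------------------
# descent-shape constants: g(tau) = tau^2 (1 - tau),  S = integral of g

_G_PEAK = 4.0 / 27.0  # g at tau = 2/3
_S1 = 1.0 / 12.0  # S(1)


def _S(tau: float | np.ndarray) -> float | np.ndarray:
    return tau**3 / 3.0 - tau**4 / 4.0


#: tau of the 10%-of-peak crossing on the rising flank of g
TAU_CROSS = float(brentq(lambda t: t * t * (1 - t) - 0.1 * _G_PEAK, 1e-6, 2.0 / 3.0))


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentOutcome:
    """True per-trial values of the six outcomes (units as reported)."""

    reaction_time_ms: float
    initial_posture_cm: float
    apa_duration_ms: float
    apa_amplitude_cm: float
    v_peak_m_s: float
    t_v_ms: float


@dataclass
class ForcePlateRecord:
    """One trial's raw plate channels plus acquisition metadata."""

    time: np.ndarray  # s, uniform grid from 0
    fy: np.ndarray  # AP shear force, N (+y forward)
    fz: np.ndarray  # vertical force, N
    mx: np.ndarray  # moment about the mediolateral axis, N*m
    sampling_rate: float
    face_onset: float  # s on the record clock
    mass: float  # kg
    z_offset: float = 0.0  # plate origin-to-surface distance, m
    meta: dict = field(default_factory=dict)


def _default_cell_means() -> pd.DataFrame:
    """Default generative cell means, (emotion, condition) x outcome.

    Condition-level marginals follow the reference estimates for this
    paradigm (RT 604/637 ms, posture -44/-43.9 cm, APA duration 265/250 ms,
    amplitude -4.57/-3.97 cm, tV 948/994 ms, V 0.563 m/s for the face-gender
    and neutral-versus-emotional conditions respectively); within-condition
    emotion structure is flat except where the paradigm shows it (shorter
    APAs and later tV for anger than fear under neutral-versus-emotional).
    """
    fg = {
        "reaction_time_ms": dict.fromkeys(EMOTIONS_GO, 604.0),
        "initial_posture_cm": dict.fromkeys(EMOTIONS_GO, -44.0),
        "apa_duration_ms": dict.fromkeys(EMOTIONS_GO, 265.0),
        "apa_amplitude_cm": dict.fromkeys(EMOTIONS_GO, -4.57),
        "v_peak_m_s": dict.fromkeys(EMOTIONS_GO, 0.563),
        "t_v_ms": dict.fromkeys(EMOTIONS_GO, 948.0),
    }
    nve = {
        "reaction_time_ms": dict.fromkeys(EMOTIONS_GO, 637.0),
        "initial_posture_cm": dict.fromkeys(EMOTIONS_GO, -43.9),
        "apa_duration_ms": {"angry": 238.0, "fearful": 260.0, "happy": 252.0},
        "apa_amplitude_cm": {"angry": -3.55, "fearful": -4.25, "happy": -4.11},
        "v_peak_m_s": dict.fromkeys(EMOTIONS_GO, 0.563),
        "t_v_ms": {"angry": 1010.0, "fearful": 961.0, "happy": 1011.0},
    }
    rows = []
    for cond, table in (("face_gender", fg), ("neutral_vs_emotional", nve)):
        for emo in EMOTIONS_GO:
            rows.append(
                {"emotion": emo, "condition": cond}
                | {k: table[k][emo] for k in OUTCOME_NAMES}
            )
    return pd.DataFrame(rows).set_index(["emotion", "condition"])


@dataclass
class GenerativeParams:
    """Tunable truth of the generator; defaults emulate the study conditions.

    Trial-level SDs are plausible values consistent with the reference
    standard errors (participant SD ~ SE * sqrt(24)); they are not published
    quantities.
    """

    cell_means: pd.DataFrame = field(default_factory=_default_cell_means)
    sd_participant: dict = field(
        default_factory=lambda: {
            "reaction_time_ms": 60.0,
            "initial_posture_cm": 1.7,
            "apa_duration_ms": 40.0,
            "apa_amplitude_cm": 1.0,
            "v_peak_m_s": 0.11,
            "t_v_ms": 130.0,
        }
    )
    sd_face: dict = field(
        default_factory=lambda: {
            "reaction_time_ms": 15.0,
            "initial_posture_cm": 0.1,
            "apa_duration_ms": 10.0,
            "apa_amplitude_cm": 0.15,
            "v_peak_m_s": 0.01,
            "t_v_ms": 15.0,
        }
    )
    sd_residual: dict = field(
        default_factory=lambda: {
            "reaction_time_ms": 80.0,
            "initial_posture_cm": 1.0,
            "apa_duration_ms": 60.0,
            "apa_amplitude_cm": 0.8,
            "v_peak_m_s": 0.08,
            "t_v_ms": 120.0,
        }
    )
    mass_mean_kg: float = 70.0
    mass_sd_kg: float = 10.0
    sampling_rate: float = 1000.0
    face_onset: float = 2.0
    force_noise_sd: float = 0.5  # N, Fy
    fz_noise_sd: float = 0.5  # N
    moment_noise_sd: float = 0.3  # N*m
    min_record_after_onset_s: float = 2.5

    def __post_init__(self) -> None:
        for d in (self.sd_participant, self.sd_face, self.sd_residual):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be non-negative")
        if self.sampling_rate <= 20.0:
            raise ValueError("sampling rate must exceed twice the 10 Hz filter cutoff")
        cm = self.cell_means
        if (cm["apa_amplitude_cm"] > 0).any():
            raise ValueError("APA amplitude cell means must be backward (<= 0)")
        if (cm["t_v_ms"] <= cm["reaction_time_ms"]).any():
            raise ValueError("tV cell means must exceed RT cell means")

    def zero_noise(self) -> "GenerativeParams":
        """Copy with all channel noise and all random-effect SDs at zero."""
        z = dict.fromkeys(OUTCOME_NAMES, 0.0)
        return replace(
            self,
            sd_participant=dict(z),
            sd_face=dict(z),
            sd_residual=dict(z),
            force_noise_sd=0.0,
            fz_noise_sd=0.0,
            moment_noise_sd=0.0,
        )


# latent feasibility bounds (keep synthesized trials physically buildable)
_CLIP = {
    "reaction_time_ms": (230.0, 1900.0),
    "initial_posture_cm": (-60.0, -20.0),
    "apa_duration_ms": (100.0, 600.0),
    "apa_amplitude_cm": (-12.0, -0.8),
    "v_peak_m_s": (0.15, 1.5),
    "t_v_ms": None,  # handled relative to RT below
}
_MIN_TV_AFTER_RT_MS = 150.0


def sample_latent_outcomes(
    params: GenerativeParams,
    schedules: list[Schedule],
    seed: int = 0,
) -> pd.DataFrame:
    """Latent outcomes for every go trial of the given schedules.

    Each outcome is mu_cell(emotion, condition) + u_participant + w_face +
    eps with independent zero-mean Gaussian draws at the configured SDs
    (independent across outcomes). Latents are clipped to the generator's
    feasibility box, which at default SDs essentially never binds. Also
    draws one body mass per participant.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sch in schedules:
        for t in sch.go_trials:
            if t.face.expression not in EMOTIONS_GO:
                raise ValueError("go trials must carry an emotional expression")
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "face_id": t.face.face_id,
                    "emotion": t.face.expression,
                    "condition": t.condition,
                    "group": t.group,
                    "presentation_index": t.presentation_index,
                }
            )
    df = pd.DataFrame(rows)
    participants = sorted(df["participant_id"].unique())
    faces = sorted(df["face_id"].unique())
    masses = {
        p: float(np.clip(rng.normal(params.mass_mean_kg, params.mass_sd_kg), 45.0, 120.0))
        for p in participants
    }
    df["mass_kg"] = df["participant_id"].map(masses)
    mu = params.cell_means
    for name in OUTCOME_NAMES:
        u = dict(zip(participants, rng.normal(0.0, params.sd_participant[name], len(participants))))
        w = dict(zip(faces, rng.normal(0.0, params.sd_face[name], len(faces))))
        eps = rng.normal(0.0, params.sd_residual[name], len(df))
        cell = mu[name].loc[list(zip(df["emotion"], df["condition"]))].to_numpy()
        y = cell + df["participant_id"].map(u).to_numpy() + df["face_id"].map(w).to_numpy() + eps
        lo_hi = _CLIP[name]
        if lo_hi is not None:
            y = np.clip(y, *lo_hi)
        df[name] = y
    df["t_v_ms"] = np.maximum(df["t_v_ms"], df["reaction_time_ms"] + _MIN_TV_AFTER_RT_MS)
    return df


# ---------------------------------------------------------------------------
# waveform construction


def _cp_trajectory(
    t: np.ndarray,
    p0: float,
    t0y: float,
    duration_s: float,
    amplitude_m: float,
) -> np.ndarray:
    """CP AP position whose *detected* onset/peak/amplitude equal the latents.

    The descent spans W = duration / (1 - tau_c) so that the 10 % crossing
    falls at t0y and the extremum at t0y + duration; the depth is scaled so
    the drop between those two instants is exactly ``amplitude_m``.
    """
    if duration_s <= 0 or amplitude_m >= 0:
        raise ValueError("APA needs positive duration and backward (negative) amplitude")
    W = duration_s / (1.0 - TAU_CROSS)
    t_start = t0y - TAU_CROSS * W
    t_peak = t0y + duration_s
    A = -amplitude_m * _S1 / (_S1 - _S(TAU_CROSS))
    Wr = 1.4 * W
    B = 12.0 * A * (Wr / W) ** 2  # acceleration-matched forward rise

    y = np.full_like(t, p0)
    tau = np.clip((t - t_start) / W, 0.0, 1.0)
    m_desc = (t >= t_start) & (t < t_peak)
    y[m_desc] = p0 - A * (_S(tau[m_desc]) / _S1)
    sig = np.clip((t - t_peak) / Wr, 0.0, 1.0)
    m_rise = t >= t_peak
    Sh = sig**2 / 2.0 - 2.0 * sig**3 / 3.0 + sig**4 / 4.0
    y[m_rise] = (p0 - A) + B * Sh[m_rise]
    return y


def _calibrated_cp(
    t: np.ndarray,
    p0: float,
    face_onset: float,
    rt_s: float,
    dur_s: float,
    amplitude_m: float,
    fs: float,
    n_iter: int = 2,
) -> np.ndarray:
    """CP trajectory whose *measured* latents survive the 10 Hz zero-lag filter.

    The latent (RT, duration, amplitude) are defined as what the standard
    measurement chain (10 Hz zero-lag Butterworth -> CP velocity -> 10 %
    onset criterion -> first backward extremum) reports. Filtering nudges the
    analytic waveform's crossing and extremum by up to ~1.5 ms / 0.05 cm at
    the shortest APAs, so the construction targets are corrected with a short
    fixed-point loop against that chain; two iterations leave residuals an
    order of magnitude inside the round-trip tolerances.
    """
    rt_t, dur_t, amp_t = rt_s, dur_s, amplitude_m
    yP = _cp_trajectory(t, p0, face_onset + rt_t, dur_t, amp_t)
    for _ in range(n_iter):
        yf = lowpass_zero_lag(yP, fs)
        vf = differentiate(yf, fs)
        try:
            t0 = detect_t0y(vf, face_onset, fs)
            d_ms, a_cm, _ = apa_phase(yf, t0, fs)
        except EventDetectionError:
            break
        rt_t -= (t0 - face_onset) - rt_s
        dur_t -= d_ms / 1000.0 - dur_s
        amp_t -= a_cm / 100.0 - amplitude_m
        dur_t = max(dur_t, 0.05)
        amp_t = min(amp_t, -1e-4)
        yP = _cp_trajectory(t, p0, face_onset + rt_t, dur_t, amp_t)
    return yP


def _cm_accel(t: np.ndarray, t0y: float, t_v: float, v_peak: float) -> np.ndarray:
    """Full-sine CM acceleration: velocity rises to exactly v_peak at t_v."""
    if t_v <= t0y:
        raise ValueError("tV must fall after the movement onset")
    P = 2.0 * (t_v - t0y)
    amp = np.pi * v_peak / P
    a = np.zeros_like(t)
    m = (t >= t0y) & (t <= t0y + P)
    a[m] = amp * np.sin(2.0 * np.pi * (t[m] - t0y) / P)
    return a


def synthesize_trial(
    latent: LatentOutcome,
    mass: float,
    params: GenerativeParams,
    seed: int | np.random.Generator = 0,
    meta: dict | None = None,
) -> ForcePlateRecord:
    """One mechanically consistent go-trial record from its latent outcomes.

    Construction: (i) the CM forward-acceleration template integrates to
    exactly V at tV and sets Fy = mass * acceleration; (ii) the CP holds the
    initial posture, performs the calibrated backward APA excursion, then
    moves to a forward plateau; (iii) Fz fluctuates around mass * g and Mx is
    set so the CP formula recovers the CP trajectory exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = params.sampling_rate
    on = params.face_onset
    rt_s = latent.reaction_time_ms / 1000.0
    dur_s = latent.apa_duration_ms / 1000.0
    tv_s = latent.t_v_ms / 1000.0
    if tv_s <= rt_s:
        raise ValueError("infeasible latent: tV must exceed RT")
    t0y = on + rt_s
    t_v = on + tv_s
    p0 = latent.initial_posture_cm / 100.0

    W = dur_s / (1.0 - TAU_CROSS)
    t_end = on + max(
        params.min_record_after_onset_s,
        (2.0 * tv_s - rt_s) + 0.3,
        rt_s + dur_s + 1.4 * W + 0.3,
    )
    n = int(round(t_end * fs)) + 1
    t = np.arange(n) / fs

    yP = _calibrated_cp(t, p0, on, rt_s, dur_s, latent.apa_amplitude_cm / 100.0, fs)
    acc = _cm_accel(t, t0y, t_v, latent.v_peak_m_s)

    fy = mass * acc + rng.normal(0.0, params.force_noise_sd, n)
    fz = mass * GRAVITY + rng.normal(0.0, params.fz_noise_sd, n)
    mx = yP * fz + rng.normal(0.0, params.moment_noise_sd, n)

    meta = dict(meta or {})
    meta.setdefault("stepping_limb", meta.get("dominant_limb", "right"))
    meta.setdefault("dominant_limb", "right")
    meta.setdefault("artifact", None)
    return ForcePlateRecord(
        time=t, fy=fy, fz=fz, mx=mx, sampling_rate=fs, face_onset=on, mass=mass, meta=meta
    )


_ARTIFACT_KINDS = ("no_step", "wrong_limb", "early_rt", "late_rt", "baseline_motion")

# nominal clean latents used as the base of every artifact trial
_BASE_LATENT = LatentOutcome(
    reaction_time_ms=600.0,
    initial_posture_cm=-44.0,
    apa_duration_ms=250.0,
    apa_amplitude_cm=-4.5,
    v_peak_m_s=0.55,
    t_v_ms=950.0,
)


def synthesize_artifact_trial(
    kind: str,
    params: GenerativeParams,
    seed: int | np.random.Generator = 0,
    ramp_cm: float = 2.0,
) -> ForcePlateRecord:
    """A go-trial record that the QC stage must reject for exactly ``kind``.

    * ``no_step`` — CP and forces stay flat after face onset (omission, rule a)
    * ``wrong_limb`` — clean step, stepping-limb flag mismatches dominance (b)
    * ``early_rt`` / ``late_rt`` — latent RT 150 / 2100 ms, outside 200-2000 (c)
    * ``baseline_motion`` — a smooth ``ramp_cm`` CP excursion inside the 500 ms
      pre-onset window, then a clean step (d)
    """
    if kind not in _ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; choose from {_ARTIFACT_KINDS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mass = params.mass_mean_kg
    latent = _BASE_LATENT
    meta = {"dominant_limb": "right", "stepping_limb": "right", "artifact": kind}

    if kind == "early_rt":
        latent = replace(latent, reaction_time_ms=150.0, t_v_ms=500.0)
    elif kind == "late_rt":
        latent = replace(latent, reaction_time_ms=2100.0, t_v_ms=2450.0)
    elif kind == "wrong_limb":
        meta["stepping_limb"] = "left"

    if kind == "no_step":
        fs = params.sampling_rate
        n = int(round((params.face_onset + params.min_record_after_onset_s) * fs)) + 1
        t = np.arange(n) / fs
        yP = np.full(n, latent.initial_posture_cm / 100.0)
        fy = rng.normal(0.0, params.force_noise_sd, n)
        fz = mass * GRAVITY + rng.normal(0.0, params.fz_noise_sd, n)
        mx = yP * fz + rng.normal(0.0, params.moment_noise_sd, n)
        return ForcePlateRecord(
            time=t, fy=fy, fz=fz, mx=mx, sampling_rate=fs,
            face_onset=params.face_onset, mass=mass, meta=meta,
        )

    rec = synthesize_trial(latent, mass, params, rng, meta)
    if kind == "baseline_motion":
        # smoothstep CP dip of ramp_cm peak-to-peak, entirely inside the QC window
        fs = params.sampling_rate
        t = rec.time
        on = rec.face_onset
        t_a, t_b = on - 0.48, on - 0.08
        s = np.clip((t - t_a) / (t_b - t_a), 0.0, 1.0)
        bump = -(ramp_cm / 100.0) * (s**2 * (3.0 - 2.0 * s))
        bump[t >= t_b] = -(ramp_cm / 100.0)
        # return to baseline well before onset would leave pp intact; keep the
        # offset through the trial so the APA still reads cleanly
        rec.mx = rec.mx + bump * rec.fz
    return rec
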