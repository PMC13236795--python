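"""Movement-event detection and the six per-trial outcome variables.

For an accepted go trial the pipeline reports:

========================  =====  =====================================================
outcome                   unit   definition
========================  =====  =====================================================
``reaction_time_ms``      ms     face onset -> t0y, the onset of AP postural change
``initial_posture_cm``    cm     mean CP AP position over the 500 ms before face onset
``apa_duration_ms``       ms     t0y -> first backward CP peak
``apa_amplitude_cm``      cm     CP shift from t0y to that peak (negative = backward)
``v_peak_m_s``            m/s    peak forward CM velocity V
``t_v_ms``                ms     face onset -> time of V
========================  =====  =====================================================

t0y is the classic 10 %-of-first-CP-velocity-peak criterion: locate the first
backward (negative) local extremum of y′P after face onset that clears a noise
floor, then walk back to the last instant at which |y′P| is 10 % of that peak
(linear interpolation between samples). Searching backward from the peak keeps
late baseline wiggles from triggering onset.

``t_v`` is referenced to face onset, not to t0y: the stance phase lasts RT plus
a few hundred ms, which is the only reading on which observed tV values around
950-990 ms are coherent. Flip ``t_v_from_onset`` to re-reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .kinematics import BASELINE_WINDOW_S, KinematicSeries, cm_velocity


class EventDetectionError(RuntimeError):
    """A movement event required for the outcomes could not be found."""


class OnsetNotFound(EventDetectionError):
    """No qualifying CP-velocity peak after face onset (step omission)."""


class NoBackwardPeak(EventDetectionError):
    """CP never reaches a backward extremum after onset."""


class NoForwardVelocity(EventDetectionError):
    """CM velocity never becomes positive (no forward progression)."""


@dataclass(frozen=True)
class EventConfig:
    #: seconds after face onset searched for the APA onset
    search_horizon_s: float = 2.5
    #: fraction of the first y'P peak defining t0y
    onset_fraction: float = 0.10
    #: noise floor for peak qualification, in pre-onset SDs of y'P
    noise_floor_mult: float = 5.0
    #: absolute floor [m/s] so that a zero-noise baseline has a finite floor
    noise_floor_min: float = 0.005
    #: a qualifying peak must also reach this fraction of the largest backward
    #: velocity in the search window (rejects isolated noise bumps)
    rel_peak_fraction: float = 0.3
    #: minimum prominence [m] of the backward CP extremum
    min_apa_prominence_m: float = 0.005
    #: reference t_v to face onset (True) or to t0y (False)
    t_v_from_onset: bool = True
    #: reference the APA amplitude to yP(t0y) (True) or to initial posture
    amplitude_from_t0y: bool = True


@dataclass(frozen=True)
class StepEvents:
    """Absolute event times [s] on the record clock."""

    t0y: float
    t_apa_peak: float
    t_v_peak: float


@dataclass(frozen=True)
class OutcomeRow:
    reaction_time_ms: float
    initial_posture_cm: float
    apa_duration_ms: float
    apa_amplitude_cm: float
    v_peak_m_s: float
    t_v_ms: float


OUTCOME_NAMES = (
    "reaction_time_ms",
    "initial_posture_cm",
    "apa_duration_ms",
    "apa_amplitude_cm",
    "v_peak_m_s",
    "t_v_ms",
)


def initial_posture(yP: np.ndarray, face_onset: float, sampling_rate: float) -> float:
    """Mean CP AP position [cm] over the 500 ms window before face onset."""
    i_on = int(round(face_onset * sampling_rate))
    n = int(round(BASELINE_WINDOW_S * sampling_rate))
    if i_on < n:
        raise ValueError("need at least 500 ms of pre-onset data")
    return float(np.mean(yP[i_on - n : i_on])) * 100.0


def detect_t0y(
    yP_vel: np.ndarray,
    face_onset: float,
    sampling_rate: float,
    config: EventConfig | None = None,
) -> float:
    """Onset of AP postural modification [s], sub-sample via interpolation."""
    config = config or EventConfig()
    i_on = int(round(face_onset * sampling_rate))
    i_end = min(len(yP_vel), i_on + int(round(config.search_horizon_s * sampling_rate)))
    pre_sd = float(np.std(yP_vel[max(0, i_on - int(BASELINE_WINDOW_S * sampling_rate)) : i_on]))
    floor = max(config.noise_floor_mult * pre_sd, config.noise_floor_min)

    window = yP_vel[i_on:i_end]
    backward_max = float(np.max(-window)) if np.any(-window > 0) else 0.0
    height = max(floor, config.rel_peak_fraction * backward_max)
    peaks, _ = find_peaks(-window, height=height)
    if peaks.size == 0:
        raise OnsetNotFound("no qualifying backward CP-velocity peak after face onset")
    i_peak = i_on + int(peaks[0])
    thr = config.onset_fraction * abs(yP_vel[i_peak])

    # last sample before the peak with |y'P| <= 10% of the peak
    below = np.nonzero(np.abs(yP_vel[i_on : i_peak + 1]) <= thr)[0]
    if below.size == 0:
        # velocity already beyond threshold at face onset; onset is the window start
        return i_on / sampling_rate
    j = i_on + int(below[-1])
    v0, v1 = abs(yP_vel[j]), abs(yP_vel[j + 1])
    frac = 0.0 if v1 == v0 else (thr - v0) / (v1 - v0)
    return (j + float(np.clip(frac, 0.0, 1.0))) / sampling_rate


def reaction_time(t0y: float, face_onset: float) -> float:
    """Reaction time [ms]: face onset to t0y."""
    if t0y <= face_onset:
        raise ValueError("t0y must fall after face onset")
    return (t0y - face_onset) * 1000.0


def apa_phase(
    yP: np.ndarray,
    t0y: float,
    sampling_rate: float,
    config: EventConfig | None = None,
    initial_posture_m: float | None = None,
) -> tuple[float, float, float]:
    """APA duration [ms] and signed amplitude [cm]; also returns t_apa_peak [s].

    The APA peak is the first local minimum of yP after t0y (the backward
    extremum preceding the forward crossing). The amplitude is referenced to
    yP(t0y) by default; pass ``initial_posture_m`` and configure
    ``amplitude_from_t0y=False`` to reference the pre-onset mean instead.
    """
    config = config or EventConfig()
    i0 = int(round(t0y * sampling_rate))
    seg = yP[i0:]
    peaks, _ = find_peaks(-seg, prominence=config.min_apa_prominence_m)
    if peaks.size == 0:
        raise NoBackwardPeak("CP moves monotonically forward after t0y")
    i_peak = i0 + int(peaks[0])
    t_peak = i_peak / sampling_rate
    if config.amplitude_from_t0y or initial_posture_m is None:
        ref = yP[i0]
    else:
        ref = initial_posture_m
    duration_ms = (t_peak - t0y) * 1000.0
    amplitude_cm = (yP[i_peak] - ref) * 100.0
    return duration_ms, amplitude_cm, t_peak


def com_peak(
    yG_vel: np.ndarray,
    face_onset: float,
    sampling_rate: float,
    t0y: float | None = None,
    config: EventConfig | None = None,
) -> tuple[float, float, float]:
    """Peak forward CM velocity V [m/s] and its time tV [ms]; also t_v_peak [s].

    Ties at equal maxima resolve to the earliest time.
    """
    config = config or EventConfig()
    if not np.any(yG_vel > 0):
        raise NoForwardVelocity("CM velocity never positive")
    i_max = int(np.argmax(yG_vel))
    t_peak = i_max / sampling_rate
    ref = face_onset if config.t_v_from_onset or t0y is None else t0y
    return float(yG_vel[i_max]), (t_peak - ref) * 1000.0, t_peak


def extract_outcomes(
    kin: KinematicSeries,
    config: EventConfig | None = None,
) -> tuple[OutcomeRow, StepEvents]:
    """Run the full event chain on one trial's kinematics.

    Fills ``kin.yG_vel`` as a side effect (integration starts at the detected
    t0y). Raises :class:`EventDetectionError` subclasses when the trial shows
    no step; callers map those to the QC omission rule.
    """
    config = config or EventConfig()
    fs = kin.sampling_rate
    ip = initial_posture(kin.yP, kin.face_onset, fs)
    t0y = detect_t0y(kin.yP_vel, kin.face_onset, fs, config)
    rt = reaction_time(t0y, kin.face_onset)
    dur, amp, t_apa = apa_phase(kin.yP, t0y, fs, config, initial_posture_m=ip / 100.0)
    kin.yG_vel = cm_velocity(kin.yG_acc, int(round(t0y * fs)), fs)
    v, tv, t_vpk = com_peak(kin.yG_vel, kin.face_onset, fs, t0y, config)
    row = OutcomeRow(
        reaction_time_ms=rt,
        initial_posture_cm=ip,
        apa_duration_ms=dur,
        apa_amplitude_cm=amp,
        v_peak_m_s=v,
        t_v_ms=tv,
    )
    return row, StepEvents(t0y=t0y, t_apa_peak=t_apa, t_v_peak=t_vpk)
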