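"""Centre-of-pressure and centre-of-mass kinematics from force-plate channels.

The plate reports, per trial, the anteroposterior (AP) shear force ``Fy`` [N],
the vertical force ``Fz`` [N] and the moment about the mediolateral axis
``Mx`` [N·m] on a uniform 1000 Hz grid. Axis convention: +y points forward
(toward the stimulus), so the backward anticipatory excursion of the centre of
pressure is negative.

Processing chain (each step has a standalone function):

1. zero-lag 10 Hz low-pass Butterworth filtering of the raw channels,
2. AP centre of pressure  yP = (Mx − Fy·z_offset) / Fz,
3. CP velocity y′P by central differences,
4. CM acceleration y″G = (Fy − baseline)/m  (Newton's second law, quiet-stance
   bias removed),
5. CM velocity y′G by trapezoidal integration with y′G(t0y) = 0.

Filtering precedes CP computation; flip ``filter_before_cop`` in
:class:`FilterConfig` to filter the CP trace instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ForcePlateRecord

GRAVITY = 9.81  # m/s^2

#: pre-onset window (s) used both for initial posture and for Fy bias removal
BASELINE_WINDOW_S = 0.5


@dataclass(frozen=True)
class FilterConfig:
    cutoff_hz: float = 10.0
    order: int = 4  # per-pass design order; forward-backward doubles it
    filter_before_cop: bool = True


def lowpass_zero_lag(x: np.ndarray, sampling_rate: float, cutoff_hz: float = 10.0, order: int = 4) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter (forward-backward application).

    The effective magnitude response is the squared single-pass response, so
    the gain at the cutoff is (1/sqrt(2))^2 = 0.5; the phase shift is zero.
    Edges are handled by reflective padding of length 3 x the filter
    polynomial length.
    """
    if cutoff_hz <= 0 or sampling_rate <= 2 * cutoff_hz:
        raise ValueError("need 0 < cutoff and sampling_rate > 2*cutoff")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate)
    padlen = 3 * max(len(a), len(b))
    if len(x) <= padlen:
        raise ValueError(f"signal too short to filter ({len(x)} <= {padlen} samples)")
    return signal.filtfilt(b, a, np.asarray(x, float), padtype="even", padlen=padlen)


def cop_ap(Fy: np.ndarray, Fz: np.ndarray, Mx: np.ndarray, z_offset: float = 0.0) -> np.ndarray:
    """AP centre of pressure [m] from plate forces and the ML-axis moment.

    ``z_offset`` is the plate origin-to-surface distance [m]; 0 for a
    surface-origin plate.
    """
    Fz = np.asarray(Fz, float)
    if np.any(Fz <= 0):
        raise ValueError("Fz must be positive everywhere (load on the plate)")
    return (np.asarray(Mx, float) - np.asarray(Fy, float) * z_offset) / Fz


def differentiate(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    """First time derivative: central differences interior, one-sided edges."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(x, 1.0 / sampling_rate)


def cm_acceleration(Fy: np.ndarray, mass: float, baseline: slice | np.ndarray) -> np.ndarray:
    """AP centre-of-mass acceleration [m/s^2] from the AP shear force.

    Newton's second law with the quiet-stance force bias (mean over the
    pre-onset ``baseline`` window) removed, so the acceleration is zero at
    rest by construction.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    Fy = np.asarray(Fy, float)
    bias = float(np.mean(Fy[baseline]))
    return (Fy - bias) / mass


def cm_velocity(yG_acc: np.ndarray, t0y_index: int, sampling_rate: float) -> np.ndarray:
    """AP CM velocity [m/s]: trapezoidal integral of y″G from t0y onward.

    Both y″G and y′G are taken as zero at movement onset; samples before
    ``t0y_index`` are zero.
    """
    yG_acc = np.asarray(yG_acc, float)
    if not 0 <= t0y_index < yG_acc.size:
        raise ValueError("t0y outside the record")
    v = np.zeros_like(yG_acc)
    dt = 1.0 / sampling_rate
    seg = yG_acc[t0y_index:]
    v[t0y_index:] = np.concatenate(([0.0], np.cumsum((seg[1:] + seg[:-1]) * (dt / 2.0))))
    return v


@dataclass
class KinematicSeries:
    """Derived CP/CM traces on the record's time base.

    ``yG_vel`` is filled in only once the movement onset is known (see
    :func:`stepinit.events.extract_outcomes`); until then it is None.
    """

    time: np.ndarray
    yP: np.ndarray
    yP_vel: np.ndarray
    yG_acc: np.ndarray
    sampling_rate: float
    face_onset: float
    yG_vel: np.ndarray | None = None

    @property
    def onset_index(self) -> int:
        return int(round(self.face_onset * self.sampling_rate))


def reduce_record(record: "ForcePlateRecord", config: FilterConfig | None = None) -> KinematicSeries:
    """Raw channels -> filtered CP position/velocity and CM acceleration."""
    config = config or FilterConfig()
    fs = record.sampling_rate
    i_on = int(round(record.face_onset * fs))
    n_base = int(round(BASELINE_WINDOW_S * fs))
    if i_on < n_base:
        raise ValueError("record must cover the 500 ms pre-onset baseline window")
    baseline = slice(i_on - n_base, i_on)

    if config.filter_before_cop:
        fy = lowpass_zero_lag(record.fy, fs, config.cutoff_hz, config.order)
        fz = lowpass_zero_lag(record.fz, fs, config.cutoff_hz, config.order)
        mx = lowpass_zero_lag(record.mx, fs, config.cutoff_hz, config.order)
        yP = cop_ap(fy, fz, mx, record.z_offset)
    else:
        yP = cop_ap(record.fy, record.fz, record.mx, record.z_offset)
        yP = lowpass_zero_lag(yP, fs, config.cutoff_hz, config.order)
        fy = lowpass_zero_lag(record.fy, fs, config.cutoff_hz, config.order)

    return KinematicSeries(
        time=record.time,
        yP=yP,
        yP_vel=differentiate(yP, fs),
        yG_acc=cm_acceleration(fy, record.mass, baseline),
        sampling_rate=fs,
        face_onset=record.face_onset,
    )
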