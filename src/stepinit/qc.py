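"""Go-trial rejection rules and rejection statistics.

A go trial is rejected for the first failing rule, checked in order:

a. a no-go response was produced (no detectable step),
b. the step was made with the wrong (non-dominant) limb,
c. the reaction time fell outside 200-2000 ms (bounds inclusive),
d. considerable CP movement in the 500 ms window before face onset
   (peak-to-peak above a configurable threshold, default 1 cm — an order of
   magnitude below a typical APA excursion; the rule itself fixes no number).

Wrong-limb detection from AP-only channels is physically impossible, so the
stepping-limb metadata flag is authoritative for rule b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventDetectionError, OutcomeRow, StepEvents
from .kinematics import BASELINE_WINDOW_S, KinematicSeries

REASONS = ("a_no_go_response", "b_wrong_limb", "c_rt_out_of_range", "d_baseline_motion")


@dataclass(frozen=True)
class QCThresholds:
    rt_min_ms: float = 200.0
    rt_max_ms: float = 2000.0
    baseline_motion_cm: float = 1.0


@dataclass(frozen=True)
class QCResult:
    trial: dict  # trial reference metadata
    accepted: bool
    reason: str  # one of REASONS or "none"


def baseline_peak_to_peak_cm(kin: KinematicSeries) -> float:
    """Peak-to-peak CP AP excursion [cm] over the pre-onset QC window."""
    i_on = kin.onset_index
    n = int(round(BASELINE_WINDOW_S * kin.sampling_rate))
    seg = kin.yP[i_on - n : i_on]
    return float(np.ptp(seg)) * 100.0


def assess_trial(
    kin: KinematicSeries,
    events_or_failure: tuple[OutcomeRow, StepEvents] | EventDetectionError,
    trial_meta: dict,
    thresholds: QCThresholds | None = None,
) -> QCResult:
    """Apply rules a-d to one go trial; first failing rule wins."""
    thresholds = thresholds or QCThresholds()
    if trial_meta.get("trial_type", "go") != "go":
        raise ValueError("QC applies to go trials only")
    ref = dict(trial_meta)

    if isinstance(events_or_failure, EventDetectionError):
        return QCResult(ref, False, "a_no_go_response")

    stepping = trial_meta.get("stepping_limb")
    dominant = trial_meta.get("dominant_limb")
    if stepping is not None and dominant is not None and stepping != dominant:
        return QCResult(ref, False, "b_wrong_limb")

    row, _ = events_or_failure
    if not (thresholds.rt_min_ms <= row.reaction_time_ms <= thresholds.rt_max_ms):
        return QCResult(ref, False, "c_rt_out_of_range")

    if baseline_peak_to_peak_cm(kin) > thresholds.baseline_motion_cm:
        return QCResult(ref, False, "d_baseline_motion")

    return QCResult(ref, True, "none")


def summarize_rejections(results: list[QCResult]) -> pd.Series:
    """Counts per reason plus total, accepted, and the rejected fraction."""
    if not results:
        raise ValueError("no QC results to summarize")
    counts = {r: 0 for r in REASONS}
    for res in results:
        if not res.accepted:
            counts[res.reason] += 1
    n = len(results)
    rejected = sum(counts.values())
    return pd.Series(
        counts
        | {
            "n_trials": n,
            "n_accepted": n - rejected,
            "n_rejected": rejected,
            "rejected_fraction": rejected / n,
        }
    )


def qc_table(results: list[QCResult]) -> pd.DataFrame:
    """Long-format QC report, one row per assessed trial."""
    rows = []
    for r in results:
        rows.append(dict(r.trial) | {"accepted": r.accepted, "reason": r.reason})
    return pd.DataFrame(rows)
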