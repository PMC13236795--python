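"""Go/no-go trial schedules for the forward single-step initiation experiment.

Two task conditions are modelled. In the *neutral-versus-emotional* condition a
participant steps forward (go) for fearful, angry or happy faces and withholds
(no-go) for neutral faces. In the *face-gender* condition the go/no-go mapping
depends only on the face's gender: half the participants step for male faces
(go-men group), the other half for female faces (go-women group).

Per participant and condition the schedule always holds 30 go and 10 no-go
trials, presented in a seeded random order. Each trial shows a fixation cross
for 2 s followed by the face for 1 s, so face onset is at 2.0 s on the trial
clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EMOTIONS_GO = ("fearful", "angry", "happy")
EXPRESSIONS = ("neutral",) + EMOTIONS_GO
CONDITIONS = ("neutral_vs_emotional", "face_gender")
GROUPS = ("all", "go_men", "go_women")

#: seconds of fixation cross preceding face onset within a trial
FIXATION_S = 2.0
#: seconds the face stays on screen
FACE_DISPLAY_S = 1.0
#: default inter-trial interval beyond fixation + face + post-movement screen
DEFAULT_ITI_S = 3.0


@dataclass(frozen=True)
class FaceStimulus:
    """One face identity at one expression."""

    face_id: str
    gender: str  # "male" | "female"
    expression: str

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.expression not in EXPRESSIONS:
            raise ValueError(f"unknown expression {self.expression!r}")


def default_face_set() -> list[str]:
    """The 10 face identities (5 male, 5 female) used throughout.

    Returns bare identity labels; expressions are attached by the schedule
    builder. Male identities sort before female ones only by label, nothing
    downstream depends on that.
    """
    return [f"M{i}" for i in range(1, 6)] + [f"F{i}" for i in range(1, 6)]


def face_gender(face_id: str) -> str:
    return "male" if face_id.startswith("M") else "female"


@dataclass(frozen=True)
class TrialSpec:
    participant_id: str
    condition: str
    group: str
    face: FaceStimulus
    trial_type: str  # "go" | "no_go"
    presentation_index: int
    face_onset_time: float = FIXATION_S


@dataclass
class Schedule:
    """Ordered trial list for one participant in one condition."""

    participant_id: str
    condition: str
    group: str
    trials: list[TrialSpec]
    seed: int
    condition_order: int = 0  # 0-based position of this condition in the session

    @property
    def go_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.trial_type == "go"]

    @property
    def no_go_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.trial_type == "no_go"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": t.participant_id,
                "condition": t.condition,
                "group": t.group,
                "face_id": t.face.face_id,
                "gender": t.face.gender,
                "expression": t.face.expression,
                "trial_type": t.trial_type,
                "presentation_index": t.presentation_index,
                "face_onset_time": t.face_onset_time,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def _check_face_set(face_ids: list[str]) -> tuple[list[str], list[str]]:
    males = sorted(f for f in face_ids if face_gender(f) == "male")
    females = sorted(f for f in face_ids if face_gender(f) == "female")
    if len(males) != 5 or len(females) != 5 or len(set(face_ids)) != 10:
        raise ValueError(
            "face set must hold exactly 5 male and 5 female identities, "
            f"got {len(males)} male / {len(females)} female"
        )
    return males, females


def _trial_multiset(condition: str, group: str, face_ids: list[str]) -> list[tuple[FaceStimulus, str]]:
    """Unordered (face, trial_type) composition for one condition/group."""
    males, females = _check_face_set(face_ids)
    trials: list[tuple[FaceStimulus, str]] = []
    if condition == "neutral_vs_emotional":
        if group != "all":
            raise ValueError("neutral_vs_emotional uses group='all'")
        for fid in males + females:
            g = face_gender(fid)
            for emo in EMOTIONS_GO:
                trials.append((FaceStimulus(fid, g, emo), "go"))
            trials.append((FaceStimulus(fid, g, "neutral"), "no_go"))
    elif condition == "face_gender":
        if group not in ("go_men", "go_women"):
            raise ValueError("face_gender needs group go_men or go_women")
        go_ids, nogo_ids = (males, females) if group == "go_men" else (females, males)
        for fid in go_ids:
            for emo in EMOTIONS_GO:
                for _ in range(2):  # each go face/expression shown twice
                    trials.append((FaceStimulus(fid, face_gender(fid), emo), "go"))
        # 3 no-go identities carry all three expressions, a 4th only anger;
        # identities picked in lowest-label order (counts are fixed, the
        # particular identities are not).
        for fid in nogo_ids[:3]:
            for emo in EMOTIONS_GO:
                trials.append((FaceStimulus(fid, face_gender(fid), emo), "no_go"))
        trials.append((FaceStimulus(nogo_ids[3], face_gender(nogo_ids[3]), "angry"), "no_go"))
    else:
        raise ValueError(f"unknown condition {condition!r}")
    assert sum(t == "go" for _, t in trials) == 30
    assert sum(t == "no_go" for _, t in trials) == 10
    return trials


def build_condition_schedule(
    condition: str,
    group: str,
    face_ids: list[str] | None = None,
    seed: int = 0,
    participant_id: str = "P01",
) -> Schedule:
    """Build one participant's 40-trial schedule for one condition.

    The trial composition is fixed by the design; only the presentation order
    is random, drawn from ``numpy.random.default_rng(seed)``.
    """
    face_ids = face_ids if face_ids is not None else default_face_set()
    multiset = _trial_multiset(condition, group, face_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(multiset))
    trials = [
        TrialSpec(
            participant_id=participant_id,
            condition=condition,
            group=group,
            face=multiset[j][0],
            trial_type=multiset[j][1],
            presentation_index=i + 1,
        )
        for i, j in enumerate(order)
    ]
    return Schedule(participant_id, condition, group, trials, seed)


def build_experiment(
    n_participants: int = 24,
    seed: int = 0,
    face_ids: list[str] | None = None,
) -> list[Schedule]:
    """Build schedules for the whole experiment.

    Each participant performs both conditions in a randomized order; exactly
    half the participants are in the go-men group and half in go-women. Returns
    one Schedule per (participant, condition), session order recorded in
    ``condition_order``.
    """
    if n_participants % 2:
        raise ValueError("n_participants must be even (half/half gender-mapping groups)")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    groups = ["go_men"] * (n_participants // 2) + ["go_women"] * (n_participants // 2)
    rng.shuffle(groups)
    schedules: list[Schedule] = []
    child_seeds = ss.spawn(n_participants)
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        prng = np.random.default_rng(child_seeds[i])
        sub_seed = int(prng.integers(0, 2**31 - 1, size=2)[0])
        sub_seed2 = int(prng.integers(0, 2**31 - 1))
        nve = build_condition_schedule(
            "neutral_vs_emotional", "all", face_ids, seed=sub_seed, participant_id=pid
        )
        fg = build_condition_schedule(
            "face_gender", groups[i], face_ids, seed=sub_seed2, participant_id=pid
        )
        pair = [nve, fg]
        if prng.integers(2):  # seeded per-participant condition order
            pair = [fg, nve]
        for k, sch in enumerate(pair):
            sch.condition_order = k
        schedules.extend(pair)
    return schedules


def schedules_to_frame(schedules: list[Schedule]) -> pd.DataFrame:
    """Flatten schedules to one long table, one row per trial."""
    return pd.concat([s.to_frame() for s in schedules], ignore_index=True)
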