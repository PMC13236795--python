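"""End-to-end run: schedule -> synthesis -> kinematics -> events -> QC -> stats.

The pipeline streams trial by trial (synthesize, reduce, extract, assess,
discard) so a full 24-participant run stays light on memory; per-trial raw
records are only written to disk when ``cache_records`` is on. Each accepted
go trial contributes one outcome row; the statistics stage then fits the
crossed mixed model once per outcome variable. A failed trial is recorded and
skipped, never fatal.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import build_experiment, schedules_to_frame
from .events import OUTCOME_NAMES, EventConfig, EventDetectionError, extract_outcomes
from .io import write_manifest, write_record, write_table
from .kinematics import FilterConfig, reduce_record
from .lmm import CrossedLMM
from .qc import QCThresholds, assess_trial, qc_table, summarize_rejections
from .simulate import GenerativeParams, LatentOutcome, sample_latent_outcomes, synthesize_trial


@dataclass
class RunConfig:
    n_participants: int = 24
    seed: int = 7
    out_dir: str | None = None
    cache_records: bool = False
    params: GenerativeParams = field(default_factory=GenerativeParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    events: EventConfig = field(default_factory=EventConfig)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    run_stats: bool = True

    @classmethod
    def from_mapping(cls, cfg: dict) -> "RunConfig":
        """Build from a flat key-value mapping (see io.load_config)."""
        kwargs = {}
        for key in ("n_participants", "seed", "out_dir", "cache_records", "run_stats"):
            if key in cfg:
                kwargs[key] = cfg[key]
        fc = {k[len("filter_"):]: v for k, v in cfg.items() if k.startswith("filter_")}
        ev = {k[len("event_"):]: v for k, v in cfg.items() if k.startswith("event_")}
        qc = {k[len("qc_"):]: v for k, v in cfg.items() if k.startswith("qc_")}
        gp = {k[len("gen_"):]: v for k, v in cfg.items() if k.startswith("gen_")}
        if fc:
            kwargs["filter"] = FilterConfig(**fc)
        if ev:
            kwargs["events"] = EventConfig(**ev)
        if qc:
            kwargs["thresholds"] = QCThresholds(**qc)
        if gp:
            kwargs["params"] = GenerativeParams(**gp)
        return cls(**kwargs)


@dataclass
class RunResult:
    schedule: pd.DataFrame
    latents: pd.DataFrame
    outcomes: pd.DataFrame  # accepted go trials only
    qc: pd.DataFrame
    rejection_summary: pd.Series
    stats: dict[str, dict[str, pd.DataFrame]]
    manifest: dict


def process_record(record, filter_config, event_config, thresholds):
    """Kinematics + events + QC for one go-trial record."""
    kin = reduce_record(record, filter_config)
    try:
        events = extract_outcomes(kin, event_config)
    except EventDetectionError as err:
        events = err
    qc_res = assess_trial(kin, events, record.meta, thresholds)
    row = None
    if not isinstance(events, EventDetectionError):
        row = events[0]
    return kin, row, qc_res


def fit_outcome_models(outcomes: pd.DataFrame) -> dict[str, dict[str, pd.DataFrame]]:
    """Fit the crossed LMM per outcome; returns anova/emmeans/contrast tables."""
    stats_out: dict[str, dict[str, pd.DataFrame]] = {}
    for name in OUTCOME_NAMES:
        model = CrossedLMM.from_dataframe(outcomes, value_col=name)
        res = model.fit()
        stats_out[name] = {
            "anova": res.anova().reset_index(),
            "emmeans": res.emmeans(),
            "contrasts_emotion": res.pairwise("emotion", by="condition"),
            "contrasts_condition": res.pairwise("condition"),
            "vcomp": pd.DataFrame([res.vcomp]),
        }
    return stats_out


def run_pipeline(config: RunConfig | None = None) -> RunResult:
    """Run the whole chain under one master seed; optionally write artifacts."""
    config = config or RunConfig()
    ss = np.random.SeedSequence(config.seed)
    s_design, s_latent, s_noise = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(3))

    schedules = build_experiment(config.n_participants, seed=s_design)
    latents = sample_latent_outcomes(config.params, schedules, seed=s_latent)
    noise_rng = np.random.default_rng(s_noise)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "records").mkdir(exist_ok=True)

    outcome_rows = []
    qc_results = []
    failures = 0
    for i, trial in latents.iterrows():
        latent = LatentOutcome(**{k: trial[k] for k in OUTCOME_NAMES})
        meta = {
            "participant_id": trial["participant_id"],
            "face_id": trial["face_id"],
            "emotion": trial["emotion"],
            "condition": trial["condition"],
            "group": trial["group"],
            "trial_type": "go",
            "presentation_index": trial["presentation_index"],
            "dominant_limb": "right",
            "stepping_limb": "right",
        }
        try:
            record = synthesize_trial(latent, trial["mass_kg"], config.params, noise_rng, meta)
            if config.cache_records and out_dir:
                name = f"{meta['participant_id']}_{meta['condition']}_{meta['presentation_index']:03d}.tsv"
                write_record(record, out_dir / "records" / name)
            _, row, qc_res = process_record(record, config.filter, config.events, config.thresholds)
        except Exception:  # one bad trial never aborts the run
            failures += 1
            continue
        qc_results.append(qc_res)
        if qc_res.accepted and row is not None:
            outcome_rows.append(
                {k: meta[k] for k in ("participant_id", "face_id", "emotion", "condition", "group", "presentation_index")}
                | row.__dict__
            )

    outcomes = pd.DataFrame(outcome_rows)
    qc_df = qc_table(qc_results)
    summary = summarize_rejections(qc_results)
    stats_out = fit_outcome_models(outcomes) if config.run_stats and len(outcomes) else {}

    manifest = {
        "stepinit_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_go_trials": int(len(latents)),
        "n_accepted": int(len(outcomes)),
        "n_failed_synthesis": failures,
        "thresholds": config.thresholds.__dict__,
        "event_config": config.events.__dict__,
        "filter_config": config.filter.__dict__,
        "rejection_summary": {k: float(v) for k, v in summary.items()},
    }

    if out_dir:
        write_table(schedules_to_frame(schedules), out_dir / "schedule.tsv")
        write_table(latents, out_dir / "latents.tsv")
        write_table(outcomes, out_dir / "outcomes.tsv")
        write_table(qc_df, out_dir / "qc.tsv")
        for name, tables in stats_out.items():
            for kind, df in tables.items():
                write_table(df, out_dir / "stats" / f"{name}__{kind}.tsv")
        write_manifest(manifest, out_dir / "manifest.json")

    return RunResult(
        schedule=schedules_to_frame(schedules),
        latents=latents,
        outcomes=outcomes,
        qc=qc_df,
        rejection_summary=summary,
        stats=stats_out,
        manifest=manifest,
    )
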