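"""Experimental design skeletons for the tone-training battery.

``generate_design`` lays out every planned trial of the eight-session
study — six two-alternative training sessions bracketed by pre/post test
batteries — as one long table, one row per trial, with the full design
annotation each task defines and no outcomes.  Cell counts follow the
study design exactly: 60 subjects in three variability conditions (LV =
single talker, HV = four talkers mixed, HVB = four talkers blocked), 288
training trials per session, 72 three-interval-oddity trials per test
session split 36/36 by item novelty and 24/24/24 by trial type, a
post-only 72-trial picture-identification test split by voice novelty, a
72-word pre/post repetition test, 36 post-only naming pictures, a
96-trial pitch-contour aptitude test, and a 120-trial tone-continuum
categorisation task (two blocks of six steps × ten repetitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignConfig", "generate_design", "TASKS"]

TASKS = (
    "training",
    "oddity",
    "picture_id",
    "repetition",
    "naming",
    "pitch_contour",
    "continuum",
)


@dataclass
class DesignConfig:
    """Counts and labels that define the planned experiment."""

    n_per_condition: int = 20
    conditions: tuple = ("LV", "HV", "HVB")
    training_sessions: int = 6
    trials_per_training_session: int = 288
    oddity_trials: int = 72           # per test session; 36/36 novelty, 24 per trial type
    picture_id_trials: int = 72       # post only; 36 trained / 36 untrained voice
    repetition_words: int = 72        # per test session; 36 trained / 36 untrained
    naming_pictures: int = 36         # post only
    aptitude_trials: int = 96         # pitch-contour test, per test session
    continuum_steps: int = 6
    continuum_repetitions: int = 20   # per step, across the two blocks
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_per_condition", "training_sessions", "trials_per_training_session",
            "oddity_trials", "picture_id_trials", "repetition_words",
            "naming_pictures", "aptitude_trials", "continuum_steps",
            "continuum_repetitions",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"design count {name!r} must be positive, got {getattr(self, name)}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be distinct")
        if self.oddity_trials % 6 != 0:
            raise ValueError(
                "oddity_trials must be divisible by 6 (2 novelty × 3 trial-type cells), "
                f"got {self.oddity_trials}"
            )
        if self.picture_id_trials % 2 != 0:
            raise ValueError(f"picture_id_trials must be even (trained/untrained voice split), got {self.picture_id_trials}")
        if self.repetition_words % 2 != 0:
            raise ValueError(f"repetition_words must be even (trained/untrained split), got {self.repetition_words}")
        if self.continuum_repetitions % 2 != 0:
            raise ValueError(f"continuum_repetitions must be even (two blocks), got {self.continuum_repetitions}")

    @property
    def n_subjects(self) -> int:
        return self.n_per_condition * len(self.conditions)

    def subject_table(self) -> pd.DataFrame:
        ids = [f"S{i + 1:03d}" for i in range(self.n_subjects)]
        cond = np.repeat(list(self.conditions), self.n_per_condition)
        return pd.DataFrame({"subject_id": ids, "condition": cond})


_COLUMNS = [
    "subject_id", "condition", "task", "session", "trial_index",
    "item_id", "item_novelty", "voice_novelty", "trial_type", "step",
]


def _per_subject_tasks(cfg: DesignConfig) -> pd.DataFrame:
    """All planned trials for one subject (subject/condition filled later)."""
    frames = []

    def add(task, session, n, **annot):
        d = pd.DataFrame({"trial_index": np.arange(1, n + 1)})
        d["task"] = task
        d["session"] = session
        for k, v in annot.items():
            d[k] = v
        frames.append(d)

    for s in range(1, cfg.training_sessions + 1):
        add("training", str(s), cfg.trials_per_training_session,
            item_id=[f"tr{i:03d}" for i in range(1, cfg.trials_per_training_session + 1)])

    n_cell = cfg.oddity_trials // 6
    for session in ("pre", "post"):
        rows = []
        i = 0
        for novelty in ("trained", "untrained"):
            for ttype in ("neutral", "easy", "hard"):
                for _ in range(n_cell):
                    i += 1
                    rows.append((i, f"od{i:03d}", novelty, ttype))
        d = pd.DataFrame(rows, columns=["trial_index", "item_id", "item_novelty", "trial_type"])
        d["task"] = "oddity"
        d["session"] = session
        frames.append(d)

    half = cfg.picture_id_trials // 2
    d = pd.DataFrame({
        "trial_index": np.arange(1, cfg.picture_id_trials + 1),
        "item_id": [f"pi{i:03d}" for i in range(1, cfg.picture_id_trials + 1)],
        "voice_novelty": ["trained"] * half + ["untrained"] * half,
    })
    d["task"] = "picture_id"
    d["session"] = "post"
    frames.append(d)

    half = cfg.repetition_words // 2
    for session in ("pre", "post"):
        d = pd.DataFrame({
            "trial_index": np.arange(1, cfg.repetition_words + 1),
            "item_id": [f"wr{i:03d}" for i in range(1, cfg.repetition_words + 1)],
            "item_novelty": ["trained"] * half + ["untrained"] * half,
        })
        d["task"] = "repetition"
        d["session"] = session
        frames.append(d)

    add("naming", "post", cfg.naming_pictures,
        item_id=[f"nm{i:03d}" for i in range(1, cfg.naming_pictures + 1)])

    for session in ("pre", "post"):
        add("pitch_contour", session, cfg.aptitude_trials,
            item_id=[f"pc{i:03d}" for i in range(1, cfg.aptitude_trials + 1)])

    reps_per_block = cfg.continuum_repetitions // 2
    for session in ("pre", "post"):
        steps = np.tile(
            np.repeat(np.arange(1, cfg.continuum_steps + 1), reps_per_block), 2
        )
        d = pd.DataFrame({
            "trial_index": np.arange(1, len(steps) + 1),
            "step": steps,
        })
        d["task"] = "continuum"
        d["session"] = session
        frames.append(d)

    out = pd.concat(frames, ignore_index=True)
    for col in _COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    return out[[c for c in _COLUMNS if c not in ("subject_id", "condition")]]


def generate_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """One row per planned trial across subjects and tasks, no outcomes.

    Deterministic given the config (the seed only matters once outcomes
    are simulated): rows are emitted in canonical subject → task →
    session → trial order.
    """
    cfg = config or DesignConfig()
    cfg.validate()
    per_subject = _per_subject_tasks(cfg)
    subjects = cfg.subject_table()
    blocks = []
    for _, srow in subjects.iterrows():
        d = per_subject.copy()
        d.insert(0, "subject_id", srow["subject_id"])
        d.insert(1, "condition", srow["condition"])
        blocks.append(d)
    out = pd.concat(blocks, ignore_index=True)
    out["step"] = out["step"].astype("Int64")
    return out
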