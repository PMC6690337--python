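"""Generative models for trial-level outcomes, continua and rater codings.

Outcomes are drawn from the same family of models the analyses assume: a
logistic regression on centred design contrasts with per-subject normal
random effects,

    P(correct) = logistic(x' beta + z' u_subject),   u ~ N(0, Sigma),

so that estimator recovery can be checked against known truth.  A latent
per-subject aptitude (a true proportion on the pitch-contour task) both
drives the pitch-contour responses and enters the other tasks as the
centred, ×10-scaled covariate the analyses use.

Continuum categorisation responses follow the logistic growth curve
``P(Tone 3 | step t) = 1 / (1 + b0 · b1^t)`` with ``b0 = b1^(-midpoint)``
— the parameterisation whose slope coefficient ``b1`` the aptitude
module recovers (b1 < 1: categorical perceiver; b1 = 1: flat; b1 > 1:
reversed).

Dual-rater production codings share a latent produced-tone label per
trial; each rater reproduces it with a stated agreement probability and
marks a trial unusable (tone label 0) at a stated rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from tonetrain.design import DesignConfig

__all__ = [
    "GenerativeParams",
    "ProductionParams",
    "RaterParams",
    "default_generative_params",
    "simulate_responses",
    "simulate_continuum",
    "simulate_ratings",
    "draw_continuum_params",
]

_SYLLABLES = [
    "ma", "mao", "bi", "dao", "shu", "hua", "bei", "men", "niu", "tang",
    "lu", "gou", "pan", "xie", "yi", "zhu", "feng", "ke", "lin", "song",
    "chuan", "deng", "hai", "jing", "qian", "ren", "tu", "wan", "xue", "yun",
    "bing", "cai", "dian", "er", "fan", "gang",
]


@dataclass
class GenerativeParams:
    """True coefficients of the generative logistic models, per task.

    ``fixed_effects[task]`` maps term names (as resolved against the
    contrast-coded design: ``intercept``, ``condition_hv``,
    ``condition_pooled``, ``test_session``, ``training_session``,
    ``item_novelty``, ``voice_novelty``, ``trial_type_easy``/``_hard``,
    ``aptitude``, ``latent_logit``, and ``a:b`` products) to log-odds
    coefficients.  ``random_sd[task]`` gives per-subject SDs for the
    random intercept and any within-subject slopes; ``random_corr[task]``
    optionally supplies their correlation matrix (identity if absent).
    ``aptitude_mean``/``aptitude_sd`` parameterise the latent true
    aptitude on the proportion scale.
    """

    fixed_effects: dict = field(default_factory=dict)
    random_sd: dict = field(default_factory=dict)
    random_corr: dict = field(default_factory=dict)
    aptitude_mean: float = 0.55
    aptitude_sd: float = 0.15
    continuum_b1_logmean: float = float(np.log(1.3))
    continuum_b1_logsd: float = 0.15
    continuum_midpoint_mean: float = 3.5
    continuum_midpoint_sd: float = 0.3

    def validate(self) -> None:
        for task, sds in self.random_sd.items():
            for term, sd in sds.items():
                if sd < 0:
                    raise ValueError(f"random SD for {task}/{term} must be >= 0, got {sd}")
        for task, corr in self.random_corr.items():
            corr = np.asarray(corr)
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError(f"random_corr[{task!r}] must have unit diagonal")
            if np.min(np.linalg.eigvalsh((corr + corr.T) / 2)) < -1e-8:
                raise ValueError(f"random_corr[{task!r}] must be positive semi-definite")
        if not 0 < self.aptitude_mean < 1:
            raise ValueError("aptitude_mean must lie in (0, 1)")
        if self.aptitude_sd < 0:
            raise ValueError("aptitude_sd must be >= 0")


@dataclass
class ProductionParams:
    """Latent accuracy of productions when no simulated outcomes are supplied."""

    tone_accuracy: float = 0.55
    pinyin_accuracy: float = 0.60

    def validate(self) -> None:
        for name in ("tone_accuracy", "pinyin_accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")


@dataclass
class RaterParams:
    """How faithfully each rater reproduces the latent produced tone."""

    agreement: float = 0.90
    unusable_rate: float = 0.034
    rating_sd: float = 1.2

    def validate(self) -> None:
        for name in ("agreement", "unusable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.rating_sd < 0:
            raise ValueError("rating_sd must be >= 0")


def default_generative_params() -> GenerativeParams:
    """Study-condition defaults.

    Coefficient magnitudes echo the effects the battery's analyses
    report on data of this design: a training-session slope of about
    0.5 log-odds, a pre-to-post improvement of about 0.3 on the oddity
    task and 0.4 on word repetition, trial-type offsets of +0.40 (easy)
    and −0.14 (hard) against neutral, a large trained-voice advantage in
    picture identification, an aptitude slope near 0.07–0.15 per scaled
    unit, and null variability-condition × session/aptitude interactions.
    """
    fixed = {
        "training": {
            "intercept": 1.3, "training_session": 0.5,
            "condition_hv": -0.79, "condition_hvb": -0.40, "aptitude": 0.13,
        },
        "oddity": {
            "intercept": 0.5, "test_session": 0.31, "item_novelty": 0.31,
            "trial_type_easy": 0.40, "trial_type_hard": -0.14,
            "condition_hv": 0.0, "condition_hvb": 0.0,
            "test_session:condition_hv": 0.0, "test_session:condition_hvb": 0.0,
            "aptitude": 0.07,
        },
        "picture_id": {
            "intercept": 1.0, "voice_novelty": -1.07,
            "condition_hv": -0.3, "condition_hvb": -0.1, "aptitude": 0.15,
        },
        "repetition": {
            "intercept": 0.0, "test_session": 0.40, "item_novelty": 0.0,
            "condition_hv": 0.0, "condition_hvb": 0.0, "aptitude": 0.07,
        },
        "naming": {
            "intercept": -0.2, "condition_hv": 0.0, "condition_hvb": 0.0,
            "aptitude": 0.08,
        },
        "pitch_contour": {"latent_logit": 1.0, "test_session": 0.21},
    }
    random_sd = {
        "training": {"intercept": 0.8, "training_session": 0.15},
        "oddity": {"intercept": 0.5, "test_session": 0.2},
        "picture_id": {"intercept": 0.7, "voice_novelty": 0.4},
        "repetition": {"intercept": 0.8, "test_session": 0.2},
        "naming": {"intercept": 0.8},
        "pitch_contour": {"intercept": 0.0},
    }
    return GenerativeParams(fixed_effects=fixed, random_sd=random_sd)


def null_generative_params() -> GenerativeParams:
    """Study-condition defaults with every variability-condition effect zeroed.

    The null world for the Bayes-factor battery: training still works
    (session effects, aptitude, random effects unchanged) but the three
    exposure conditions are exchangeable.
    """
    params = default_generative_params()
    for task_terms in params.fixed_effects.values():
        for term in list(task_terms):
            if "condition" in term:
                task_terms[term] = 0.0
    return params


# --------------------------------------------------------------- term columns

def _latent_aptitude(subjects: pd.DataFrame, params: GenerativeParams, rng) -> pd.Series:
    lat = rng.normal(params.aptitude_mean, params.aptitude_sd, size=len(subjects))
    lat = np.clip(lat, 0.05, 0.98)
    return pd.Series(lat, index=subjects["subject_id"].to_numpy(), name="latent_aptitude")


def _resolve_term(term: str, df: pd.DataFrame, latent: pd.Series) -> np.ndarray:
    """One generator design column, centred the way the analyses centre it."""
    if ":" in term:
        out = np.ones(len(df))
        for part in term.split(":"):
            out = out * _resolve_term(part, df, latent)
        return out
    if term == "intercept":
        return np.ones(len(df))
    if term in ("condition_hv", "condition_hvb"):
        level = "HV" if term == "condition_hv" else "HVB"
        raw = (df["condition"] == level).astype(float).to_numpy()
        return raw - raw.mean()
    if term == "condition_pooled":
        raw = (df["condition"] != "LV").astype(float).to_numpy()
        return raw - raw.mean()
    if term == "training_session":
        s = df["session"].astype(float).to_numpy()
        return s - s.mean()
    if term == "test_session":
        raw = (df["session"] == "post").astype(float).to_numpy()
        return raw - raw.mean()
    if term in ("item_novelty", "voice_novelty"):
        raw = (df[term] == "untrained").astype(float).to_numpy()
        return raw - raw.mean()
    if term in ("trial_type_easy", "trial_type_hard"):
        level = term.rsplit("_", 1)[1]
        raw = (df["trial_type"] == level).astype(float).to_numpy()
        return raw - raw.mean()
    if term == "aptitude":
        scaled = latent.loc[df["subject_id"]].to_numpy() * 10.0
        return scaled - scaled.mean()
    if term == "latent_logit":
        return logit(latent.loc[df["subject_id"]].to_numpy())
    raise KeyError(term)


def _design_matrix(df, terms, latent) -> np.ndarray:
    cols, unknown = [], []
    for t in terms:
        try:
            cols.append(_resolve_term(t, df, latent))
        except KeyError as exc:
            unknown.append(str(exc.args[0]))
    if unknown:
        raise KeyError(f"unmapped coefficient name(s): {sorted(set(unknown))}")
    return np.column_stack(cols)


def _random_effects(task, params: GenerativeParams, subjects, rng):
    sds = params.random_sd.get(task, {"intercept": 0.0})
    terms = list(sds)
    sd = np.array([sds[t] for t in terms], dtype=float)
    q, n = len(terms), len(subjects)
    corr = np.asarray(params.random_corr.get(task, np.eye(q)), dtype=float)
    cov = np.outer(sd, sd) * corr
    # eigendecomposition handles the sd = 0 (degenerate) case cleanly
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    w = np.clip(w, 0.0, None)
    U = rng.standard_normal((n, q)) @ (V * np.sqrt(w)).T
    return terms, pd.DataFrame(U, index=subjects, columns=terms)


def simulate_responses(
    design: pd.DataFrame,
    params: GenerativeParams | None = None,
    seed: int = 0,
    shuffle: bool = True,
) -> pd.DataFrame:
    """Draw binary outcomes for every non-continuum task in the design.

    Outcomes are Bernoulli(logistic(η)) with η the task's fixed part plus
    the subject's random effects; identical (design, params, seed) give
    identical output.  Continuum trials are left to
    :func:`simulate_continuum`.
    """
    params = params or default_generative_params()
    params.validate()
    rng = np.random.default_rng(seed)
    subjects = design[["subject_id", "condition"]].drop_duplicates().reset_index(drop=True)
    latent = _latent_aptitude(subjects, params, rng)
    out = design.copy()
    out["correct"] = pd.NA
    out["latent_aptitude"] = latent.loc[out["subject_id"]].to_numpy()
    for task in [t for t in out["task"].unique() if t != "continuum"]:
        mask = (out["task"] == task).to_numpy()
        df = out.loc[mask]
        terms = params.fixed_effects.get(task, {"intercept": 0.0})
        X = _design_matrix(df, list(terms), latent)
        beta = np.array([terms[t] for t in terms], dtype=float)
        eta = X @ beta
        re_terms, U = _random_effects(task, params, subjects["subject_id"].to_numpy(), rng)
        Z = _design_matrix(df, re_terms, latent)
        u_rows = U.loc[df["subject_id"]].to_numpy()
        eta = eta + np.sum(Z * u_rows, axis=1)
        if not np.all(np.isfinite(eta)):
            raise ValueError(f"non-finite linear predictor in task {task!r}")
        out.loc[mask, "correct"] = (rng.random(mask.sum()) < expit(eta)).astype(int)
    if shuffle:
        # global permutation + stable sort on the session keys = independent
        # within-session shuffles, driven by the same seed
        perm = np.random.default_rng(seed + 1).permutation(len(out))
        out = out.iloc[perm]
        out = out.sort_values(
            ["subject_id", "task", "session"], kind="stable"
        ).reset_index(drop=True)
    out["correct"] = out["correct"].astype("Int64")
    return out


def draw_continuum_params(
    subjects: pd.DataFrame, params: GenerativeParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-subject true (b1, midpoint) for the categorisation curve."""
    params = params or default_generative_params()
    rng = np.random.default_rng(seed + 7)
    b1 = np.exp(rng.normal(params.continuum_b1_logmean, params.continuum_b1_logsd, len(subjects)))
    mid = rng.normal(params.continuum_midpoint_mean, params.continuum_midpoint_sd, len(subjects))
    return pd.DataFrame(
        {"subject_id": subjects["subject_id"].to_numpy(), "b1": b1, "midpoint": mid}
    )


def simulate_continuum(
    subject_params: pd.DataFrame,
    seed: int = 0,
    n_steps: int = 6,
    repetitions: int = 20,
    sessions: tuple = ("pre", "post"),
) -> pd.DataFrame:
    """Tone-2/Tone-3 categorisation responses along the step continuum.

    ``subject_params`` needs columns ``subject_id``, ``b1``, ``midpoint``
    (true psychometric slope and crossover).  Each session contains two
    blocks of ``n_steps × repetitions/2`` trials (default 120 per subject
    per session over steps 1–6).
    """
    if not 2 <= n_steps <= 6:
        raise ValueError(f"continuum steps must lie within 1–6 (need 2–6 steps), got {n_steps}")
    if repetitions <= 0 or repetitions % 2:
        raise ValueError(f"repetitions must be a positive even count, got {repetitions}")
    for col in ("subject_id", "b1", "midpoint"):
        if col not in subject_params.columns:
            raise ValueError(f"subject_params must supply per-subject {col!r}")
    rng = np.random.default_rng(seed)
    reps_per_block = repetitions // 2
    steps = np.tile(np.repeat(np.arange(1, n_steps + 1), reps_per_block), 2)
    rows = []
    for _, srow in subject_params.iterrows():
        b1, mid = float(srow["b1"]), float(srow["midpoint"])
        b0 = b1 ** (-mid)
        for session in sessions:
            with np.errstate(over="ignore", under="ignore"):
                p3 = 1.0 / (1.0 + b0 * np.power(b1, steps.astype(float)))
            chose3 = rng.random(len(steps)) < p3
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": srow["subject_id"],
                        "task": "continuum",
                        "session": session,
                        "trial_index": np.arange(1, len(steps) + 1),
                        "step": steps,
                        "choice": np.where(chose3, "tone3", "tone2"),
                        "chose_tone3": chose3.astype(int),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_ratings(
    trials: pd.DataFrame,
    production_params: ProductionParams | None = None,
    rater_params: RaterParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dual-rater codings of production trials (long format, 2 rows/trial).

    A latent produced-tone label is shared by both raters: the target
    tone when the production is correct (taken from the ``correct``
    column when the trials come from :func:`simulate_responses`,
    otherwise drawn at ``production_params.tone_accuracy``), a random
    other tone otherwise.  Each rater reproduces the latent label with
    probability ``agreement`` and codes 0 (unusable) at
    ``unusable_rate``.
    """
    production_params = production_params or ProductionParams()
    rater_params = rater_params or RaterParams()
    production_params.validate()
    rater_params.validate()
    rng = np.random.default_rng(seed)
    df = trials.reset_index(drop=True)
    n = len(df)
    item_idx = (
        pd.factorize(df["item_id"])[0]
        if "item_id" in df.columns and df["item_id"].notna().all()
        else np.arange(n)
    )
    target_tone = (item_idx % 4) + 1
    target_pinyin = np.array(_SYLLABLES, dtype=object)[item_idx % len(_SYLLABLES)]
    if "correct" in df.columns and df["correct"].notna().all():
        tone_ok = df["correct"].to_numpy(dtype=float) > 0.5
    else:
        tone_ok = rng.random(n) < production_params.tone_accuracy
    offset = rng.integers(1, 4, size=n)  # wrong tone: shift within {1..4}
    produced_tone = np.where(tone_ok, target_tone, (target_tone - 1 + offset) % 4 + 1)
    pinyin_ok = rng.random(n) < production_params.pinyin_accuracy
    produced_pinyin = np.where(
        pinyin_ok, target_pinyin, np.char.add(target_pinyin.astype(str), "x")
    )
    quality = 3.5 + 1.5 * tone_ok + 0.8 * pinyin_ok
    records = []
    for rater_id in (1, 2):
        unusable = rng.random(n) < rater_params.unusable_rate
        agree = rng.random(n) < rater_params.agreement
        shift = rng.integers(1, 4, size=n)
        label = np.where(agree, produced_tone, (produced_tone - 1 + shift) % 4 + 1)
        label = np.where(unusable, 0, label)
        rating = np.clip(
            np.rint(rng.normal(quality, rater_params.rating_sd)), 1, 7
        ).astype(int)
        records.append(
            pd.DataFrame(
                {
                    "trial_id": [
                        f"{s}_{t}_{ss}_{i:03d}"
                        for s, t, ss, i in zip(
                            df["subject_id"], df["task"], df["session"], df["trial_index"]
                        )
                    ],
                    "subject_id": df["subject_id"].to_numpy(),
                    "task": df["task"].to_numpy(),
                    "session": df["session"].to_numpy(),
                    "rater_id": rater_id,
                    "tone_label": label,
                    "rating": rating,
                    "transcription": produced_pinyin,
                    "target_tone": target_tone,
                    "target_transcription": target_pinyin,
                }
            )
        )
    return pd.concat(records, ignore_index=True)
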