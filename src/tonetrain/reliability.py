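"""Production-coding pipeline: usability filtering, accuracy, agreement.

Each production trial (word repetition or picture naming) carries two
independent raters' codings: a tone label 1–4 (0 when no usable tone
could be identified), a 1–7 nativelikeness rating, and a pinyin
transcription of the segmental content.  The pipeline removes unusable
trials (either rater coded 0, plus any fully excluded subjects), derives
binary tone/pinyin accuracy against the trial's targets, and quantifies
inter-rater agreement: unweighted Cohen's kappa for the binary measures
(labelled on the Landis–Koch bands) and a two-way mixed-effects,
consistency, average-measures intraclass correlation for the 1–7 rating
(labelled on the Cicchetti bands).

Pinyin accuracy is segmental only: transcriptions are canonicalised by
lowercasing and stripping whitespace, tone digits and diacritics before
the exact-match comparison.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "RemovalStats",
    "ReliabilityResult",
    "filter_unusable",
    "derive_accuracy",
    "cohen_kappa",
    "icc_average",
    "landis_koch_label",
    "cicchetti_label",
    "canonical_pinyin",
]


@dataclass(frozen=True)
class RemovalStats:
    """Accounting for trials removed before analysis."""

    count: int
    denominator: int
    percent: float  # count/denominator × 100, rounded to 2 decimals


@dataclass(frozen=True)
class ReliabilityResult:
    statistic: str  # "kappa" | "icc"
    value: float
    label: str
    n_items: int
    raters: tuple = (1, 2)


def landis_koch_label(kappa: float) -> str:
    """Qualitative agreement band for Cohen's kappa (Landis & Koch)."""
    if kappa <= 0:
        return "poor agreement"
    if kappa <= 0.20:
        return "slight agreement"
    if kappa <= 0.40:
        return "fair agreement"
    if kappa <= 0.60:
        return "moderate agreement"
    if kappa <= 0.80:
        return "substantial agreement"
    return "almost perfect agreement"


def cicchetti_label(icc: float) -> str:
    """Qualitative band for an intraclass correlation (Cicchetti)."""
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def filter_unusable(
    records: pd.DataFrame,
    excluded_subjects: tuple = (),
    key: str = "either",
    analysis_rater: int = 2,
) -> tuple[pd.DataFrame, RemovalStats]:
    """Drop unusable production trials and fully excluded subjects.

    A trial is unusable when a rater coded tone label 0 — by default
    when *either* rater did (``key="either"``); ``key="analysis"``
    restricts the test to the analysis rater.  The removal percentage is
    computed over all trials, excluded subjects included, and rounded to
    two decimals.
    """
    if records.empty:
        return records.copy(), RemovalStats(0, 0, 0.0)
    if key not in ("either", "analysis"):
        raise ValueError(f"key must be 'either' or 'analysis', got {key!r}")
    trial_labels = records.pivot_table(
        index="trial_id", columns="rater_id", values="tone_label", aggfunc="first"
    )
    if key == "either":
        unusable_trials = trial_labels.index[(trial_labels == 0).any(axis=1)]
    else:
        unusable_trials = trial_labels.index[trial_labels[analysis_rater] == 0]
    denom = trial_labels.shape[0]
    subj_of_trial = records.drop_duplicates("trial_id").set_index("trial_id")["subject_id"]
    removed_mask = subj_of_trial.index.isin(unusable_trials) | subj_of_trial.isin(
        excluded_subjects
    )
    removed = int(removed_mask.sum())
    keep_ids = subj_of_trial.index[~removed_mask]
    usable = records[records["trial_id"].isin(keep_ids)].reset_index(drop=True)
    percent = round(100.0 * removed / denom, 2) if denom else 0.0
    return usable, RemovalStats(count=removed, denominator=denom, percent=percent)


def canonical_pinyin(s: str) -> str:
    """Lowercase, strip whitespace, tone digits and diacritics."""
    s = str(s).strip().lower()
    s = "".join(ch for ch in s if not ch.isspace() and not ch.isdigit())
    decomposed = unicodedata.normalize("NFD", s)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def derive_accuracy(
    records: pd.DataFrame, measure: str, rater: int = 2
) -> pd.DataFrame:
    """Binary accuracy table from one rater's usable codings.

    ``measure="tone"``: correct iff the rater's tone label equals the
    target tone.  ``measure="pinyin"``: correct iff the canonicalised
    transcription exactly equals the canonicalised target (any segmental
    error scores 0).  Records missing a target are skipped with a
    warning column rather than silently scored.
    """
    if measure not in ("tone", "pinyin"):
        raise ValueError(f"measure must be 'tone' or 'pinyin', got {measure!r}")
    df = records[records["rater_id"] == rater].copy()
    target_col = "target_tone" if measure == "tone" else "target_transcription"
    missing = df[target_col].isna()
    if missing.any():
        import warnings

        warnings.warn(
            f"{int(missing.sum())} record(s) missing {target_col}; skipped",
            UserWarning, stacklevel=2,
        )
        df = df[~missing]
    if measure == "tone":
        df["correct"] = (
            df["tone_label"].astype(int) == df["target_tone"].astype(int)
        ).astype(int)
    else:
        df["correct"] = (
            df["transcription"].map(canonical_pinyin)
            == df["target_transcription"].map(canonical_pinyin)
        ).astype(int)
    keep = ["trial_id", "subject_id", "task", "session", "correct"]
    return df[[c for c in keep if c in df.columns]].reset_index(drop=True)


def cohen_kappa(rater1, rater2) -> ReliabilityResult:
    """Unweighted Cohen's kappa between two raters' paired labels."""
    a = np.asarray(rater1)
    b = np.asarray(rater2)
    if a.shape != b.shape:
        raise ValueError(f"rater vectors must have equal length, got {a.shape} vs {b.shape}")
    if len(np.unique(np.concatenate([a, b]))) < 2:
        raise ValueError(
            "kappa undefined: both raters used a single category (chance agreement = 1)"
        )
    kappa = float(cohen_kappa_score(a, b))
    return ReliabilityResult(
        statistic="kappa", value=kappa, label=landis_koch_label(kappa), n_items=len(a)
    )


def icc_average(ratings: pd.DataFrame) -> ReliabilityResult:
    """Average-measures, two-way mixed, consistency ICC of an items × raters table.

    Rows with missing cells are dropped listwise.  Computed via
    pingouin's ICC3k variant, equivalently (MS_items − MS_error)/MS_items
    for k raters.
    """
    mat = ratings.dropna()
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError(
            f"need >=2 items and >=2 raters after listwise deletion, got {mat.shape}"
        )
    if np.allclose(mat.to_numpy().var(axis=1).sum() + mat.to_numpy().mean(axis=1).var(), 0):
        raise ValueError("ICC undefined: no between-item variance")
    long = mat.reset_index(names="item").melt(
        id_vars="item", var_name="rater", value_name="score"
    )
    import warnings

    import pingouin as pg

    with warnings.catch_warnings():
        # identical rater columns make MS_error = 0; the F ratio pingouin
        # also reports divides by it, which is irrelevant to the ICC value
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = pg.intraclass_corr(
            data=long, targets="item", raters="rater", ratings="score"
        ).set_index("Type")
    # pingouin labels the two-way mixed consistency average-measures variant
    # ICC3k (older releases) or ICC(C,k)
    key = "ICC3k" if "ICC3k" in tab.index else "ICC(C,k)"
    value = float(tab.loc[key, "ICC"])
    if not np.isfinite(value):
        raise ValueError("ICC undefined: no between-item variance")
    return ReliabilityResult(
        statistic="icc",
        value=value,
        label=cicchetti_label(value),
        n_items=mat.shape[0],
        raters=tuple(mat.columns),
    )
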