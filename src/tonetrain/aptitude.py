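"""Individual-aptitude measures: pitch-contour score and continuum slope.

Two pre-training measures of tone-perception aptitude are computed.

The pitch-contour score is each subject's proportion correct on the
96-trial pitch-contour identification test at pre-test, multiplied by 10
(one unit of the covariate ≈ a 10-percentage-point difference in test
performance) and centred against the analysis sample's mean so it can
enter the logistic models as a continuous predictor.  Only pre-test
scores are used: the measure itself improves with training, so post-test
scores would conflate aptitude with the treatment.

The continuum slope fits each subject's per-step Tone-3 proportions with
the logistic growth curve Y = 1 / (1/u + b0·b1^t), u = 1, by ordinary
least squares on the log-linearised form ln(1/Y − 1) = ln b0 + t·ln b1.
Smaller b1 means a steeper, more categorical psychometric function;
b1 = 1 is flat and b1 > 1 reversed.  Subjects with b1 > 1.2 fail the
screening threshold and are excluded from slope-based analyses.
Per-step proportions of exactly 0 or 1 receive a continuity correction
of 1/(2·n_t) before the log transform.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "pitch_contour_aptitude",
    "fit_categorization_slope",
    "apply_slope_exclusions",
    "SLOPE_THRESHOLD",
]

SLOPE_THRESHOLD = 1.2


def pitch_contour_aptitude(trials: pd.DataFrame, session: str = "pre") -> pd.DataFrame:
    """Per-subject scaled, centred pitch-contour accuracy.

    Returns a frame with ``subject_id``, ``proportion_correct``,
    ``scaled`` (= proportion × 10) and ``centred`` (= scaled − sample
    mean); the centred values sum to zero over the scored sample.
    Subjects contributing no trials in the requested session are dropped
    with a warning.
    """
    df = trials
    if "task" in df.columns:
        df = df[df["task"] == "pitch_contour"]
    if "session" in df.columns:
        df = df[df["session"] == session]
    df = df.dropna(subset=["correct"])
    if df.empty:
        raise ValueError(f"no pitch-contour trials found for session {session!r}")
    all_subjects = trials["subject_id"].unique()
    scores = (
        df.groupby("subject_id")["correct"]
        .agg(proportion_correct="mean", n_trials="size")
        .reset_index()
    )
    missing = set(all_subjects) - set(scores["subject_id"])
    if missing:
        warnings.warn(
            f"{len(missing)} subject(s) had no scorable pitch-contour trials and "
            f"were excluded: {sorted(map(str, missing))[:5]}...",
            UserWarning, stacklevel=2,
        )
    scores["proportion_correct"] = scores["proportion_correct"].astype(float)
    scores["scaled"] = scores["proportion_correct"] * 10.0
    scores["centred"] = scores["scaled"] - scores["scaled"].mean()
    return scores


def fit_categorization_slope(
    responses: pd.DataFrame,
    threshold: float = SLOPE_THRESHOLD,
    session: str | None = "pre",
) -> pd.DataFrame:
    """Per-subject logistic-growth slope b1 from continuum responses.

    ``responses`` needs ``subject_id``, ``step`` and either a binary
    ``chose_tone3`` column or a ``choice`` column with "tone2"/"tone3"
    labels.  Returns one row per subject with ``b0``, ``b1``, ``flat``
    (no step-to-step variation in the proportions) and ``excluded``
    (b1 > threshold).
    """
    df = responses
    if session is not None and "session" in df.columns:
        df = df[df["session"] == session]
    if "chose_tone3" in df.columns:
        y = df["chose_tone3"].astype(float)
    elif "choice" in df.columns:
        y = (df["choice"] == "tone3").astype(float)
    else:
        raise ValueError("responses need a 'chose_tone3' or 'choice' column")
    work = pd.DataFrame(
        {"subject_id": df["subject_id"].to_numpy(), "step": df["step"].astype(int).to_numpy(), "y": y.to_numpy()}
    )
    rows = []
    for sid, g in work.groupby("subject_id", sort=True):
        by_step = g.groupby("step")["y"].agg(["mean", "size"])
        if len(by_step) < 2:
            raise ValueError(
                f"subject {sid!r}: need >=2 distinct continuum steps, got {len(by_step)}"
            )
        p = by_step["mean"].to_numpy()
        n_t = by_step["size"].to_numpy()
        t = by_step.index.to_numpy(dtype=float)
        # continuity correction for degenerate per-step proportions
        p = np.where(p <= 0.0, 1.0 / (2.0 * n_t), p)
        p = np.where(p >= 1.0, 1.0 - 1.0 / (2.0 * n_t), p)
        w = np.log(1.0 / p - 1.0)
        flat = bool(np.allclose(w, w[0]))
        if flat:
            b1, b0 = 1.0, float(np.exp(w.mean()))
        else:
            slope, intercept = np.polyfit(t, w, 1)
            b1, b0 = float(np.exp(slope)), float(np.exp(intercept))
        rows.append(
            {
                "subject_id": sid,
                "b0": b0,
                "b1": b1,
                "flat": flat,
                "excluded": bool(b1 > threshold),
                "n_steps": len(by_step),
            }
        )
    return pd.DataFrame(rows)


def apply_slope_exclusions(
    fits: pd.DataFrame, threshold: float = SLOPE_THRESHOLD
) -> tuple[pd.DataFrame, int]:
    """Split a slope roster at the exclusion threshold.

    Returns the retained roster (b1 <= threshold) and the number
    excluded; the ``excluded`` flags are recomputed for the supplied
    threshold so overriding it is safe.
    """
    fits = fits.copy()
    fits["excluded"] = fits["b1"] > threshold
    kept = fits[~fits["excluded"]].reset_index(drop=True)
    return kept, int(fits["excluded"].sum())
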