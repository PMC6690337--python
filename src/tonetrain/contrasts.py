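"""Centred contrast coding for categorical and continuous predictors.

All analyses evaluate effects averaged over the other predictors' levels
rather than at a reference level.  That is achieved by replacing factors
with centred dummy columns: a dummy is built against a stated baseline
(0/1) and then has its observed mean subtracted, so each derived column
has mean zero over the rows it was built from.  On balanced groups the
codes are exact fractions, e.g. for the three-level variability factor
with baseline LV the HV dummy becomes {LV: −1/3, HV: 2/3, HVB: −1/3}; in
pooled mode the single LV-vs-(HV ∪ HVB) column becomes
{LV: −2/3, HV: 1/3, HVB: 1/3}.

Centring constants come from the observed frequencies of the rows being
coded (so post-exclusion imbalance is absorbed into the constants); the
constants are recorded on the returned scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContrastScheme",
    "centred_dummies",
    "centred_binary",
    "pooled_contrast",
    "centre_numeric",
    "build_contrasts",
]


@dataclass
class ContrastScheme:
    """Record of how one predictor was turned into centred column(s).

    ``columns`` maps each derived column name to its level→code mapping
    (categorical factors) or to the (centre, scale) pair (continuous
    predictors).
    """

    factor: str
    columns: dict = field(default_factory=dict)
    centring: dict = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)


def _check_levels(series: pd.Series, levels: list, factor: str) -> None:
    observed = set(series.dropna().unique())
    unknown = observed - set(levels)
    if unknown:
        raise ValueError(
            f"unknown level(s) {sorted(map(str, unknown))} for factor {factor!r}; "
            f"expected {levels}"
        )


def centred_dummies(
    data: pd.DataFrame,
    factor: str,
    baseline: str,
    levels: list | None = None,
    prefix: str | None = None,
) -> tuple[pd.DataFrame, ContrastScheme]:
    """Code a k-level factor as k−1 centred dummies against ``baseline``."""
    if levels is None:
        levels = sorted(data[factor].dropna().unique().tolist())
    if baseline not in levels:
        raise ValueError(f"baseline {baseline!r} not among levels {levels}")
    _check_levels(data[factor], levels, factor)
    prefix = prefix or factor
    out = data.copy()
    scheme = ContrastScheme(factor=factor)
    for level in levels:
        if level == baseline:
            continue
        col = f"{prefix}_{str(level).lower()}"
        raw = (out[factor] == level).astype(float)
        centre = float(raw.mean())
        out[col] = raw - centre
        scheme.columns[col] = {
            lv: (1.0 - centre if lv == level else -centre) for lv in levels
        }
        scheme.centring[col] = centre
    return out, scheme


def centred_binary(
    data: pd.DataFrame,
    factor: str,
    reference: str,
    other: str | None = None,
    name: str | None = None,
) -> tuple[pd.DataFrame, ContrastScheme]:
    """Code a 2-level factor 0/1 with ``reference`` = 0, then centre."""
    levels = sorted(data[factor].dropna().unique().tolist())
    if other is None:
        rest = [lv for lv in levels if lv != reference]
        if len(rest) != 1:
            raise ValueError(
                f"factor {factor!r} must have exactly two levels, found {levels}"
            )
        other = rest[0]
    _check_levels(data[factor], [reference, other], factor)
    name = name or f"{factor}_c"
    out = data.copy()
    raw = (out[factor] == other).astype(float)
    centre = float(raw.mean())
    out[name] = raw - centre
    scheme = ContrastScheme(
        factor=factor,
        columns={name: {reference: -centre, other: 1.0 - centre}},
        centring={name: centre},
    )
    return out, scheme


def pooled_contrast(
    data: pd.DataFrame,
    factor: str = "condition",
    baseline: str = "LV",
    name: str = "condition_pooled",
) -> tuple[pd.DataFrame, ContrastScheme]:
    """Single centred column pooling all non-baseline levels against the baseline.

    Used for the Bayes-factor models, which contrast LV with the pooled
    high-variability conditions for maximal evidence.
    """
    levels = sorted(data[factor].dropna().unique().tolist())
    if baseline not in levels:
        raise ValueError(f"baseline {baseline!r} not among levels {levels}")
    out = data.copy()
    raw = (out[factor] != baseline).astype(float)
    centre = float(raw.mean())
    out[name] = raw - centre
    scheme = ContrastScheme(
        factor=factor,
        columns={
            name: {lv: (-centre if lv == baseline else 1.0 - centre) for lv in levels}
        },
        centring={name: centre},
    )
    return out, scheme


def centre_numeric(
    data: pd.DataFrame,
    column: str,
    scale: float = 1.0,
    name: str | None = None,
) -> tuple[pd.DataFrame, ContrastScheme]:
    """Centre (and optionally pre-scale) a numeric predictor."""
    name = name or f"{column}_c"
    out = data.copy()
    scaled = out[column].astype(float) * scale
    centre = float(scaled.mean())
    out[name] = scaled - centre
    scheme = ContrastScheme(
        factor=column,
        columns={name: (centre, scale)},
        centring={name: centre},
        scaling={name: scale},
    )
    return out, scheme


def build_contrasts(
    data: pd.DataFrame, factor_specs: list[dict]
) -> tuple[pd.DataFrame, list[ContrastScheme]]:
    """Apply a list of contrast specifications to a trial table.

    Each spec is a dict with ``kind`` in {"dummies", "binary", "pooled",
    "numeric"} plus the keyword arguments of the corresponding builder.
    Returns the augmented table and the schemes, in order.
    """
    builders = {
        "dummies": centred_dummies,
        "binary": centred_binary,
        "pooled": pooled_contrast,
        "numeric": centre_numeric,
    }
    schemes: list[ContrastScheme] = []
    out = data
    for spec in factor_specs:
        spec = dict(spec)
        kind = spec.pop("kind")
        try:
            builder = builders[kind]
        except KeyError:
            raise ValueError(f"unknown contrast kind {kind!r}") from None
        out, scheme = builder(out, **spec)
        schemes.append(scheme)
    return out, schemes
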