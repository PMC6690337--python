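"""Informed Bayes factors with a half-normal model of the alternative.

The evidence for a directional hypothesis H1 against a point null H0 is
summarised by the Bayes factor

    B = m1 / m0

where the data enter through a normal likelihood for the coefficient
estimate, ``Normal(beta; theta, se^2)``, H0 fixes ``theta = 0``, and H1
places a half-normal prior ``HN(0, x)`` on ``theta >= 0`` — mode at zero,
scale ``x`` set to a principled estimate of the predicted effect, mass
only in the predicted direction.  ``beta`` keeps its observed sign, so an
effect opposite to prediction pushes B toward the null.

All quantities live on the log-odds scale of the logistic mixed models
that produce ``beta`` and ``se``.  The marginal likelihood under H1 has a
closed form (a normal-by-normal convolution truncated to the positive
half-line), which is used everywhere; a quadrature route is retained for
cross-checking.

Scale-derivation rules
----------------------
Four rules translate quantities estimated elsewhere in a data set into
the H1 scale ``x``:

* main effect of pooled variability: ``x = p_bar - b`` (grand-mean
  log-odds minus task-baseline log-odds);
* session-by-variability interaction: ``x = t_bar`` (mean pre-to-post
  improvement across conditions);
* aptitude-by-variability interaction: ``x = a_bar`` (mean aptitude
  effect across conditions);
* three-way aptitude-by-session-by-variability interaction:
  ``x = (maxa - ba) / 2`` with ``maxa`` the maximal aptitude effect the
  scale permits and ``ba`` the baseline aptitude effect in the data.

Conclusions follow the 1/3 and 3 conventions: ``B < 1/3`` is substantial
evidence for the null, ``B > 3`` substantial evidence for H1, anything
between (boundaries included) is ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "NULL_THRESHOLD",
    "H1_THRESHOLD",
    "HalfNormalH1",
    "BayesFactorResult",
    "RobustnessRegion",
    "SampleSizeProjection",
    "bf_halfnormal",
    "conclusion_category",
    "robustness_region",
    "evaluate_contrast",
    "chance_logodds",
    "scale_main_effect",
    "scale_session_interaction",
    "scale_aptitude_interaction",
    "scale_threeway",
    "max_aptitude_effect",
    "required_sample_size",
]

NULL_THRESHOLD = 1.0 / 3.0
H1_THRESHOLD = 3.0

#: chance/minimal performance per task kind, as log-odds of the chance
#: success probability (signed: at or below zero)
_CHANCE_PROB = {
    "two_afc": 0.5,          # two-alternative forced choice
    "four_way_tone": 0.25,   # pick one of four tones
    "pinyin_minimal": 1.0 / 72.0,  # one correct response in a 72-item test
    "three_oddity": 1.0 / 3.0,     # three-interval oddity
}


@dataclass(frozen=True)
class HalfNormalH1:
    """Scale of the half-normal H1 prior plus how it was derived."""

    scale: float
    derivation_case: str  # main_effect | session_interaction | aptitude_interaction | threeway
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"H1 scale must be positive, got {self.scale}")


@dataclass(frozen=True)
class RobustnessRegion:
    """Interval of H1 scales supporting the same qualitative conclusion.

    ``hi`` is ``inf`` for substantial-null conclusions (an ever more
    diffuse prior only strengthens the case for the null).  ``empty`` is
    set when no positive scale yields the reference category.
    """

    lo: float
    hi: float
    category: str
    empty: bool = False

    def __str__(self) -> str:  # Table-style "lo : hi"
        if self.empty:
            return "(empty)"
        hi = "inf" if math.isinf(self.hi) else f"{self.hi:.2f}"
        return f"{self.lo:.2f} : {hi}"


@dataclass(frozen=True)
class BayesFactorResult:
    """One contrast's Bayes-factor evaluation."""

    beta: float
    se: float
    h1: HalfNormalH1
    B: float
    category: str
    robustness: RobustnessRegion


@dataclass(frozen=True)
class SampleSizeProjection:
    """Outcome of the SE ∝ 1/sqrt(n) sample-size projection."""

    n_required: int | None
    attainable: bool
    criterion: float
    b_at_n0: float
    b_limit: float  # B in the large-n limit actually reached by the scan


def _log_bf_closed(beta, se, x):
    """log Bayes factor in closed form, vectorised and underflow-safe.

    The H1 marginal ∫_0^∞ N(beta; θ, se²) · HN(θ; 0, x) dθ equals
    2·N(beta; 0, se²+x²)·Φ(μ_post/σ_post) — the product of two normal
    densities is a normal in θ times N(beta; 0, se²+x²); truncation to
    θ ≥ 0 contributes Φ(μ_post/σ_post) and the half-normal
    normalisation the factor 2.  Everything is evaluated on the log
    scale so extreme z = beta/se stay representable.
    """
    s2 = se * se + x * x
    sd = np.sqrt(s2)
    log_m1 = np.log(2.0) + norm.logpdf(beta, 0.0, sd) + norm.logcdf(beta * x / (se * sd))
    log_m0 = norm.logpdf(beta, 0.0, se)
    return log_m1 - log_m0


def _marginal_h1_quad(beta: float, se: float, x: float) -> float:
    """Quadrature route for the H1 marginal likelihood (cross-check)."""

    def integrand(theta: float) -> float:
        return norm.pdf(beta, theta, se) * 2.0 * norm.pdf(theta, 0.0, x)

    upper = max(8.0 * x, beta + 8.0 * se, 1.0)
    val, _ = integrate.quad(integrand, 0.0, upper, epsabs=1e-10, limit=200)
    return val


def bf_halfnormal(beta: float, se: float, x: float, method: str = "closed_form") -> float:
    """Bayes factor for H1: θ ~ half-normal(0, x) against H0: θ = 0.

    Parameters
    ----------
    beta, se
        Coefficient estimate and standard error on the log-odds scale.
        ``beta`` keeps its sign; negative estimates (opposite to the
        predicted direction) yield B < 1.
    x
        Scale (SD) of the half-normal H1 prior, log-odds units.
    method
        ``"closed_form"`` (default) or ``"quad"`` for adaptive
        quadrature; the two agree to well below 1e-6.
    """
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    if not x > 0:
        raise ValueError(f"H1 scale must be positive, got {x}")
    if method == "closed_form":
        return float(np.exp(_log_bf_closed(beta, se, x)))
    if method == "quad":
        return _marginal_h1_quad(beta, se, x) / norm.pdf(beta, 0.0, se)
    raise ValueError(f"unknown method {method!r}")


def conclusion_category(B: float) -> str:
    """Classify a Bayes factor by the 1/3 and 3 conventions.

    Boundary values count as ambiguous (the intervals are open).
    """
    if not B > 0:
        raise ValueError(f"Bayes factor must be positive, got {B}")
    if B < NULL_THRESHOLD:
        return "substantial_null"
    if B > H1_THRESHOLD:
        return "substantial_H1"
    return "ambiguous"


def robustness_region(
    beta: float,
    se: float,
    x_used: float,
    x_max: float = 50.0,
    step: float = 0.01,
) -> RobustnessRegion:
    """Maximal contiguous interval of scales sharing the conclusion at ``x_used``.

    The grid runs over ``(0, x_max]`` at ``step`` resolution.  If the
    region extends to the smallest grid point its lower endpoint is
    reported as 0 (as x → 0+ the prior collapses onto the null and
    B → 1, so only ambiguous regions actually touch 0).  A
    substantial-null region that reaches ``x_max`` is reported with an
    infinite upper endpoint.
    """
    reference = conclusion_category(bf_halfnormal(beta, se, x_used))
    xs = np.arange(step, x_max + step / 2, step)
    bs = np.exp(_log_bf_closed(beta, se, xs))
    match = np.empty(xs.shape, dtype=bool)
    match[:] = False
    if reference == "substantial_null":
        match = bs < NULL_THRESHOLD
    elif reference == "substantial_H1":
        match = bs > H1_THRESHOLD
    else:
        match = (bs >= NULL_THRESHOLD) & (bs <= H1_THRESHOLD)
    if not match.any():
        return RobustnessRegion(lo=math.nan, hi=math.nan, category=reference, empty=True)
    # contiguous run containing the grid point nearest x_used
    idx = int(np.clip(round(x_used / step) - 1, 0, len(xs) - 1))
    if not match[idx]:
        # x_used off-grid near a boundary: snap to the nearest matching point
        matching = np.flatnonzero(match)
        idx = matching[np.argmin(np.abs(xs[matching] - x_used))]
    lo_i = idx
    while lo_i > 0 and match[lo_i - 1]:
        lo_i -= 1
    hi_i = idx
    while hi_i < len(xs) - 1 and match[hi_i + 1]:
        hi_i += 1
    lo = 0.0 if lo_i == 0 else round(float(xs[lo_i]), 2)
    if hi_i == len(xs) - 1:
        hi = math.inf if reference == "substantial_null" else round(float(xs[hi_i]), 2)
    else:
        hi = round(float(xs[hi_i]), 2)
    return RobustnessRegion(lo=lo, hi=hi, category=reference)


def evaluate_contrast(beta: float, se: float, h1: HalfNormalH1 | float) -> BayesFactorResult:
    """Full Bayes-factor evaluation of one contrast: B, category, robustness."""
    if not isinstance(h1, HalfNormalH1):
        h1 = HalfNormalH1(scale=float(h1), derivation_case="supplied")
    B = bf_halfnormal(beta, se, h1.scale)
    return BayesFactorResult(
        beta=beta,
        se=se,
        h1=h1,
        B=B,
        category=conclusion_category(B),
        robustness=robustness_region(beta, se, h1.scale),
    )


def chance_logodds(task_kind: str) -> float:
    """Log-odds of chance (or minimal) performance for a task kind.

    two_afc → logit(1/2) = 0; four_way_tone → logit(1/4) ≈ −1.099;
    pinyin_minimal → logit(1/72) ≈ −4.263 (one correct response in 72,
    since a true zero has no log-odds); three_oddity → logit(1/3).
    """
    try:
        p = _CHANCE_PROB[task_kind]
    except KeyError:
        raise ValueError(
            f"unknown task kind {task_kind!r}; expected one of {sorted(_CHANCE_PROB)}"
        ) from None
    return math.log(p / (1.0 - p))


def scale_main_effect(p_bar_logodds: float, baseline_logodds: float) -> HalfNormalH1:
    """H1 scale for a predicted main effect: x = grand mean − baseline.

    The largest conceivable group difference is twice the headroom of the
    grand mean over baseline; half of that (≈2 SD of the half-normal)
    gives the scale.
    """
    x = p_bar_logodds - baseline_logodds
    if not x > 0:
        raise ValueError(
            f"grand mean ({p_bar_logodds}) must exceed baseline ({baseline_logodds})"
        )
    return HalfNormalH1(
        scale=x,
        derivation_case="main_effect",
        inputs={"p_bar": p_bar_logodds, "baseline": baseline_logodds},
    )


def scale_session_interaction(t_bar: float) -> HalfNormalH1:
    """H1 scale for a session-by-variability interaction: x = mean improvement."""
    if not t_bar > 0:
        raise ValueError(f"mean session effect must be positive, got {t_bar}")
    return HalfNormalH1(scale=t_bar, derivation_case="session_interaction", inputs={"t_bar": t_bar})


def scale_aptitude_interaction(a_bar: float) -> HalfNormalH1:
    """H1 scale for an aptitude-by-variability interaction: x = mean aptitude effect."""
    if not a_bar > 0:
        raise ValueError(f"mean aptitude effect must be positive, got {a_bar}")
    return HalfNormalH1(scale=a_bar, derivation_case="aptitude_interaction", inputs={"a_bar": a_bar})


def scale_threeway(max_aptitude_effect: float, baseline_aptitude_effect: float) -> HalfNormalH1:
    """H1 scale for the three-way interaction: x = (maxa − ba) / 2."""
    maxa, ba = max_aptitude_effect, baseline_aptitude_effect
    if not (maxa > ba >= 0):
        raise ValueError(f"need maxa > ba >= 0, got maxa={maxa}, ba={ba}")
    return HalfNormalH1(
        scale=(maxa - ba) / 2.0,
        derivation_case="threeway",
        inputs={"maxa": maxa, "ba": ba},
    )


def max_aptitude_effect(
    ceiling_logodds: float, chance_logodds: float, aptitude_range: float
) -> float:
    """Maximal per-unit aptitude effect the scale permits.

    Assumes maximal-aptitude subjects sit at ceiling (e.g. 71/72 correct,
    log-odds 4.263) and minimal-aptitude subjects at chance; the log-odds
    span divided by the length of the aptitude predictor gives the
    steepest slope per one-unit aptitude step.
    """
    if not aptitude_range > 0:
        raise ValueError(f"aptitude range must be positive, got {aptitude_range}")
    if not ceiling_logodds > chance_logodds:
        raise ValueError(
            f"ceiling ({ceiling_logodds}) must exceed chance ({chance_logodds})"
        )
    return (ceiling_logodds - chance_logodds) / aptitude_range


def required_sample_size(
    beta: float,
    se: float,
    x: float,
    n0: int,
    criterion: float = NULL_THRESHOLD,
    n_max: int = 100_000,
) -> SampleSizeProjection:
    """Smallest n at which the projected Bayes factor reaches ``criterion``.

    Holds ``beta`` and the H1 scale fixed and shrinks the standard error
    as SE(n) = se · sqrt(n0 / n), i.e. the usual 1/sqrt(n) precision
    gain.  Scans n upward from ``n0``; if the criterion is never crossed
    by ``n_max`` (the estimate is too far from zero in the predicted
    direction for the null ever to accrue substantial evidence), the
    projection is reported non-attainable with the limiting B reached.
    """
    if n0 <= 0:
        raise ValueError(f"n0 must be positive, got {n0}")
    b0 = bf_halfnormal(beta, se, x)
    if b0 <= criterion:
        return SampleSizeProjection(
            n_required=n0, attainable=True, criterion=criterion, b_at_n0=b0, b_limit=b0
        )
    ns = np.arange(n0, n_max + 1)
    ses = se * np.sqrt(n0 / ns)
    with np.errstate(over="ignore"):
        bs = np.exp(_log_bf_closed(beta, ses, x))
    hits = np.flatnonzero(bs <= criterion)
    if hits.size == 0:
        return SampleSizeProjection(
            n_required=None,
            attainable=False,
            criterion=criterion,
            b_at_n0=b0,
            b_limit=float(bs[-1]),
        )
    n_req = int(ns[hits[0]])
    return SampleSizeProjection(
        n_required=n_req,
        attainable=True,
        criterion=criterion,
        b_at_n0=b0,
        b_limit=float(bs[hits[0]]),
    )
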