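"""Combined-treatment composition, additive lower bound, and synergy gain.

A two-course treatment (e.g. PDT followed by PTT with the same nanocomplex)
is modelled through the three-state fate of each cell after the first course:
dead cells remain dead, affected (partially damaged) cells and unaffected
cells each carry their own conditional death probability under the second
course.  The composed death rate is

    P(D) = P_d1 * 1 + P_a1 * P(d2|a1) + P_na1 * P(d2|na1).

When the conditional terms are unknown, treating the two courses as
independent Bernoulli kills and ignoring sensitisation of affected cells
yields the additive lower bound (Bliss-independence-style)

    B_L = p_d1 + (1 - p_d1) * p_d2.

The synergy gain S_G is the difference between an observed (or composed)
combined death rate and a comparison course: positive gain is synergy,
near-zero is additivity, negative is antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .states import StateProbabilities


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class CombinationInput:
    """Inputs describing a two-course treatment.

    ``p_d1`` and ``p_d2`` are the marginal death probabilities of each course
    alone.  ``observed_combined`` is the measured death rate of the combined
    course when available.  ``p_d2_given_a1`` / ``p_d2_given_na1`` are the
    conditional death probabilities of the second course for cells left
    affected / unaffected by the first; the conditional for cells already
    dead is identically 1.
    """

    p_d1: float
    p_d2: float
    observed_combined: float | None = None
    p_d2_given_a1: float | None = None
    p_d2_given_na1: float | None = None

    def __post_init__(self) -> None:
        _check_fraction("p_d1", self.p_d1)
        _check_fraction("p_d2", self.p_d2)
        for name in ("observed_combined", "p_d2_given_a1", "p_d2_given_na1"):
            v = getattr(self, name)
            if v is not None:
                _check_fraction(name, v)


@dataclass(frozen=True)
class CombinationResult:
    """Summary of a combined-treatment evaluation."""

    lower_bound: float
    gain: float | None
    synergy_class: str | None
    percent_gain: int | None
    gain_components: tuple[float, float] | None = None


def lower_bound(p_d1: float, p_d2: float) -> float:
    """Additive (independence) lower bound for the combined death rate.

    ``p_d1 + (1 - p_d1) * p_d2``: the kill rate of two independent courses
    with no sensitisation of surviving cells.  Symmetric in its arguments and
    bounded by [max(p_d1, p_d2), 1].
    """
    p1 = _check_fraction("p_d1", p_d1)
    p2 = _check_fraction("p_d2", p_d2)
    return p1 + (1.0 - p1) * p2


def gain_from_observation(observed_combined: float, baseline: float) -> float:
    """Synergy gain: observed combined death rate minus a comparison rate.

    The baseline is either the additive lower bound (prediction mode) or the
    same-treatment full-course death rate at matched total duration
    (experimental mode).  The result may be negative (antagonism).
    """
    obs = _check_fraction("observed_combined", observed_combined)
    base = _check_fraction("baseline", baseline)
    return obs - base


def compose_death_rate(inp: CombinationInput, states: StateProbabilities) -> float:
    """Composed death rate of a two-course treatment via the three-state model.

    Requires the conditional terms on ``inp``; without them the additive
    :func:`lower_bound` is the available fallback.
    """
    if inp.p_d2_given_a1 is None or inp.p_d2_given_na1 is None:
        raise ValueError(
            "conditional terms p_d2_given_a1 and p_d2_given_na1 are required; "
            "use lower_bound(p_d1, p_d2) when they are unknown"
        )
    d = states.p_d * 1.0 + states.p_a * inp.p_d2_given_a1 + states.p_na * inp.p_d2_given_na1
    return float(min(1.0, max(0.0, d)))


def gain_decomposition(
    inp: CombinationInput,
    states: StateProbabilities,
    same_treatment_conditionals: tuple[float, float],
) -> tuple[float, float]:
    """Split the cross-vs-same-treatment gain into affected/unaffected parts.

    ``same_treatment_conditionals`` is ``(p_d2_given_a1, p_d2_given_na1)``
    for a continuation of the *first* treatment.  Returns
    ``(gain_affected, gain_unaffected)`` where

        gain_affected   = P_a1  * (p_cross(d2|a1)  - p_same(d2|a1))
        gain_unaffected = P_na1 * (p_cross(d2|na1) - p_same(d2|na1))

    Their sum equals the difference of the two composed death rates (the
    P_d1 term cancels because dead cells remain dead under either course).
    """
    if inp.p_d2_given_a1 is None or inp.p_d2_given_na1 is None:
        raise ValueError("cross-treatment conditional terms required")
    same_a1 = _check_fraction("same p_d2_given_a1", same_treatment_conditionals[0])
    same_na1 = _check_fraction("same p_d2_given_na1", same_treatment_conditionals[1])
    g_a = states.p_a * (inp.p_d2_given_a1 - same_a1)
    g_na = states.p_na * (inp.p_d2_given_na1 - same_na1)
    return float(g_a), float(g_na)


def classify_synergy(gain: float, epsilon: float = 0.01) -> str:
    """Classify a gain as ``synergetic``, ``additive`` or ``antagonistic``.

    ``epsilon`` (fraction units) is the half-width of the additive band
    around zero.  The default of one percentage point matches the reading of
    sub-1-pp course gains as merely additive; pass a smaller band to call
    synergy more aggressively.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if gain > epsilon:
        return "synergetic"
    if gain < -epsilon:
        return "antagonistic"
    return "additive"


def percent_gain(gain: float, denominator: float, convention: str = "truncate") -> int:
    """Integer percent gain, ``100 * gain / denominator`` reduced by convention.

    The denominator (a reference death rate: the single-treatment rate or the
    lower bound) and the reduction convention (``truncate`` toward zero or
    ``round`` half-to-even) are always explicit; neither is defaulted
    silently in reports.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    ratio = 100.0 * gain / denominator
    if convention == "truncate":
        return int(ratio)
    if convention == "round":
        return int(round(ratio))
    raise ValueError(f"unknown convention {convention!r}")


def combine(
    inp: CombinationInput,
    states: StateProbabilities | None = None,
    epsilon: float = 0.01,
    percent_convention: str = "round",
) -> CombinationResult:
    """One-call summary: lower bound, gain vs the bound, class and percent gain.

    With ``observed_combined`` present the gain is observed minus the lower
    bound; otherwise, if states and conditional terms are supplied, the
    composed rate stands in for the observation.  Percent gain is expressed
    relative to the lower bound.
    """
    bl = lower_bound(inp.p_d1, inp.p_d2)
    observed = inp.observed_combined
    components = None
    if observed is None and states is not None and inp.p_d2_given_a1 is not None:
        observed = compose_death_rate(inp, states)
    if observed is None:
        return CombinationResult(lower_bound=bl, gain=None, synergy_class=None, percent_gain=None)
    g = gain_from_observation(observed, bl)
    return CombinationResult(
        lower_bound=bl,
        gain=g,
        synergy_class=classify_synergy(g, epsilon),
        percent_gain=percent_gain(g, bl, percent_convention),
        gain_components=components,
    )
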