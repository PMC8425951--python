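"""Paired-compound additivity/synergy classification with significance tiers.

A pair's normalized effect E_AB is compared with the sum of its single-
agent effects E_A + E_B.  In the default relative mode a pair is additive
when it reaches the sum less a 10% margin (E_AB >= 0.90 * sum) and
potentially synergistic when it exceeds the sum by 25% or more
(E_AB >= 1.25 * sum); an absolute percentage-point mode (sum - 10 / sum +
25 points) is provided because either reading of the margin is defensible.
Significance tiers mark pairs beating one (+) or both (++) single-agent
controls in per-group t-tests at the Bonferroni-adjusted alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stats import two_sample_t

__all__ = [
    "CombinationResult",
    "classify_additivity",
    "significance_tier",
    "enhanced_median",
    "combination_table",
]

ADDITIVE_MARGIN = 0.10
SYNERGY_MARGIN = 0.25


@dataclass(frozen=True)
class CombinationResult:
    """One compound pair: effects, additivity class, significance tier."""

    pair: tuple
    e_a: float = math.nan
    e_b: float = math.nan
    e_ab: float = math.nan
    sum_ab: float = math.nan
    additivity: str = "none"
    tier: str = "ns"
    enhanced_median: bool = False
    lethal: bool = False


def classify_additivity(e_a: float, e_b: float, e_ab: float, mode: str = "relative") -> str:
    """'synergistic', 'additive', or 'none' for one pair of effects.

    Synergistic pairs also satisfy the additive criterion; the returned
    label is the strongest class reached.
    """
    if not all(math.isfinite(v) for v in (e_a, e_b, e_ab)):
        raise ValueError("effects must be finite")
    total = e_a + e_b
    if mode == "relative":
        if total <= 0:
            raise ValueError("relative mode needs e_a + e_b > 0")
        additive_at = (1.0 - ADDITIVE_MARGIN) * total
        synergy_at = (1.0 + SYNERGY_MARGIN) * total
    elif mode == "absolute_pp":
        additive_at = total - 100.0 * ADDITIVE_MARGIN
        synergy_at = total + 100.0 * SYNERGY_MARGIN
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if e_ab >= synergy_at:
        return "synergistic"
    if e_ab >= additive_at:
        return "additive"
    return "none"


def significance_tier(pair_values, a_values, b_values, alpha_adjusted: float) -> str:
    """'plus_plus' if the pair significantly beats both singles, 'plus' if
    exactly one, 'ns' otherwise (pooled t-test, greater-mean direction)."""
    wins = 0
    for single in (a_values, b_values):
        t, p = two_sample_t(pair_values, single, variance="pooled", sides="two")
        if t > 0 and p < alpha_adjusted:
            wins += 1
    return {0: "ns", 1: "plus", 2: "plus_plus"}[wins]


def enhanced_median(pair_values, a_values, b_values) -> bool:
    """True when the pair's median strictly beats both single-agent medians."""
    med = float(np.median(np.asarray(pair_values, dtype=float)))
    best_single = max(
        float(np.median(np.asarray(a_values, dtype=float))),
        float(np.median(np.asarray(b_values, dtype=float))),
    )
    return med > best_single


def combination_table(
    effects_by_condition: dict,
    pairs,
    lethal_pairs=(),
    alpha_adjusted: float = 0.05,
    mode: str = "relative",
) -> list[CombinationResult]:
    """Build one :class:`CombinationResult` per nominal pair.

    ``effects_by_condition`` maps condition label (a compound id, or
    ``"A+B"`` for a pair) to its normalized per-well values; lethal pairs
    (supplied as annotations — lethality is observed, not computed) carry
    ``lethal=True`` and no effect fields or classification.
    """
    lethal = {frozenset(p) for p in lethal_pairs}
    results = []
    for a, b in pairs:
        key = frozenset((a, b))
        pair_label = f"{a}+{b}"
        if key in lethal:
            results.append(CombinationResult(pair=(a, b), lethal=True))
            continue
        for cid in (a, b):
            if cid not in effects_by_condition:
                raise KeyError(f"missing single-agent values for {cid!r} (pair {pair_label})")
        if pair_label not in effects_by_condition:
            alt = f"{b}+{a}"
            if alt not in effects_by_condition:
                raise KeyError(f"missing pair values for {pair_label!r}")
            pair_label = alt
        va = np.asarray(effects_by_condition[a], dtype=float)
        vb = np.asarray(effects_by_condition[b], dtype=float)
        vab = np.asarray(effects_by_condition[pair_label], dtype=float)
        e_a, e_b, e_ab = float(va.mean()), float(vb.mean()), float(vab.mean())
        results.append(
            CombinationResult(
                pair=(a, b),
                e_a=e_a,
                e_b=e_b,
                e_ab=e_ab,
                sum_ab=e_a + e_b,
                additivity=classify_additivity(e_a, e_b, e_ab, mode=mode),
                tier=significance_tier(vab, va, vb, alpha_adjusted),
                enhanced_median=enhanced_median(vab, va, vb),
            )
        )
    return results
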