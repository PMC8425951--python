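"""Per-concentration SSMD scoring and primary-screen hit calling.

The strictly standardized mean difference (SSMD),
``beta = (mu_1 - mu_2) / sqrt(sigma_1^2 + sigma_2^2)``, scores each
compound concentration against the ablated (negative) controls of the same
run.  A compound whose best concentration reaches SSMD >= 1 and that
survives artifact exclusion (autofluorescence, lethality) is a hit.  Hits
are banded by their maximal SSMD — fairly moderate [1, 1.28), moderate
[1.28, 1.645), semi-strong [1.645, 2), strong [2, 3), very strong >= 3 —
and labelled by dose trend (concentration-dependent, discontinuous, or
singular).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import spearmanr

__all__ = [
    "SSMDResult",
    "HitRecord",
    "UndefinedScoreError",
    "ssmd",
    "classify_effect",
    "dose_trend",
    "call_hits",
    "score_screen",
    "EFFECT_BANDS",
]

#: Effect-class bands on max SSMD, closed on the left.
EFFECT_BANDS = [
    (1.0, 1.28, "fairly_moderate"),
    (1.28, 1.645, "moderate"),
    (1.645, 2.0, "semi_strong"),
    (2.0, 3.0, "strong"),
    (3.0, math.inf, "very_strong"),
]

HIT_THRESHOLD = 1.0
DOSE_TREND_RHO = 0.7


class UndefinedScoreError(ValueError):
    """SSMD is undefined (both group variances are zero)."""


@dataclass(frozen=True)
class SSMDResult:
    """SSMD of one compound concentration vs the run's ablated controls."""

    compound_id: str
    concentration_uM: float
    n_wells: int
    mean: float
    sd: float
    ssmd: float


@dataclass(frozen=True)
class HitRecord:
    """Per-compound hit decision with effect class and dose-trend label."""

    compound_id: str
    max_ssmd: float
    best_concentration_uM: float
    effect_class: str
    dose_trend: str
    is_hit: bool
    exclusion: str = "none"


def ssmd(treated_signals, neg_signals, estimator: str = "mm") -> float:
    """SSMD of a treated group against negative controls.

    estimator "mm" is the method-of-moments plug-in
    ``(xbar_t - xbar_n) / sqrt(s_t^2 + s_n^2)``;  "umvue" multiplies it by
    the small-sample Gamma correction
    ``sqrt(2/K) * Gamma(K/2) / Gamma((K-1)/2)`` with ``K = n_t + n_n - 2``,
    removing the upward bias of ``1/s`` at the small per-concentration
    sample sizes typical of qHTS plates.
    """
    t = np.asarray(treated_signals, dtype=float)
    n = np.asarray(neg_signals, dtype=float)
    if t.size < 2 or n.size < 2:
        raise ValueError("need >= 2 values per group")
    var_sum = t.var(ddof=1) + n.var(ddof=1)
    if var_sum == 0:
        raise UndefinedScoreError("both group variances are zero")
    beta = (t.mean() - n.mean()) / math.sqrt(var_sum)
    if estimator == "mm":
        return float(beta)
    if estimator == "umvue":
        k = t.size + n.size - 2
        correction = math.sqrt(2.0 / k) * math.exp(gammaln(k / 2) - gammaln((k - 1) / 2))
        return float(beta * correction)
    raise ValueError(f"unknown estimator {estimator!r}")


def classify_effect(score: float) -> str:
    """Band an SSMD score; below 1 is 'none'. Total on finite reals."""
    if not math.isfinite(score):
        raise ValueError(f"SSMD must be finite, got {score}")
    for low, high, label in EFFECT_BANDS:
        if low <= score < high:
            return label
    return "none"


def dose_trend(ssmd_by_concentration: dict) -> str:
    """Label the concentration profile of a compound's SSMD scores.

    singular: exactly one concentration reaches SSMD >= 1.
    concentration_dependent: Spearman rank correlation between
    log-concentration and SSMD >= 0.7 across all levels and at least two
    levels reach SSMD >= 1.
    discontinuous: anything else.

    The underlying screen reported these three categories without a
    numeric rule; the Spearman criterion is this module's
    operationalization and the threshold is configurable via
    ``DOSE_TREND_RHO``.
    """
    if len(ssmd_by_concentration) < 3:
        raise ValueError("need >= 3 scored concentrations")
    concs = np.array(sorted(ssmd_by_concentration), dtype=float)
    scores = np.array([ssmd_by_concentration[c] for c in concs])
    n_active = int((scores >= HIT_THRESHOLD).sum())
    if n_active == 1:
        return "singular"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> nan rho
        rho = spearmanr(np.log(concs), scores).statistic
    if n_active >= 2 and np.isfinite(rho) and rho >= DOSE_TREND_RHO:
        return "concentration_dependent"
    return "discontinuous"


def call_hits(screen_results, exclusions: dict | None = None) -> list[HitRecord]:
    """Flag hits from per-concentration SSMD results.

    ``screen_results`` is an iterable of :class:`SSMDResult` covering every
    compound at every concentration; ``exclusions`` maps compound_id ->
    reason ("autofluorescent" or "lethal") from visual inspection.  Excluded
    compounds are retained in the output with ``is_hit`` False and the
    reason recorded, for audit.
    """
    exclusions = dict(exclusions or {})
    by_compound: dict[str, list[SSMDResult]] = {}
    for res in screen_results:
        by_compound.setdefault(res.compound_id, []).append(res)
    for cid in set(exclusions) - set(by_compound):
        warnings.warn(f"excluded compound {cid!r} not present in screen results")
    records = []
    for cid in sorted(by_compound):
        results = by_compound[cid]
        # best level: highest SSMD; ties broken toward the lowest
        # concentration (favouring potency)
        best = max(results, key=lambda r: (r.ssmd, -r.concentration_uM))
        profile = {r.concentration_uM: r.ssmd for r in results}
        trend = dose_trend(profile) if len(profile) >= 3 else "singular"
        exclusion = exclusions.get(cid, "none")
        records.append(
            HitRecord(
                compound_id=cid,
                max_ssmd=best.ssmd,
                best_concentration_uM=best.concentration_uM,
                effect_class=classify_effect(best.ssmd),
                dose_trend=trend,
                is_hit=bool(best.ssmd >= HIT_THRESHOLD and exclusion == "none"),
                exclusion=exclusion,
            )
        )
    return records


def _usable(rec) -> bool:
    return rec.alive and "dispensing_error" not in rec.flags


def score_screen(records, estimator: str = "mm") -> list[SSMDResult]:
    """SSMD score table for a whole run's well table.

    Negative controls are the run's ablated (+prodrug, vehicle-only)
    ``neg_ctrl`` wells; each (compound, concentration) drug group is scored
    against them.  Dead and dispensing-error wells are dropped.
    """
    neg = [r.raw_signal for r in records if r.group == "neg_ctrl" and _usable(r)]
    if len(neg) < 2:
        raise ValueError("need >= 2 usable neg_ctrl wells to score a screen")
    groups: dict[tuple, list[float]] = {}
    for r in records:
        if r.group == "drug" and _usable(r):
            groups.setdefault((r.compound_id, r.concentration_uM), []).append(r.raw_signal)
    results = []
    for (cid, conc), vals in sorted(groups.items()):
        if len(vals) < 2:
            continue
        arr = np.asarray(vals)
        results.append(
            SSMDResult(
                compound_id=cid,
                concentration_uM=conc,
                n_wells=len(vals),
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)),
                ssmd=ssmd(vals, neg, estimator=estimator),
            )
        )
    return results
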