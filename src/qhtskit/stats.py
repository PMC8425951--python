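"""Confirmation-stage effect statistics and the hypothesis-testing toolkit.

Per-well signals are normalized to the control signal window of their own
run — ablated controls at 0%, non-ablated controls at 100% — which absorbs
between-fish reporter variation and between-assay window drift and lets
identical conditions be pooled across experimental repeats:

    N_i = 100 * (S_i - Xbar_neg) / (Xbar_pos - Xbar_neg)

Pooled effects are reported with t-based 95% confidence intervals and
Bonferroni-adjusted significance.  The remaining operations wrap the
study's testing toolkit (Student/Welch t, Fisher's exact, Mann-Whitney U,
Benjamini-Hochberg FDR, delta-delta-Ct fold change) behind one surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizedEffect",
    "DegenerateWindowError",
    "normalize",
    "pooled_effect",
    "two_sample_t",
    "bonferroni_alpha",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "bh_fdr",
    "ddct_fold_change",
]


class DegenerateWindowError(ValueError):
    """The control signal window has zero width."""


@dataclass(frozen=True)
class NormalizedEffect:
    """Pooled normalized effect (% of signal window) for one condition."""

    condition: str
    values: tuple
    effect: float
    ci95: tuple
    n: int
    p: float = math.nan
    alpha_adjusted: float = math.nan
    significant: bool = False


def normalize(signals, neg_mean: float, pos_mean: float):
    """Per-well percent-of-window values; may fall outside [0, 100]."""
    if pos_mean == neg_mean:
        raise DegenerateWindowError("pos_mean equals neg_mean: zero signal window")
    s = np.asarray(signals, dtype=float)
    return 100.0 * (s - neg_mean) / (pos_mean - neg_mean)


def pooled_effect(
    normalized_values_by_repeat,
    condition: str = "",
    p: float = math.nan,
    alpha_adjusted: float = math.nan,
) -> NormalizedEffect:
    """Pool normalized values across repeats: mean and t-based 95% CI."""
    values = np.concatenate([np.asarray(v, dtype=float) for v in normalized_values_by_repeat])
    n = values.size
    if n < 2:
        raise ValueError("need >= 2 pooled values")
    effect = float(values.mean())
    half = float(sps.t.ppf(0.975, n - 1) * values.std(ddof=1) / math.sqrt(n))
    significant = bool(p < alpha_adjusted) if math.isfinite(p) else False
    return NormalizedEffect(
        condition=condition,
        values=tuple(values),
        effect=effect,
        ci95=(effect - half, effect + half),
        n=n,
        p=p,
        alpha_adjusted=alpha_adjusted,
        significant=significant,
    )


def two_sample_t(a, b, variance: str = "pooled", sides: str = "two") -> tuple[float, float]:
    """Student's (pooled-variance) or Welch's t-test; two-sided by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if variance not in ("pooled", "welch"):
        raise ValueError(f"unknown variance option {variance!r}")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ValueError("zero combined variance")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sides]
    res = sps.ttest_ind(a, b, equal_var=(variance == "pooled"), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(alpha_family: float, m: int) -> tuple[float, float]:
    """Family-wise alpha divided by the comparison count.

    Returns ``(alpha_adjusted, display)`` where display is the 3-decimal
    rounded value used in report tables (e.g. 0.05/12 -> 0.004).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must be in (0, 1)")
    adjusted = alpha_family / m
    return adjusted, round(adjusted, 3)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    The two-sided p sums hypergeometric probabilities (margins fixed) of
    all tables at most as probable as the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("cells must be non-negative integers")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def mann_whitney_u(a, b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    mode "exact" enumerates the null permutation distribution (valid
    without ties), "normal_approx" uses the tie-corrected continuity-
    corrected normal approximation, and "auto" picks exact for
    ``n_a + n_b <= 20`` without ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("need >= 1 value per group")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if mode == "auto":
        mode = "exact" if (a.size + b.size <= 20 and not has_ties) else "normal_approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ddct_fold_change(
    ct_target_kd: float, ct_ref_kd: float, ct_target_ctl: float, ct_ref_ctl: float
) -> float:
    """Relative expression 2^-ddCt from qPCR cycle thresholds.

    ddCt = (Ct_target - Ct_ref)_knockdown - (Ct_target - Ct_ref)_control.
    """
    cts = (ct_target_kd, ct_ref_kd, ct_target_ctl, ct_ref_ctl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_kd - ct_ref_kd) - (ct_target_ctl - ct_ref_ctl)
    return 2.0**-ddct
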