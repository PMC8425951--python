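"""Sample-size and power computation for window-fraction effects.

The design question: how many larvae per condition are needed to detect a
treatment that recovers a fraction ``f`` of the control signal window
(mu_pos - mu_neg) at type-I error alpha and type-II error beta?  The
treated-group variance is interpolated between the control variances,
``sigma_t^2 = (1 - f) * sigma_neg^2 + f * sigma_pos^2``, reflecting that a
partially rescued population sits between the two control populations.

Two analytic methods are offered: the closed-form normal approximation

    n = ceil( (z_{1-alpha(/2)} + z_{1-beta})^2 * (sigma_t^2 + sigma_neg^2)
              / (f * window)^2 )

and "t_iterative", which searches for the smallest n whose exact
noncentral-t two-sample test power reaches 1 - beta (the z form
understates n below about n = 5).  ``power_mc`` verifies either by
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AssayControls", "PowerSpec", "required_n", "power_mc", "power_exact"]


@dataclass(frozen=True)
class AssayControls:
    """Control-group moments defining the signal window, in AU."""

    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float

    def __post_init__(self):
        if self.sigma_neg < 0 or self.sigma_pos < 0:
            raise ValueError("sigmas must be >= 0")
        if self.window <= 0:
            raise ValueError("window mu_pos - mu_neg must be > 0")

    @property
    def window(self) -> float:
        return self.mu_pos - self.mu_neg


@dataclass(frozen=True)
class PowerSpec:
    """Detectable window fraction f and error rates."""

    effect_fraction: float
    alpha: float = 0.05
    beta: float = 0.05
    sidedness: str = "one"

    def __post_init__(self):
        if not 0.0 < self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must be in (0, 1)")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")


def _treated_variance(controls: AssayControls, f: float) -> float:
    return (1.0 - f) * controls.sigma_neg**2 + f * controls.sigma_pos**2


def power_exact(controls: AssayControls, f: float, n: int, alpha: float = 0.05,
                sidedness: str = "one") -> float:
    """Exact two-sample pooled-t power via the noncentral t distribution."""
    var_sum = _treated_variance(controls, f) + controls.sigma_neg**2
    delta = f * controls.window / math.sqrt(var_sum / n)
    nu = 2 * n - 2
    if sidedness == "one":
        crit = sps.t.ppf(1.0 - alpha, nu)
        return float(sps.nct.sf(crit, nu, delta))
    crit = sps.t.ppf(1.0 - alpha / 2.0, nu)
    return float(sps.nct.sf(crit, nu, delta) + sps.nct.cdf(-crit, nu, delta))


def required_n(controls: AssayControls, spec: PowerSpec, method: str = "normal") -> int:
    """Per-group sample size to detect a fraction-f window effect.

    method "normal" is the closed-form z approximation; "t_iterative"
    increments n until the exact noncentral-t power reaches 1 - beta.
    A floor of n = 2 is enforced.
    """
    f = spec.effect_fraction
    effect = f * controls.window
    if effect == 0:
        raise ValueError("effect_fraction * window must be nonzero")
    var_sum = _treated_variance(controls, f) + controls.sigma_neg**2
    if method == "normal":
        z_a = sps.norm.ppf(1.0 - spec.alpha / (2.0 if spec.sidedness == "two" else 1.0))
        z_b = sps.norm.ppf(1.0 - spec.beta)
        n = math.ceil((z_a + z_b) ** 2 * var_sum / effect**2)
        return max(2, n)
    if method == "t_iterative":
        n = 2
        while power_exact(controls, f, n, spec.alpha, spec.sidedness) < 1.0 - spec.beta:
            n += 1
            if n > 10**6:
                raise RuntimeError("required_n did not converge")
        return n
    raise ValueError(f"unknown method {method!r}")


def power_mc(
    controls: AssayControls,
    f: float,
    n: int,
    alpha: float = 0.05,
    sidedness: str = "one",
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo power of the pooled t-test at per-group size n.

    Simulates Gaussian control and treated groups (treated mean
    ``mu_neg + f * window``, interpolated variance) and returns the
    rejection fraction with its binomial standard error.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    rng = np.random.default_rng(seed)
    sd_t = math.sqrt(_treated_variance(controls, f))
    treated = rng.normal(controls.mu_neg + f * controls.window, sd_t, size=(reps, n))
    neg = rng.normal(controls.mu_neg, controls.sigma_neg, size=(reps, n))
    # vectorised pooled two-sample t across replicates
    diff = treated.mean(axis=1) - neg.mean(axis=1)
    sp2 = (treated.var(axis=1, ddof=1) + neg.var(axis=1, ddof=1)) / 2.0
    tstat = diff / np.sqrt(sp2 * 2.0 / n)
    nu = 2 * n - 2
    if sidedness == "one":
        reject = tstat > sps.t.ppf(1.0 - alpha, nu)
    else:
        reject = np.abs(tstat) > sps.t.ppf(1.0 - alpha / 2.0, nu)
    power = float(reject.mean())
    se = math.sqrt(max(power * (1.0 - power), 1e-12) / reps)
    return power, se
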