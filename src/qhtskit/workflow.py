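"""Stage pipelines gluing the modules into the screening workflow.

Each function takes in-memory well records and returns plain data
structures (dataclasses / DataFrames); the CLI wraps these with file I/O.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import combination as comb
from . import hits as hits_mod
from . import qc as qc_mod
from .plate import WellRecord
from .stats import NormalizedEffect, bonferroni_alpha, fisher_exact_2x2, normalize, pooled_effect, two_sample_t

__all__ = ["screen_run", "confirm_runs", "combo_runs", "power_table", "ssmd_frame", "hits_frame"]


def _usable(rec: WellRecord) -> bool:
    return rec.alive and "dispensing_error" not in rec.flags


def screen_run(
    records,
    run_id: str = "run",
    estimator: str = "mm",
    cutoff_k: float = 3.0,
    exclusions: dict | None = None,
):
    """Primary-stage analysis of one run.

    Returns ``(QCReport, ssmd_results, hit_records, heatmaps)`` where
    heatmaps maps plate_id -> 8x12 signal matrix.  Pos-ctrl wells reading
    below the background cutoff are excluded as dispensing errors and all
    remaining signals are floored at the cutoff before scoring.
    """
    nontrans = [r.raw_signal for r in records if r.group == "nontransgenic"]
    cutoff = qc_mod.signal_cutoff(nontrans, k=cutoff_k)
    records = qc_mod.apply_cutoff(records, cutoff, policy="flag_posctrl")
    report = qc_mod.qc_report(records, run_id, k=cutoff_k, estimator=estimator)
    records = qc_mod.apply_cutoff(records, cutoff, policy="floor")
    ssmd_results = hits_mod.score_screen(records, estimator=estimator)
    hit_records = hits_mod.call_hits(ssmd_results, exclusions)
    heatmaps = {
        pid: qc_mod.plate_heatmap_matrix(records, pid)
        for pid in sorted({r.plate_id for r in records})
    }
    return report, ssmd_results, hit_records, heatmaps


def ssmd_frame(ssmd_results) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in ssmd_results])


def hits_frame(hit_records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in hit_records])


def _run_window(records) -> tuple[float, float]:
    neg = [r.raw_signal for r in records if r.group == "neg_ctrl" and _usable(r)]
    pos = [r.raw_signal for r in records if r.group == "pos_ctrl" and _usable(r)]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("run lacks usable neg_ctrl/pos_ctrl wells for normalization")
    return float(np.mean(neg)), float(np.mean(pos))


def normalized_values_by_condition(runs: dict, key=None) -> dict:
    """Normalize each run against its own controls and pool by condition.

    ``runs`` maps run_id -> well records.  ``key`` maps a drug WellRecord
    to a condition label (default ``compound@conc``); control wells are
    pooled under ``"+ctrl:neg"`` and ``"+ctrl:pos"``.  Returns condition ->
    dict with keys values (list of normalized %), alive, dead.
    """
    key = key or (lambda rec: f"{rec.compound_id}@{rec.concentration_uM:g}")
    out: dict[str, dict] = {}

    def bucket(label):
        return out.setdefault(label, {"values": [], "alive": 0, "dead": 0})

    for run_id, records in runs.items():
        neg_mean, pos_mean = _run_window(records)
        for rec in records:
            if rec.group == "drug":
                label = key(rec)
            elif rec.group == "neg_ctrl":
                label = "+ctrl:neg"
            elif rec.group == "pos_ctrl":
                label = "+ctrl:pos"
            else:
                continue
            b = bucket(label)
            if "dispensing_error" in rec.flags:
                continue
            if rec.alive:
                b["alive"] += 1
                b["values"].append(float(normalize([rec.raw_signal], neg_mean, pos_mean)[0]))
            else:
                b["dead"] += 1
    return out


def confirm_runs(
    runs: dict,
    reference: str = "vs_ablated",
    alpha: float = 0.05,
    family_size: int | None = None,
    key=None,
) -> pd.DataFrame:
    """Confirmation-stage pooled effects with adjusted significance.

    One row per condition: pooled normalized effect, 95% CI, n, t-test p
    against the chosen reference controls (ablated by default), the
    Bonferroni-adjusted alpha, and a Fisher's-exact lethality p against
    the pooled ablated controls' alive/dead counts.
    """
    if reference not in ("vs_ablated", "vs_nonablated"):
        raise ValueError(f"unknown reference {reference!r}")
    pooled = normalized_values_by_condition(runs, key=key)
    ref_label = "+ctrl:neg" if reference == "vs_ablated" else "+ctrl:pos"
    ref_values = pooled[ref_label]["values"]
    neg_counts = pooled["+ctrl:neg"]
    conditions = [c for c in sorted(pooled) if not c.startswith("+ctrl:")]
    m = family_size if family_size is not None else max(len(conditions), 1)
    alpha_adj, alpha_display = bonferroni_alpha(alpha, m)
    rows = []
    for cond in conditions:
        vals = pooled[cond]["values"]
        if len(vals) < 2:
            continue
        _, p = two_sample_t(vals, ref_values, variance="pooled", sides="two")
        eff = pooled_effect([vals], condition=cond, p=p, alpha_adjusted=alpha_adj)
        lethality_p = fisher_exact_2x2(
            [
                [pooled[cond]["alive"], pooled[cond]["dead"]],
                [neg_counts["alive"], neg_counts["dead"]],
            ]
        )
        rows.append(
            {
                "condition": cond,
                "effect_pct": eff.effect,
                "ci_low": eff.ci95[0],
                "ci_high": eff.ci95[1],
                "n": eff.n,
                "p": p,
                "alpha_adjusted": alpha_adj,
                "alpha_display": alpha_display,
                "significant": eff.significant,
                "lethality_fisher_p": lethality_p,
            }
        )
    return pd.DataFrame(rows)


def combo_runs(
    runs: dict,
    pairs,
    lethal_pairs=(),
    alpha: float = 0.05,
    family_size: int | None = None,
    mode: str = "relative",
) -> pd.DataFrame:
    """Paired-compound analysis: one classified row per nominal pair."""
    pooled = normalized_values_by_condition(runs, key=lambda rec: rec.compound_id)
    effects = {
        c: d["values"] for c, d in pooled.items() if not c.startswith("+ctrl:")
    }
    m = family_size if family_size is not None else max(len(effects), 1)
    alpha_adj, _ = bonferroni_alpha(alpha, m)
    results = comb.combination_table(
        effects, pairs, lethal_pairs=lethal_pairs, alpha_adjusted=alpha_adj, mode=mode
    )
    rows = []
    for r in results:
        d = asdict(r)
        d["pair"] = f"{r.pair[0]}+{r.pair[1]}"
        rows.append(d)
    return pd.DataFrame(rows)


def power_table(controls, f_grid, alpha_grid, beta_grid, sidedness="one", method="normal") -> pd.DataFrame:
    """Sample-size table over grids of effect fraction and error rates."""
    from .power import PowerSpec, required_n

    rows = []
    for f in f_grid:
        for a in alpha_grid:
            for b in beta_grid:
                spec = PowerSpec(f, a, b, sidedness)
                rows.append(
                    {"effect_fraction": f, "alpha": a, "beta": b,
                     "n_per_group": required_n(controls, spec, method=method)}
                )
    return pd.DataFrame(rows)
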