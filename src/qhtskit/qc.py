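"""Signal-cutoff determination, well filtering, and assay-level SSMD QC.

A screening run is qualified before hit calling: non-transgenic larvae
define a background signal cutoff (mean + k*SD), wells are filtered or
floored against it, and the separation between ablated and non-ablated
control groups is summarised by an SSMD quality-control score.  A score of
1.645 or better (the semi-strong boundary) qualifies the assay; the
reported screening assay scored 1.67.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .hits import ssmd
from .plate import ROWS, N_COLS, WellRecord

__all__ = [
    "QCReport",
    "InsufficientControlsError",
    "signal_cutoff",
    "apply_cutoff",
    "ssmd_qc",
    "qc_report",
    "plate_heatmap_matrix",
]

MIN_NONTRANSGENIC = 8
PASS_THRESHOLD = 1.645
MARGINAL_THRESHOLD = 1.0


class InsufficientControlsError(ValueError):
    """Too few control wells to qualify the assay."""


@dataclass(frozen=True)
class QCReport:
    """Per-run QC summary: cutoff, flag counts, SSMD QC score, verdict."""

    run_id: str
    cutoff: float
    n_flagged: dict
    ssmd_qc: float
    verdict: str


def signal_cutoff(nontransgenic_signals, k: float = 3.0) -> float:
    """Background cutoff = mean + k*SD (sample SD) of non-transgenic wells."""
    x = np.asarray(nontransgenic_signals, dtype=float)
    if x.size < MIN_NONTRANSGENIC:
        raise InsufficientControlsError(
            f"need >= {MIN_NONTRANSGENIC} non-transgenic wells, got {x.size}"
        )
    return float(x.mean() + k * x.std(ddof=1))


def apply_cutoff(records, cutoff: float, policy: str = "floor"):
    """Apply the background cutoff to a well table.

    policy "floor": signals below the cutoff are raised to it (flag
    ``below_cutoff`` retained so the substitution is auditable) — ablated
    wells cannot meaningfully read below background.
    policy "flag_posctrl": non-ablated (pos_ctrl) wells below the cutoff
    are flagged ``dispensing_error`` — a transgenic larva cannot read at
    background, so the well must be empty — and excluded downstream.
    """
    if policy not in ("floor", "flag_posctrl"):
        raise ValueError(f"unknown policy {policy!r}")
    out = []
    for rec in records:
        if policy == "floor":
            if rec.raw_signal < cutoff:
                rec = replace(
                    rec, raw_signal=cutoff, flags=rec.flags | {"below_cutoff"}
                )
        else:
            if rec.group == "pos_ctrl" and rec.raw_signal < cutoff:
                rec = rec.with_flags("dispensing_error")
        out.append(rec)
    return out


def ssmd_qc(pos_signals, neg_signals, estimator: str = "mm") -> tuple[float, str]:
    """Assay-quality SSMD of non-ablated vs ablated controls, with verdict.

    pass if score >= 1.645, marginal if 1 <= score < 1.645, fail below 1.
    """
    score = ssmd(pos_signals, neg_signals, estimator=estimator)
    if score >= PASS_THRESHOLD:
        verdict = "pass"
    elif score >= MARGINAL_THRESHOLD:
        verdict = "marginal"
    else:
        verdict = "fail"
    return score, verdict


def _usable(rec: WellRecord) -> bool:
    return rec.alive and "dispensing_error" not in rec.flags


def qc_report(records, run_id: str, k: float = 3.0, estimator: str = "mm") -> QCReport:
    """Qualify one run from its well table (controls must be present).

    Control wells already flagged as dispensing errors (empty wells read
    background only) are excluded from the score, as they measure the
    dispenser rather than the assay.
    """
    nontrans = [r.raw_signal for r in records if r.group == "nontransgenic"]
    pos = [r.raw_signal for r in records if r.group == "pos_ctrl" and _usable(r)]
    neg = [r.raw_signal for r in records if r.group == "neg_ctrl" and _usable(r)]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientControlsError(
            f"run {run_id}: need >= 2 pos_ctrl and >= 2 neg_ctrl wells"
        )
    cutoff = signal_cutoff(nontrans, k=k)
    flag_counts = Counter(flag for r in records for flag in r.flags)
    score, verdict = ssmd_qc(pos, neg, estimator=estimator)
    return QCReport(run_id, cutoff, dict(flag_counts), score, verdict)


def plate_heatmap_matrix(records, plate_id: str, sentinel: float = np.nan) -> np.ndarray:
    """8x12 matrix of raw signals for one plate; missing wells = sentinel."""
    m = np.full((len(ROWS), N_COLS), sentinel, dtype=float)
    found = False
    for rec in records:
        if rec.plate_id == plate_id:
            m[ROWS.index(rec.row), rec.col - 1] = rec.raw_signal
            found = True
    if not found:
        raise ValueError(f"no wells found for plate {plate_id!r}")
    return m
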