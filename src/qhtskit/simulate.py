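"""Synthetic reporter-ablation screen generator with planted pharmacology.

The generative model emulates a per-larva fluorescence assay in which a
transgene reporter B (lognormal across larvae) sits on a small
autofluorescence background A (truncated normal), prodrug ablation
collapses the reporter to a residual fraction ``r`` (default 0.13, i.e. an
87% signal decrease at the screening dose), and a protective compound
rescues a Hill-shaped fraction P(c) of the ablated signal:

    ablated well:      S = A + B * (r + (1 - r) * P(c))
    non-ablated well:  S = A + B
    no larva / dead:   S = A

Toxic compounds kill larvae with a log-logistic concentration-lethality
curve; autofluorescent compounds add ``autofluor_gain * c`` to every well;
dispensing errors leave a well without a larva.  Every simulated compound
is recorded in a :class:`TruthTable` so downstream hit calling can be
benchmarked against known ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .plate import (
    ROWS,
    N_COLS,
    DilutionDesign,
    ScreenDesign,
    WellRecord,
    layout_qhts_plate,
    layout_screen,
)

__all__ = [
    "LognormalParams",
    "TruncNormalParams",
    "ProtectionParams",
    "ToxicityParams",
    "SimulationConfig",
    "CompoundTruth",
    "TruthTable",
    "hill_protection",
    "simulate_well",
    "simulate_screen",
    "simulate_combination",
]

COMPOUND_CLASSES = ("inactive", "protective", "toxic", "autofluorescent")


@dataclass(frozen=True)
class LognormalParams:
    """Lognormal distribution given as (median, geometric CV)."""

    median: float
    gcv: float

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log(1.0 + self.gcv**2))


@dataclass(frozen=True)
class TruncNormalParams:
    """Normal(mean, sd) truncated at zero."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ProtectionParams:
    """Hill dose-response of planted protectants: Emax, EC50 (uM), Hill h."""

    emax: float = 0.5
    ec50_uM: float = 0.25
    hill: float = 2.0


@dataclass(frozen=True)
class ToxicityParams:
    """Log-logistic death probability: concentration at 50% lethality, slope."""

    lc50_uM: float = 2.0
    slope: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic screen.

    Defaults emulate the screening assay's working conditions: the
    reporter baseline and background give a control signal window whose
    SSMD quality-control score is ~1.7, and ``residual_fraction`` 0.13
    reproduces the 87% ablation-induced signal decrease at the screening
    prodrug dose.
    """

    seed: int = 0
    n_compounds: int = 100
    frac_protective: float = 0.1
    baseline: LognormalParams = field(default_factory=lambda: LognormalParams(1000.0, 0.53))
    background: TruncNormalParams = field(default_factory=lambda: TruncNormalParams(50.0, 12.0))
    residual_fraction: float = 0.13
    protection: ProtectionParams = field(default_factory=ProtectionParams)
    toxicity: ToxicityParams = field(default_factory=ToxicityParams)
    frac_toxic: float = 0.0
    frac_autofluorescent: float = 0.0
    autofluor_gain: float = 200.0
    dispensing_error_rate: float = 0.02

    def __post_init__(self):
        for name in ("frac_protective", "frac_toxic", "frac_autofluorescent",
                     "residual_fraction", "dispensing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if (self.frac_protective + self.frac_toxic + self.frac_autofluorescent) > 1.0:
            raise ValueError("class fractions sum to more than 1")
        if not 0.0 < self.protection.emax <= 1.0:
            raise ValueError("protection.emax must be in (0, 1]")
        if self.protection.ec50_uM <= 0:
            raise ValueError("protection.ec50_uM must be > 0")
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be >= 0")


@dataclass(frozen=True)
class CompoundTruth:
    """Planted ground truth for one simulated compound."""

    compound_id: str
    compound_class: str
    emax: float = 0.0
    ec50_uM: float = float("nan")
    hill: float = float("nan")
    lc50_uM: float = float("nan")
    slope: float = float("nan")
    autofluor_gain: float = 0.0


class TruthTable:
    """Mapping compound_id -> :class:`CompoundTruth` with CSV round-trip."""

    def __init__(self, entries):
        self._entries: dict[str, CompoundTruth] = {}
        for e in entries:
            if e.compound_id in self._entries:
                raise ValueError(f"duplicate compound {e.compound_id}")
            if e.compound_class not in COMPOUND_CLASSES:
                raise ValueError(f"unknown class {e.compound_class}")
            self._entries[e.compound_id] = e

    def __getitem__(self, compound_id: str) -> CompoundTruth:
        return self._entries[compound_id]

    def __contains__(self, compound_id) -> bool:
        return compound_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def ids_of_class(self, compound_class: str) -> list[str]:
        return [e.compound_id for e in self if e.compound_class == compound_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TruthTable":
        df = pd.read_csv(path).fillna(float("nan"))
        return cls(CompoundTruth(**row) for row in df.to_dict("records"))


def hill_protection(conc_uM, emax: float, ec50_uM: float, hill: float):
    """Hill rescue fraction P(c) = Emax * c^h / (c^h + EC50^h); P(0) = 0."""
    c = np.asarray(conc_uM, dtype=float)
    with np.errstate(divide="ignore"):
        ch = np.where(c > 0, c, np.nan) ** hill
    p = np.where(c > 0, emax * ch / (ch + ec50_uM**hill), 0.0)
    return p if p.shape else float(p)


def _death_probability(conc_uM, tox: ToxicityParams):
    c = np.asarray(conc_uM, dtype=float)
    with np.errstate(divide="ignore"):
        p = np.where(c > 0, 1.0 / (1.0 + (tox.lc50_uM / np.where(c > 0, c, 1.0)) ** tox.slope), 0.0)
    return p


def _draw_background(config: SimulationConfig, rng: np.random.Generator, size: int):
    # rejection-free truncation: resample the (rare) negatives
    a = rng.normal(config.background.mean, config.background.sd, size)
    while True:
        neg = a < 0
        if not neg.any():
            return a
        a[neg] = rng.normal(config.background.mean, config.background.sd, int(neg.sum()))


def _draw_signals(
    config: SimulationConfig,
    truth: CompoundTruth,
    conc_uM: float,
    ablated: bool,
    rng: np.random.Generator,
    size: int,
    has_larva: bool = True,
):
    """Vectorised signal draw; returns (signal, alive, dispensing_error)."""
    bg = _draw_background(config, rng, size)
    b = rng.lognormal(config.baseline.mu, config.baseline.sigma, size)
    disp = rng.random(size) < config.dispensing_error_rate if has_larva else np.ones(size, bool)
    alive = np.ones(size, dtype=bool)
    if truth.compound_class == "toxic" and conc_uM > 0:
        tox = ToxicityParams(truth.lc50_uM, truth.slope)
        alive = rng.random(size) >= _death_probability(conc_uM, tox)
    if truth.compound_class == "protective":
        p = hill_protection(conc_uM, truth.emax, truth.ec50_uM, truth.hill)
    else:
        p = 0.0
    r = config.residual_fraction
    reporter = b * ((r + (1.0 - r) * p) if ablated else 1.0)
    present = alive & ~disp & has_larva
    signal = bg + np.where(present, reporter, 0.0)
    signal = signal + truth.autofluor_gain * conc_uM
    return np.clip(signal, 0.0, None), alive, disp


_NO_COMPOUND = CompoundTruth("", "inactive")


def simulate_well(
    config: SimulationConfig,
    compound_class: str,
    concentration_uM: float,
    ablated: bool,
    rng: np.random.Generator,
    *,
    plate_id: str = "sim",
    row: str = "A",
    col: int = 1,
) -> WellRecord:
    """Draw a single drug-treated well of the given planted compound class."""
    truth = _truth_for_class(config, "SIM", compound_class)
    sig, alive, disp = _draw_signals(config, truth, concentration_uM, ablated, rng, 1)
    flags = frozenset({"dispensing_error"}) if disp[0] else frozenset()
    return WellRecord(
        plate_id, row, col, "SIM", concentration_uM, "drug",
        float(sig[0]), bool(alive[0]), flags,
    )


def _truth_for_class(config: SimulationConfig, compound_id: str, compound_class: str) -> CompoundTruth:
    if compound_class == "protective":
        p = config.protection
        return CompoundTruth(compound_id, "protective", p.emax, p.ec50_uM, p.hill)
    if compound_class == "toxic":
        t = config.toxicity
        return CompoundTruth(compound_id, "toxic", lc50_uM=t.lc50_uM, slope=t.slope)
    if compound_class == "autofluorescent":
        return CompoundTruth(compound_id, "autofluorescent", autofluor_gain=config.autofluor_gain)
    if compound_class == "inactive":
        return CompoundTruth(compound_id, "inactive")
    raise ValueError(f"unknown compound class {compound_class!r}")


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_compounds
    n_prot = round(n * config.frac_protective)
    n_tox = round(n * config.frac_toxic)
    n_auto = round(n * config.frac_autofluorescent)
    classes = (
        ["protective"] * n_prot + ["toxic"] * n_tox
        + ["autofluorescent"] * n_auto
        + ["inactive"] * (n - n_prot - n_tox - n_auto)
    )
    rng.shuffle(classes)
    return classes


def _control_wells(
    config: SimulationConfig,
    counts: dict,
    rng: np.random.Generator,
    plate_prefix: str,
) -> list[WellRecord]:
    """Dedicated control plate(s): ablated neg, non-ablated pos, nontransgenic."""
    records = []
    idx = 0
    for group in ("neg_ctrl", "pos_ctrl", "nontransgenic"):
        n = counts.get(group, 0)
        if n == 0:
            continue
        if group == "nontransgenic":
            sig = _draw_background(config, rng, n)
            alive = np.ones(n, bool)
            disp = np.zeros(n, bool)
        else:
            ablated = group == "neg_ctrl"
            sig, alive, disp = _draw_signals(config, _NO_COMPOUND, 0.0, ablated, rng, n)
        for i in range(n):
            plate_no, within = divmod(idx, 96)
            col, row_i = divmod(within, len(ROWS))
            flags = frozenset({"dispensing_error"}) if disp[i] else frozenset()
            records.append(
                WellRecord(
                    f"{plate_prefix}-P{plate_no + 1}", ROWS[row_i], col + 1,
                    "", 0.0, group, float(sig[i]), bool(alive[i]), flags,
                )
            )
            idx += 1
    return records


def _fill_plate(
    config: SimulationConfig,
    layout: list[WellRecord],
    truth: CompoundTruth,
    rng: np.random.Generator,
    ablated: bool = True,
) -> list[WellRecord]:
    """Replace zero-initialised signals in a layout with simulated draws."""
    out = []
    drug_idx = [i for i, w in enumerate(layout) if w.group == "drug"]
    by_conc: dict[float, list[int]] = {}
    for i in drug_idx:
        by_conc.setdefault(layout[i].concentration_uM, []).append(i)
    filled: dict[int, WellRecord] = {}
    for conc, idxs in by_conc.items():
        sig, alive, disp = _draw_signals(config, truth, conc, ablated, rng, len(idxs))
        for j, i in enumerate(idxs):
            w = layout[i]
            flags = w.flags | ({"dispensing_error"} if disp[j] else set())
            filled[i] = replace(
                w, raw_signal=float(sig[j]), alive=bool(alive[j]), flags=frozenset(flags)
            )
    for i, w in enumerate(layout):
        if i in filled:
            out.append(filled[i])
        else:  # blank placeholder wells: background only, no larva
            out.append(replace(w, raw_signal=float(_draw_background(config, rng, 1)[0])))
    return out


def simulate_screen(
    config: SimulationConfig,
    design: ScreenDesign | None = None,
    run_id: str = "run1",
) -> tuple[list[WellRecord], TruthTable]:
    """Simulate one screening run: control plates plus one titration per compound.

    Fully reproducible from ``config.seed`` (and ``run_id``, so repeats of
    the same configuration can be drawn independently by renaming the run).
    """
    design = design or ScreenDesign.primary_default()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(run_id.encode())])
    )
    records = _control_wells(config, design.controls, rng, f"{run_id}-CTRL")
    classes = _assign_classes(config, rng)
    truths = []
    dil = design.dilution
    single_plate = (
        dil.replicates_per_level % len(ROWS) == 0
        and dil.n_levels * dil.replicates_per_level <= len(ROWS) * N_COLS
    )
    for k, compound_class in enumerate(classes, start=1):
        cid = f"C{k:04d}"
        truth = _truth_for_class(config, cid, compound_class)
        truths.append(truth)
        if single_plate:
            layout = layout_qhts_plate(cid, dil, plate_id=f"{run_id}-{cid}-P1")
        else:
            layout = layout_screen(cid, dil, plate_prefix=f"{run_id}-{cid}")
        records.extend(_fill_plate(config, layout, truth, rng, ablated=True))
    return records, TruthTable(truths)


_INTERACTIONS = ("bliss", "linear_additive_capped", "none")


def simulate_combination(
    config: SimulationConfig,
    pair: tuple[CompoundTruth, CompoundTruth],
    interaction: str,
    concentrations_uM: tuple[float, ...] = (4.0,),
    n_per_group: int = 30,
    run_id: str = "combo1",
) -> list[WellRecord]:
    """Simulate a paired-compound run: both singles, the pair, and controls.

    The pair's rescue fraction combines the singles' Hill fractions at the
    same concentration under the chosen interaction model: Bliss
    independence ``P_A + P_B - P_A*P_B``, capped linear additivity
    ``min(P_A + P_B, 1)``, or ``none`` (highest single agent,
    ``max(P_A, P_B)``).
    """
    if interaction not in _INTERACTIONS:
        raise ValueError(f"unknown interaction {interaction!r}; use one of {_INTERACTIONS}")
    ta, tb = pair
    for t in (ta, tb):
        if t.compound_class != "protective":
            raise ValueError(f"{t.compound_id} is not protective in the truth table")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(run_id.encode())])
    )
    records = _control_wells(
        config, {"neg_ctrl": max(n_per_group, 30), "pos_ctrl": max(n_per_group, 30)},
        rng, f"{run_id}-CTRL",
    )
    pair_id = f"{ta.compound_id}+{tb.compound_id}"
    idx = 0
    for conc in concentrations_uM:
        p_a = hill_protection(conc, ta.emax, ta.ec50_uM, ta.hill)
        p_b = hill_protection(conc, tb.emax, tb.ec50_uM, tb.hill)
        if interaction == "bliss":
            p_ab = p_a + p_b - p_a * p_b
        elif interaction == "linear_additive_capped":
            p_ab = min(p_a + p_b, 1.0)
        else:
            p_ab = max(p_a, p_b)
        groups = [
            (ta.compound_id, ta),
            (tb.compound_id, tb),
            # pair emitted as a pseudo-compound whose planted Emax realises
            # P_AB exactly at this concentration
            (pair_id, CompoundTruth(pair_id, "protective", emax=float(p_ab),
                                    ec50_uM=1e-9, hill=1.0)),
        ]
        for cid, truth in groups:
            sig, alive, disp = _draw_signals(config, truth, conc, True, rng, n_per_group)
            for i in range(n_per_group):
                plate_no, within = divmod(idx, 96)
                col, row_i = divmod(within, len(ROWS))
                flags = frozenset({"dispensing_error"}) if disp[i] else frozenset()
                records.append(
                    WellRecord(
                        f"{run_id}-P{plate_no + 1}", ROWS[row_i], col + 1,
                        cid, conc, "drug", float(sig[i]), bool(alive[i]), flags,
                    )
                )
                idx += 1
    return records
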