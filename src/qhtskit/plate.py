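"""Screen domain types, 96-well plate layout, and well-table I/O.

The canonical exchange format is a long-format CSV with one row per well
(columns ``plate_id,row,col,compound_id,concentration_uM,group,raw_signal,
alive,flags``).  Concentrations are always micromolar; rows are letters A-H
and columns integers 1-12 (standard 96-well convention).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GROUPS",
    "FLAGS",
    "ROWS",
    "WellRecord",
    "DilutionDesign",
    "ScreenDesign",
    "InvalidDesignError",
    "LayoutError",
    "WellTableError",
    "generate_series",
    "layout_qhts_plate",
    "layout_screen",
    "read_well_table",
    "write_well_table",
]

ROWS = "ABCDEFGH"
N_COLS = 12

#: Valid well groups.  ``drug`` wells carry a compound and concentration;
#: control groups (ablated neg_ctrl, non-ablated pos_ctrl, nontransgenic
#: background) and blank placeholder wells carry neither.
GROUPS = frozenset({"drug", "neg_ctrl", "pos_ctrl", "nontransgenic", "blank"})
CONTROL_GROUPS = frozenset({"neg_ctrl", "pos_ctrl", "nontransgenic", "blank"})

#: Status flags a well can accumulate during QC and exclusion handling.
FLAGS = frozenset(
    {"below_cutoff", "dispensing_error", "excluded_autofluorescent", "excluded_lethal"}
)

CSV_COLUMNS = [
    "plate_id",
    "row",
    "col",
    "compound_id",
    "concentration_uM",
    "group",
    "raw_signal",
    "alive",
    "flags",
]


class InvalidDesignError(ValueError):
    """A dilution or screen design violates its invariants."""


class LayoutError(ValueError):
    """A design cannot be placed on a 96-well plate."""


class WellTableError(ValueError):
    """A well-table file violates the format or a record invariant."""


@dataclass(frozen=True)
class WellRecord:
    """One larva/well: plate address, treatment, and measured signal."""

    plate_id: str
    row: str
    col: int
    compound_id: str
    concentration_uM: float
    group: str
    raw_signal: float
    alive: bool = True
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.row not in ROWS:
            raise WellTableError(f"row must be one of {ROWS}, got {self.row!r}")
        if not 1 <= self.col <= N_COLS:
            raise WellTableError(f"col must be in 1..{N_COLS}, got {self.col}")
        if self.group not in GROUPS:
            raise WellTableError(f"unknown group {self.group!r}")
        if self.group in CONTROL_GROUPS and (
            self.compound_id or self.concentration_uM != 0
        ):
            raise WellTableError(
                f"group {self.group!r} wells must have empty compound and zero "
                f"concentration (well {self.plate_id}:{self.row}{self.col})"
            )
        if not (math.isfinite(self.raw_signal) and self.raw_signal >= 0):
            raise WellTableError(
                f"raw_signal must be finite and >= 0, got {self.raw_signal}"
            )
        if self.concentration_uM < 0:
            raise WellTableError("concentration_uM must be >= 0")
        unknown = set(self.flags) - FLAGS
        if unknown:
            raise WellTableError(f"unknown flags {sorted(unknown)}")
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def well(self) -> str:
        """Well address like ``A01``."""
        return f"{self.row}{self.col:02d}"

    def with_flags(self, *new_flags: str) -> "WellRecord":
        return replace(self, flags=self.flags | frozenset(new_flags))


@dataclass(frozen=True)
class DilutionDesign:
    """A geometric dilution series: top concentration, fold, level count."""

    top_concentration_uM: float
    fold: float
    n_levels: int
    replicates_per_level: int = 16

    def __post_init__(self):
        if not (self.top_concentration_uM > 0 and math.isfinite(self.top_concentration_uM)):
            raise InvalidDesignError("top_concentration_uM must be positive and finite")
        if not self.fold > 1:
            raise InvalidDesignError("fold must be > 1")
        if self.n_levels < 1:
            raise InvalidDesignError("n_levels must be >= 1")
        if self.replicates_per_level < 1:
            raise InvalidDesignError("replicates_per_level must be >= 1")


@dataclass(frozen=True)
class ScreenDesign:
    """Dilution series plus per-run control-well counts for one stage."""

    dilution: DilutionDesign
    controls: dict = field(
        default_factory=lambda: {"neg_ctrl": 32, "pos_ctrl": 32, "nontransgenic": 16}
    )
    stage: str = "primary"

    def __post_init__(self):
        if self.stage not in {"primary", "confirmation"}:
            raise InvalidDesignError(f"unknown stage {self.stage!r}")
        bad = set(self.controls) - {"neg_ctrl", "pos_ctrl", "nontransgenic"}
        if bad:
            raise InvalidDesignError(f"unknown control groups {sorted(bad)}")
        if any(v < 0 for v in self.controls.values()):
            raise InvalidDesignError("control counts must be >= 0")

    @classmethod
    def primary_default(cls) -> "ScreenDesign":
        """Primary qHTS stage: 4 uM top, twofold, 6 levels, 16 wells each."""
        return cls(DilutionDesign(4.0, 2.0, 6, 16), stage="primary")

    @classmethod
    def confirmation_default(cls) -> "ScreenDesign":
        """Confirmation stage: 100 uM top, fivefold, 8 levels, 30 wells each."""
        return cls(DilutionDesign(100.0, 5.0, 8, 30), stage="confirmation")


def generate_series(design: DilutionDesign) -> list[float]:
    """Concentrations of the dilution series, strictly decreasing, in uM.

    >>> generate_series(DilutionDesign(4.0, 2.0, 6))
    [4.0, 2.0, 1.0, 0.5, 0.25, 0.125]
    """
    return [design.top_concentration_uM / design.fold**i for i in range(design.n_levels)]


def layout_qhts_plate(
    compound_id: str, design: DilutionDesign, plate_id: str | None = None
) -> list[WellRecord]:
    """Lay one compound's titration onto a single 96-well plate.

    Each concentration occupies a contiguous block of whole columns
    (``replicates_per_level / 8`` columns), highest concentration leftmost.
    Unused columns are emitted as ``blank`` placeholder wells so the plate
    is always complete.  Signals are zero-initialised; the simulator or an
    instrument import fills them in.
    """
    if not compound_id:
        raise LayoutError("compound_id must be non-empty")
    reps = design.replicates_per_level
    if reps % len(ROWS) != 0:
        raise LayoutError(
            f"replicates_per_level must be divisible by {len(ROWS)} for the "
            f"column-block layout, got {reps}"
        )
    cols_per_level = reps // len(ROWS)
    if design.n_levels * reps > len(ROWS) * N_COLS:
        raise LayoutError(
            f"design needs {design.n_levels * reps} wells; a plate has 96"
        )
    plate_id = plate_id or f"{compound_id}-P1"
    series = generate_series(design)
    records = []
    for col in range(1, N_COLS + 1):
        level = (col - 1) // cols_per_level
        for row in ROWS:
            if level < design.n_levels:
                records.append(
                    WellRecord(plate_id, row, col, compound_id, series[level], "drug", 0.0)
                )
            else:
                records.append(WellRecord(plate_id, row, col, "", 0.0, "blank", 0.0))
    return records


def layout_screen(
    compound_id: str, design: DilutionDesign, plate_prefix: str | None = None
) -> list[WellRecord]:
    """Lay a titration of arbitrary size across as many plates as needed.

    Used for designs that do not fit the single-plate column-block contract
    (e.g. the confirmation stage's 8 levels x 30 replicates).  Wells are
    filled column-major, each concentration contiguous, spilling onto
    additional plates ``<prefix>-P2``, ``-P3``, ...
    """
    if not compound_id:
        raise LayoutError("compound_id must be non-empty")
    prefix = plate_prefix or compound_id
    series = generate_series(design)
    records = []
    idx = 0
    for conc in series:
        for _ in range(design.replicates_per_level):
            plate_no, within = divmod(idx, 96)
            col, row_i = divmod(within, len(ROWS))
            records.append(
                WellRecord(
                    f"{prefix}-P{plate_no + 1}", ROWS[row_i], col + 1,
                    compound_id, conc, "drug", 0.0,
                )
            )
            idx += 1
    # pad the final plate with blanks so every emitted plate is complete
    while idx % 96:
        plate_no, within = divmod(idx, 96)
        col, row_i = divmod(within, len(ROWS))
        records.append(
            WellRecord(f"{prefix}-P{plate_no + 1}", ROWS[row_i], col + 1, "", 0.0, "blank", 0.0)
        )
        idx += 1
    return records


def _parse_record(rowdict: dict, line_no: int) -> WellRecord:
    try:
        flags = frozenset(f for f in (rowdict.get("flags") or "").split(";") if f)
        return WellRecord(
            plate_id=rowdict["plate_id"],
            row=rowdict["row"],
            col=int(rowdict["col"]),
            compound_id=rowdict["compound_id"] or "",
            concentration_uM=float(rowdict["concentration_uM"]),
            group=rowdict["group"],
            raw_signal=float(rowdict["raw_signal"]),
            alive=rowdict.get("alive", "True") in ("True", "true", "1"),
            flags=flags,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise WellTableError(f"line {line_no}: {exc}") from exc


def read_well_table(path) -> list[WellRecord]:
    """Read and validate a well-table CSV; returns records in file order."""
    records: list[WellRecord] = []
    seen: set[tuple] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS[:-1] if c not in header]  # flags optional
        if missing:
            raise WellTableError(f"missing columns: {missing}")
        for line_no, rowdict in enumerate(reader, start=2):
            rec = _parse_record(rowdict, line_no)
            key = (rec.plate_id, rec.row, rec.col)
            if key in seen:
                raise WellTableError(
                    f"line {line_no}: duplicate well {rec.plate_id}:{rec.well}"
                )
            seen.add(key)
            records.append(rec)
    return records


def write_well_table(records, path) -> None:
    """Write records to CSV in the canonical dialect (read/write round-trips)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.plate_id,
                    rec.row,
                    rec.col,
                    rec.compound_id,
                    repr(rec.concentration_uM),
                    rec.group,
                    repr(rec.raw_signal),
                    rec.alive,
                    ";".join(sorted(rec.flags)),
                ]
            )
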