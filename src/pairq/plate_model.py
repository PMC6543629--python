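"""Domain types for qPCR plates and the tabular formats the tool reads and writes.

A plate run is a collection of per-well amplification curves (baseline-subtracted
fluorescence, RFU, one reading per thermal cycle) plus layout metadata that groups
wells into dilution sets. Readings may be negative: baseline subtraction leaves
instrument noise around zero. All downstream analysis is expressed in terms of the
dilution step ``D`` (log fold-dilution at base ``b``), never in absolute
concentrations; nominal concentrations are carried as metadata only.

File formats are plain long-format CSV (UTF-8, '.' decimal point):

* fluorescence: header ``well,cycle,rfu``, one row per reading;
* layout: header ``well,set_id,dilution_step,concentration`` (concentration may
  be empty);
* Cq table: header ``well,cq``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellId",
    "FluorescenceSeries",
    "WellMeta",
    "PlateRun",
    "DilutionSet",
    "EmptyWindowError",
    "read_fluorescence_table",
    "write_fluorescence_table",
    "read_layout",
    "write_layout",
    "read_cq_table",
    "write_cq_table",
    "build_dilution_sets",
]

_WELL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


class EmptyWindowError(ValueError):
    """No fluorescence reading falls inside the requested RFU window."""


@dataclass(frozen=True, order=True)
class WellId:
    """A plate coordinate such as ``A1`` or ``H12``.

    Rows are letters (``A``–``H`` on a 96-well plate, but arbitrary letter rows
    are accepted), columns positive integers. The string form is the row letter
    immediately followed by the column number.
    """

    row: str
    column: int

    def __post_init__(self) -> None:
        if not self.row.isalpha() or self.row != self.row.upper():
            raise ValueError(f"invalid well row {self.row!r}")
        if self.column < 1:
            raise ValueError(f"invalid well column {self.column}")

    @classmethod
    def parse(cls, text: str) -> "WellId":
        m = _WELL_RE.match(str(text).strip())
        if m is None:
            raise ValueError(f"cannot parse well id {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclass
class FluorescenceSeries:
    """One amplification curve: per-cycle RFU readings for a single well.

    Cycles are 1-based, strictly consecutive (1, 2, ..., n). Readings may be
    negative (baseline-subtracted noise).
    """

    well: WellId
    cycles: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.cycles.shape != self.rfu.shape or self.cycles.ndim != 1:
            raise ValueError("cycles and rfu must be 1-D arrays of equal length")
        if len(self.cycles) == 0:
            raise ValueError("empty fluorescence series")
        expected = np.arange(1, len(self.cycles) + 1)
        if not np.array_equal(self.cycles, expected):
            raise ValueError(
                f"well {self.well}: cycles must be 1..n without gaps (missing cycle?)"
            )
        if not np.all(np.isfinite(self.rfu)):
            raise ValueError(f"well {self.well}: non-finite rfu reading")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def reading(self, cycle: int) -> float:
        """RFU at a 1-based cycle number."""
        if not 1 <= cycle <= self.n_cycles:
            raise ValueError(f"cycle {cycle} outside 1..{self.n_cycles}")
        return float(self.rfu[cycle - 1])


@dataclass(frozen=True)
class WellMeta:
    """Layout metadata for one well: which dilution set it belongs to and at
    what dilution step. ``dilution_step`` is the integer exponent D of the
    fold-dilution (D=0 is the undiluted sample). ``concentration`` (nominal,
    e.g. ng of template) is informational only."""

    well: WellId
    set_id: str
    dilution_step: int
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dilution_step < 0:
            raise ValueError("dilution_step must be >= 0")
        if self.concentration is not None and not self.concentration > 0:
            raise ValueError("concentration must be positive when given")


@dataclass
class DilutionSet:
    """An ordered group of wells spanning dilution steps of one serial dilution.

    ``base`` is the fold-dilution per step (2 for two-fold series, 10 for
    ten-fold). The set is the unit for which one efficiency estimate is made.
    """

    set_id: str
    wells: list
    base: float
    steps: list

    def __post_init__(self) -> None:
        if len(self.wells) != len(self.steps):
            raise ValueError("wells and steps must align")
        if len(self.wells) < 2:
            raise ValueError(f"dilution set {self.set_id}: need at least 2 wells")
        if len(set(self.steps)) != len(self.steps):
            raise ValueError(f"dilution set {self.set_id}: repeated dilution_step")
        if not self.base > 1:
            raise ValueError("dilution base must be > 1")
        order = np.argsort(self.steps)
        self.wells = [self.wells[i] for i in order]
        self.steps = [int(self.steps[i]) for i in order]

    def step_of(self, well: WellId) -> int:
        return self.steps[self.wells.index(well)]


@dataclass
class PlateRun:
    """All data of one qPCR run: curves, layout, and (optionally) Cq calls."""

    series: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    cq: Optional[dict] = None
    cq_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        counts = {s.n_cycles for s in self.series.values()}
        if len(counts) > 1:
            raise ValueError(f"series have unequal cycle counts: {sorted(counts)}")
        for w in self.meta:
            if w not in self.series and (self.cq is None or w not in self.cq):
                raise ValueError(f"well {w} in layout has neither fluorescence nor Cq data")

    @property
    def n_cycles(self) -> Optional[int]:
        if not self.series:
            return None
        return next(iter(self.series.values())).n_cycles

    @property
    def wells(self) -> list:
        return sorted(self.series.keys())


def read_fluorescence_table(path) -> PlateRun:
    """Read a long-format fluorescence CSV (``well,cycle,rfu``) into a PlateRun.

    Row order in the file is irrelevant. Duplicate (well, cycle) rows, gaps in
    the cycle sequence and non-numeric readings are rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["well", "cycle", "rfu"], path)
    try:
        df["cycle"] = pd.to_numeric(df["cycle"], errors="raise").astype(int)
        df["rfu"] = pd.to_numeric(df["rfu"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cycle or rfu value") from exc
    if df["rfu"].isna().any() or df["cycle"].isna().any():
        raise ValueError(f"{path}: missing cycle or rfu value")
    if df.duplicated(subset=["well", "cycle"]).any():
        dup = df[df.duplicated(subset=["well", "cycle"])].iloc[0]
        raise ValueError(f"{path}: duplicate reading for well {dup['well']} cycle {dup['cycle']}")
    series = {}
    for well_str, grp in df.groupby("well", sort=True):
        wid = WellId.parse(well_str)
        grp = grp.sort_values("cycle")
        series[wid] = FluorescenceSeries(wid, grp["cycle"].to_numpy(), grp["rfu"].to_numpy())
    return PlateRun(series=series)


def write_fluorescence_table(plate: PlateRun, path) -> None:
    rows = [
        (str(w), int(c), float(f))
        for w in plate.wells
        for c, f in zip(plate.series[w].cycles, plate.series[w].rfu)
    ]
    pd.DataFrame(rows, columns=["well", "cycle", "rfu"]).to_csv(path, index=False)


def read_layout(path, base: float = 2.0):
    """Read a layout CSV into well metadata and dilution sets.

    ``base`` (fold-dilution per step) is not stored in the file; it is supplied
    here (CLI flag ``--base``). Returns ``(meta, sets)`` where ``meta`` maps
    WellId to :class:`WellMeta` and ``sets`` is a list of :class:`DilutionSet`
    in order of first appearance, wells ordered by dilution step.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["well", "set_id", "dilution_step"], path)
    meta = {}
    for _, row in df.iterrows():
        wid = WellId.parse(row["well"])
        conc = None
        if "concentration" in df.columns and pd.notna(row.get("concentration")):
            conc = float(row["concentration"])
        if wid in meta:
            raise ValueError(f"{path}: duplicate layout row for well {wid}")
        meta[wid] = WellMeta(wid, str(row["set_id"]), int(row["dilution_step"]), conc)
    sets = build_dilution_sets(meta.values(), base=base)
    return meta, sets


def build_dilution_sets(metas: Sequence[WellMeta], base: float = 2.0) -> list:
    """Group well metadata into dilution sets (order of first appearance)."""
    by_set: dict = {}
    for m in metas:
        by_set.setdefault(m.set_id, []).append(m)
    sets = []
    for set_id, members in by_set.items():
        sets.append(
            DilutionSet(
                set_id=set_id,
                wells=[m.well for m in members],
                base=base,
                steps=[m.dilution_step for m in members],
            )
        )
    return sets


def write_layout(meta: Mapping[WellId, WellMeta], path) -> None:
    rows = [
        (str(m.well), m.set_id, m.dilution_step, "" if m.concentration is None else m.concentration)
        for m in meta.values()
    ]
    pd.DataFrame(rows, columns=["well", "set_id", "dilution_step", "concentration"]).to_csv(
        path, index=False
    )


def read_cq_table(path) -> dict:
    """Read a ``well,cq`` CSV into a map WellId -> Cq (fractional cycle)."""
    df = pd.read_csv(path)
    _require_columns(df, ["well", "cq"], path)
    if df.empty:
        warnings.warn(f"{path}: empty Cq table", stacklevel=2)
        return {}
    cq_vals = pd.to_numeric(df["cq"], errors="coerce")
    if cq_vals.isna().any():
        bad = df.loc[cq_vals.isna(), "well"].iloc[0]
        raise ValueError(f"{path}: non-numeric Cq for well {bad}")
    if (cq_vals < 0).any():
        bad = df.loc[cq_vals < 0, "well"].iloc[0]
        raise ValueError(f"{path}: negative Cq for well {bad}")
    return {WellId.parse(w): float(c) for w, c in zip(df["well"], cq_vals)}


def write_cq_table(cq: Mapping[WellId, float], path) -> None:
    rows = sorted(((str(w), float(c)) for w, c in cq.items()), key=lambda r: r[0])
    pd.DataFrame(rows, columns=["well", "cq"]).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
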