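"""Downstream relative quantification.

Back-calculates the fluorescence-equivalent of the initial template,
F0 = F_i / (1+E)**i, from in-window readings; computes Pfaffl-style expression
ratios ratio = (1+E)**(Cq_control - Cq_sample) from Cq values; bounds the
worst-case ratio error among replicate wells for both routes; and builds the
dilution-ratio accuracy table, which scores each method against the known
fold-dilutions of the plate.

Error convention for accuracy rows: error_pct = 100 * (observed - expected) /
observed, i.e. the share of the *observed* fold that is spurious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import pairwise as _pairwise
from .calibration import calibration_efficiency
from .plate_model import DilutionSet, FluorescenceSeries, PlateRun, WellId

__all__ = [
    "F0Estimate",
    "RatioResult",
    "AccuracyTable",
    "estimate_f0",
    "pfaffl_ratio",
    "max_error_analysis",
    "dilution_accuracy_table",
]


@dataclass
class F0Estimate:
    well: WellId
    f0: float
    e_used: float
    n_readings: int

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")


@dataclass
class RatioResult:
    ratio: float
    method: str  # "pfaffl_cq" | "f0_based"
    inputs: dict


@dataclass
class AccuracyTable:
    """Per-group observed fold-dilutions and errors for both methods, plus the
    per-method average absolute error (reference group excluded)."""

    table: pd.DataFrame
    avg_error_pairwise_pct: float
    avg_error_calibration_pct: float


def estimate_f0(series: FluorescenceSeries, window, e: float) -> F0Estimate:
    """Initial-template fluorescence: mean of F_i/(1+e)**i over in-window readings."""
    if not e > -1:
        raise ValueError("efficiency must exceed -1")
    mask = window.contains(series.rfu) & (series.rfu > 0)
    if not mask.any():
        raise ValueError(
            f"well {series.well}: no in-window reading for F0 estimation"
        )
    f0s = series.rfu[mask] / (1.0 + e) ** series.cycles[mask]
    return F0Estimate(
        well=series.well, f0=float(f0s.mean()), e_used=float(e), n_readings=int(mask.sum())
    )


def pfaffl_ratio(e: float, cq_sample: float, cq_control: float) -> RatioResult:
    """Relative expression ratio (1+e)**(cq_control - cq_sample).

    The base is the amplification factor 1+E, with E the fractional efficiency
    (E = 1 is perfect doubling). Reciprocal in its two Cq arguments.
    """
    if not e > -1:
        raise ValueError("efficiency must exceed -1")
    ratio = (1.0 + e) ** (cq_control - cq_sample)
    return RatioResult(
        ratio=float(ratio),
        method="pfaffl_cq",
        inputs={"e": e, "cq_sample": cq_sample, "cq_control": cq_control},
    )


def _undiluted_wells(sets: Sequence[DilutionSet]):
    """Wells at the lowest dilution step present (D = 0 on standard layouts)."""
    min_step = min(min(s.steps) for s in sets)
    return [
        (dset, well)
        for dset in sets
        for well, step in zip(dset.wells, dset.steps)
        if step == min_step
    ]


def max_error_analysis(
    plate: PlateRun,
    sets: Sequence[DilutionSet],
    method: str,
    window=None,
    efficiency: Optional[float] = None,
) -> RatioResult:
    """Worst-case ratio among replicate undiluted wells (true ratio is 1).

    ``pfaffl_cq``: the ratio from the extreme Cq values among the replicate
    undiluted wells, at the maximal per-set calibration efficiency (error is
    maximal when E is maximal). ``f0_based``: max(F0)/min(F0) among the same
    wells, F0 back-calculated with the maximal per-set pairwise efficiency.
    ``efficiency`` overrides the internally determined maximal E.
    """
    repl = _undiluted_wells(sets)
    if len(repl) < 2:
        raise ValueError("need >= 2 replicate undiluted wells")
    if method == "pfaffl_cq":
        if plate.cq is None:
            raise ValueError("pfaffl_cq analysis requires Cq data")
        if efficiency is None:
            fits = [calibration_efficiency(plate.cq, dset) for dset in sets]
            efficiency = max(f.efficiency for f in fits)
        cqs = [plate.cq[w] for _, w in repl if w in plate.cq]
        if len(cqs) < 2:
            raise ValueError("need >= 2 Cq values among undiluted wells")
        # worst-case apparent fold between identical wells: earliest vs latest Cq
        res = pfaffl_ratio(efficiency, cq_sample=min(cqs), cq_control=max(cqs))
        res.inputs["n_wells"] = len(cqs)
        return res
    if method == "f0_based":
        if window is None:
            raise ValueError("f0_based analysis requires an RFU window")
        if efficiency is None:
            ests = [
                _pairwise.set_efficiency(plate, dset, window) for dset in sets
            ]
            efficiency = max(e.e_mean for e in ests)
        f0s = [
            estimate_f0(plate.series[w], window, efficiency).f0 for _, w in repl
        ]
        return RatioResult(
            ratio=float(max(f0s) / min(f0s)),
            method="f0_based",
            inputs={"e": efficiency, "n_wells": len(f0s)},
        )
    raise ValueError(f"unknown method {method!r}")


def dilution_accuracy_table(
    plate: PlateRun,
    sets: Sequence[DilutionSet],
    groups: Mapping[str, str],
    expected_folds: Mapping[str, float],
    reference_group: str,
    window,
    outlier_removal: bool = True,
) -> AccuracyTable:
    """Score both methods against the known fold-dilutions between well groups.

    ``groups`` maps set_id -> group label; ``expected_folds`` maps group label
    -> expected fold relative to ``reference_group`` (reference itself = 1).
    For the pairwise route each set's efficiency gives per-well F0 values and
    the group fold is mean F0(reference) / mean F0(group). For the classical
    route the fold is the Pfaffl ratio of group-mean Cq against the reference
    group-mean Cq at the group's mean calibration efficiency.
    """
    by_group: dict = {}
    for dset in sets:
        g = groups.get(dset.set_id)
        if g is None:
            continue
        by_group.setdefault(g, []).append(dset)
    if reference_group not in by_group:
        raise ValueError(f"reference group {reference_group!r} has no sets")

    def group_summaries(gsets):
        f0s, cqs, cal_es = [], [], []
        for dset in gsets:
            e_pw = _pairwise.set_efficiency(
                plate, dset, window, outlier_removal=outlier_removal
            ).e_mean
            for well in dset.wells:
                f0s.append(estimate_f0(plate.series[well], window, e_pw).f0)
            if plate.cq is not None:
                cal_es.append(calibration_efficiency(plate.cq, dset).efficiency)
                cqs.extend(plate.cq[w] for w in dset.wells if w in plate.cq)
        return (
            float(np.mean(f0s)),
            float(np.mean(cqs)) if cqs else None,
            float(np.mean(cal_es)) if cal_es else None,
        )

    summ = {g: group_summaries(gs) for g, gs in by_group.items()}
    ref_f0, ref_cq, _ = summ[reference_group]

    rows = []
    err_pw, err_cal = [], []
    for g, (f0_g, cq_g, e_cal_g) in summ.items():
        expected = 1.0 if g == reference_group else float(expected_folds[g])
        fold_f0 = ref_f0 / f0_g
        fold_cq = None
        if cq_g is not None and ref_cq is not None and e_cal_g is not None:
            # fold of reference over group: dilute groups cross the threshold later
            fold_cq = pfaffl_ratio(e_cal_g, cq_sample=ref_cq, cq_control=cq_g).ratio
        if g == reference_group:
            e_pw_pct = e_cq_pct = np.nan
        else:
            e_pw_pct = 100.0 * (fold_f0 - expected) / fold_f0
            err_pw.append(abs(e_pw_pct))
            e_cq_pct = np.nan
            if fold_cq is not None:
                e_cq_pct = 100.0 * (fold_cq - expected) / fold_cq
                err_cal.append(abs(e_cq_pct))
        rows.append(
            {
                "group": g,
                "expected_fold": expected,
                "fold_f0": fold_f0,
                "error_f0_pct": e_pw_pct,
                "fold_cq": fold_cq if fold_cq is not None else np.nan,
                "error_cq_pct": e_cq_pct,
            }
        )
    table = pd.DataFrame(rows)
    return AccuracyTable(
        table=table,
        avg_error_pairwise_pct=float(np.mean(err_pw)) if err_pw else float("nan"),
        avg_error_calibration_pct=float(np.mean(err_cal)) if err_cal else float("nan"),
    )
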