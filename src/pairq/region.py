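"""Exponential-phase window determination.

qPCR efficiency estimation from raw fluorescence is only meaningful inside the
window where the signal is above the baseline noise but not yet damped by
saturation. This module provides the pieces used to choose that window:

* :func:`noise_profile` — pooled early-cycle readings, characterising the
  baseline noise band (roughly -10..+10 RFU on typical instruments);
* :func:`first_outlier_cycle` — lower bound: the first cycle whose reading
  rises significantly above a linear background fitted to all earlier cycles
  (a studentized-prediction-residual takeoff test);
* :func:`fdm_cycle` — upper bound: the First Derivative Maximum, the cycle of
  steepest fluorescence increase, after which saturation dominates;
* :func:`stable_region_scan` — per-cycle efficiency under a candidate F0,
  locating the initial span where E is flat;
* :func:`boundary_grid_search` — empirical selection of the best RFU window by
  the Monte-Carlo precision of the pairwise estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .plate_model import DilutionSet, FluorescenceSeries, PlateRun
from . import pairwise as _pairwise
from . import precision as _precision

__all__ = [
    "FluorWindow",
    "NoiseProfile",
    "StableRegionScan",
    "noise_profile",
    "first_outlier_cycle",
    "fdm_cycle",
    "stable_region_scan",
    "boundary_grid_search",
]

#: noise band magnitude (RFU) below which a window lower bound is suspect
NOISE_FLOOR_RFU = 10.0


@dataclass(frozen=True)
class FluorWindow:
    """Closed RFU interval [lower, upper] admitting readings to the analysis.

    The default 20-180 RFU suits two-fold Actb-like series on a CFX-class
    instrument (roughly 4 in-window readings per curve); always overridable.
    """

    lower: float = 20.0
    upper: float = 180.0

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(f"window requires 0 < lower < upper, got {self.lower}..{self.upper}")

    def contains(self, rfu) -> np.ndarray:
        return (np.asarray(rfu) >= self.lower) & (np.asarray(rfu) <= self.upper)

    def clamped(self, profile: "NoiseProfile") -> "FluorWindow":
        """Raise the lower bound to the noise floor when the measured noise
        band reaches it; warns rather than silently adjusting."""
        reach = max(abs(profile.min), abs(profile.max))
        if reach >= NOISE_FLOOR_RFU and self.lower < NOISE_FLOOR_RFU:
            warnings.warn(
                f"window lower bound {self.lower} RFU is inside the measured noise band "
                f"(±{reach:.1f} RFU); clamping to {NOISE_FLOOR_RFU} RFU",
                stacklevel=2,
            )
            return FluorWindow(NOISE_FLOOR_RFU, self.upper)
        return self


@dataclass
class NoiseProfile:
    """Pooled early-cycle readings and their summary."""

    values: np.ndarray
    min: float
    max: float
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


def noise_profile(plate: PlateRun, cycle_range: Tuple[int, int], bins: int = 25) -> NoiseProfile:
    """Pool the readings of ``cycle_range`` (inclusive 1-based bounds) across
    all wells and summarise their distribution."""
    lo, hi = cycle_range
    n_cyc = plate.n_cycles
    if n_cyc is None:
        raise ValueError("plate has no fluorescence series")
    if not (1 <= lo <= hi <= n_cyc):
        raise ValueError(f"cycle range {lo}..{hi} outside plate cycles 1..{n_cyc}")
    pooled = np.concatenate([plate.series[w].rfu[lo - 1 : hi] for w in plate.wells])
    counts, edges = np.histogram(pooled, bins=bins)
    return NoiseProfile(
        values=pooled,
        min=float(pooled.min()),
        max=float(pooled.max()),
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
        bin_edges=edges,
        counts=counts,
    )


def first_outlier_cycle(
    series: FluorescenceSeries,
    alpha: float = 0.01,
    min_background: int = 5,
    confirm: bool = True,
) -> Optional[int]:
    """First cycle whose reading rises significantly above the background trend.

    For each candidate cycle c, an ordinary linear trend is fitted to cycles
    1..c-1 and the studentized prediction residual of F(c) is compared to the
    one-sided t quantile at ``alpha``. With ``confirm`` (default) the next
    reading must also exceed its own threshold against the same background fit,
    which keeps the per-series false-flag rate near alpha instead of
    accumulating it over every scanned cycle. Returns ``None`` when no
    amplification takeoff is detected.
    """
    if series.n_cycles < 8:
        raise ValueError("need at least 8 cycles to detect a takeoff")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    y = series.rfu
    n = series.n_cycles
    for c in range(min_background + 1, n + 1):
        if _exceeds_background(y, c, alpha) and (
            not confirm or c == n or _exceeds_background(y, c, alpha, probe=c + 1)
        ):
            return c
    return None


def _exceeds_background(y: np.ndarray, c: int, alpha: float, probe: Optional[int] = None) -> bool:
    """Studentized prediction residual of cycle ``probe`` (default c) against a
    linear fit to cycles 1..c-1, tested one-sided at ``alpha``."""
    probe = c if probe is None else probe
    m = c - 1
    x = np.arange(1, c, dtype=float)
    X = np.column_stack([np.ones(m), x])
    beta, *_ = np.linalg.lstsq(X, y[:m], rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y[:m] - fitted) ** 2))
    df = m - 2
    x0 = np.array([1.0, float(probe)])
    pred = float(x0 @ beta)
    resid = y[probe - 1] - pred
    if df < 1:
        return False
    s2 = rss / df
    if s2 <= 1e-24:  # numerically perfect background fit
        scale = max(1.0, float(np.max(np.abs(y[:m]))))
        return resid > 1e-9 * scale
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * (1.0 + x0 @ xtx_inv @ x0))
    return resid / se > stats.t.ppf(1.0 - alpha, df)


def fdm_cycle(series: FluorescenceSeries) -> Tuple[int, float]:
    """First Derivative Maximum: the cycle maximising the centered finite
    difference (F(c+1) - F(c-1))/2, ties broken to the earliest cycle.
    Returns ``(cycle, rfu_at_cycle)``. Invariant to adding a constant."""
    if series.n_cycles < 3:
        raise ValueError("need at least 3 cycles for a centered derivative")
    y = series.rfu
    d = (y[2:] - y[:-2]) / 2.0  # derivative at cycles 2..n-1
    k = int(np.argmax(d))  # argmax takes the first maximum
    cycle = k + 2
    return cycle, float(y[cycle - 1])


@dataclass
class StableRegionScan:
    """Per-cycle efficiency under a candidate F0 and the detected stable span."""

    cycles: np.ndarray  # cycles with positive readings (E defined)
    e_values: np.ndarray  # E(i) at those cycles
    stable_span: Optional[Tuple[int, int]]  # first/last cycle of the stable run
    span_sd: float  # sd of E inside the span (nan if no span)


def stable_region_scan(
    series: FluorescenceSeries,
    f0: float,
    base: float = 2.0,
    sd_tol: float = 0.01,
    min_rfu: float = NOISE_FLOOR_RFU,
) -> StableRegionScan:
    """Scan per-cycle efficiency E(i) = (F_i / f0)^(1/i) - 1 under candidate f0.

    Only cycles with positive readings have a defined E; cycles with readings
    below ``min_rfu`` are treated as noise, not detected signal. The stable
    span is the longest initial run of detected-signal cycles whose E standard
    deviation stays within ``sd_tol``. (The base-b form
    b**((log_b F - log_b f0)/i) - 1 is algebraically identical for every base.)
    """
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    if not base > 1:
        raise ValueError("base must be > 1")
    pos = series.rfu > 0
    if not pos.any():
        raise ValueError(f"well {series.well}: no positive readings")
    cycles = series.cycles[pos].astype(int)
    e_vals = (series.rfu[pos] / f0) ** (1.0 / cycles) - 1.0

    detected = series.cycles[series.rfu >= min_rfu]
    span: Optional[Tuple[int, int]] = None
    span_sd = float("nan")
    if len(detected) > 0:
        start = int(detected[0])
        run = [c for c in range(start, int(series.cycles[-1]) + 1) if c in set(detected.tolist())]
        # longest initial contiguous run of detected cycles
        contiguous = [run[0]]
        for c in run[1:]:
            if c == contiguous[-1] + 1:
                contiguous.append(c)
            else:
                break
        idx = {int(c): i for i, c in enumerate(cycles)}
        best_end = contiguous[0]
        for end in contiguous:
            vals = np.array([e_vals[idx[c]] for c in range(start, end + 1) if c in idx])
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            if sd <= sd_tol:
                best_end = end
                span_sd = sd
            else:
                break
        span = (start, best_end)
    return StableRegionScan(cycles=cycles, e_values=e_vals, stable_span=span, span_sd=span_sd)


def boundary_grid_search(
    plate: PlateRun,
    sets: Sequence[DilutionSet],
    candidates: Sequence[FluorWindow],
    n_per_sampling: int = 3,
    n_samplings: int = 100,
    seed: int = 0,
    outlier_removal: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo precision of the pairwise estimator for each candidate window.

    For every window the per-set pairwise efficiency is computed and the
    Monte-Carlo SD over resampled triplets of sets (module :mod:`precision`)
    recorded. The same seed is used for every window so the comparison is
    paired. Windows in which any set yields fewer than two in-window readings
    are marked infeasible rather than raising. Rows are sorted ascending by SD,
    infeasible rows last.
    """
    if len(sets) < n_per_sampling:
        raise ValueError("need at least n_per_sampling replicate sets")
    rows = []
    for win in candidates:
        estimates = {}
        feasible = True
        try:
            for dset in sets:
                est = _pairwise.set_efficiency(
                    plate, dset, win, outlier_removal=outlier_removal
                )
                estimates[dset.set_id] = est.e_mean
        except ValueError:
            feasible = False
        if feasible:
            mc = _precision.monte_carlo_precision(
                estimates, n_per_sampling=n_per_sampling, n_samplings=n_samplings, seed=seed
            )
            rows.append((win.lower, win.upper, True, mc.sd, mc.mean, mc.e_max, mc.e_min, mc.range))
        else:
            rows.append((win.lower, win.upper, False) + (np.nan,) * 5)
    df = pd.DataFrame(
        rows, columns=["lower", "upper", "feasible", "sd", "mean_e", "e_max", "e_min", "range"]
    )
    return df.sort_values(["feasible", "sd"], ascending=[False, True], na_position="last").reset_index(
        drop=True
    )
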