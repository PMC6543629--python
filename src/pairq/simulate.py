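"""Synthetic qPCR plate generator.

Generates plates with the statistical structure the pairwise estimator assumes:
classical exponential growth F_i = (F0 / b^D) (1+E)^i in the pre-saturation
phase, a smooth logistic approach to a plateau, and additive Gaussian baseline
noise. The defaults emulate a 96-well run of 16 replicate two-fold six-step
dilution sets read over 33 cycles, with noise spanning roughly -10..+10 RFU
(sd 3) and signal emerging from the noise floor around cycle 13 for the
undiluted sample at E = 0.8.

The saturation model multiplies each cycle's increment by (1 - F/plateau), the
simplest smooth damping that yields a stable-then-declining per-cycle
efficiency; with ``plateau = inf`` and ``noise_sd = 0`` the generated curve is
exactly the classical formula, which the exactness tests rely on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .plate_model import (
    DilutionSet,
    FluorescenceSeries,
    PlateRun,
    WellId,
    WellMeta,
    build_dilution_sets,
)

__all__ = ["SimParams", "simulate_plate", "call_cq"]

_ROWS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class SimParams:
    """Parameters of one synthetic plate.

    e_true          amplification efficiency E, in (0, 1.1]
    f0_undiluted    fluorescence-equivalent of undiluted template (RFU units)
    base            fold-dilution per step (2 or 10, typically)
    steps           dilution steps D of each set (default 0..5)
    n_sets          number of replicate dilution sets
    n_cycles        thermal cycles read
    plateau         saturation ceiling in RFU (np.inf disables saturation)
    noise_sd        sd of additive Gaussian baseline noise, RFU
    noise_mean      mean of the baseline noise (instrument offsets need not be 0)
    f0_jitter_cv    lognormal sigma of an optional per-well multiplicative F0 jitter
    set_f0_scale    optional per-set multipliers on f0_undiluted (emulates plates
                    where replicate sets start from different template amounts)
    seed            RNG seed; same params + seed give bit-identical plates
    """

    e_true: float = 0.8
    f0_undiluted: float = 0.008
    base: float = 2.0
    steps: Sequence[int] = (0, 1, 2, 3, 4, 5)
    n_sets: int = 16
    n_cycles: int = 33
    plateau: float = 2000.0
    noise_sd: float = 3.0
    noise_mean: float = 0.0
    f0_jitter_cv: float = 0.0
    set_f0_scale: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.e_true <= 1.1:
            raise ValueError("e_true must be in (0, 1.1]")
        if not self.f0_undiluted > 0:
            raise ValueError("f0_undiluted must be positive")
        if not self.base > 1:
            raise ValueError("base must be > 1")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.plateau > 0:
            raise ValueError("plateau must be positive")
        if len(set(self.steps)) != len(self.steps) or len(self.steps) < 1:
            raise ValueError("steps must be distinct and non-empty")
        if self.set_f0_scale is not None and len(self.set_f0_scale) != self.n_sets:
            raise ValueError("set_f0_scale must have one entry per set")


def _plate_layout(n_sets: int, n_steps: int):
    """Assign wells row-wise: each set occupies a contiguous block of columns.

    With six steps this reproduces the two-blocks-per-row layout of a 96-well
    plate of 16 replicate six-sets (A1-6, A7-12, B1-6, ...).
    """
    blocks_per_row = max(1, 12 // n_steps)
    layouts = []
    for s in range(n_sets):
        row = _ROWS[s // blocks_per_row]
        block = s % blocks_per_row
        first_col = block * n_steps + 1
        set_id = f"{row}{first_col}-{first_col + n_steps - 1}"
        wells = [WellId(row, first_col + k) for k in range(n_steps)]
        layouts.append((set_id, wells))
    return layouts


def growth_curve(
    f_start: float, e: float, n_cycles: int, plateau: float = math.inf
) -> np.ndarray:
    """Noise-free curve: F_i for i = 1..n_cycles starting from template f_start.

    Each cycle's increment is damped by (1 - F/plateau); with plateau = inf the
    result equals f_start * (1+e)**i exactly.
    """
    out = np.empty(n_cycles)
    f = f_start
    for i in range(n_cycles):
        f = f + f * e * (1.0 - f / plateau)
        out[i] = f
    return out


def simulate_plate(params: SimParams) -> PlateRun:
    """Generate a synthetic :class:`PlateRun` under ``params``.

    Deterministic for a fixed seed. The layout metadata (set ids, dilution
    steps, nominal concentrations 100 * scale / b**D) is attached, so
    ``build_dilution_sets(plate.meta.values(), base)`` recovers the sets.
    """
    rng = np.random.default_rng(params.seed)
    series: dict = {}
    meta: dict = {}
    scales = params.set_f0_scale if params.set_f0_scale is not None else [1.0] * params.n_sets
    for (set_id, wells), scale in zip(_plate_layout(params.n_sets, len(params.steps)), scales):
        for well, step in zip(wells, params.steps):
            f0 = params.f0_undiluted * scale / params.base**step
            if params.f0_jitter_cv > 0:
                f0 *= rng.lognormal(0.0, params.f0_jitter_cv)
            clean = growth_curve(f0, params.e_true, params.n_cycles, params.plateau)
            noise = rng.normal(params.noise_mean, params.noise_sd, params.n_cycles)
            rfu = clean + noise if params.noise_sd > 0 else clean + params.noise_mean
            series[well] = FluorescenceSeries(well, np.arange(1, params.n_cycles + 1), rfu)
            meta[well] = WellMeta(well, set_id, int(step), 100.0 * scale / params.base**step)
    return PlateRun(series=series, meta=meta)


def call_cq(plate: PlateRun, threshold: float) -> dict:
    """Threshold-crossing Cq calls: fractional cycle where each curve first
    reaches ``threshold`` RFU.

    Interpolation between the flanking cycles is linear on log fluorescence
    (exact for pure exponentials); it falls back to linear interpolation when
    the lower flanking reading is non-positive. Wells that never cross get no
    entry (with a warning).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    out: dict = {}
    for well in plate.wells:
        s = plate.series[well]
        above = np.nonzero(s.rfu >= threshold)[0]
        if len(above) == 0:
            warnings.warn(f"well {well}: never crosses threshold {threshold}", stacklevel=2)
            continue
        k = int(above[0])
        if k == 0:
            out[well] = 1.0
            continue
        f_lo, f_hi = s.rfu[k - 1], s.rfu[k]
        if f_lo > 0:
            frac = (math.log(threshold) - math.log(f_lo)) / (math.log(f_hi) - math.log(f_lo))
        else:
            frac = (threshold - f_lo) / (f_hi - f_lo)
        out[well] = float(k + frac)  # cycle k is 1-based index k, crossing in (k, k+1)
    return out


def default_sets(params: SimParams):
    """Dilution sets matching the layout :func:`simulate_plate` produces."""
    layouts = _plate_layout(params.n_sets, len(params.steps))
    return [
        DilutionSet(set_id, list(wells), params.base, list(params.steps))
        for set_id, wells in layouts
    ]
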