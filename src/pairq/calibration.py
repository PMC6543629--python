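"""Classical calibration-curve efficiency estimation (the baseline method).

Cq values of a serial dilution are regressed on log10 concentration; the
amplification efficiency follows from the slope:

    E = 10 ** (-1/slope) - 1

(slope is negative for amplifying reactions: more dilute samples cross the
threshold later). Regressing on log10 with the 10-based formula is
mathematically identical to regressing on log_b with E = b**(-1/slope_b) - 1
for any base b, so a single code path serves all dilution bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import math

from scipy import stats as sps

from .plate_model import DilutionSet, WellId

__all__ = ["CalibrationFit", "calibration_efficiency"]


@dataclass
class CalibrationFit:
    slope: float  # cycles per log10 concentration
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int
    set_id: Optional[str] = None


def calibration_efficiency(
    cq: Mapping[WellId, float],
    dset: DilutionSet,
    concentrations: Optional[Mapping[WellId, float]] = None,
) -> CalibrationFit:
    """OLS fit of Cq against log10(concentration) for one dilution set.

    When no explicit concentrations are given they derive from the dilution
    steps: conc = base**(-D) in arbitrary units (the arbitrary unit shifts the
    intercept only; slope and efficiency are scale-invariant).
    """
    xs, ys = [], []
    for well, step in zip(dset.wells, dset.steps):
        if well not in cq:
            continue
        if concentrations is not None:
            conc = concentrations[well]
        else:
            conc = dset.base ** (-step)
        if not conc > 0:
            raise ValueError(f"well {well}: concentration must be positive")
        xs.append(math.log10(conc))
        ys.append(float(cq[well]))
    if len(set(xs)) < 2:
        raise ValueError(
            f"set {dset.set_id}: need Cq values at >= 2 distinct concentrations"
        )
    fit = sps.linregress(xs, ys)
    if fit.slope == 0:
        raise ValueError(f"set {dset.set_id}: zero slope, efficiency undefined")
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=10.0 ** (-1.0 / fit.slope) - 1.0,
        n_points=len(xs),
        set_id=dset.set_id,
    )
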