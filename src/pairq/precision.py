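"""Monte-Carlo precision assessment of replicate efficiency estimates.

Precision (random error) of an estimation method is measured by resampling:
from the pool of per-set efficiency estimates (one per replicate dilution set),
draw many "samplings" of a few sets each — mirroring the common wet-lab
practice of running a calibration curve in triplicate — average the estimates
within each sampling, and summarise the spread of the sampling means (SD, max,
min, range). Smaller SD means higher precision. Sets within one sampling are
drawn without replacement (three *different* replicas form a triplicate);
samplings are drawn independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["MonteCarloResult", "monte_carlo_precision"]


@dataclass
class MonteCarloResult:
    sampling_means: np.ndarray
    sd: float
    e_max: float
    e_min: float
    range: float
    mean: float
    method: str
    seed: int
    n_per_sampling: int

    @property
    def n_samplings(self) -> int:
        return len(self.sampling_means)


def monte_carlo_precision(
    estimates: Mapping[str, float],
    n_per_sampling: int = 3,
    n_samplings: int = 100,
    seed: int = 0,
    method: str = "",
) -> MonteCarloResult:
    """Resample ``n_per_sampling``-set means ``n_samplings`` times and summarise.

    ``estimates`` maps replicate-set ids to their efficiency estimates. The SD
    is the sample standard deviation (n-1 denominator) of the sampling means;
    max/min/range are over the sampling means as well. Deterministic for a
    fixed seed (set ids are ordered before drawing).
    """
    ids = sorted(estimates)
    values = np.array([estimates[i] for i in ids], dtype=float)
    if n_per_sampling < 1:
        raise ValueError("n_per_sampling must be >= 1")
    if n_per_sampling > len(values):
        raise ValueError(
            f"n_per_sampling = {n_per_sampling} exceeds the {len(values)} available sets"
        )
    if n_samplings < 2:
        raise ValueError("n_samplings must be >= 2")
    rng = np.random.default_rng(seed)
    means = np.empty(n_samplings)
    for k in range(n_samplings):
        pick = rng.choice(len(values), size=n_per_sampling, replace=False)
        means[k] = values[pick].mean()
    return MonteCarloResult(
        sampling_means=means,
        sd=float(means.std(ddof=1)),
        e_max=float(means.max()),
        e_min=float(means.min()),
        range=float(means.max() - means.min()),
        mean=float(means.mean()),
        method=method,
        seed=seed,
        n_per_sampling=n_per_sampling,
    )
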