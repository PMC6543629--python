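"""The pairwise combinatorial efficiency estimator.

One amplification efficiency value is computed for every valid pair of
fluorescence readings admitted from a dilution set:

    E_ij = b ** ((log_b F_j - log_b F_i + (D2 - D1)) / (j - i)) - 1

where i, j are cycle numbers, F the readings, D the dilution steps of the two
wells at fold-dilution base b (D1 = D2 for readings on the same curve). Pairs
sharing a cycle number are excluded (j - i = 0). A six-well two-fold set with
an RFU window admitting ~4 readings per curve yields on the order of 200-260
pairwise E values, enough for distribution diagnostics (skew, excess kurtosis,
chi-square against a fitted normal at 0.05-wide bins) and a non-parametric
outlier rule: histogram bins with fewer than 5 values, scanning outward from
the modal bin, mark the cutoffs beyond which values are discarded. The set's
efficiency is the arithmetic mean of the retained values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .plate_model import DilutionSet, EmptyWindowError, PlateRun, WellId

__all__ = [
    "ReadingRef",
    "PairwiseEValue",
    "PairwiseEArray",
    "DistributionStats",
    "EfficiencyEstimate",
    "admit_readings",
    "pairwise_efficiency",
    "enumerate_pairs",
    "distribution_stats",
    "exclude_outliers",
    "set_efficiency",
]

#: histogram bin width on the E axis, as used by the chi-square procedure
DEFAULT_BIN_WIDTH = 0.05
#: bins with fewer values than this are statistically unreliable (chi-square rule)
MIN_BIN_COUNT = 5
#: minimum array size for the chi-square / outlier machinery
MIN_N_FOR_CHI2 = 50


@dataclass(frozen=True)
class ReadingRef:
    """One admitted fluorescence reading with its provenance."""

    well: WellId
    cycle: int
    rfu: float
    dilution_step: int

    def __post_init__(self) -> None:
        if not self.rfu > 0:
            raise ValueError("admitted readings must have positive rfu")


@dataclass(frozen=True)
class PairwiseEValue:
    value: float
    a: ReadingRef
    b: ReadingRef


@dataclass
class PairwiseEArray:
    """All per-pair efficiency values of one dilution set, with provenance."""

    values: list
    set_id: Optional[str] = None
    window: Optional[object] = None
    base: float = 2.0

    @property
    def e_values(self) -> np.ndarray:
        return np.array([v.value for v in self.values], dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DistributionStats:
    """Normality diagnostics of a pairwise-E array.

    Moments are the bias-corrected (spreadsheet-compatible) versions: adjusted
    Fisher-Pearson skewness and excess kurtosis (normal -> 0). The chi-square
    goodness-of-fit compares the 0.05-binned histogram with a normal at the
    sample mean and sd; tail bins whose expected count falls below
    ``MIN_BIN_COUNT`` are pooled into single left/right cells, and
    df = cells - 3 (two estimated parameters plus the total).
    """

    n: int
    skew: float
    kurtosis_excess: float
    bin_width: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    chi2_stat: Optional[float] = None
    chi2_df: Optional[int] = None
    chi2_p: Optional[float] = None
    normal_rejected: Optional[bool] = None
    frac_low_expected: Optional[float] = None
    chi2_valid: Optional[bool] = None


@dataclass
class EfficiencyEstimate:
    """A set-level efficiency with provenance counts."""

    e_mean: float
    method: str
    n_total: int
    n_retained: int
    excluded_low_cutoff: Optional[float] = None
    excluded_high_cutoff: Optional[float] = None
    e_raw: Optional[float] = None
    set_id: Optional[str] = None


def admit_readings(plate: PlateRun, dset: DilutionSet, window) -> list:
    """All readings of the set's wells inside the RFU window, tagged with D.

    Window membership is the closed interval [lower, upper]. Non-positive
    readings are inadmissible regardless of the window (their logarithm does
    not exist); a positive lower bound makes this moot.
    """
    refs = []
    for well, step in zip(dset.wells, dset.steps):
        if well not in plate.series:
            raise ValueError(f"well {well} of set {dset.set_id} has no fluorescence data")
        s = plate.series[well]
        mask = window.contains(s.rfu) & (s.rfu > 0)
        for c, f in zip(s.cycles[mask], s.rfu[mask]):
            refs.append(ReadingRef(well, int(c), float(f), int(step)))
    if not refs:
        raise EmptyWindowError(
            f"set {dset.set_id}: no reading inside window {window.lower}..{window.upper} RFU"
        )
    return refs


def pairwise_efficiency(a: ReadingRef, b: ReadingRef, base: float = 2.0) -> float:
    """Per-pair efficiency E_ij (orientation-invariant; see module docstring)."""
    if a.cycle == b.cycle:
        raise ValueError("pair shares a cycle: efficiency undefined (division by zero)")
    if not (a.rfu > 0 and b.rfu > 0):
        raise ValueError("pairwise efficiency requires positive readings")
    log_b = math.log(base)
    num = (math.log(b.rfu) - math.log(a.rfu)) / log_b + (b.dilution_step - a.dilution_step)
    return base ** (num / (b.cycle - a.cycle)) - 1.0


def enumerate_pairs(
    readings: Sequence[ReadingRef],
    base: float = 2.0,
    set_id: Optional[str] = None,
    window=None,
    cross_well_only: bool = False,
) -> PairwiseEArray:
    """All unordered pairs of admitted readings, excluding same-cycle pairs.

    Same-well pairs (D1 = D2) are included by default — the pair formula holds
    on a single curve just as across curves; only pairs occurring on the same
    cycle carry no efficiency information. ``cross_well_only`` restricts to
    pairs from different wells for sensitivity analysis.
    """
    if len(readings) < 2:
        raise ValueError("need at least 2 admitted readings to form pairs")
    values = []
    for i in range(len(readings)):
        for j in range(i + 1, len(readings)):
            a, b = readings[i], readings[j]
            if a.cycle == b.cycle:
                continue
            if cross_well_only and a.well == b.well:
                continue
            values.append(PairwiseEValue(pairwise_efficiency(a, b, base), a, b))
    return PairwiseEArray(values=values, set_id=set_id, window=window, base=base)


def _histogram(values: np.ndarray, bin_width: float):
    """Half-open bins [k*w, (k+1)*w) anchored at zero, spanning the data."""
    k_min = math.floor(values.min() / bin_width)
    k_max = math.floor(values.max() / bin_width)
    edges = np.arange(k_min, k_max + 2) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def distribution_stats(
    array, bin_width: float = DEFAULT_BIN_WIDTH, alpha: float = 0.05
) -> DistributionStats:
    """Skew, excess kurtosis, binned histogram and chi-square normality test.

    Requires n >= 3 for the moments; the chi-square fields are filled only for
    n >= 50 (below that the binned frequencies are too sparse to test).
    """
    values = array.e_values if isinstance(array, PairwiseEArray) else np.asarray(array, float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 values for distribution statistics")
    edges, counts = _histogram(values, bin_width)
    out = DistributionStats(
        n=n,
        skew=float(sps.skew(values, bias=False)),
        kurtosis_excess=float(sps.kurtosis(values, fisher=True, bias=False)),
        bin_width=bin_width,
        bin_edges=edges,
        bin_counts=counts,
    )
    if n < MIN_N_FOR_CHI2:
        warnings.warn(
            f"n = {n} < {MIN_N_FOR_CHI2}: chi-square normality test not computed", stacklevel=2
        )
        return out

    m = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate (zero-variance) array: chi-square test not computed",
                      stacklevel=2)
        return out
    z = (edges - m) / sd
    cdf = sps.norm.cdf(z)
    expected = n * np.diff(cdf)
    keep = np.nonzero(expected >= MIN_BIN_COUNT)[0]
    if len(keep) == 0:
        cells_obs = [counts.sum()]
        cells_exp = [expected.sum()]
    else:
        lo, hi = keep[0], keep[-1]
        cells_obs, cells_exp = [], []
        if lo > 0:  # pooled left tail (plus mass below the first edge)
            cells_obs.append(counts[:lo].sum())
            cells_exp.append(expected[:lo].sum() + n * cdf[0])
        cells_obs.extend(counts[lo : hi + 1])
        cells_exp.extend(expected[lo : hi + 1])
        if hi < len(counts) - 1:  # pooled right tail (plus mass above the last edge)
            cells_obs.append(counts[hi + 1 :].sum())
            cells_exp.append(expected[hi + 1 :].sum() + n * (1.0 - cdf[-1]))
    cells_obs = np.asarray(cells_obs, float)
    cells_exp = np.asarray(cells_exp, float)
    chi2 = float(np.sum((cells_obs - cells_exp) ** 2 / cells_exp))
    df = max(1, len(cells_obs) - 3)
    out.chi2_stat = chi2
    out.chi2_df = df
    out.chi2_p = float(sps.chi2.sf(chi2, df))
    out.normal_rejected = bool(out.chi2_p < alpha)
    out.frac_low_expected = float(np.mean(cells_exp < MIN_BIN_COUNT))
    out.chi2_valid = bool(n >= MIN_N_FOR_CHI2 and out.frac_low_expected <= 0.20)
    return out


def exclude_outliers(
    array: PairwiseEArray,
    stats: Optional[DistributionStats] = None,
    min_count: int = MIN_BIN_COUNT,
) -> EfficiencyEstimate:
    """Frequency-based outlier exclusion and the set-level mean efficiency.

    Scanning outward from the modal histogram bin, the first bin below the mode
    with count < ``min_count`` sets the low cutoff at that bin's upper edge, and
    the first such bin above the mode sets the high cutoff at its lower edge;
    values outside [low, high] are discarded. When every bin is sparse no
    exclusion is applied (with a warning).
    """
    values = array.e_values
    n = len(values)
    if n < MIN_N_FOR_CHI2:
        raise ValueError(f"outlier exclusion needs n >= {MIN_N_FOR_CHI2}, got {n}")
    if stats is None:
        stats = distribution_stats(array)
    counts, edges = stats.bin_counts, stats.bin_edges
    e_raw = float(values.mean())
    low_cut: Optional[float] = None
    high_cut: Optional[float] = None
    if (counts >= min_count).any():
        mode = int(np.argmax(counts))
        for i in range(mode - 1, -1, -1):
            if counts[i] < min_count:
                low_cut = float(edges[i + 1])
                break
        for i in range(mode + 1, len(counts)):
            if counts[i] < min_count:
                high_cut = float(edges[i])
                break
    else:
        warnings.warn("distribution too sparse: every bin below the frequency floor; "
                      "no outliers excluded", stacklevel=2)
    lo = -np.inf if low_cut is None else low_cut
    hi = np.inf if high_cut is None else high_cut
    retained = values[(values >= lo) & (values <= hi)]
    return EfficiencyEstimate(
        e_mean=float(retained.mean()),
        method="pairwise",
        n_total=n,
        n_retained=int(len(retained)),
        excluded_low_cutoff=low_cut,
        excluded_high_cutoff=high_cut,
        e_raw=e_raw,
        set_id=array.set_id,
    )


def set_efficiency(
    plate: PlateRun,
    dset: DilutionSet,
    window,
    base: Optional[float] = None,
    outlier_removal: bool = True,
    cross_well_only: bool = False,
) -> EfficiencyEstimate:
    """One dilution set's pairwise efficiency: admit readings, enumerate pairs,
    and (optionally) exclude low-frequency outliers. Deterministic."""
    b = dset.base if base is None else base
    readings = admit_readings(plate, dset, window)
    array = enumerate_pairs(
        readings, base=b, set_id=dset.set_id, window=window, cross_well_only=cross_well_only
    )
    if len(array) == 0:
        raise ValueError(f"set {dset.set_id}: all admitted pairs share cycles")
    values = array.e_values
    if outlier_removal and len(array) >= MIN_N_FOR_CHI2:
        stats = distribution_stats(array)
        return exclude_outliers(array, stats)
    if outlier_removal:
        warnings.warn(
            f"set {dset.set_id}: only {len(array)} pairs (< {MIN_N_FOR_CHI2}); "
            "outlier exclusion skipped",
            stacklevel=2,
        )
    mean = float(values.mean())
    return EfficiencyEstimate(
        e_mean=mean,
        method="pairwise",
        n_total=len(array),
        n_retained=len(array),
        e_raw=mean,
        set_id=dset.set_id,
    )
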