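"""The pairwise estimator: per-pair formula, pair enumeration, distribution
diagnostics and the frequency-based outlier rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pairq import (
    EmptyWindowError,
    FluorWindow,
    PairwiseEArray,
    PairwiseEValue,
    ReadingRef,
    WellId,
    admit_readings,
    distribution_stats,
    enumerate_pairs,
    exclude_outliers,
    pairwise_efficiency,
    set_efficiency,
)

A1, A2 = WellId("A", 1), WellId("A", 2)


def _ref(cycle, rfu, step=0, well=A1):
    return ReadingRef(well, cycle, rfu, step)


# ---- pairwise_efficiency ---------------------------------------------------


def test_doubling_within_one_well():
    assert pairwise_efficiency(_ref(20, 100.0), _ref(21, 200.0)) == pytest.approx(1.0, abs=1e-12)


def test_dilution_catchup_in_one_cycle_means_doubling():
    # equal readings one cycle apart across a 2-fold dilution step
    a = _ref(20, 150.0, step=0, well=A1)
    b = _ref(21, 150.0, step=1, well=A2)
    assert pairwise_efficiency(a, b) == pytest.approx(1.0, abs=1e-12)


def test_equal_cycles_and_nonpositive_rfu_rejected():
    with pytest.raises(ValueError, match="cycle"):
        pairwise_efficiency(_ref(20, 100.0), _ref(20, 150.0, well=A2))
    with pytest.raises(ValueError):
        ReadingRef(A1, 20, -1.0, 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    fi=st.floats(0.1, 1e4), fj=st.floats(0.1, 1e4),
    i=st.integers(1, 40), j=st.integers(1, 40),
    d1=st.integers(0, 5), d2=st.integers(0, 5),
    base=st.sampled_from([2.0, 10.0]),
)
def test_orientation_invariance(fi, fj, i, j, d1, d2, base):
    if i == j:
        return
    a, b = _ref(i, fi, d1, A1), _ref(j, fj, d2, A2)
    e_ab = pairwise_efficiency(a, b, base)
    e_ba = pairwise_efficiency(b, a, base)
    assert e_ab == e_ba
    assert e_ab > -1.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    fi=st.floats(0.1, 1e4), fj=st.floats(0.1, 1e4),
    i=st.integers(1, 40), j=st.integers(5, 45),
    d2=st.integers(0, 4),
)
def test_dilution_coherence(fi, fj, i, j, d2):
    """Multiplying a well's readings by b and incrementing its D leaves every
    cross-well pairwise E unchanged."""
    if i == j:
        return
    a = _ref(i, fi, 0, A1)
    b = _ref(j, fj, d2, A2)
    b_shift = _ref(j, fj / 2.0, d2 + 1, A2)
    assert pairwise_efficiency(a, b) == pytest.approx(pairwise_efficiency(a, b_shift), rel=1e-12)


def test_recovers_generating_efficiency(noiseless_plate, window):
    plate, sets, params = noiseless_plate
    readings = admit_readings(plate, sets[0], window)
    arr = enumerate_pairs(readings, base=2.0)
    np.testing.assert_allclose(arr.e_values, params.e_true, atol=1e-12)


# ---- admit_readings / enumerate_pairs --------------------------------------


def test_admitted_readings_carry_dilution_steps(noiseless_plate, window):
    plate, sets, _ = noiseless_plate
    readings = admit_readings(plate, sets[0], window)
    assert {r.dilution_step for r in readings} == set(range(6))
    assert all(window.lower <= r.rfu <= window.upper for r in readings)
    # E=0.8, 2-fold: the 20-180 RFU band holds ~4 readings per curve
    assert 18 <= len(readings) <= 30


def test_empty_window_rejected(noiseless_plate):
    plate, sets, _ = noiseless_plate
    with pytest.raises(EmptyWindowError):
        admit_readings(plate, sets[0], FluorWindow(1e9, 1e10))


def _brute_force_count(cycles, cross_well_only=False, wells=None):
    n = len(cycles)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if cycles[i] == cycles[j]:
                continue
            if cross_well_only and wells[i] == wells[j]:
                continue
            count += 1
    return count


def test_pair_count_closed_form_and_oracle():
    """|pairs| = C(n,2) - sum_c C(n_c,2), validated against a brute-force
    double loop on 200 random instances of up to 50 readings."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = rng.integers(2, 51)
        cycles = rng.integers(1, 15, size=n)
        readings = [
            ReadingRef(WellId("A", int(k % 12) + 1), int(c), float(rng.uniform(1, 100)), int(k % 6))
            for k, c in enumerate(cycles)
        ]
        arr = enumerate_pairs(readings, base=2.0)
        brute = _brute_force_count(cycles.tolist())
        _, counts = np.unique(cycles, return_counts=True)
        closed = n * (n - 1) // 2 - int(sum(c * (c - 1) // 2 for c in counts))
        assert len(arr) == brute == closed


def test_single_reading_rejected():
    with pytest.raises(ValueError):
        enumerate_pairs([_ref(5, 10.0)])


def test_cross_well_only_excludes_same_well_pairs():
    readings = [_ref(10, 10.0, 0, A1), _ref(11, 18.0, 0, A1), _ref(12, 20.0, 1, A2)]
    full = enumerate_pairs(readings)
    cross = enumerate_pairs(readings, cross_well_only=True)
    assert len(full) == 3 and len(cross) == 2
    assert all(v.a.well != v.b.well for v in cross.values)


# ---- distribution_stats ----------------------------------------------------


def test_symmetric_sample_has_zero_skew():
    stats = distribution_stats(np.array([0.7, 0.9] * 30))
    assert stats.skew == pytest.approx(0.0, abs=1e-12)


def test_moments_match_spreadsheet_conventions():
    rng = np.random.default_rng(7)
    x = rng.gamma(2.0, 0.1, size=400)
    stats = distribution_stats(x)
    assert stats.skew == pytest.approx(sps.skew(x, bias=False), abs=1e-12)
    assert stats.kurtosis_excess == pytest.approx(sps.kurtosis(x, bias=False), abs=1e-12)


def test_seeded_normal_sample_passes_chi_square():
    rng = np.random.default_rng(123)
    x = rng.standard_normal(10_000)
    stats = distribution_stats(x)
    assert stats.normal_rejected is False
    assert abs(stats.skew) < 0.1
    assert abs(stats.kurtosis_excess) < 0.2
    assert stats.chi2_valid


def test_leptokurtic_sample_rejected_as_normal():
    rng = np.random.default_rng(5)
    x = rng.standard_t(df=2, size=2000) * 0.1 + 0.8
    stats = distribution_stats(x)
    assert stats.kurtosis_excess > 1.0
    assert stats.normal_rejected is True


def test_small_sample_skips_chi_square():
    with pytest.warns(UserWarning, match="chi-square"):
        stats = distribution_stats(np.linspace(0.5, 1.0, 20))
    assert stats.chi2_stat is None and stats.normal_rejected is None


def test_histogram_bins_anchored_at_zero():
    stats = distribution_stats(np.array([0.62, 0.74, 0.88] * 20))
    assert stats.bin_edges[0] == pytest.approx(0.60)
    np.testing.assert_allclose(np.diff(stats.bin_edges), 0.05)
    assert stats.bin_counts.sum() == 60


# ---- exclude_outliers --------------------------------------------------------


def _as_array(values):
    refs = [PairwiseEValue(float(v), _ref(1, 1.0), _ref(2, 2.0)) for v in values]
    return PairwiseEArray(values=refs, set_id="t")


def test_distant_values_excluded():
    rng = np.random.default_rng(11)
    core = rng.normal(0.80, 0.01, 100)
    values = np.concatenate([core, [2.0, 2.01, 2.02]])
    est = exclude_outliers(_as_array(values))
    assert est.n_total == 103 and est.n_retained == 100
    assert est.e_mean == pytest.approx(0.80, abs=0.005)
    assert est.excluded_high_cutoff is not None and est.excluded_high_cutoff <= 1.0


def test_single_bin_array_unchanged():
    values = np.full(60, 0.81)
    est = exclude_outliers(_as_array(values))
    assert est.n_retained == est.n_total == 60
    assert est.e_mean == pytest.approx(0.81)


def test_sparse_distribution_warns_and_keeps_all():
    values = np.linspace(-0.5, 3.0, 60)  # ~1 value per 0.05 bin
    with pytest.warns(UserWarning, match="sparse"):
        est = exclude_outliers(_as_array(values))
    assert est.n_retained == 60


def test_exclusion_never_increases_spread(noisy_plate, window):
    plate, sets, _ = noisy_plate
    for dset in sets[:4]:
        arr = enumerate_pairs(admit_readings(plate, dset, window), base=2.0, set_id=dset.set_id)
        est = exclude_outliers(arr)
        vals = arr.e_values
        lo = -np.inf if est.excluded_low_cutoff is None else est.excluded_low_cutoff
        hi = np.inf if est.excluded_high_cutoff is None else est.excluded_high_cutoff
        retained = vals[(vals >= lo) & (vals <= hi)]
        assert retained.std(ddof=1) <= vals.std(ddof=1)


# ---- set_efficiency ----------------------------------------------------------


def test_noiseless_set_efficiency_exact(noiseless_plate, window):
    plate, sets, params = noiseless_plate
    est = set_efficiency(plate, sets[0], window)
    assert est.e_mean == pytest.approx(params.e_true, abs=1e-12)
    assert est.n_retained == est.n_total


def test_parameter_recovery_under_noise():
    """Median bias of the set-level estimate over 200 seeded noisy single-set
    plates stays below 0.02."""
    from pairq import SimParams, default_sets, simulate_plate

    window = FluorWindow(20, 180)
    biases = []
    for seed in range(200):
        params = SimParams(n_sets=1, seed=seed)
        plate = simulate_plate(params)
        dset = default_sets(params)[0]
        est = set_efficiency(plate, dset, window)
        biases.append(est.e_mean - params.e_true)
    assert abs(np.median(biases)) < 0.02


def test_set_efficiency_deterministic(noisy_plate, window):
    plate, sets, _ = noisy_plate
    a = set_efficiency(plate, sets[0], window)
    b = set_efficiency(plate, sets[0], window)
    assert a == b
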