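import numpy as np
import pytest

import pilsync as ps
from pilsync import InsufficientDataError, PeakSeries, find_peaks, phase_differences
from pilsync.synchrony import synchrony_compare


def _series(times):
    times = np.asarray(times, dtype=float)
    return PeakSeries("s", times, np.ones_like(times), np.ones_like(times))


def test_sine_peaks_at_analytic_maxima():
    t = np.arange(0.0, 100.0, 0.1)
    pk = find_peaks(t, np.sin(2 * np.pi * t / 24.0), min_prominence=0.1,
                    transient_cutoff=0.0)
    np.testing.assert_allclose(pk.peak_times, [6.0, 30.0, 54.0, 78.0], atol=0.05)
    np.testing.assert_allclose(pk.periods, 24.0, atol=0.1)


def test_constant_signal_has_no_peaks():
    t = np.arange(0.0, 50.0, 0.1)
    pk = find_peaks(t, np.ones_like(t), transient_cutoff=0.0)
    assert len(pk) == 0


def _brute_force_peaks(values, min_prominence):
    """Independent prominence rule: for each strict local maximum, walk out
    to the nearest higher sample on each side; the prominence is the peak
    height minus the higher of the two interval minima."""
    idx = []
    for i in range(1, len(values) - 1):
        if not (values[i] > values[i - 1] and values[i] > values[i + 1]):
            continue
        left = values[:i][::-1]
        stop = np.nonzero(left > values[i])[0]
        lmin = left[: stop[0]].min() if len(stop) else left.min()
        right = values[i + 1:]
        stop = np.nonzero(right > values[i])[0]
        rmin = right[: stop[0]].min() if len(stop) else right.min()
        if values[i] - max(lmin, rmin) >= min_prominence:
            idx.append(i)
    return np.array(idx)


def test_peaks_match_brute_force_oracle():
    t = np.arange(0.0, 200.0, 0.1)
    sig = np.sin(2 * np.pi * t / 17.0) + 0.6 * np.sin(2 * np.pi * t / (17.0 * np.sqrt(2)))
    prom = 0.2
    got = find_peaks(t, sig, min_prominence=prom, transient_cutoff=0.0)
    want_idx = _brute_force_peaks(sig, prom)
    assert len(got) == len(want_idx)
    np.testing.assert_allclose(got.peak_times, t[want_idx], atol=0.1)


def test_too_few_samples_raises():
    with pytest.raises(InsufficientDataError):
        find_peaks(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0]),
                   transient_cutoff=1.5)


def test_identical_series_zero_dispersion():
    s = _series([10.0, 20.0, 30.0])
    out = phase_differences(s, s)
    np.testing.assert_array_equal(out.phase_differences, 0.0)
    assert out.dispersion == 0.0
    assert out.n_pairs == 3


def test_constant_shift_is_phase_locked():
    a = _series([10.0, 20.0, 30.0])
    b = _series([12.0, 22.0, 32.0])
    out = phase_differences(a, b)
    np.testing.assert_allclose(out.phase_differences, -2.0)
    assert out.dispersion == pytest.approx(0.0, abs=1e-12)
    assert out.mean_phase == pytest.approx(-2.0)


def test_dispersion_is_sample_standard_deviation():
    out = phase_differences(_series([10.0, 20.0]), _series([9.0, 17.0]))
    np.testing.assert_allclose(np.sort(out.phase_differences), [1.0, 3.0])
    assert out.dispersion == pytest.approx(np.sqrt(2.0))
    assert out.density_fit[0] == pytest.approx(2.0)


def test_offset_invariance():
    rng = np.random.default_rng(7)
    base = np.sort(rng.uniform(0.0, 300.0, 8))
    other = np.sort(rng.uniform(0.0, 300.0, 8))
    d0 = phase_differences(_series(base), _series(other)).dispersion
    for shift in (5.0, -3.0, 40.0):
        d = phase_differences(_series(base + shift), _series(other)).dispersion
        # dispersion scores locking, not lag: uniform shifts that do not
        # change the pairing leave it unchanged
        if np.array_equal(
            np.argsort([abs(a - b) for a in base for b in other]),
            np.argsort([abs(a + shift - b) for a in base for b in other]),
        ):
            assert d == pytest.approx(d0)


def test_ordered_pairing_mode():
    a = _series([10.0, 20.0, 30.0, 40.0])
    b = _series([11.0, 21.0, 31.0])
    out = phase_differences(a, b, mode="ordered")
    np.testing.assert_allclose(out.phase_differences, -1.0)
    assert out.n_pairs == 3


def test_empty_series_rejected():
    with pytest.raises(InsufficientDataError):
        phase_differences(_series([1.0]), _series([1.0, 2.0]))


def test_period_recovery_on_sinusoid():
    t = np.arange(0.0, 400.0, 0.1)
    pk = find_peaks(t, np.cos(2 * np.pi * t / 37.5), transient_cutoff=100.0)
    assert np.all(np.abs(pk.periods - 37.5) < 0.1)


def test_compare_equal_trajectories_equal_scores(onset_trajectories):
    traj = onset_trajectories["coupled"]
    table = synchrony_compare({"a": traj, "b": traj}, transient_cutoff=50.0)
    assert table["dispersion"].nunique() == 1
    assert set(table["status"]) == {"ok"}


def test_compare_is_deterministic(onset_trajectories):
    t1 = synchrony_compare(onset_trajectories, transient_cutoff=50.0)
    t2 = synchrony_compare(onset_trajectories, transient_cutoff=50.0)
    assert t1.equals(t2)


def test_pils_coupling_tightens_phase_locking(onset_trajectories):
    """The full model aligns the BR and auxin outputs; cutting the
    BR -> PILS coupling leaves them drifting within the onset window."""
    table = synchrony_compare(onset_trajectories, transient_cutoff=50.0)
    table = table.set_index("scenario")
    assert table.loc["coupled", "dispersion"] < table.loc["uncoupled", "dispersion"]


def test_flat_trajectory_flagged_not_scored():
    t = np.arange(0.0, 300.0, 0.1)
    flat = ps.Trajectory(times=t, states=np.ones((len(t), 10)))
    table = synchrony_compare({"flat": flat}, transient_cutoff=50.0)
    assert table.loc[0, "status"] == "no_oscillation"
    assert np.isnan(table.loc[0, "dispersion"])
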