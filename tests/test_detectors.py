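"""Unit tests for the four detection methods and the CP extraction rules."""

from __future__ import annotations

import numpy as np
import pytest

from spikecpd import (
    ConfigurationError,
    SpikeTrain,
    ThresholdPair,
    TimeGrid,
    detect_classification,
    detect_isi_ratio,
    detect_moving_average,
    detect_pure_isi,
    extract_cps,
    fit_classifier,
    loo_classification,
)
from spikecpd.detectors import (
    ClassifierModel,
    ClassificationDetector,
    ISIRatioDetector,
    MovingAverageDetector,
    PureISIDetector,
    category_borders,
)


class TestExtractCPs:
    def test_single_episode_single_cp(self, default_grid):
        t = default_grid.times()
        train = SpikeTrain(times=np.array([1.0, 190.0]), duration=200.0)
        ind = (t >= 100.0) & (t <= 110.0)
        assert extract_cps(ind, train, 40.0, default_grid).tolist() == [100.0]

    def test_reset_after_accept_len_in_new_interval(self, default_grid):
        t = default_grid.times()
        train = SpikeTrain(times=np.array([95.0, 130.0, 170.0]), duration=200.0)
        ind = (t >= 100.0) & (t <= 160.0)
        cps = extract_cps(ind, train, 40.0, default_grid)
        assert cps.tolist() == [100.0, 140.0]

    def test_never_two_cps_between_the_same_spikes(self, default_grid):
        t = default_grid.times()
        train = SpikeTrain(times=np.array([95.0, 170.0]), duration=200.0)
        ind = (t >= 100.0) & (t <= 160.0)
        assert extract_cps(ind, train, 40.0, default_grid).tolist() == [100.0]

    def test_empty_indicator(self, default_grid):
        train = SpikeTrain(times=np.array([5.0]), duration=200.0)
        ind = np.zeros(default_grid.n, dtype=bool)
        assert extract_cps(ind, train, 30.0, default_grid).size == 0


class TestPureISI:
    def test_short_isi_fires_at_spike(self, default_grid):
        tr = SpikeTrain(times=np.array([0.0, 100.0, 103.0, 106.0]), duration=200.0)
        res_in, _ = detect_pure_isi(tr, default_grid, ThresholdPair(5.0, 500.0))
        assert res_in.cp_times.tolist() == [103.0]

    def test_gap_crossing_at_s1_plus_theta(self, default_grid):
        tr = SpikeTrain(times=np.array([0.0, 10.0, 20.0, 120.0]), duration=200.0)
        _, res_de = detect_pure_isi(tr, default_grid, ThresholdPair(1.0, 50.0))
        assert res_de.cp_times[0] == pytest.approx(70.0, abs=default_grid.dt + 1e-9)

    def test_periodic_train_silent(self, default_grid):
        tr = SpikeTrain(times=np.arange(0.0, 200.0, 10.0), duration=200.0)
        res_in, res_de = detect_pure_isi(tr, default_grid, ThresholdPair(5.0, 50.0))
        assert res_in.n_cps == 0 and res_de.n_cps == 0


class TestISIRatio:
    def test_increase_at_spike_with_small_ratio(self):
        tr = SpikeTrain(times=np.array([0.0, 10.0, 20.0, 24.0]), duration=100.0)
        grid = TimeGrid(0.1, 0.0, 100.0)
        res_in, _ = detect_isi_ratio(tr, grid, 0.0, ThresholdPair(0.5, 2.0))
        assert res_in.cp_times.tolist() == [24.0]  # R = 4/10 at the spike

    def test_decrease_crossing_at_s1_plus_theta_times_ipre(self, default_grid):
        tr = SpikeTrain(times=np.array([0.0, 10.0, 20.0, 120.0]), duration=200.0)
        _, res_de = detect_isi_ratio(tr, default_grid, 0.0, ThresholdPair(0.5, 2.0))
        assert res_de.cp_times[0] == pytest.approx(40.0, abs=default_grid.dt + 1e-9)

    def test_periodic_train_has_unit_ratio(self, default_grid):
        tr = SpikeTrain(times=np.arange(0.0, 200.0, 10.0), duration=200.0)
        res_in, res_de = detect_isi_ratio(tr, default_grid, 0.0, ThresholdPair(0.9, 1.1))
        assert res_in.n_cps == 0 and res_de.n_cps == 0

    def test_ratio_at_spikes_is_i1_over_i2_at_omega_zero(self, random_train_factory):
        tr = random_train_factory(21, n_spikes=100)
        grid = TimeGrid(0.1, 0.0, tr.duration)
        det = ISIRatioDetector(tr, grid, 0.0)
        sp = tr.times
        expected = (sp[2:] - sp[1:-1]) / (sp[1:-1] - sp[:-2])
        assert np.array_equal(det._ratio_at_spike[2:], expected)

    def test_threshold_domain_validation(self, default_grid):
        tr = SpikeTrain(times=np.arange(0.0, 200.0, 10.0), duration=200.0)
        det = ISIRatioDetector(tr, default_grid, 0.5)
        with pytest.raises(ConfigurationError):
            det.detect("increase", 1.2)
        with pytest.raises(ConfigurationError):
            det.detect("decrease", 0.8)


class TestMovingAverage:
    def test_periodic_train_silent(self, default_grid):
        tr = SpikeTrain(times=np.arange(0.0, 200.0, 10.0), duration=200.0)
        res_in, res_de = detect_moving_average(
            tr, default_grid, 50.0, ThresholdPair(1.0, 1.0)
        )
        assert res_in.n_cps == 0 and res_de.n_cps == 0

    def test_burst_fires_at_first_short_isi_spike(self):
        times = np.concatenate([np.arange(0.0, 120.0, 20.0), [102.0, 104.0, 106.0]])
        tr = SpikeTrain(times=np.sort(times), duration=200.0)
        grid = TimeGrid(0.1, 0.0, 200.0)
        res_in, _ = detect_moving_average(tr, grid, 50.0, ThresholdPair(1.0, 8.0))
        assert res_in.n_cps >= 1
        assert res_in.cp_times[0] == pytest.approx(102.0, abs=grid.dt)

    def test_gap_fires_decrease_during_pause(self):
        times = np.concatenate([np.arange(0.0, 100.0, 5.0), [195.0]])
        tr = SpikeTrain(times=times, duration=250.0)
        grid = TimeGrid(0.1, 0.0, 250.0)
        _, res_de = detect_moving_average(tr, grid, 50.0, ThresholdPair(8.0, 1.0))
        assert res_de.n_cps >= 1
        assert 95.0 < res_de.cp_times[0] < 195.0

    def test_increase_cps_only_at_spike_times(self, random_train_factory):
        tr = random_train_factory(4, n_spikes=150)
        grid = TimeGrid(0.1, 0.0, tr.duration)
        det = MovingAverageDetector(tr, grid, 100.0)
        for theta in (0.5, 1.0, 2.0):
            res = det.detect("increase", theta)
            for cp in res.cp_times:
                # a spike falls within the CP's grid bin
                assert np.any((tr.times > cp - grid.dt) & (tr.times <= cp))


@pytest.mark.parametrize(
    "make_det, direction, thetas",
    [
        (lambda tr, g: PureISIDetector(tr, g), "increase", [2.0, 5.0, 10.0]),
        (lambda tr, g: PureISIDetector(tr, g), "decrease", [60.0, 40.0, 25.0]),
        (lambda tr, g: ISIRatioDetector(tr, g, 0.5), "increase", [0.2, 0.5, 0.8]),
        (lambda tr, g: ISIRatioDetector(tr, g, 0.5), "decrease", [4.0, 2.0, 1.3]),
        (lambda tr, g: MovingAverageDetector(tr, g, 50.0), "increase", [3.0, 1.5, 0.5]),
        (lambda tr, g: MovingAverageDetector(tr, g, 50.0), "decrease", [3.0, 1.5, 0.5]),
    ],
)
def test_relaxing_threshold_grows_crossing_episodes(
    random_train_factory, make_det, direction, thetas
):
    """Pointwise monotonicity: every crossing at a strict threshold remains a
    crossing at any more permissive threshold (episodes only grow/merge)."""
    tr = random_train_factory(13, n_spikes=150)
    grid = TimeGrid(0.1, 0.0, tr.duration)
    det = make_det(tr, grid)
    prev = None
    for theta in thetas:  # ordered strict -> relaxed
        ind = det.indicator(direction, theta)
        if prev is not None:
            assert np.all(ind[prev])  # strict crossings survive relaxation
        prev = ind


class TestClassifierFit:
    def test_geometric_borders(self):
        borders = category_borders(1.0, 100.0, 2)
        assert borders[0] == 0.0
        assert borders[1] == pytest.approx(10.0)
        assert borders[2] == np.inf

    def test_border_degenerate_inputs(self):
        with pytest.raises(ConfigurationError):
            category_borders(0.0, 10.0, 5)
        with pytest.raises(ConfigurationError):
            category_borders(10.0, 10.0, 5)

    @pytest.fixture
    def small_fit(self):
        rng = np.random.default_rng(5)
        trains = []
        for trial in range(3):
            isis = 0.5 + rng.exponential(12.0, size=60)
            times = np.cumsum(isis)
            times = times[times < 790.0]
            trains.append(SpikeTrain(times=times, duration=800.0, trial_id=trial))
        changes = [200.0, 500.0]
        grid = TimeGrid(1.0, 0.0, 800.0)
        model = fit_classifier(trains, changes, 0.5, 4, (10.0, 40.0), grid)
        return trains, changes, grid, model

    def test_frequency_table_bounds_and_formula(self, small_fit):
        _, _, _, model = small_fit
        total = model.counts_in + model.counts_cde
        assert np.all((model.freq >= 0.0) & (model.freq <= 1.0))
        nz = total > 0
        assert np.allclose(model.freq[nz], model.counts_in[nz] / total[nz])
        assert np.all(model.freq[~nz] == 0.0)

    def test_count_conservation(self, small_fit):
        from spikecpd import isi_series

        trains, _, grid, model = small_fit
        t = grid.times()
        n_valid = 0
        for tr in trains:
            ser = isi_series(tr.times, t, grid.dt, omega=model.omega)
            n_valid += int(
                np.sum(np.isfinite(ser["i_a"]) & np.isfinite(ser["i_pre"]))
            )
        assert int((model.counts_in + model.counts_cde).sum()) == n_valid

    def test_brute_force_recount(self, small_fit):
        """Re-derive N_in / N_c,de per category pair with the scalar ISI
        functions and explicit loops; must match the fitted counts exactly."""
        from spikecpd import InsufficientHistoryError, adjusting_isi, weighted_previous_isi

        trains, changes, grid, model = small_fit
        k = model.k
        n_in = np.zeros((k, k), dtype=int)
        n_cde = np.zeros((k, k), dtype=int)

        def category(x):
            c = 1
            while c < k and x > model.borders[c]:
                c += 1
            return c

        for tr in trains:
            for t in grid.times():
                # evaluate at the spike when one falls inside the grid bin
                in_bin = tr.times[(tr.times > t - grid.dt) & (tr.times <= t)]
                query = float(in_bin[-1]) if in_bin.size else float(t)
                try:
                    i_a = adjusting_isi(tr, query)
                    i_pre = weighted_previous_isi(tr, query, model.omega)
                except InsufficientHistoryError:
                    continue
                pair = (category(i_pre) - 1, category(i_a) - 1)
                inside = any(c + 10.0 <= t <= c + 40.0 for c in changes)
                if inside:
                    n_in[pair] += 1
                else:
                    n_cde[pair] += 1
        assert np.array_equal(n_in, model.counts_in)
        assert np.array_equal(n_cde, model.counts_cde)

    def test_pure_category_pairs_give_extreme_frequencies(self, small_fit):
        _, _, _, model = small_fit
        only_inside = (model.counts_in > 0) & (model.counts_cde == 0)
        only_outside = (model.counts_in == 0) & (model.counts_cde > 0)
        assert np.all(model.freq[only_inside] == 1.0)
        assert np.all(model.freq[only_outside] == 0.0)


class TestClassificationDetect:
    def _toy_model(self, freq):
        return ClassifierModel(
            borders=np.array([0.0, 2.0, 8.0, np.inf]),
            k=3,
            omega=0.0,
            freq=freq,
            counts_in=np.zeros((3, 3), dtype=int),
            counts_cde=np.zeros((3, 3), dtype=int),
            direction="increase",
            train_window=(10.0, 40.0),
        )

    def test_zero_table_and_theta_one_detect_nothing(self, random_train_factory):
        tr = random_train_factory(2, n_spikes=80)
        grid = TimeGrid(0.1, 0.0, tr.duration)
        model = self._toy_model(np.zeros((3, 3)))
        assert detect_classification(model, tr, grid, 0.0).n_cps == 0
        rich = self._toy_model(np.full((3, 3), 0.6))
        assert detect_classification(rich, tr, grid, 1.0).n_cps == 0

    def test_single_marked_pair_fires_once_at_its_spike(self):
        # at the spike t=56: i1=1 (category 1), i2=5 (category 2) -> pair (2,1)
        freq = np.zeros((3, 3))
        freq[1, 0] = 0.9
        model = self._toy_model(freq)
        tr = SpikeTrain(times=np.array([20.0, 40.0, 50.0, 55.0, 56.0, 80.0]),
                        duration=120.0)
        grid = TimeGrid(0.1, 0.0, 120.0)
        res = detect_classification(model, tr, grid, 0.5)
        assert res.cp_times.tolist() == [56.0]


class TestLeaveOneOut:
    def test_needs_two_trials(self, random_train_factory):
        tr = random_train_factory(1)
        grid = TimeGrid(0.5, 0.0, tr.duration)
        with pytest.raises(ConfigurationError):
            loo_classification([tr], [100.0], 0.0, 4, (10.0, 40.0), 0.5, grid)

    def test_identical_trials_give_identical_models(self):
        times = np.cumsum(0.5 + np.random.default_rng(8).exponential(12.0, size=50))
        tr1 = SpikeTrain(times=times, duration=700.0, trial_id=0)
        tr2 = SpikeTrain(times=times.copy(), duration=700.0, trial_id=1)
        grid = TimeGrid(1.0, 0.0, 700.0)
        m1 = fit_classifier([tr1], [300.0], 0.5, 4, (10.0, 40.0), grid)
        m2 = fit_classifier([tr2], [300.0], 0.5, 4, (10.0, 40.0), grid)
        assert np.array_equal(m1.borders, m2.borders)
        assert np.array_equal(m1.freq, m2.freq)

    def test_one_result_per_trial(self):
        rng = np.random.default_rng(31)
        trains = []
        for i in range(3):
            times = np.cumsum(0.5 + rng.exponential(12.0, size=60))
            trains.append(
                SpikeTrain(times=times[times < 990.0], duration=1000.0, trial_id=i)
            )
        grid = TimeGrid(0.5, 0.0, 1000.0)
        results = loo_classification(
            trains, [200.0, 500.0], 0.0, 4, (10.0, 40.0), 0.5, grid
        )
        assert len(results) == len(trains)


class TestGridRefinement:
    @pytest.mark.parametrize(
        "detect",
        [
            lambda tr, g: detect_pure_isi(tr, g, ThresholdPair(5.0, 50.0)),
            lambda tr, g: detect_isi_ratio(tr, g, 0.0, ThresholdPair(0.5, 2.0)),
            lambda tr, g: detect_moving_average(tr, g, 50.0, ThresholdPair(2.0, 2.0)),
        ],
    )
    def test_halving_dt_preserves_cps(self, detect):
        times = np.concatenate(
            [np.arange(10.0, 150.0, 20.0), [152.0, 154.0, 156.0], [290.0, 310.0]]
        )
        tr = SpikeTrain(times=times, duration=400.0)
        coarse = TimeGrid(0.1, 0.0, 400.0)
        fine = TimeGrid(0.05, 0.0, 400.0)
        for res_c, res_f in zip(detect(tr, coarse), detect(tr, fine)):
            assert res_c.n_cps == res_f.n_cps
            assert np.all(np.abs(res_c.cp_times - res_f.cp_times) <= coarse.dt + 1e-9)
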