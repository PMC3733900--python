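"""Response statistics against brute-force oracles and closed forms."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apoptosim as ap
from apoptosim.deterministic import Trajectory
from apoptosim.stats import (classify_bimodality, coefficient_of_variation,
                             fano_factor, response_delay,
                             steady_state_value,
                             stochastic_bistability_thresholds)


def _traj(cea):
    cea = np.asarray(cea, dtype=float)
    t = np.arange(len(cea), dtype=float)
    states = np.zeros((len(cea), 5))
    states[:, 4] = cea
    return Trajectory(t, states)


class TestSteadyState:
    def test_constant_trajectory(self):
        v, conv = steady_state_value(_traj(np.full(100, 7.0)))
        assert v == 7.0 and conv

    def test_noisy_stationary_tail_mean(self):
        rng = np.random.default_rng(0)
        plateau = rng.normal(5.0, 0.1, size=200)
        cea = np.concatenate([np.linspace(0, 5, 300), plateau])
        v, conv = steady_state_value(_traj(cea))
        assert v == pytest.approx(plateau[-50:].mean())
        assert conv

    def test_monotone_ramp_flagged(self):
        v, conv = steady_state_value(_traj(np.linspace(0, 10, 200)))
        assert not conv


class TestResponseDelay:
    def test_linear_ramp_half_crossing(self):
        # ramp 0 -> S over [0, T]; ref = S crosses S/2 at T/2
        tr = _traj(np.linspace(0, 8.0, 101))
        assert response_delay(tr, 8.0).t_d == pytest.approx(50.0)

    def test_step_crossing(self):
        # a recorded step crosses within one grid interval of the jump
        cea = np.zeros(100)
        cea[37:] = 4.0
        assert response_delay(_traj(cea), 4.0).t_d == pytest.approx(37.0,
                                                                    abs=1.0)

    def test_flat_zero_is_non_responder(self):
        d = response_delay(_traj(np.zeros(50)), 1.0)
        assert not d.responded and d.t_d is None

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            response_delay(_traj(np.ones(10)), 0.0)

    def test_monotone_in_reference(self):
        rng = np.random.default_rng(3)
        cea = np.cumsum(rng.uniform(0, 1, 300))
        tr = _traj(cea)
        tds = [response_delay(tr, r).t_d for r in (1.0, 5.0, 50.0, 200.0)]
        assert all(a <= b for a, b in zip(tds, tds[1:]))


class TestNoiseMeasures:
    def test_known_values(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(0.5)
        assert fano_factor([4, 4, 4]) == 0.0

    def test_poisson_fano_near_one(self):
        draws = np.random.default_rng(1).poisson(50, size=20000)
        assert fano_factor(draws) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("fn", [coefficient_of_variation, fano_factor])
    def test_domain_errors(self, fn):
        with pytest.raises(ValueError):
            fn([])
        with pytest.raises(ValueError):
            fn([1.0])
        with pytest.raises(ValueError):
            fn([-1.0, 1.0])  # zero mean

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=2,
                    max_size=40))
    def test_definitional_recomputation(self, values):
        v = np.array(values)
        m = v.mean()
        sd = np.sqrt(((v - m) ** 2).sum() / (len(v) - 1))
        assert coefficient_of_variation(v) == pytest.approx(sd / m)
        assert fano_factor(v) == pytest.approx(sd ** 2 / m)


class TestBimodality:
    def test_constant_sample_unimodal(self):
        assert not classify_bimodality(np.full(30, 5.0)).is_bimodal

    def test_two_tight_clusters_recovered(self):
        rng = np.random.default_rng(2)
        lo = rng.normal(55, 3, size=40)
        hi = rng.normal(960, 30, size=40)
        bm = classify_bimodality(np.concatenate([lo, hi]))
        assert bm.is_bimodal
        assert bm.low_mode_mean == pytest.approx(lo.mean())
        assert bm.high_mode_mean == pytest.approx(hi.mean())
        assert bm.low_fraction == pytest.approx(0.5)

    def test_minimum_occupancy_enforced(self):
        vals = np.concatenate([np.full(99, 10.0), [1000.0]])
        assert not classify_bimodality(vals).is_bimodal

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            classify_bimodality(np.arange(10))

    def test_permutation_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        data = np.concatenate([rng.normal(1, 0.05, 30),
                               rng.normal(9, 0.3, 30)])
        a = classify_bimodality(data)
        b = classify_bimodality(rng.permutation(data))
        c = classify_bimodality(data * 7.5)
        assert a.is_bimodal == b.is_bimodal == c.is_bimodal
        assert a.threshold == pytest.approx(b.threshold)
        assert c.threshold == pytest.approx(7.5 * a.threshold)
        assert c.low_mode_mean == pytest.approx(7.5 * a.low_mode_mean)


class TestStochasticThresholds:
    def _populations(self, window=(0.3, 0.7), n=40):
        """Zero-noise surrogate: below the window all-low, inside split,
        above all-high."""
        rng = np.random.default_rng(5)
        cc = np.linspace(0.1, 1.0, 10)
        pops = []
        for c in cc:
            if c < window[0]:
                pops.append(rng.normal(50, 2, n))
            elif c > window[1]:
                pops.append(rng.normal(950, 20, n))
            else:
                pops.append(np.concatenate([rng.normal(50, 2, n // 2),
                                            rng.normal(950, 20, n - n // 2)]))
        return cc, pops

    def test_window_recovered(self):
        cc, pops = self._populations()
        off, on = stochastic_bistability_thresholds(cc, pops)
        assert off == pytest.approx(0.3, abs=0.11)
        assert on == pytest.approx(0.7, abs=0.11)

    def test_all_unimodal_scan(self):
        rng = np.random.default_rng(6)
        cc = np.linspace(0.1, 1.0, 6)
        pops = [rng.normal(50, 2, 30) for _ in cc]
        assert stochastic_bistability_thresholds(cc, pops) == (None, None)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            stochastic_bistability_thresholds([0.1, 0.2], [[1] * 30] * 2)
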