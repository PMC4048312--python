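"""Transfer-entropy estimator tests.

The plug-in estimator is validated against a closed-form copy process, an
independently coded dictionary-counting transfer entropy, and grid-search
oracles for the optimal binarization threshold.
"""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from gtenet import (FluorescenceRecording, GTEParams, ParameterError,
                    ValidationError, conditioning_mask, difference_filter,
                    gte_matrix, gte_pair, make_fixture,
                    optimal_binarization_threshold,
                    select_conditioning_level, symbolize)


def textbook_te(x, y, k=1, ift=False, base=2.0):
    """Independent dictionary-counting transfer entropy oracle.

    TE(x -> y) = sum p(y_{t}, y_past, x_past) log p(y_t | y_past, x_past)
    / p(y_t | y_past), estimated by naive tuple counting.
    """
    from collections import Counter
    shift = 1 if ift else 0
    joint = Counter()
    for t in range(k, len(y)):
        y_next = y[t]
        y_past = tuple(y[t - k:t])
        x_past = tuple(x[t - k + shift:t + shift])
        joint[(y_next, y_past, x_past)] += 1
    n = sum(joint.values())
    c_yx = Counter()
    c_yy = Counter()
    c_y = Counter()
    for (y_next, y_past, x_past), c in joint.items():
        c_yx[(y_past, x_past)] += c
        c_yy[(y_next, y_past)] += c
        c_y[y_past] += c
    te = 0.0
    for (y_next, y_past, x_past), c in joint.items():
        p_num = c / c_yx[(y_past, x_past)]
        p_den = c_yy[(y_next, y_past)] / c_y[y_past]
        te += (c / n) * np.log(p_num / p_den) / np.log(base)
    return te


def no_mask(n_samples):
    return np.ones(n_samples + 1, dtype=bool)


class TestDifferenceFilter:
    def test_constant_trace_all_zero(self):
        out = difference_filter(np.full((50, 3), 2.5))
        assert out.shape == (49, 3)
        assert np.all(out == 0)

    def test_linear_ramp_constant_slope(self):
        t = np.arange(30)[:, None] * 0.7
        assert np.allclose(difference_filter(t), 0.7)

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            difference_filter(np.ones((1, 4)))


class TestOptimalThreshold:
    def test_symmetric_mixture_gives_half_amplitude(self):
        assert optimal_binarization_threshold(0.03, 0.1, 0.5) == pytest.approx(0.05)

    def test_vanishing_noise_limit(self):
        assert optimal_binarization_threshold(1e-9, 0.1, 0.01) == pytest.approx(
            0.05, abs=1e-6)

    def test_matches_grid_search_maximizer(self):
        """The closed form must equal the argmax of the correct-mapping
        probability (1-p) Phi(x/sigma) + p (1 - Phi((x - dF)/sigma))."""
        sigma, df, p = 0.03, 0.1, 0.01
        grid = np.arange(0.0, 0.2, 1e-6)
        correct = (1 - p) * norm.cdf(grid / sigma) + p * (
            1 - norm.cdf((grid - df) / sigma))
        best = grid[np.argmax(correct)]
        assert optimal_binarization_threshold(sigma, df, p) == pytest.approx(
            best, abs=2e-6)

    @pytest.mark.parametrize("sigma,df,p", [(0.05, 0.2, 0.1), (0.01, 0.05, 0.3)])
    def test_grid_search_other_regimes(self, sigma, df, p):
        grid = np.arange(-0.1, 0.4, 1e-5)
        correct = (1 - p) * norm.cdf(grid / sigma) + p * (
            1 - norm.cdf((grid - df) / sigma))
        best = grid[np.argmax(correct)]
        assert optimal_binarization_threshold(sigma, df, p) == pytest.approx(
            best, abs=2e-5)

    def test_invalid_probability(self):
        with pytest.raises(ParameterError):
            optimal_binarization_threshold(0.03, 0.1, 0.0)


class TestSymbolize:
    def test_all_below_threshold_zero(self):
        assert np.all(symbolize(np.zeros((10, 2)), 0.5) == 0)

    def test_minus_inf_threshold_all_ones(self):
        assert np.all(symbolize(np.random.default_rng(0).normal(size=(20, 2)),
                                -np.inf) == 1)

    def test_tie_maps_to_zero(self):
        assert symbolize(np.array([[0.5]]), 0.5)[0, 0] == 0

    def test_optimal_threshold_maximizes_mapping_accuracy(self, rng):
        """Planted two-Gaussian spikes: Eq-form threshold at least matches
        the accuracy of every other tested threshold."""
        sigma, df, p = 0.04, 0.12, 0.02
        n = 200_000
        spikes = rng.random(n) < p
        signal = spikes * df + rng.normal(0, sigma, n)
        thr_opt = optimal_binarization_threshold(sigma, df, p)

        def accuracy(thr):
            mapped = signal > thr
            return np.mean(mapped == spikes)

        acc_opt = accuracy(thr_opt)
        for thr in np.linspace(0.01, 0.2, 25):
            assert acc_opt >= accuracy(thr) - 2e-3


class TestConditioning:
    def make_rec(self, pop, n=4):
        values = np.tile(np.asarray(pop, float)[:, None], (1, n))
        return FluorescenceRecording(values, 0.02)

    def test_infinite_level_keeps_everything(self):
        rec = self.make_rec(np.random.default_rng(1).random(100))
        assert conditioning_mask(rec, np.inf).all()

    def test_minus_inf_level_empty(self):
        rec = self.make_rec(np.random.default_rng(1).random(100))
        assert not conditioning_mask(rec, -np.inf).any()

    def test_square_wave_mask_matches_phase(self):
        pop = np.tile([0.1, 0.1, 0.9, 0.9], 25)
        rec = self.make_rec(pop)
        mask = conditioning_mask(rec, 0.5)
        assert np.array_equal(mask, pop < 0.5)

    def test_level_selection_recovers_gaussian_mean_plus_3sd(self, rng):
        mus, sds = 0.2, 0.04
        levels = []
        for s in range(5):
            pop = np.random.default_rng(s).normal(mus, sds, 20_000)
            rec = FluorescenceRecording(pop[:, None], 0.02)
            levels.append(select_conditioning_level(rec, n_sd=3.0))
        assert np.mean(levels) == pytest.approx(mus + 3 * sds, rel=0.05)

    def test_level_falls_between_separated_modes(self, rng):
        lo = rng.normal(0.1, 0.01, 9000)
        hi = rng.normal(0.9, 0.01, 1000)
        pop = np.concatenate([lo, hi])
        rng.shuffle(pop)
        rec = FluorescenceRecording(pop[:, None], 0.02)
        level = select_conditioning_level(rec)
        assert (lo < level).mean() > 0.99  # keeps the low mode
        assert (hi > level).all()          # excludes the burst mode

    def test_constant_signal_raises(self):
        rec = self.make_rec(np.full(100, 0.3))
        with pytest.raises(ValidationError):
            select_conditioning_level(rec)


class TestGTEPair:
    def params(self, k=1, ift=False):
        return GTEParams(markov_order=k, ift_enabled=ift,
                         spike_amplitude=0.1, noise_sd=0.03,
                         firing_prob_per_frame=0.1, min_samples=10)

    def test_independent_series_near_zero(self, rng):
        x = (rng.random(100_000) < 0.5).astype(np.int8)
        y = (rng.random(100_000) < 0.5).astype(np.int8)
        score = gte_pair(x, y, None, self.params())
        assert score < 0.01

    def test_copy_process_one_bit(self, rng):
        x = (rng.random(100_000) < 0.5).astype(np.int8)
        y = np.roll(x, 1)  # y[t] = x[t-1]
        y[0] = 0
        score = gte_pair(x, y, None, self.params(k=1))
        assert score == pytest.approx(1.0, abs=0.01)

    def test_copy_process_reverse_direction_zero(self, rng):
        x = (rng.random(100_000) < 0.5).astype(np.int8)
        y = np.roll(x, 1)
        y[0] = 0
        assert gte_pair(y, x, None, self.params(k=1)) < 0.01

    def test_matches_textbook_te_on_random_instances(self, rng):
        """Exact count-level agreement with an independent implementation
        (no conditioning, IFT off)."""
        for _ in range(50):
            k = int(rng.integers(1, 3))
            n = int(rng.integers(200, 2000))
            x = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(np.int8)
            y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(np.int8)
            mine = gte_pair(x, y, None, self.params(k=k))
            ref = textbook_te(x, y, k=k)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_matches_textbook_te_with_ift(self, rng):
        for _ in range(20):
            n = 1000
            x = (rng.random(n) < 0.4).astype(np.int8)
            y = (rng.random(n) < 0.4).astype(np.int8)
            mine = gte_pair(x, y, None, self.params(k=2, ift=True))
            ref = textbook_te(x, y, k=2, ift=True)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            gte_pair(np.zeros(10, np.int8), np.zeros(11, np.int8), None,
                     self.params())

    def test_undersampling_warns(self):
        p = GTEParams(min_samples=1000)
        with pytest.warns(UserWarning):
            gte_pair(np.zeros(50, np.int8), np.zeros(50, np.int8), None, p)

    def test_scores_nonnegative(self, rng):
        for _ in range(20):
            n = 5000
            x = (rng.random(n) < 0.3).astype(np.int8)
            y = (rng.random(n) < 0.3).astype(np.int8)
            assert gte_pair(x, y, None, self.params(k=2)) >= 0


class TestGTEMatrix:
    def test_copy_chain_recovered(self):
        bundle = make_fixture("copy-chain", seed=0)
        scores = gte_matrix(bundle["recording"], bundle["gte_params"])
        n = scores.n_neurons
        truth = bundle["adjacency"]
        # every chain link must outscore every non-link
        offdiag = ~np.eye(n, dtype=bool)
        link_scores = scores.scores[truth.astype(bool)]
        non_scores = scores.scores[offdiag & ~truth.astype(bool)]
        assert link_scores.min() > non_scores.max()

    def test_permutation_equivariance(self, rng):
        bundle = make_fixture("copy-chain", seed=1)
        rec = bundle["recording"]
        params = bundle["gte_params"]
        perm = rng.permutation(rec.n_neurons)
        rec_p = FluorescenceRecording(rec.values[:, perm], rec.frame_interval)
        s = gte_matrix(rec, params).scores
        s_p = gte_matrix(rec_p, params).scores
        assert np.allclose(s[np.ix_(perm, perm)], s_p, equal_nan=True)

    def test_time_shuffling_destroys_scores(self, rng):
        bundle = make_fixture("copy-chain", seed=2)
        rec = bundle["recording"]
        shuffled = rec.values.copy()
        for i in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, i])
        rec_s = FluorescenceRecording(shuffled, rec.frame_interval)
        s = gte_matrix(rec_s, bundle["gte_params"]).scores
        offdiag = ~np.eye(rec.n_neurons, dtype=bool)
        # plug-in bias only: well below the 1-bit copy signal
        assert np.nanmax(s[offdiag]) < 0.05

    def test_conditioning_above_signal_range_equals_unconditioned(self):
        bundle = make_fixture("copy-chain", seed=3)
        rec = bundle["recording"]
        params = bundle["gte_params"]
        finite_high = float(rec.population_average.max()) + 1.0
        p_hi = dataclasses.replace(params, conditioning_level=finite_high)
        p_inf = dataclasses.replace(params, conditioning_level=np.inf)
        s1 = gte_matrix(rec, p_hi).scores
        s2 = gte_matrix(rec, p_inf).scores
        assert np.allclose(s1, s2, equal_nan=True)


class TestThresholdInflationRobustness:
    def test_chain_ranking_survives_30_percent_threshold_inflation(self):
        """Raising the binarization threshold up to 30% above the optimal
        separation value must not destroy the reconstruction ranking."""
        import dataclasses
        bundle = make_fixture("copy-chain", seed=7)
        params = bundle["gte_params"]
        truth = bundle["adjacency"].astype(bool)
        n = truth.shape[0]
        offdiag = ~np.eye(n, dtype=bool)
        base_thr = params.threshold()
        for factor in (1.0, 1.15, 1.30):
            p = dataclasses.replace(params,
                                    binarization_threshold=base_thr * factor)
            scores = gte_matrix(bundle["recording"], p).scores
            assert scores[truth].min() > scores[offdiag & ~truth].max()
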