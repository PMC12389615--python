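import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nppkit import opgd, synth
from nppkit.opgd import (
    StratifiedSample,
    discretize,
    factor_detector,
    interaction_detector,
    jenks_breaks,
    optimize_discretization,
    q_significance,
    q_statistic,
    sample_at_scale,
    select_scale,
)
from nppkit.raster import GridError
from nppkit.synth import ScenarioConfig

from conftest import make_grid


def _brute_force_q(y, labels):
    """Independent oracle: 1 - SSW/SST via plain group-by loops."""
    y = np.asarray(y, dtype=float)
    sst = ((y - y.mean()) ** 2).sum()
    ssw = 0.0
    for lab in set(labels.tolist()):
        grp = y[labels == lab]
        ssw += ((grp - grp.mean()) ** 2).sum()
    return 1 - ssw / sst


class TestQStatistic:
    def test_single_stratum_zero(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        assert q_statistic(StratifiedSample(y, np.zeros(50, dtype=int))) == pytest.approx(0.0)

    def test_perfect_stratification_one(self):
        y = np.repeat([1.0, 5.0, 9.0], 10)
        labels = np.repeat([0, 1, 2], 10)
        assert q_statistic(StratifiedSample(y, labels)) == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(200)
        labels = rng.integers(0, 6, 200)
        q = q_statistic(StratifiedSample(y, labels))
        assert q == pytest.approx(_brute_force_q(y, labels), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(GridError):
            q_statistic(StratifiedSample(np.ones(10), np.arange(10) % 2))

    @given(st.integers(0, 2**31), st.floats(0.1, 100), st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(80)
        labels = rng.integers(0, 4, 80)
        q1 = q_statistic(StratifiedSample(y, labels))
        q2 = q_statistic(StratifiedSample(a * y + b, labels))
        assert q1 == pytest.approx(q2, abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(100)
        labels = rng.integers(0, 5, 100)
        q1 = q_statistic(StratifiedSample(y, labels))
        q2 = q_statistic(StratifiedSample(y, 99 - labels))
        assert q1 == pytest.approx(q2)

    def test_exact_variance_decomposition(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(150)
        labels = rng.integers(0, 5, 150)
        q, ssw, sst, n, l = opgd.q_decomposition(StratifiedSample(y, labels))
        ssb = sst - ssw
        assert q == pytest.approx(ssb / sst, abs=1e-10)


class TestQSignificance:
    def test_q_zero_p_one(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(100)
        sample = StratifiedSample(y, np.zeros(100, dtype=int))
        assert q_significance(sample) == pytest.approx(1.0)

    def test_p_decreases_with_q(self):
        rng = np.random.default_rng(5)
        n = 300
        labels = np.repeat(np.arange(3), n // 3)
        ps = []
        for effect in (0.0, 0.5, 1.5):
            y = rng.standard_normal(n) + effect * labels
            # central mode: p is a monotone function of q at fixed (N, L);
            # the noncentral mode estimates its noncentrality from the same
            # data and is deliberately conservative
            ps.append(q_significance(StratifiedSample(y, labels), mode="central"))
        assert ps[0] > ps[1] > ps[2]

    def test_null_expectation(self):
        # E[q] under independence is (L-1)/(N-1)
        rng = np.random.default_rng(6)
        qs = [q_statistic(StratifiedSample(rng.standard_normal(200),
                                           rng.integers(0, 5, 200)))
              for _ in range(300)]
        assert np.mean(qs) == pytest.approx(4 / 199, abs=0.005)


class TestDiscretize:
    def test_equal_interval_edges(self):
        x = np.linspace(0, 10, 101)
        _, edges = discretize(x, "equal_interval", 5)
        np.testing.assert_allclose(edges, [0, 2, 4, 6, 8, 10], atol=1e-12)

    def test_quantile_balanced(self):
        x = np.arange(100, dtype=float)
        labels, _ = discretize(x, "quantile", 4)
        counts = np.bincount(labels)
        assert counts.tolist() == [25, 25, 25, 25]

    def test_natural_breaks_two_clusters(self):
        x = np.array([1.0, 1.0, 1.0, 9.0, 9.0, 9.0])
        labels, edges = discretize(x, "natural_breaks", 2)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]
        assert 1.0 < edges[1] < 9.0

    def test_jenks_matches_exhaustive_split(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 10, 30))
        edges = jenks_breaks(x, 2)
        # exhaustive search over all single split points
        best_cost, best_split = np.inf, None
        for s in range(1, len(x)):
            cost = x[:s].var() * s + x[s:].var() * (len(x) - s)
            if cost < best_cost:
                best_cost, best_split = cost, s
        labels = (x >= edges[1]).astype(int)
        assert labels.sum() == len(x) - best_split

    def test_geometric_interval_spans_range(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(3, 50, 200)
        _, edges = discretize(x, "geometric_interval", 5)
        assert edges[0] == pytest.approx(x.min())
        assert edges[-1] == pytest.approx(x.max())
        widths = np.diff(edges)
        ratios = widths[1:] / widths[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-6)

    def test_std_dev_edges(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(500)
        _, edges = discretize(x, "std_dev", 4)
        internal = edges[1:-1]
        np.testing.assert_allclose(internal, [x.mean() - x.std(), x.mean(), x.mean() + x.std()],
                                   atol=1e-9)

    def test_constant_input_single_stratum(self):
        labels, _ = discretize(np.ones(10), "quantile", 4)
        assert set(labels) == {0}

    def test_k_below_two_rejected(self):
        with pytest.raises(GridError):
            discretize(np.arange(10.0), "quantile", 1)


class TestOptimizeDiscretization:
    def test_step_function_recovered(self):
        # three tight clusters in x, y constant per cluster: every method with
        # k = 3 separates them exactly, so the fewer-bins tie-break wins
        rng = np.random.default_rng(10)
        centers = rng.choice([1.0, 5.0, 9.0], 600)
        x = centers + rng.uniform(-0.3, 0.3, 600)
        y = centers * 10.0
        method, k, q = optimize_discretization(y, x)
        assert k == 3
        assert q == pytest.approx(1.0, abs=1e-9)

    def test_independent_tie_breaks_to_smallest_k(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 400)
        y = rng.standard_normal(400)
        method, k, q = optimize_discretization(y, x)
        assert q < 0.1

    def test_returned_q_consistent(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, 300)
        y = x + rng.standard_normal(300)
        method, k, q = optimize_discretization(y, x)
        labels, _ = discretize(x, method, k)
        assert q == pytest.approx(q_statistic(StratifiedSample(y, labels)), abs=1e-12)


class TestScaleSelection:
    def test_single_scale_returned(self):
        cfg = ScenarioConfig(shape=(48, 48), seed=14)
        static = synth.generate_static_layers(cfg)
        _, base = synth.response_base_field(cfg)
        response = cfg.grid(base.astype(np.float32))
        factors = {"vegtype": (static["vegtype"], "categorical"),
                   "elevation": (static["elevation"], "continuous")}
        best, table = select_scale(response, factors, [4.0], cfg.pixel_size_m)
        assert best == 4.0

    def test_injected_scale_recovered(self):
        cfg = ScenarioConfig(shape=(120, 120), seed=15, strata_q_target=0.6, strata_block=8)
        static = synth.generate_static_layers(cfg)
        _, base = synth.response_base_field(cfg)
        response = cfg.grid(base.astype(np.float32))
        factors = {"vegtype": (static["vegtype"], "categorical"),
                   "elevation": (static["elevation"], "continuous"),
                   "soil_moisture": (static["soil_moisture"], "continuous")}
        best, _ = select_scale(response, factors, [3, 4, 5, 6, 8, 10], cfg.pixel_size_m)
        assert best == 4.0  # strata injected on 8-pixel (4 km) blocks

    def test_fewer_than_two_factors_rejected(self):
        cfg = ScenarioConfig(shape=(24, 24), seed=16)
        _, base = synth.response_base_field(cfg)
        response = cfg.grid(base.astype(np.float32))
        with pytest.raises(GridError):
            select_scale(response, {"one": (response, "continuous")}, [3, 4], 500.0)


class TestFactorDetector:
    def test_exact_copy_q_one(self):
        rng = np.random.default_rng(17)
        labels = rng.integers(0, 4, 500)
        y = labels * 10.0
        table = pd.DataFrame({"y": y, "f": labels})
        results, _ = factor_detector(table, {"f": "categorical"})
        assert results[0].q == pytest.approx(1.0)

    def test_noise_factor_low_q(self):
        rng = np.random.default_rng(18)
        table = pd.DataFrame({"y": rng.standard_normal(2000),
                              "noise": rng.uniform(0, 1, 2000)})
        results, _ = factor_detector(table, {"noise": "continuous"})
        assert results[0].q < 0.05

    def test_sorted_descending(self):
        rng = np.random.default_rng(19)
        labels = rng.integers(0, 4, 500)
        y = labels * 5.0 + rng.standard_normal(500)
        table = pd.DataFrame({"y": y, "good": labels, "noise": rng.uniform(0, 1, 500)})
        results, _ = factor_detector(table, {"good": "categorical", "noise": "continuous"})
        assert results[0].factor == "good"
        assert results[0].q >= results[1].q


class TestInteraction:
    def test_trivial_partition_identity(self):
        rng = np.random.default_rng(20)
        la = rng.integers(0, 4, 300)
        y = la * 2.0 + rng.standard_normal(300)
        lb = np.zeros(300, dtype=int)  # single stratum
        res = interaction_detector(y, la, lb)
        assert res.q12 == pytest.approx(res.q1, abs=1e-12)

    def test_additive_independent_factors(self):
        rng = np.random.default_rng(21)
        n = 4000
        la = rng.integers(0, 3, n)
        lb = rng.integers(0, 3, n)
        y = la * 1.0 + lb * 1.0 + rng.standard_normal(n) * 0.3
        res = interaction_detector(y, la, lb)
        assert res.q12 == pytest.approx(res.q1 + res.q2, abs=0.05)
        assert res.category in {"independent", "nonlinear_enhance", "bifactor_enhance"}

    def test_nonlinear_enhance_detected(self):
        rng = np.random.default_rng(22)
        n = 2000
        la = rng.integers(0, 2, n)
        lb = rng.integers(0, 2, n)
        y = (la ^ lb) * 10.0 + rng.standard_normal(n) * 0.1  # pure interaction
        res = interaction_detector(y, la, lb)
        assert res.category == "nonlinear_enhance"
        assert res.q12 > res.q1 + res.q2

    def test_refinement_monotonicity(self):
        rng = np.random.default_rng(23)
        violations = 0
        for _ in range(100):
            n = 300
            la = rng.integers(0, 3, n)
            lb = rng.integers(0, 3, n)
            # ensure no stratum (marginal or crossed) is dropped
            cross = la * 3 + lb
            if np.bincount(cross, minlength=9).min() < 2:
                continue
            y = rng.standard_normal(n) + 0.5 * la
            res = interaction_detector(y, la, lb)
            if res.q12 < max(res.q1, res.q2) - 1e-12:
                violations += 1
        assert violations == 0

    def test_singleton_cross_rejected(self):
        # marginal strata are fine but every crossed stratum is a singleton
        y = np.arange(6, dtype=float)
        la = np.array([0, 0, 0, 1, 1, 1])
        lb = np.array([0, 1, 2, 0, 1, 2])
        with pytest.raises(GridError, match="coarser"):
            interaction_detector(y, la, lb)
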