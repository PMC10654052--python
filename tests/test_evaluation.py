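"""Bhattacharyya pseudo-R², per-class R², cross-validation schemes and
semivariograms, checked against hand calculations and an independent
brute-force arithmetic path."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leaftypes as lt
from tests.conftest import make_plot


def brute_force_r2_bc(observed, predicted):
    """Independent evaluation of the pseudo-R² with scalar arithmetic only
    (no vectorization shared with the implementation)."""
    n = len(observed)
    e_model, e_mean = [], []
    mean = [sum(o[k] for o in observed) / n for k in range(4)]
    for o, p in zip(observed, predicted):
        bc = sum(math.sqrt(o[k] * p[k]) for k in range(4))
        e_model.append(1 - bc)
        bc_mean = sum(math.sqrt(o[k] * mean[k]) for k in range(4))
        e_mean.append(1 - bc_mean)
    mae_model = sum(e_model) / n
    mae_mean = sum(e_mean) / n
    return 1 - mae_model / mae_mean


comp_strategy = st.lists(st.floats(min_value=1e-6, max_value=1), min_size=4, max_size=4).map(
    lambda v: [x / sum(v) for x in v]
)


class TestBhattacharyya:
    @pytest.mark.parametrize("o,p,expected", [
        ([1, 0, 0, 0], [1, 0, 0, 0], 1.0),
        ([1, 0, 0, 0], [0, 1, 0, 0], 0.0),
        ([0.5, 0.5, 0, 0], [0.25, 0.75, 0, 0], math.sqrt(0.125) + math.sqrt(0.375)),
    ])
    def test_known_values(self, o, p, expected):
        assert lt.bhattacharyya(o, p) == pytest.approx(expected, abs=1e-12)

    @given(comp_strategy, comp_strategy)
    @settings(max_examples=50, deadline=None)
    def test_symmetry_bounds_identity(self, o, p):
        bc = lt.bhattacharyya(o, p)
        assert 0 <= bc <= 1
        assert bc == pytest.approx(lt.bhattacharyya(p, o), abs=1e-12)
        assert lt.bhattacharyya(o, o) == pytest.approx(1.0, abs=1e-9)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            lt.bhattacharyya([-0.1, 0.6, 0.25, 0.25], [0.25] * 4)


class TestPseudoR2:
    def test_perfect_prediction_is_one(self):
        obs = np.array([[0.7, 0.1, 0.1, 0.1], [0.2, 0.3, 0.4, 0.1], [0.25, 0.25, 0.25, 0.25]])
        rep = lt.pseudo_r2(obs, obs)
        assert rep.r2_bc == pytest.approx(1.0, abs=1e-12)
        assert rep.mae_model == pytest.approx(0.0, abs=1e-12)

    def test_mean_prediction_is_zero(self):
        obs = np.array([[0.6, 0.2, 0.1, 0.1], [0.1, 0.5, 0.2, 0.2], [0.3, 0.3, 0.2, 0.2]])
        mean = np.tile(obs.mean(axis=0), (3, 1))
        assert lt.pseudo_r2(obs, mean).r2_bc == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_two_observation_case(self):
        obs = [[1, 0, 0, 0], [0, 1, 0, 0]]
        pred = [[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0]]
        rep = lt.pseudo_r2(obs, pred)
        assert rep.mae_model == pytest.approx(1 - math.sqrt(0.5), abs=1e-12)
        assert rep.mae_mean == pytest.approx(1 - math.sqrt(0.5), abs=1e-12)
        assert rep.r2_bc == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_agrees_with_brute_force_oracle(self, n):
        rng = np.random.default_rng(42 + n)
        obs = rng.dirichlet(np.ones(4), size=n)
        pred = rng.dirichlet(np.ones(4), size=n)
        got = lt.pseudo_r2(obs, pred).r2_bc
        want = brute_force_r2_bc(obs.tolist(), pred.tolist())
        assert got == pytest.approx(want, abs=1e-12)

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        obs = rng.dirichlet(np.ones(4), size=8)
        pred = rng.dirichlet(np.ones(4), size=8)
        perm = rng.permutation(8)
        assert lt.pseudo_r2(obs, pred).r2_bc == pytest.approx(
            lt.pseudo_r2(obs[perm], pred[perm]).r2_bc, abs=1e-12)

    def test_too_few_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            lt.pseudo_r2([[1, 0, 0, 0]], [[1, 0, 0, 0]])
        with pytest.raises(ValueError):
            lt.pseudo_r2([[1, 0, 0, 0]] * 3, [[1, 0, 0, 0]] * 2)


class TestPerClassR2:
    def test_perfect_and_constant(self):
        obs = np.array([[0.2, 0.8, 0, 0], [0.6, 0.4, 0, 0]])
        assert lt.per_class_r2(obs, obs, 0) == pytest.approx(1.0)
        const = np.tile(obs[:, :].mean(axis=0), (2, 1))
        assert lt.per_class_r2(obs, const, 0) == pytest.approx(0.0)

    def test_hand_sse_sst(self):
        obs = np.array([[0, 1, 0, 0], [1, 0, 0, 0]])
        pred = np.array([[0.25, 0.75, 0, 0], [0.75, 0.25, 0, 0]])
        # class 0: obs (0,1), pred (0.25,0.75): SSE=0.125, SST=0.5
        assert lt.per_class_r2(obs, pred, 0) == pytest.approx(0.75)

    def test_zero_variance_flagged_nan(self):
        obs = np.array([[0.5, 0.5, 0, 0]] * 3)
        assert math.isnan(lt.per_class_r2(obs, obs, 2))


def mean_model_factory(train_plots, train_obs):
    mean = np.asarray(train_obs).mean(axis=0)
    return lambda test_plots: np.tile(mean, (len(test_plots), 1))


class TestKFoldCV:
    def _plots_obs(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        plots = [make_plot([("BE", 20.0)] * 10, plot_id=f"p{i}",
                           lat=float(rng.uniform(-10, 10)), lon=float(rng.uniform(-10, 10)))
                 for i in range(n)]
        obs = rng.dirichlet(np.ones(4), size=n)
        return plots, obs

    def test_folds_partition_plots(self):
        folds = lt.evaluation.assign_folds(23, 10, seed=1)
        assert len(folds) == 23
        assert set(folds) == set(range(10))

    def test_mean_model_scores_near_zero(self):
        plots, obs = self._plots_obs(50, seed=3)
        rep = lt.kfold_cv(plots, obs, mean_model_factory, k=10, seed=5)
        assert abs(rep.r2_bc) < 0.1  # null model: no skill beyond the mean

    def test_deterministic_given_seed(self):
        plots, obs = self._plots_obs(30, seed=2)
        r1 = lt.kfold_cv(plots, obs, mean_model_factory, k=5, seed=9)
        r2 = lt.kfold_cv(plots, obs, mean_model_factory, k=5, seed=9)
        assert r1.r2_bc == r2.r2_bc

    def test_k_below_two_rejected(self):
        plots, obs = self._plots_obs(10)
        with pytest.raises(ValueError):
            lt.kfold_cv(plots, obs, mean_model_factory, k=1)


class TestHaversineAndBufferedLOO:
    def test_one_degree_longitude_at_equator(self):
        assert lt.haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_buffer_radius_gates_training_set(self):
        """Two plots 111.19 km apart: excluded from each other's training
        set at radius 120 km but not at radius 100 km."""
        seen = {}

        def recording_factory(train_plots, train_obs):
            recording_factory.train_sizes.append(len(train_plots))
            mean = np.asarray(train_obs).mean(axis=0)
            return lambda tp: np.tile(mean, (len(tp), 1))

        plots = [make_plot([("BE", 20.0)] * 10, plot_id="a", lat=0, lon=0),
                 make_plot([("BD", 20.0)] * 10, plot_id="b", lat=0, lon=1),
                 make_plot([("NE", 20.0)] * 10, plot_id="c", lat=0, lon=5)]
        obs = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], dtype=float)

        recording_factory.train_sizes = []
        lt.buffered_loo_cv(plots, obs, recording_factory, radius_km=100)
        sizes_100 = list(recording_factory.train_sizes)

        recording_factory.train_sizes = []
        lt.buffered_loo_cv(plots, obs, recording_factory, radius_km=120)
        sizes_120 = list(recording_factory.train_sizes)

        # at 100 km the 111.19 km neighbour is training data; at 120 km it is not
        assert sizes_100[0] == 2 and sizes_120[0] == 1

    def test_radius_zero_is_classic_loo(self):
        rng = np.random.default_rng(1)
        plots = [make_plot([("BE", 20.0)] * 10, plot_id=f"p{i}",
                           lat=float(rng.uniform(-30, 30)), lon=float(rng.uniform(-30, 30)))
                 for i in range(8)]
        obs = rng.dirichlet(np.ones(4), size=8)

        sizes = []

        def factory(train_plots, train_obs):
            sizes.append(len(train_plots))
            return mean_model_factory(train_plots, train_obs)

        rep = lt.buffered_loo_cv(plots, obs, factory, radius_km=0)
        assert sizes == [7] * 8  # only the focal plot left out
        assert rep.r2_bc <= 1

    def test_all_excluded_plot_skipped(self, caplog):
        # a and b are ~1112 km apart; c sits ~556 km from each, so at a
        # 600 km buffer c has no admissible training data and is skipped
        plots = [make_plot([("BE", 20.0)] * 10, plot_id="a", lat=0, lon=0),
                 make_plot([("BD", 20.0)] * 10, plot_id="b", lat=0, lon=10),
                 make_plot([("NE", 20.0)] * 10, plot_id="c", lat=0, lon=5)]
        obs = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], dtype=float)
        rep = lt.buffered_loo_cv(plots, obs, mean_model_factory, radius_km=600)
        assert rep.n_obs == 2  # the isolated plot was skipped


class TestSemivariogram:
    def test_identical_residuals_give_zero(self):
        res = np.ones((10, 4))
        lats = np.linspace(0, 5, 10)
        lons = np.zeros(10)
        out = lt.empirical_semivariogram(res, lats, lons, [0, 200, 400, 800])
        filled = out["semivariance"].dropna()
        assert (filled == 0).all()

    def test_two_point_hand_value(self):
        out = lt.empirical_semivariogram([0.0, 2.0], [0, 0], [0, 1], [0, 200])
        assert out["semivariance"].iloc[0] == pytest.approx(2.0)
        assert out["n_pairs"].iloc[0] == 1

    def test_white_noise_is_flat_at_sigma2(self):
        rng = np.random.default_rng(8)
        n, sigma = 400, 0.5
        res = rng.normal(0, sigma, size=(n, 1))
        lats = rng.uniform(-5, 5, n)
        lons = rng.uniform(-5, 5, n)
        out = lt.empirical_semivariogram(res, lats, lons, [0, 300, 600, 900, 1200])
        vals = out["semivariance"].dropna()
        assert np.all(np.abs(vals - sigma**2) < 0.05)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            lt.empirical_semivariogram([1.0], [0], [0], [0, 100])


def test_report_invariant_enforced():
    with pytest.raises(ValueError):
        lt.EvaluationReport(r2_bc=0.9, mae_model=0.5, mae_mean=0.5)
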