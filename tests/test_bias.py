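"""Adaptive bias potential: energies, forces, ladder scaling, refits."""

import warnings

import numpy as np
import pytest

from ahremd.bias import BiasState, bias_energy, bias_forces, update_bias
from ahremd.gmm import GMMModel

STD_PEAK = 1 / np.sqrt(2 * np.pi)


def unit_model(mu=0.0, sigma=1.0):
    return GMMModel(weights=[1.0], means=[mu], widths=[sigma])


class TestBiasEnergy:
    def test_reference_replica_is_always_unbiased(self):
        b = BiasState(replica_index=1, increment=4.0,
                      models={"CV_1": unit_model()}, interval_index=5)
        assert bias_energy(b, {"CV_1": 0.0}) == 0.0

    def test_closed_form_peak_value(self):
        """r=2, increment 4, standard-normal model, x at the mean:
        4 * 0.3989423."""
        b = BiasState(replica_index=2, increment=4.0,
                      models={"CV_1": unit_model()}, interval_index=1)
        assert bias_energy(b, {"CV_1": 0.0}) == pytest.approx(1.5957691, abs=1e-6)

    def test_ladder_scaling_ratio(self):
        models = {"CV_1": unit_model(0.5, 0.8)}
        b2 = BiasState(replica_index=2, increment=4.0, models=models,
                       interval_index=1)
        b8 = BiasState(replica_index=8, increment=4.0, models=models,
                       interval_index=1)
        for x in (0.0, 0.5, 2.0):
            assert bias_energy(b8, {"CV_1": x}) == pytest.approx(
                7.0 * bias_energy(b2, {"CV_1": x}))

    def test_additive_over_cvs(self):
        ma, mb = unit_model(0.0, 1.0), unit_model(3.0, 0.5)
        both = BiasState(replica_index=3, increment=2.0,
                         models={"A": ma, "B": mb}, interval_index=1)
        only_a = BiasState(replica_index=3, increment=2.0, models={"A": ma},
                           interval_index=1)
        only_b = BiasState(replica_index=3, increment=2.0, models={"B": mb},
                           interval_index=1)
        assert bias_energy(both, {"A": 0.3, "B": 2.5}) == pytest.approx(
            bias_energy(only_a, {"A": 0.3}) + bias_energy(only_b, {"B": 2.5}))

    def test_nonnegative_everywhere(self):
        b = BiasState(replica_index=5, increment=4.0,
                      models={"CV_1": unit_model(1.0, 0.3)}, interval_index=2)
        xs = np.linspace(-5, 5, 101)
        assert all(bias_energy(b, {"CV_1": float(x)}) >= 0.0 for x in xs)

    def test_missing_model_after_first_interval_fails(self):
        b = BiasState(replica_index=2, increment=4.0, models={}, interval_index=2)
        with pytest.raises(ValueError, match="no bias models"):
            bias_energy(b, {"CV_1": 0.0})
        assert bias_energy(
            BiasState(replica_index=2, increment=4.0, interval_index=0),
            {"CV_1": 0.0}) == 0.0

    def test_serialization_round_trip(self):
        b = BiasState(replica_index=4, increment=4.0,
                      models={"CV_1": unit_model(0.2, 0.9)}, interval_index=7)
        b2 = BiasState.from_dict(b.to_dict())
        assert b2.replica_index == 4 and b2.interval_index == 7
        assert bias_energy(b2, {"CV_1": 0.4}) == pytest.approx(
            bias_energy(b, {"CV_1": 0.4}))


class TestBiasForces:
    def test_reference_replica_zero_force(self, bead_spec, bead_cvs):
        b = BiasState(replica_index=1, increment=4.0,
                      models={cv.name: unit_model(4.0, 1.0) for cv in bead_cvs},
                      interval_index=1)
        f = bias_forces(b, bead_spec.initial_coordinates, bead_cvs)
        assert np.all(f == 0.0)

    def test_pushes_away_from_density_peak_in_1d(self):
        """With the model peak left of the particle, -dp/dx > 0 there: the
        bias force pushes further away from the peak."""
        from _helpers import origin_cv

        cv = origin_cv()
        b = BiasState(replica_index=2, increment=4.0,
                      models={"CV_1": unit_model(0.5, 0.2)}, interval_index=1)
        coords = np.array([[0.9]])  # right of the peak at |x| = 0.5
        f = bias_forces(b, coords, [cv])
        assert f[0, 0] > 0.0
        coords = np.array([[0.2]])  # left of the peak
        f = bias_forces(b, coords, [cv])
        assert f[0, 0] < 0.0

    def test_matches_finite_difference_of_energy(self, bead_spec, bead_cvs):
        from ahremd.cv import compute_cv

        rng = np.random.default_rng(0)
        models = {cv.name: GMMModel(weights=[0.6, 0.4], means=[4.0, 7.5],
                                    widths=[0.8, 1.2]) for cv in bead_cvs}
        b = BiasState(replica_index=3, increment=4.0, models=models,
                      interval_index=1)
        for _ in range(10):
            coords = bead_spec.initial_coordinates + 0.3 * rng.standard_normal(
                bead_spec.initial_coordinates.shape)
            f = bias_forces(b, coords, bead_cvs)

            def energy(c):
                return bias_energy(b, {cv.name: compute_cv(c, cv)
                                       for cv in bead_cvs})

            h = 1e-6
            fd = np.zeros_like(coords)
            for i in range(coords.shape[0]):
                for d in range(coords.shape[1]):
                    cp, cm = coords.copy(), coords.copy()
                    cp[i, d] += h
                    cm[i, d] -= h
                    fd[i, d] = -(energy(cp) - energy(cm)) / (2 * h)
            scale = np.abs(f).max()
            np.testing.assert_allclose(f, fd, atol=max(scale, 1e-3) * 1e-5)


class TestUpdateBias:
    def _history(self, rng, n_intervals=3, per_interval=200, loc=4.0):
        return {"CV_1": [rng.normal(loc, 0.4, per_interval)
                         for _ in range(n_intervals)]}

    def test_first_update_activates_replicas_2_plus(self, bead_cvs):
        rng = np.random.default_rng(1)
        history = {cv.name: [rng.normal(5.0, 0.5, 300)] for cv in bead_cvs}
        states = update_bias(history, bead_cvs, n_replicas=4, seed=0,
                             interval_index=1)
        assert len(states) == 4
        vals = {cv.name: 5.0 for cv in bead_cvs}
        assert bias_energy(states[0], vals) == 0.0
        assert all(bias_energy(s, vals) > 0.0 for s in states[1:])

    def test_bias_peaks_where_sampling_concentrated(self):
        from _helpers import origin_cv

        cv = origin_cv()
        rng = np.random.default_rng(2)
        history = {"CV_1": [rng.normal(4.0, 0.3, 500)]}
        states = update_bias(history, [cv], n_replicas=2, seed=0)
        model = states[1].models["CV_1"]
        # mixture mean equals the pooled sample mean; density mode sits there
        from ahremd.gmm import gmm_density
        mix_mean = float(np.dot(model.weights, model.means))
        assert mix_mean == pytest.approx(history["CV_1"][0].mean(), abs=1e-6)
        grid = np.linspace(2, 6, 801)
        mode = grid[np.argmax(gmm_density(model, grid))]
        assert mode == pytest.approx(4.0, abs=0.15)

    def test_sliding_window_drops_old_samples(self):
        from _helpers import origin_cv

        cv = origin_cv()
        rng = np.random.default_rng(3)
        old = [rng.normal(-3.0, 0.2, 200) for _ in range(4)]
        recent = [rng.normal(4.0, 0.3, 200) for _ in range(10)]
        full = update_bias({"CV_1": old + recent}, [cv], n_replicas=2, seed=5,
                           window=10)
        trunc = update_bias({"CV_1": recent}, [cv], n_replicas=2, seed=5,
                            window=10)
        np.testing.assert_array_equal(full[1].models["CV_1"].means,
                                      trunc[1].models["CV_1"].means)

    def test_insufficient_samples_keeps_previous_model(self):
        from _helpers import origin_cv

        cv = origin_cv()
        rng = np.random.default_rng(4)
        prev = update_bias({"CV_1": [rng.normal(4.0, 0.3, 300)]}, [cv],
                           n_replicas=2, seed=0, interval_index=1)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            nxt = update_bias({"CV_1": [np.array([1.0, 2.0])]}, [cv],
                              n_replicas=2, seed=0, previous=prev,
                              interval_index=2)
        assert any("retaining previous model" in str(w.message) for w in rec)
        np.testing.assert_array_equal(nxt[1].models["CV_1"].means,
                                      prev[1].models["CV_1"].means)

    def test_without_previous_model_insufficient_samples_fail(self):
        from _helpers import origin_cv

        with pytest.raises(ValueError, match="cannot build bias"):
            update_bias({"CV_1": [np.array([1.0])]}, [origin_cv()], n_replicas=2,
                        seed=0)
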