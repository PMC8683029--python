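"""Toy systems and the Langevin propagator: closed forms, Boltzmann fidelity,
reproducibility."""

import numpy as np
import pytest
from scipy import stats

from ahremd import (Frame, boltzmann_cdf, langevin_step, make_domain_bead_model,
                    make_double_well, make_harmonic, make_muller_brown, simulate)
from ahremd.analysis import integrated_autocorrelation_time


def decorrelate(x, n_max=None):
    tau = integrated_autocorrelation_time(x)
    sub = x[:: max(1, int(np.ceil(tau)))]
    return sub if n_max is None else sub[:n_max]


class TestDoubleWell:
    @pytest.mark.parametrize("x,expected", [(0.0, 6.0), (1.0, 0.0), (-1.0, 0.0),
                                            (2.0, 54.0)])
    def test_quartic_closed_form(self, x, expected):
        spec = make_double_well(6.0, 1.0)
        assert spec.potential.energy(np.array([[[x]]]))[0] == pytest.approx(expected)

    def test_force_vanishes_at_minima_and_barrier_top(self):
        spec = make_double_well(6.0, 1.0)
        for x in (-1.0, 0.0, 1.0):
            f = spec.potential.forces(np.array([[[x]]]))
            assert f[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("h,a", [(-1.0, 1.0), (6.0, 0.0), (0.0, 1.0)])
    def test_rejects_nonpositive_parameters(self, h, a):
        with pytest.raises(ValueError):
            make_double_well(h, a)


class TestLangevin:
    def test_harmonic_equipartition(self):
        """Long-run positional variance of the kT=1, k=1 harmonic well is 1."""
        spec = make_harmonic(k=1.0)
        x = simulate(spec, 400_000, seed=3, save_period=10)[:, 0, 0]
        tau = integrated_autocorrelation_time(x)
        n_eff = len(x) / tau
        se = np.sqrt(2.0 / n_eff)  # SE of a variance estimate, relative
        assert x.var() == pytest.approx(1.0, abs=3 * se)

    def test_zero_temperature_decays_to_rest(self):
        spec = make_harmonic(k=1.0, kT=0.0)
        x0 = np.array([[2.0]])
        x = simulate(spec, 5000, seed=0, save_period=100, x0=x0)[:, 0, 0]
        assert abs(x[-1]) < 1e-3
        assert np.all(np.abs(np.diff(np.abs(x))) >= -1e-12)

    def test_double_well_symmetric_occupancy(self):
        """A 2 kT barrier is crossed often; occupancies converge to 1/2."""
        spec = make_double_well(2.0, 1.0)
        x = simulate(spec, 2_000_000, seed=5, save_period=20)[:, 0, 0]
        frac = (x > 0).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("make", [lambda: make_harmonic(k=1.0),
                                      lambda: make_double_well(2.0, 1.0)])
    def test_boltzmann_fidelity(self, make):
        """Empirical CDF of decorrelated samples matches the analytic
        Boltzmann CDF (KS p > 0.01, up to 10,000 samples)."""
        spec = make()
        x = simulate(spec, 10_000_000, seed=11, save_period=50)[:, 0, 0]
        sub = decorrelate(x[len(x) // 20:], 10_000)
        assert len(sub) >= 5_000
        cdf = boltzmann_cdf(lambda v: spec.potential.energy(v[:, None, None]),
                            spec.kT, -4.5, 4.5)
        p = stats.kstest(sub, cdf).pvalue
        assert p > 0.01

    def test_dt_halving_leaves_variance_within_error(self):
        var = {}
        err = {}
        for dt in (0.02, 0.01):
            spec = make_harmonic(k=1.0, dt=dt)
            x = simulate(spec, 600_000, seed=9, save_period=10)[:, 0, 0]
            tau = integrated_autocorrelation_time(x)
            var[dt] = x.var()
            err[dt] = np.sqrt(2.0 * tau / len(x))
        assert abs(var[0.02] - var[0.01]) < 3 * (err[0.02] + err[0.01])

    def test_bitwise_reproducibility(self):
        spec = make_double_well(6.0, 1.0)
        a = simulate(spec, 20_000, seed=42, save_period=10)
        b = simulate(spec, 20_000, seed=42, save_period=10)
        np.testing.assert_array_equal(a, b)

    def test_single_step_api_matches_block_path(self):
        """langevin_step iterated with one stream reproduces simulate()."""
        spec = make_harmonic(k=1.0)
        rng = np.random.default_rng(7)
        frame = Frame(step_index=0, coordinates=spec.initial_coordinates,
                      potential_energy=0.0)
        xs = []
        for _ in range(200):
            frame = langevin_step(frame, spec, rng=rng)
            xs.append(frame.coordinates[0, 0])
        ref = simulate(spec, 200, seed=7, save_period=1)[:, 0, 0]
        np.testing.assert_allclose(np.array(xs), ref, atol=1e-10)

    def test_nonfinite_force_is_reported(self):
        spec = make_harmonic(k=1.0)
        frame = Frame(step_index=3, coordinates=np.array([[0.5]]),
                      potential_energy=0.0)
        with pytest.raises((FloatingPointError, ValueError)):
            langevin_step(frame, spec, extra_force=np.array([[np.nan]]),
                          rng=np.random.default_rng(0))


class TestBeadModel:
    def test_counts_and_groups(self):
        spec = make_domain_bead_model(n_domains=3, beads_per_domain=4, seed=1)
        assert spec.n_particles == 12
        assert sorted(spec.groups) == ["domain_0", "domain_1", "domain_2"]
        assert all(len(v) == 4 for v in spec.groups.values())

    def test_seed_determinism(self):
        a = make_domain_bead_model(seed=5)
        b = make_domain_bead_model(seed=5)
        np.testing.assert_array_equal(a.initial_coordinates, b.initial_coordinates)
        c = make_domain_bead_model(seed=6)
        assert not np.array_equal(a.initial_coordinates, c.initial_coordinates)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_domain_bead_model(beads_per_domain=8, jitter=0.0,
                                   min_separation=1.5, seed=0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_domain_bead_model(n_domains=1)
        with pytest.raises(ValueError):
            make_domain_bead_model(beads_per_domain=1)
        with pytest.raises(ValueError):
            make_domain_bead_model(inter_domain=(4.0, 8.0, 4.0))

    def test_metastable_modes_at_both_minima(self):
        """The inter-domain double well holds the COM distance near whichever
        minimum the run starts from (metastable states at 4 and at 8)."""
        from ahremd.cv import AtomGroup, CVDefinition, compute_cv_batch

        spec = make_domain_bead_model(n_domains=2, beads_per_domain=3,
                                      inter_domain=(8.0, 4.0, 8.0), seed=2)
        i0, i1 = spec.groups["domain_0"], spec.groups["domain_1"]
        cv = CVDefinition(
            name="d",
            group_a=AtomGroup(name="A", indices=i0, masses=spec.masses[i0]),
            group_b=AtomGroup(name="B", indices=i1, masses=spec.masses[i1]),
        )
        d_closed = compute_cv_batch(simulate(spec, 40_000, seed=3, save_period=40), cv)
        assert np.median(d_closed[len(d_closed) // 2:]) == pytest.approx(4.0, abs=0.6)

        x0 = spec.initial_coordinates.copy()
        x0[i1, 0] += 4.0  # displace second domain to the open minimum
        d_open = compute_cv_batch(simulate(spec, 40_000, seed=4, save_period=40,
                                           x0=x0), cv)
        assert np.median(d_open[len(d_open) // 2:]) == pytest.approx(8.0, abs=0.6)


class TestMuellerBrown:
    def test_forces_match_finite_differences(self):
        spec = make_muller_brown()
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = np.array([[[-0.5, 1.0]]]) + 0.3 * rng.standard_normal((1, 1, 2))
            f = spec.potential.forces(x)
            h = 1e-6
            for d in range(2):
                xp, xm = x.copy(), x.copy()
                xp[0, 0, d] += h
                xm[0, 0, d] -= h
                fd = -(spec.potential.energy(xp) - spec.potential.energy(xm)) / (2 * h)
                assert f[0, 0, d] == pytest.approx(fd[0], rel=1e-5, abs=1e-8)
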