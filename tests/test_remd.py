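"""Replica-exchange orchestration: Metropolis correctness, bookkeeping,
determinism, restart."""

import numpy as np
import pytest
from scipy import stats

from _helpers import origin_cv
from ahremd import (Frame, ScheduleConfig, attempt_exchange, make_double_well,
                    run_campaign, simulate)
from ahremd.bias import BiasState
from ahremd.gmm import GMMModel
from ahremd.remd import EnsembleState, run_interval

STD_PEAK = 1 / np.sqrt(2 * np.pi)


def _frame(x):
    return Frame(step_index=0, coordinates=np.array([[x]]), potential_energy=0.0)


def _bias(r, increment=4.0, mu=0.0, sigma=1.0):
    return BiasState(replica_index=r, increment=increment,
                     models={"CV_1": GMMModel(weights=[1.0], means=[mu],
                                              widths=[sigma])},
                     interval_index=1)


class TestAttemptExchange:
    def test_identical_biases_always_accept(self):
        cv = origin_cv()
        rng = np.random.default_rng(0)
        b = _bias(1)
        for x in np.linspace(-2, 2, 20):
            rec = attempt_exchange(_frame(x), _frame(-x), b, b, [cv], 1.0, rng)
            assert rec.delta == 0.0 and rec.accepted

    def test_antisymmetry_under_swap(self):
        cv = origin_cv()
        rng = np.random.default_rng(1)
        bi, bj = _bias(2), _bias(5)
        fi, fj = _frame(0.3), _frame(1.7)
        d_fwd = attempt_exchange(fi, fj, bi, bj, [cv], 1.0, rng).delta
        d_rev = attempt_exchange(fj, fi, bi, bj, [cv], 1.0, rng).delta
        assert d_fwd == pytest.approx(-d_rev, rel=1e-12)

    def test_unit_exponent_accepts_at_inverse_e(self):
        """An engineered Delta/kT = 1 pair accepts with frequency e^-1."""
        cv = origin_cv()
        b1 = BiasState(replica_index=1, increment=0.0, interval_index=1,
                       models={"CV_1": GMMModel(weights=[1.0], means=[0.0],
                                                widths=[1.0])})
        b2 = _bias(2, increment=1.0 / STD_PEAK)
        fi, fj = _frame(0.0), _frame(40.0)  # p(0)=peak, p(40)~0
        rng = np.random.default_rng(123)
        n = 20_000
        acc = sum(attempt_exchange(fi, fj, b1, b2, [cv], 1.0, rng).accepted
                  for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) / n)
        assert acc / n == pytest.approx(p, abs=3 * sigma)
        rec = attempt_exchange(fi, fj, b1, b2, [cv], 1.0, rng)
        assert rec.delta == pytest.approx(1.0, abs=1e-9)


class TestRunInterval:
    def test_exchange_attempt_bookkeeping(self, dw_spec, dw_cvs):
        sched = ScheduleConfig(n_replicas=6, steps_per_interval=800,
                               exchange_period=80, n_intervals=1, seed=0)
        ens = EnsembleState.initialize(dw_spec, dw_cvs, sched)
        run_interval(ens, dw_spec, sched)
        # 10 sweeps alternating parity: even sweeps have 3 pairs, odd 2
        assert len(ens.exchange_log) == 5 * 3 + 5 * 2
        for rec in ens.exchange_log:
            assert rec.pair[1] == rec.pair[0] + 1

    def test_interval_zero_replicas_statistically_equivalent(self, dw_spec,
                                                             dw_cvs):
        """Before any bias exists all replicas run the same Hamiltonian."""
        sched = ScheduleConfig(n_replicas=8, steps_per_interval=20_000,
                               exchange_period=80, save_period=20,
                               n_intervals=1, seed=3)
        ens = EnsembleState.initialize(dw_spec, dw_cvs, sched)
        run_interval(ens, dw_spec, sched)
        vals = ens.cv_history["CV_1"][0]  # (n_saves, R)
        for r in (1, 4, 7):
            p = stats.ks_2samp(vals[:, 0], vals[:, r]).pvalue
            assert p > 0.01

    def test_single_replica_degenerates_to_plain_md(self, dw_spec, dw_cvs):
        sched = ScheduleConfig(n_replicas=1, steps_per_interval=4000,
                               exchange_period=100, n_intervals=3, seed=2)
        res = run_campaign(dw_spec, dw_cvs, sched)
        assert res.exchanges.empty
        assert len(res.ensemble.bias_snapshots) == 3
        assert np.isfinite(res.reference_positions).all()


class TestCampaign:
    def test_deterministic_exchange_log_and_trajectory(self, dw_spec, dw_cvs):
        sched = ScheduleConfig(n_replicas=4, steps_per_interval=2000,
                               exchange_period=100, n_intervals=4, seed=11)
        a = run_campaign(dw_spec, dw_cvs, sched)
        b = run_campaign(dw_spec, dw_cvs, sched)
        assert a.exchanges.equals(b.exchanges)
        np.testing.assert_array_equal(a.reference_positions,
                                      b.reference_positions)

    def test_restart_resumes_bitwise(self, dw_spec, dw_cvs, tmp_path):
        long = ScheduleConfig(n_replicas=4, steps_per_interval=2000,
                              exchange_period=100, n_intervals=6, seed=4)
        short = ScheduleConfig(n_replicas=4, steps_per_interval=2000,
                               exchange_period=100, n_intervals=3, seed=4)
        full = run_campaign(dw_spec, dw_cvs, long, outdir=str(tmp_path / "full"))
        run_campaign(dw_spec, dw_cvs, short, outdir=str(tmp_path / "part"))
        resumed = run_campaign(dw_spec, dw_cvs, long,
                               outdir=str(tmp_path / "part"), restart=True)
        assert resumed.exchanges.equals(full.exchanges)
        np.testing.assert_array_equal(resumed.reference_positions,
                                      full.reference_positions)

    def test_outputs_written_and_readable(self, dw_spec, dw_cvs, tmp_path):
        import pandas as pd

        from ahremd.io import read_xyz

        sched = ScheduleConfig(n_replicas=3, steps_per_interval=1600,
                               exchange_period=80, n_intervals=3, seed=6)
        run_campaign(dw_spec, dw_cvs, sched, outdir=str(tmp_path))
        hist = pd.read_csv(tmp_path / "cv_history.csv")
        assert set(hist.columns) == {"step", "interval", "replica", "CV_1"}
        assert sorted(hist["replica"].unique()) == [1, 2, 3]
        ex = pd.read_csv(tmp_path / "exchanges.csv")
        assert {"step", "replica_i", "replica_j", "delta", "accepted"} <= set(ex.columns)
        traj = read_xyz(tmp_path / "replica_1.xyz")
        assert traj.ndim == 3 and traj.shape[1] == 1
        assert len(list((tmp_path / "bias_snapshots").glob("*.json"))) == 3

    def test_reference_slot_bias_stays_zero(self, dw_spec, dw_cvs):
        sched = ScheduleConfig(n_replicas=4, steps_per_interval=2000,
                               exchange_period=100, n_intervals=3, seed=8)
        res = run_campaign(dw_spec, dw_cvs, sched)
        assert res.ensemble.biases[0].prefactor == 0.0
        assert all(b.prefactor > 0 for b in res.ensemble.biases[1:])

    def test_acceptance_decreases_with_bias_gap(self, dw_spec, dw_cvs):
        """Doubling the increment cannot raise the neighbor acceptance."""
        accs = {}
        for inc in (1.0, 8.0):
            sched = ScheduleConfig(n_replicas=4, steps_per_interval=4800,
                                   exchange_period=80, n_intervals=8, seed=13,
                                   increment=inc)
            res = run_campaign(dw_spec, dw_cvs, sched)
            accs[inc] = res.exchanges["accepted"].mean()
        assert accs[8.0] < accs[1.0]
        assert accs[8.0] > 0.0

    def test_fused_kernel_agrees_with_generic_integrator(self, dw_spec):
        """The fused 1D ladder kernel and the generic batched integrator
        produce the same trajectory for the same noise."""
        from ahremd._kernels import _ladder_block_py, ladder_block
        from ahremd.bias import batched_bias_forces
        from ahremd.systems import _baoab_block

        cv = origin_cv()
        model = GMMModel(weights=[0.5, 0.5], means=[0.8, 1.4], widths=[0.3, 0.5])
        prefs = np.array([0.0, 4.0, 12.0])
        rng = np.random.default_rng(5)
        noise = rng.standard_normal((200, 3, 1, 1))
        x0 = np.array([[[1.0]], [[-1.0]], [[0.5]]])

        xa, va = x0.copy(), np.zeros_like(x0)

        def force_fn(x):
            return dw_spec.potential.forces(x) + batched_bias_forces(
                prefs, {"CV_1": model}, x, [cv])

        _baoab_block(xa, va, 200, dw_spec, force_fn, noise)

        xb = x0[:, 0, 0].copy()
        vb = np.zeros(3)
        amps = model.weights / (model.widths * np.sqrt(2 * np.pi))
        args = (0, dw_spec.potential.h, dw_spec.potential.a**2, prefs,
                model.means, model.widths, amps,
                float(np.exp(-dw_spec.friction * dw_spec.dt)),
                float(np.sqrt(dw_spec.kT * (1 - np.exp(-2 * dw_spec.friction * dw_spec.dt)))),
                dw_spec.dt, noise[:, :, 0, 0])
        ladder_block(xb, vb, *args)
        np.testing.assert_allclose(xb, xa[:, 0, 0], atol=1e-10)

        xc = x0[:, 0, 0].copy()
        vc = np.zeros(3)
        _ladder_block_py(xc, vc, *args)
        np.testing.assert_allclose(xc, xa[:, 0, 0], atol=1e-10)
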