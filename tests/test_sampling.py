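import numpy as np
import pytest
from scipy import integrate

from afcv import (
    ExchangeEvent, ExchangeLog, Hill, ToySystem, WTMetadParams, bias_energy,
    coordinate_cv, demux, pt_exchange_attempt, pt_metad_run,
    read_exchange_log, run_langevin, synthetic_exchange_log,
    write_exchange_log, wt_metad_run,
)
from afcv.constants import KB


def harmonic(k=1.0, n_dof=1):
    return ToySystem(
        n_dof,
        lambda x: 0.5 * k * float((np.asarray(x) ** 2).sum()),
        lambda x: k * np.asarray(x, dtype=float),
    )


def variance_check(samples, expected, corr_time, dt_per_sample):
    """3-standard-error equipartition check with an autocorrelation-aware
    effective sample size."""
    n_eff = max(len(samples) * dt_per_sample / (2.0 * corr_time), 2.0)
    var = samples.var()
    se = expected * np.sqrt(2.0 / n_eff)
    assert abs(var - expected) < 3.0 * se, (var, expected, se)


class TestLangevin:
    def test_zero_temperature_descends_monotonically(self):
        res = run_langevin(harmonic(k=5.0), 200, dt=0.05, temperature=0.0,
                           x0=np.array([2.0]))
        assert (np.diff(res.energies) <= 1e-12).all()
        assert abs(res.positions[-1, 0]) < 1e-6

    def test_same_seed_is_bitwise_identical(self):
        a = run_langevin(harmonic(), 500, dt=0.01, temperature=300.0, seed=42)
        b = run_langevin(harmonic(), 500, dt=0.01, temperature=300.0, seed=42)
        assert np.array_equal(a.positions, b.positions)

    def test_different_seed_differs(self):
        a = run_langevin(harmonic(), 100, dt=0.01, temperature=300.0, seed=1)
        b = run_langevin(harmonic(), 100, dt=0.01, temperature=300.0, seed=2)
        assert not np.array_equal(a.positions, b.positions)

    def test_equipartition_on_harmonic_well(self):
        k, T, dt = 1.0, 300.0, 0.01
        res = run_langevin(harmonic(k=k), 150_000, dt=dt, temperature=T,
                           seed=11, sample_stride=10)
        variance_check(res.positions[:, 0], KB * T / k, corr_time=1.0 / k,
                       dt_per_sample=10 * dt)

    def test_nonfinite_force_aborts_with_step(self):
        bad = ToySystem(1, lambda x: 0.0, lambda x: np.array([np.nan]))
        with pytest.raises(RuntimeError, match="step 0"):
            run_langevin(bad, 10, dt=0.01, temperature=300.0)


class TestBiasEnergy:
    def test_no_hills_is_zero(self):
        v, dv = bias_energy([], 0.3)
        assert v == 0.0 and np.array_equal(dv, [0.0])

    def test_at_center_equals_height(self):
        v, _ = bias_energy([Hill(0.0, (0.7,), (0.1,), 0.5, 8.0)], 0.7)
        assert v == pytest.approx(0.5, rel=1e-15)

    def test_two_hills_match_hand_sum(self):
        hills = [Hill(0.0, (0.2,), (0.1,), 0.5, 8.0),
                 Hill(1.0, (0.9,), (0.3,), 0.25, 8.0)]
        s = 0.55
        hand = (0.5 * np.exp(-(s - 0.2) ** 2 / (2 * 0.1**2))
                + 0.25 * np.exp(-(s - 0.9) ** 2 / (2 * 0.3**2)))
        hand_d = (0.5 * np.exp(-(s - 0.2) ** 2 / (2 * 0.1**2)) * (-(s - 0.2) / 0.1**2)
                  + 0.25 * np.exp(-(s - 0.9) ** 2 / (2 * 0.3**2)) * (-(s - 0.9) / 0.3**2))
        v, dv = bias_energy(hills, s)
        assert v == pytest.approx(hand, rel=1e-12)
        assert dv[0] == pytest.approx(hand_d, rel=1e-12)

    def test_two_dimensional_hill(self):
        hills = [Hill(0.0, (0.0, 1.0), (0.5, 0.2), 1.0, None)]
        v, dv = bias_energy(hills, np.array([0.5, 0.8]))
        hand = np.exp(-0.5 * ((0.5 / 0.5) ** 2 + (-0.2 / 0.2) ** 2))
        assert v == pytest.approx(hand, rel=1e-12)
        assert dv.shape == (2,)


class TestWellTemperedMechanics:
    def setup_run(self, n_hills=3, stride=50):
        flat = ToySystem(1, lambda x: 0.0, lambda x: np.zeros(1))
        params = WTMetadParams(hill_height_0=0.5, widths=(0.1,), bias_factor=8.0,
                               deposition_stride=stride, temperature=300.0)
        return wt_metad_run(flat, coordinate_cv(0), params, n_hills * stride,
                            seed=0, dt=0.001)

    def test_first_hill_height_is_exactly_w0(self):
        res = self.setup_run()
        assert res.hills[0].height == 0.5

    def test_repeated_deposition_follows_closed_form(self):
        # a constant CV pins every hill to the same point, so each deposition
        # sees exactly the bias accumulated there -- the damping law in
        # closed form, independent of the walker's thermal motion
        constant_cv = lambda x: (np.array([0.0]), np.zeros((1, 1)))
        flat = ToySystem(1, lambda x: 0.0, lambda x: np.zeros(1))
        w0, gamma, T = 0.5, 8.0, 300.0
        params = WTMetadParams(hill_height_0=w0, widths=(0.1,), bias_factor=gamma,
                               deposition_stride=10, temperature=T)
        res = wt_metad_run(flat, constant_cv, params, 31, seed=0, dt=0.001)
        dT = (gamma - 1.0) * T
        assert res.hills[0].height == w0
        h1 = res.hills[0].height
        assert res.hills[1].height == pytest.approx(
            w0 * np.exp(-h1 / (KB * dT)), rel=1e-12
        )
        v2 = h1 + res.hills[1].height
        assert res.hills[2].height == pytest.approx(
            w0 * np.exp(-v2 / (KB * dT)), rel=1e-12
        )

    def test_heights_nonincreasing_at_fixed_location(self):
        constant_cv = lambda x: (np.array([0.0]), np.zeros((1, 1)))
        flat = ToySystem(1, lambda x: 0.0, lambda x: np.zeros(1))
        params = WTMetadParams(deposition_stride=5, temperature=300.0)
        res = wt_metad_run(flat, constant_cv, params, 100, seed=3, dt=1e-5)
        heights = [h.height for h in res.hills]
        assert len(heights) >= 10
        assert all(b <= a + 1e-15 for a, b in zip(heights, heights[1:]))

    def test_colvar_table_has_time_cv_bias(self):
        res = self.setup_run()
        assert list(res.colvar.columns) == ["time", "afcv", "bias"]
        assert (np.diff(res.colvar["time"]) > 0).all()


class TestExchangeAttempt:
    def test_equal_energy_always_accepted(self, rng):
        assert pt_exchange_attempt(5.0, 5.0, 0, 0, 0, 0, 300.0, 400.0, rng)

    def test_equal_temperature_always_accepted(self, rng):
        assert pt_exchange_attempt(1.0, 9.0, 0, 0, 0, 0, 350.0, 350.0, rng)

    def test_acceptance_rate_matches_closed_form(self):
        rng = np.random.default_rng(17)
        # fix (beta_i - beta_j)(U_i - U_j) = -0.5
        t_i, t_j = 300.0, 400.0
        du = -0.5 / (1 / (KB * t_i) - 1 / (KB * t_j))
        n = 100_000
        acc = sum(
            pt_exchange_attempt(du, 0.0, 0, 0, 0, 0, t_i, t_j, rng) for _ in range(n)
        )
        p = np.exp(-0.5)
        assert abs(acc / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_bias_cross_terms_shift_the_exponent(self):
        rng = np.random.default_rng(0)
        # large favorable bias term forces acceptance regardless of energies
        assert pt_exchange_attempt(0.0, 100.0, 100.0, 0.0, 100.0, 0.0,
                                   300.0, 301.0, rng)


class TestParallelTempering:
    def test_equal_temperature_pair_always_swaps(self):
        # ladder must strictly increase; emulate equal-T by tiny spacing and
        # identical systems -> acceptance 1 whenever energies match exactly
        res = pt_metad_run(harmonic(), coordinate_cv(0), None,
                           ladder=(300.0, 300.0 + 1e-9), exchange_stride=10,
                           n_steps=100, seed=0, dt=0.01)
        acc = [ev.accepted for ev in res.log.events]
        assert acc and all(acc)

    def test_zero_exchange_stride_gives_empty_log(self):
        res = pt_metad_run(harmonic(), coordinate_cv(0), None,
                           ladder=(300.0, 400.0), exchange_stride=0,
                           n_steps=200, seed=0, dt=0.01)
        assert res.log.events == []

    def test_acceptance_matches_quadrature_oracle(self):
        k, ti, tj = 1.0, 300.0, 400.0
        res = pt_metad_run(harmonic(k), coordinate_cv(0), None,
                           ladder=(ti, tj), exchange_stride=200,
                           n_steps=200_000, seed=21, dt=0.01, sample_stride=1000)
        events = res.log.events
        emp = np.mean([ev.accepted for ev in events])

        bi, bj = 1 / (KB * ti), 1 / (KB * tj)

        def integrand(x, y):
            pi = np.sqrt(k * bi / (2 * np.pi)) * np.exp(-0.5 * k * bi * x * x)
            pj = np.sqrt(k * bj / (2 * np.pi)) * np.exp(-0.5 * k * bj * y * y)
            du = 0.5 * k * (x * x - y * y)
            return pi * pj * np.exp(np.minimum(0.0, (bi - bj) * du))

        oracle, _ = integrate.dblquad(integrand, -np.inf, np.inf,
                                      lambda _: -np.inf, lambda _: np.inf)
        sigma = np.sqrt(oracle * (1 - oracle) / len(events))
        assert abs(emp - oracle) < 3 * sigma + 0.01

    def test_unbiased_pt_preserves_boltzmann_variance(self):
        k, dt = 1.0, 0.01
        res = pt_metad_run(harmonic(k), coordinate_cv(0), None,
                           ladder=(300.0, 400.0), exchange_stride=100,
                           n_steps=150_000, seed=5, dt=dt, sample_stride=10)
        for slot, temp in zip(res.slots, (300.0, 400.0)):
            variance_check(slot.positions[:, 0], KB * temp / k,
                           corr_time=1.0 / k, dt_per_sample=10 * dt)


class TestDemux:
    def test_empty_log_is_identity(self):
        log = ExchangeLog((300.0, 310.0, 320.0), [])
        res = demux(log)
        assert np.array_equal(res.final_permutation, [0, 1, 2])

    def test_single_swap(self):
        log = ExchangeLog((300.0, 310.0, 320.0),
                          [ExchangeEvent(5.0, 0, 1, True)])
        res = demux(log)
        assert np.array_equal(res.slot_of_replica[0], [0, 1, 2])
        assert np.array_equal(res.slot_of_replica[1], [1, 0, 2])

    def test_rejected_swap_changes_nothing(self):
        log = ExchangeLog((300.0, 310.0), [ExchangeEvent(1.0, 0, 1, False)])
        assert np.array_equal(demux(log).final_permutation, [0, 1])

    def test_thousand_random_swaps_match_composition_oracle(self):
        log, truth = synthetic_exchange_log(8, 1000, acceptance_rate=0.6, seed=9)
        res = demux(log)
        assert np.array_equal(res.final_permutation, truth)
        # bijection at every recorded time
        for row in res.slot_of_replica:
            assert np.array_equal(np.sort(row), np.arange(8))
        # composing the recorded swaps onto the returned assignment restores
        # the identity (walk the events backwards)
        slots = res.final_permutation.copy()
        replica_at = np.argsort(slots)
        for ev in reversed(log.events):
            if ev.accepted:
                ra, rb = replica_at[ev.slot_a], replica_at[ev.slot_b]
                slots[ra], slots[rb] = ev.slot_b, ev.slot_a
                replica_at[ev.slot_a], replica_at[ev.slot_b] = rb, ra
        assert np.array_equal(slots, np.arange(8))

    def test_out_of_range_slot_rejected(self):
        log = ExchangeLog((300.0, 310.0), [ExchangeEvent(1.0, 0, 1, True)])
        with pytest.raises(ValueError, match="slot"):
            demux(log, n_replicas=1)


def test_exchange_log_text_round_trip(tmp_path):
    log, _ = synthetic_exchange_log(4, 25, acceptance_rate=0.5, seed=2)
    back = read_exchange_log(write_exchange_log(log, tmp_path / "exch.log"))
    assert back.ladder == log.ladder
    assert back.events == log.events
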