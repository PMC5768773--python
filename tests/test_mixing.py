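"""Tests for forward mixing, per-vent apportionment, the joint cross-vent
fit, and Monte-Carlo propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventmix.isotope_core import Convention, IsotopeValue, SigmaFloors, VentAverage, aggregate_by_vent
from ventmix.mixing import (
    Endmember,
    MixingConfig,
    MixtureObservation,
    apportion_vent,
    forward_mix,
    joint_fit,
    mc_propagate,
)
from ventmix.synthetic import GeneratorTruth, generate


def _f(v, s=0.0):
    return IsotopeValue(v, s, Convention.F14C)


def _d(v, s=0.0):
    return IsotopeValue(v, s, Convention.DELTA13C)


def _c(v, s=0.0):
    return IsotopeValue(v, s, Convention.CONC)


def _em(label, c, f, d):
    return Endmember(label, _c(c), _f(f), _d(d))


DEAD = _em("dead", 112.0, 0.0, -12.7)
MODERN = _em("modern", 40.0, 1.02, 8.4)


class TestForwardMix:
    def test_single_endmember_identity(self):
        obs = forward_mix([MODERN])
        assert obs.conc_total.value == pytest.approx(40.0)
        assert obs.f14c_mix.value == pytest.approx(1.02)
        assert obs.d13c_mix.value == pytest.approx(8.4)

    def test_field_scale_example(self):
        obs = forward_mix([DEAD, MODERN])
        assert obs.conc_total.value == pytest.approx(152.0)
        assert obs.f14c_mix.value == pytest.approx(0.26842, abs=1e-5)
        assert obs.d13c_mix.value == pytest.approx(-7.147, abs=1e-3)

    def test_order_invariance(self):
        a = forward_mix([DEAD, MODERN])
        b = forward_mix([MODERN, DEAD])
        assert a.f14c_mix.value == pytest.approx(b.f14c_mix.value, rel=1e-15)
        assert a.d13c_mix.value == pytest.approx(b.d13c_mix.value, rel=1e-15)

    def test_all_zero_concentration_errors(self):
        with pytest.raises(ValueError):
            forward_mix([_em("dead", 0.0, 0.0, -12.7)])

    @given(
        c1=st.floats(0.1, 200.0),
        c2=st.floats(0.1, 200.0),
        f1=st.floats(0.0, 1.1),
        f2=st.floats(0.0, 1.1),
        d1=st.floats(-30.0, 10.0),
        d2=st.floats(-30.0, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_outputs_are_convex_combinations(self, c1, c2, f1, f2, d1, d2):
        obs = forward_mix([_em("a", c1, f1, d1), _em("b", c2, f2, d2)])
        assert min(f1, f2) - 1e-12 <= obs.f14c_mix.value <= max(f1, f2) + 1e-12
        assert min(d1, d2) - 1e-9 <= obs.d13c_mix.value <= max(d1, d2) + 1e-9


class TestApportionVent:
    def test_dead_only_when_f14c_zero(self):
        ap = apportion_vent(MixtureObservation(_c(100.0), f14c_mix=_f(0.0)))
        assert ap.c_modern.value == 0.0
        assert ap.c_dead.value == pytest.approx(100.0)

    def test_marker3_scale_apportionment(self):
        ap = apportion_vent(MixtureObservation(_c(158.0), f14c_mix=_f(0.56)))
        assert ap.c_modern.value == pytest.approx(86.745, abs=1e-2)
        assert ap.c_dead.value == pytest.approx(71.255, abs=1e-2)
        assert not ap.clipped

    def test_round_trip_on_forward_example(self):
        obs = forward_mix([DEAD, MODERN])
        ap = apportion_vent(obs)
        assert ap.c_dead.value == pytest.approx(112.0, rel=1e-9)
        assert ap.c_modern.value == pytest.approx(40.0, rel=1e-9)

    def test_mixture_hotter_than_modern_is_clipped_and_flagged(self):
        ap = apportion_vent(MixtureObservation(_c(100.0), f14c_mix=_f(1.1)))
        assert ap.clipped
        assert ap.c_dead.value == 0.0
        assert ap.c_modern.value == pytest.approx(100.0)

    def test_requires_f14c(self):
        with pytest.raises(ValueError):
            apportion_vent(MixtureObservation(_c(100.0)))

    def test_solves_missing_modern_delta_by_mass_balance(self):
        obs = forward_mix([DEAD, MODERN])
        ap = apportion_vent(obs, d13c_dead=-12.7)
        assert ap.d13c_modern.value == pytest.approx(8.4, rel=1e-9)

    def test_solves_missing_dead_delta_by_mass_balance(self):
        obs = forward_mix([DEAD, MODERN])
        ap = apportion_vent(obs, d13c_modern=8.4)
        assert ap.d13c_dead.value == pytest.approx(-12.7, rel=1e-9)

    @given(
        c_dead=st.floats(1.0, 300.0),
        c_mod=st.floats(1.0, 300.0),
        f_mod=st.floats(0.5, 1.1),
    )
    @settings(max_examples=100, deadline=None)
    def test_apportion_inverts_forward_mix(self, c_dead, c_mod, f_mod):
        obs = forward_mix([_em("dead", c_dead, 0.0, -12.7), _em("mod", c_mod, f_mod, 8.4)])
        cfg = MixingConfig(f14c_modern=f_mod)
        ap = apportion_vent(obs, cfg)
        assert ap.c_dead.value == pytest.approx(c_dead, rel=1e-7, abs=1e-7)
        assert ap.c_modern.value == pytest.approx(c_mod, rel=1e-7, abs=1e-7)
        # mass conservation
        total = ap.c_dead.value + ap.c_modern.value
        assert total == pytest.approx(obs.conc_total.value, abs=1e-9 * max(1.0, total))


def _noise_free_averages(c_modern=None, drop_f14c=("C",)):
    truth = GeneratorTruth(
        noise_f14c=0.0, noise_d13c=0.0, noise_conc_rel=0.0,
        drop_f14c=drop_f14c,
        **({"c_modern": c_modern, "replicates": {k: 2 for k in c_modern}} if c_modern else {}),
    )
    ds, _ = generate(truth)
    return aggregate_by_vent(ds), truth


class TestJointFit:
    def test_noise_free_recovery_to_1e6_relative(self):
        avgs, truth = _noise_free_averages()
        res = joint_fit(avgs, MixingConfig(), monte_carlo=False)
        assert res.shared["c_dead"].value == pytest.approx(112.0, rel=1e-6)
        assert res.shared["d13c_dead"].value == pytest.approx(-12.7, rel=1e-6)
        assert res.shared["d13c_modern"].value == pytest.approx(8.4, rel=1e-6)
        for marker, c_mod in truth.c_modern.items():
            assert res.per_vent[marker].c_modern.value == pytest.approx(
                c_mod, rel=1e-6, abs=1e-6
            )
        assert res.weighted_sse < 1e-10

    def test_vent_without_f14c_contributes_reduced_residuals(self):
        avgs, _ = _noise_free_averages(drop_f14c=("C",))
        res = joint_fit(avgs, MixingConfig(), monte_carlo=False)
        # 4 conc + 3 CF + 4 Cδ rows
        assert res.n_obs == 11
        assert res.n_params == 7

    def test_mass_conservation_per_vent(self):
        ds, _ = generate(GeneratorTruth(), seed=3)
        avgs = aggregate_by_vent(ds)
        res = joint_fit(avgs, MixingConfig(), monte_carlo=False)
        for a in avgs:
            v = res.per_vent[a.marker_id]
            if not v.clipped:
                assert v.c_dead.value + v.c_modern.value == pytest.approx(
                    a.concentration.value, abs=1e-9 * a.concentration.value
                )

    def test_single_vent_reduces_to_apportion_vent(self):
        a = VentAverage("3", n=2, concentration=_c(158.0), f14c=_f(0.56), d13c=_d(-4.3))
        res = joint_fit([a], MixingConfig(share_dead_conc=False, share_d13c=False),
                        monte_carlo=False)
        ap = apportion_vent(
            MixtureObservation(_c(158.0), f14c_mix=_f(0.56), d13c_mix=_d(-4.3))
        )
        assert res.per_vent["3"].c_dead.value == pytest.approx(ap.c_dead.value, rel=1e-12)
        assert res.per_vent["3"].c_modern.value == pytest.approx(ap.c_modern.value, rel=1e-12)

    def test_underdetermined_system_errors_with_deficit(self):
        avgs = [
            VentAverage("A", n=1, concentration=_c(100.0), f14c=_f(0.3)),
            VentAverage("B", n=1, concentration=_c(120.0)),
        ]
        with pytest.raises(ValueError, match="underdetermined"):
            joint_fit(avgs, MixingConfig(), monte_carlo=False)

    def test_scale_equivariance(self):
        avgs, _ = _noise_free_averages()
        k = 3.7
        scaled = [
            VentAverage(
                a.marker_id,
                a.n,
                concentration=_c(a.concentration.value * k, a.concentration.sigma * k),
                d13c=a.d13c,
                f14c=a.f14c,
            )
            for a in avgs
        ]
        base = joint_fit(avgs, MixingConfig(), monte_carlo=False)
        big = joint_fit(scaled, MixingConfig(), monte_carlo=False)
        assert big.shared["c_dead"].value == pytest.approx(
            k * base.shared["c_dead"].value, rel=1e-6
        )
        assert big.shared["d13c_dead"].value == pytest.approx(
            base.shared["d13c_dead"].value, rel=1e-6
        )
        assert big.shared["d13c_modern"].value == pytest.approx(
            base.shared["d13c_modern"].value, rel=1e-6
        )

    def test_fit_f14c_modern_recovers_truth_noise_free(self):
        avgs, _ = _noise_free_averages()
        res = joint_fit(avgs, MixingConfig(fit_f14c_modern=True), monte_carlo=False)
        assert res.shared["f14c_modern"].value == pytest.approx(1.02, rel=1e-6)


class TestMcPropagate:
    def test_zero_sigmas_and_zero_floors_give_zero_sd(self):
        avgs, _ = _noise_free_averages()
        cfg = MixingConfig(mc_draws=100, floors=SigmaFloors(0.0, 0.0, 0.0))
        out = mc_propagate(
            lambda a: np.array([a[0].concentration.value]), avgs, cfg, ["c"]
        )
        assert out["c"].sd == 0.0
        assert out["c"].n_failed == 0

    def test_same_seed_reproduces_summaries_exactly(self):
        ds, _ = generate(GeneratorTruth(), seed=5)
        avgs = aggregate_by_vent(ds)
        cfg = MixingConfig(mc_draws=150, seed=11)
        fn = lambda a: np.array([a[0].concentration.value * 2.0])
        out1 = mc_propagate(fn, avgs, cfg, ["p"])
        out2 = mc_propagate(fn, avgs, cfg, ["p"])
        assert out1 == out2

    def test_linear_fn_sd_matches_delta_method_within_3pct(self):
        a = VentAverage("X", n=1, concentration=_c(100.0, 2.0), f14c=_f(0.5, 0.04))
        cfg = MixingConfig(mc_draws=100_000, seed=2, floors=SigmaFloors(0.0, 0.0, 0.0))
        out = mc_propagate(
            lambda avgs: np.array(
                [3.0 * avgs[0].concentration.value - 50.0 * avgs[0].f14c.value]
            ),
            [a],
            cfg,
            ["lin"],
        )
        analytic = np.hypot(3.0 * 2.0, 50.0 * 0.04)
        assert out["lin"].sd == pytest.approx(analytic, rel=0.03)

    def test_high_failure_rate_raises(self):
        avgs, _ = _noise_free_averages()
        cfg = MixingConfig(mc_draws=100)

        def flaky(a):
            raise ValueError("no fit")

        with pytest.raises(RuntimeError, match="failure rate"):
            mc_propagate(flaky, avgs, cfg)
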