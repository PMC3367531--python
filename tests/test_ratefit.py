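"""Rate-surface family: detailed-balance identity, fitting, equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stepstone.experiment import observations_from_params
from stepstone.ratefit import (
    RateObservation,
    RateSurfaceModel,
    RateSurfaceParams,
    equilibrium_probabilities,
    fit_common_contact_factor,
    fit_rate_surface,
    log_common_contact_factor,
    log_rate,
    observations_to_arrays,
    plane_fit_log_ratio,
)
from stepstone.structgen import Structure


def _params(**kw):
    defaults = dict(log_k_max=-0.5, alpha_hb=0.8, alpha_c=0.25, alpha_q=3.0, q_mid=0.4)
    defaults.update(kw)
    return RateSurfaceParams(**defaults)


class TestDetailedBalanceIdentity:
    @settings(max_examples=50, deadline=None)
    @given(
        a_hb=hst.floats(0.05, 5.0),
        a_c=hst.floats(0.05, 5.0),
        de=hst.floats(-20.0, 20.0),
        dn=hst.floats(-40.0, 40.0),
        q=hst.floats(0.0, 1.0),
    )
    def test_log_ratio_factorizes_exactly(self, a_hb, a_c, de, dn, q):
        """ln k_AB - ln k_BA = -alpha_HB dE_HB + alpha_c dN_c, exactly."""
        p = _params(alpha_hb=a_hb, alpha_c=a_c)
        fwd = log_rate(p, de, dn, q)
        rev = log_rate(p, -de, -dn, q)
        assert fwd - rev == pytest.approx(-a_hb * de + a_c * dn, abs=1e-10)

    def test_g_normalized_at_identical_structures(self):
        p = _params()
        assert log_common_contact_factor(1.0, p.alpha_q, p.q_mid) == pytest.approx(0.0)

    def test_g_cancels_in_ratio(self):
        p = _params(alpha_q=7.0, q_mid=0.3)
        for q in (0.1, 0.5, 0.9):
            diff = log_rate(p, 2.0, -3.0, q) - log_rate(p, -2.0, 3.0, q)
            assert diff == pytest.approx(log_rate(p, 2.0, -3.0, 1.0) - log_rate(p, -2.0, 3.0, 1.0))

    def test_surface_monotone_directions(self):
        p = _params()
        de = np.linspace(-5, 5, 21)
        assert np.all(np.diff(log_rate(p, de, 0.0, 1.0)) < 0)  # down in dE_HB
        dn = np.linspace(-20, 20, 21)
        assert np.all(np.diff(log_rate(p, 0.0, dn, 1.0)) > 0)  # up in dN_c

    def test_step_like_saturation(self):
        """Far on the favorable side of both sigmoids the surface is flat."""
        p = _params(alpha_hb=2.0, alpha_c=1.0)
        favorable = log_rate(p, np.array([-20.0, -30.0]), np.array([30.0, 40.0]), 1.0)
        full_range = log_rate(p, np.array([20.0]), np.array([-40.0]), 1.0)
        span = favorable.max() - full_range.min()
        assert np.ptp(favorable) < 0.05 * span


class TestRateSurfaceModel:
    def test_noiseless_recovery(self):
        truth = _params()
        obs = observations_from_params(truth, n=80, rng_seed=1, noise=0.0)
        X, y, w = observations_to_arrays(obs)
        model = RateSurfaceModel().fit(X, y, sample_weight=w)
        p = model.params_
        assert p.alpha_hb == pytest.approx(truth.alpha_hb, rel=1e-2)
        assert p.alpha_c == pytest.approx(truth.alpha_c, rel=1e-2)
        assert p.log_k_max == pytest.approx(truth.log_k_max, abs=1e-2)
        assert model.residual_rms_ < 1e-6

    def test_noisy_recovery_within_two_se(self):
        truth = _params()
        obs = observations_from_params(truth, n=150, rng_seed=5, noise=0.1)
        params, diag = fit_rate_surface(obs)
        se = diag["stderr"]
        assert abs(params.alpha_hb - truth.alpha_hb) < 2 * se["alpha_hb"]
        assert abs(params.alpha_c - truth.alpha_c) < 2 * se["alpha_c"]

    def test_scale_invariance_absorbed_in_k_max(self):
        truth = _params()
        obs = observations_from_params(truth, n=60, rng_seed=2)
        scaled = [
            RateObservation(o.de_hb, o.dn_c, o.q, 10 * o.k_ab, 10 * o.k_ba)
            for o in obs
        ]
        p1, _ = fit_rate_surface(obs)
        p2, _ = fit_rate_surface(scaled)
        assert p2.alpha_hb == pytest.approx(p1.alpha_hb, rel=1e-4)
        assert p2.log_k_max == pytest.approx(p1.log_k_max + np.log(10), abs=1e-4)

    def test_one_sided_design_rejected(self):
        truth = _params()
        obs = observations_from_params(truth, n=30, rng_seed=3)
        X = np.array([[abs(o.de_hb), o.dn_c, o.q] for o in obs])
        y = np.array([o.k_ab for o in obs])
        with pytest.raises(ValueError, match="dE_HB"):
            RateSurfaceModel().fit(X, y)

    def test_sklearn_param_protocol(self):
        m = RateSurfaceModel(fit_common_contact=False)
        assert m.get_params()["fit_common_contact"] is False
        m.set_params(fit_common_contact=True)
        assert m.fit_common_contact is True
        with pytest.raises(ValueError):
            m.set_params(bogus=1)

    def test_predict_requires_fit(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            RateSurfaceModel().predict(np.zeros((1, 3)))

    def test_predict_matches_family(self):
        truth = _params()
        obs = observations_from_params(truth, n=60, rng_seed=4)
        X, y, w = observations_to_arrays(obs)
        model = RateSurfaceModel().fit(X, y, sample_weight=w)
        assert np.allclose(model.predict(X), y, rtol=1e-4)


class TestCommonContactFactor:
    def test_known_g_recovered(self):
        truth = _params(alpha_q=4.0, q_mid=0.45)
        obs = observations_from_params(truth, n=120, rng_seed=7)
        base = RateSurfaceParams(truth.log_k_max, truth.alpha_hb, truth.alpha_c)
        fitted = fit_common_contact_factor(obs, base)
        assert fitted.alpha_q == pytest.approx(4.0, rel=0.05)
        assert fitted.q_mid == pytest.approx(0.45, abs=0.02)

    def test_insufficient_spread_fixes_g_to_one(self):
        truth = _params()
        obs = [
            RateObservation(o.de_hb, o.dn_c, 0.5, o.k_ab, o.k_ba)
            for o in observations_from_params(truth, n=40, rng_seed=8)
        ]
        base = RateSurfaceParams(truth.log_k_max, truth.alpha_hb, truth.alpha_c)
        with pytest.warns(UserWarning, match="q spread"):
            fitted = fit_common_contact_factor(obs, base)
        assert np.exp(log_common_contact_factor(0.3, fitted.alpha_q, fitted.q_mid)) == pytest.approx(1.0)


class TestPlaneFit:
    def test_exact_on_family_data(self):
        truth = _params()
        obs = observations_from_params(truth, n=60, rng_seed=9)
        plane = plane_fit_log_ratio(obs)
        assert plane.r_squared == pytest.approx(1.0, abs=1e-10)
        assert plane.c_hb == pytest.approx(-truth.alpha_hb, abs=1e-8)
        assert plane.c_c == pytest.approx(truth.alpha_c, abs=1e-8)

    def test_antisymmetry_under_pair_reversal(self):
        truth = _params()
        obs = observations_from_params(truth, n=60, rng_seed=10, noise=0.05)
        rev = [o.reversed() for o in obs]
        p_fwd = plane_fit_log_ratio(obs)
        p_rev = plane_fit_log_ratio(rev)
        assert p_rev.c_hb == pytest.approx(p_fwd.c_hb)
        assert p_rev.c_c == pytest.approx(p_fwd.c_c)

    def test_noisy_coefficients_within_two_se(self):
        truth = _params()
        obs = observations_from_params(truth, n=200, rng_seed=11, noise=0.1)
        plane = plane_fit_log_ratio(obs)
        assert abs(plane.c_hb + truth.alpha_hb) < 2 * plane.stderr[0] + 0.02
        assert abs(plane.c_c - truth.alpha_c) < 2 * plane.stderr[1] + 0.005

    def test_zero_rates_excluded_with_warning(self):
        truth = _params()
        obs = observations_from_params(truth, n=20, rng_seed=12)
        obs.append(RateObservation(1.0, 1.0, 0.5, 0.0, 0.1))
        with pytest.warns(UserWarning, match="zero rate"):
            plane = plane_fit_log_ratio(obs)
        assert plane.excluded == 1


def _struct(ehb_count, n_c, length=30):
    pairs = [(i, j) for i in range(length) for j in range(i + 3, length)]
    return Structure(
        id=f"s-{ehb_count}-{n_c}", length=length, ss="C" * length,
        contacts=frozenset(pairs[:n_c]), n_hbonds=ehb_count,
    )


class TestEquilibriumProbabilities:
    def test_identical_descriptors_equal_probability(self):
        p = _params()
        probs = equilibrium_probabilities([_struct(3, 10), _struct(3, 10)], p)
        assert probs[0] == pytest.approx(probs[1]) == pytest.approx(0.5)

    def test_normalization(self):
        p = _params()
        probs = equilibrium_probabilities([_struct(2, 5), _struct(4, 9), _struct(1, 20)], p)
        assert probs.sum() == pytest.approx(1.0)

    def test_detailed_balance_with_family_rates(self):
        p = _params()
        structs = [_struct(2, 5), _struct(5, 12), _struct(3, 18)]
        probs = equilibrium_probabilities(structs, p)
        for i, a in enumerate(structs):
            for j, b in enumerate(structs):
                if i == j:
                    continue
                k_ab = np.exp(log_rate(p, b.hb_energy - a.hb_energy, b.n_contacts - a.n_contacts, 0.7))
                k_ba = np.exp(log_rate(p, a.hb_energy - b.hb_energy, a.n_contacts - b.n_contacts, 0.7))
                assert probs[i] * k_ab == pytest.approx(probs[j] * k_ba, rel=1e-12)

    def test_designability_ordering(self):
        """P grows with H-bond count at fixed contacts and vice versa."""
        p = _params()
        by_hb = equilibrium_probabilities([_struct(h, 10) for h in (1, 3, 5, 7)], p)
        assert np.all(np.diff(by_hb) > 0)
        by_nc = equilibrium_probabilities([_struct(3, n) for n in (5, 10, 15, 20)], p)
        assert np.all(np.diff(by_nc) > 0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_probabilities([], _params())
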