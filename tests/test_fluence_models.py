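"""Fluence-model checks against independent transcriptions of the closed
forms and against the governing equations themselves (ODE residual and
flux-conservation boundary condition)."""

import math

import numpy as np
import pytest

from sfdi_layers import (
    DomainError,
    ExponentialSum,
    FluenceModelChoice,
    OpticalProperties,
    SingularConfigurationError,
    delta_p1_fluence,
    derive_transport_coefficients,
    evaluate_fluence,
    fluence_model,
    mod_delta_p1_fluence,
    mu_eff_prime,
    sda_fluence,
)
from sfdi_layers.partial_volume import alpha_partial_volume

from conftest import ALL_MODELS, certified_grid_points


# --- independent raw transcriptions (kept deliberately un-collected) -----

def raw_sda(props, fx, z):
    d = derive_transport_coefficients(props)
    mep = mu_eff_prime(d, fx)
    r = d.R_sda
    ratio = mep / d.mu_tr
    a = 3 * (props.mu_s_prime / d.mu_tr) / (ratio**2 - 1)
    c = -a * (1 + 3 * r) / (ratio + 3 * r)
    return a * np.exp(-d.mu_tr * z) + c * np.exp(-mep * z)


def raw_delta_p1(props, fx, z):
    d = derive_transport_coefficients(props)
    mep = mu_eff_prime(d, fx)
    c_star = 3 * d.mu_tr * d.mu_s_star / (2 * mep)
    zb = (2 / (3 * d.mu_tr)) * d.R_prime
    return (c_star / (mep - d.mu_tr_star)
            * (np.exp(-d.mu_tr_star * z) - np.exp(-mep * z))
            + c_star / (mep + d.mu_tr_star)
            * (np.exp(-d.mu_tr_star * z) - np.exp(-mep * (z + 2 * zb))))


def raw_mod_delta_p1(props, fx, z):
    d = derive_transport_coefficients(props)
    mep = mu_eff_prime(d, fx)
    a_p = 3 * d.mu_s_star * (d.mu_tr_star + d.g_star * d.mu_a) / (mep**2 - d.mu_tr_star**2)
    h = 2 * d.R_prime / (3 * d.mu_tr)
    c_p = -(a_p * (1 + h * d.mu_tr_star)
            + 2 * d.R_prime * d.g_star * d.mu_s_star / d.mu_tr) / (1 + h * mep)
    return (1 + a_p) * np.exp(-d.mu_tr_star * z) + c_p * np.exp(-mep * z)


RAW = {FluenceModelChoice.SDA: raw_sda,
       FluenceModelChoice.DELTA_P1: raw_delta_p1,
       FluenceModelChoice.MOD_DELTA_P1: raw_mod_delta_p1}


@pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
def test_collected_form_matches_raw_transcription(model):
    """ExponentialSum evaluation equals the un-collected closed forms at 100
    seeded random (parameters, z) draws, to machine precision."""
    rng = np.random.default_rng(1234)
    for _ in range(100):
        props = OpticalProperties(
            mu_a=rng.uniform(0.01, 0.1), mu_s_prime=rng.uniform(0.5, 5.0),
            g=rng.uniform(0.7, 0.9), n=1.4)
        fx = rng.uniform(0.0, 0.5)
        z = rng.uniform(0.0, 10.0)
        try:
            s = fluence_model(props, fx, model)
        except SingularConfigurationError:
            continue
        assert evaluate_fluence(s, z) == pytest.approx(
            float(RAW[model](props, fx, z)), rel=1e-11, abs=1e-13)


def test_sda_solves_diffusion_equation_and_boundary_condition(fig2_props):
    """Independent verification of the SDA amplitudes: phi solves
    phi'' - mu_eff'^2 phi = -3 mu_tr mu_s' exp(-mu_tr z) and the
    partial-current boundary condition phi(0) = phi'(0)/(3 R mu_tr)."""
    d = derive_transport_coefficients(fig2_props)
    for fx in (0.0, 0.1, 0.3):
        mep = mu_eff_prime(d, fx)
        s = sda_fluence(fig2_props, fx)
        (a, k1), (c, k2) = s.terms
        for z in (0.0, 0.2, 1.0):
            phi = a * math.exp(-k1 * z) + c * math.exp(-k2 * z)
            phi_dd = a * k1**2 * math.exp(-k1 * z) + c * k2**2 * math.exp(-k2 * z)
            source = -3 * d.mu_tr * fig2_props.mu_s_prime * math.exp(-d.mu_tr * z)
            assert phi_dd - mep**2 * phi == pytest.approx(source, rel=1e-9)
        phi0 = a + c
        dphi0 = -a * k1 - c * k2
        assert phi0 == pytest.approx(dphi0 / (3 * d.R_sda * d.mu_tr), rel=1e-10)


def test_mod_delta_p1_boundary_condition_on_certified_grid():
    """The diffuse part of mod-delta-P1 satisfies the flux-conservation
    boundary condition to < 1e-9 relative at every certified grid point."""
    for props, fx in certified_grid_points():
        d = derive_transport_coefficients(props)
        mep = mu_eff_prime(d, fx)
        s = mod_delta_p1_fluence(props, fx)
        (amp_tr, _), (c_p, _) = s.terms
        a_p = amp_tr - 1.0  # strip the collimated "1"
        phi0 = a_p + c_p
        dphi0 = -a_p * d.mu_tr_star - c_p * mep
        residual = (phi0 - (2 / (3 * d.mu_tr)) * d.R_prime * dphi0
                    + (2 / d.mu_tr) * d.R_prime * d.g_star * d.mu_s_star)
        assert abs(residual) / abs(phi0) < 1e-9


def test_mod_delta_p1_solves_its_governing_equation(fig2_props):
    """The diffuse particular amplitude satisfies the 1-D delta-P1 ODE with
    the exponentially attenuated collimated source."""
    d = derive_transport_coefficients(fig2_props)
    for fx in (0.0, 0.2, 0.5):
        mep = mu_eff_prime(d, fx)
        s = mod_delta_p1_fluence(fig2_props, fx)
        (amp_tr, k1), (c_p, k2) = s.terms
        a_p = amp_tr - 1.0
        for z in (0.0, 0.5, 2.0):
            phi = a_p * math.exp(-k1 * z) + c_p * math.exp(-k2 * z)
            phi_dd = a_p * k1**2 * math.exp(-k1 * z) + c_p * k2**2 * math.exp(-k2 * z)
            # RHS: -3 mu_s*(mu_tr + g* mu_tr*) q0(z), q0 = exp(-mu_tr* z)
            source = -3 * d.mu_s_star * (d.mu_tr + d.g_star * d.mu_tr_star) \
                * math.exp(-d.mu_tr_star * z)
            assert phi_dd - mep**2 * phi == pytest.approx(source, rel=1e-9)


@pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
def test_frequency_zero_reduces_to_planar_form(model, fig2_props):
    """At fx = 0 every rate mu_eff'(0) collapses to mu_eff term-by-term."""
    d = derive_transport_coefficients(fig2_props)
    s = fluence_model(fig2_props, 0.0, model)
    rates = sorted(k for _, k in s.terms)
    expected_fast = d.mu_tr if model is FluenceModelChoice.SDA else d.mu_tr_star
    assert rates[0] == pytest.approx(d.mu_eff, rel=1e-14)
    assert rates[1] == pytest.approx(expected_fast, rel=1e-14)


@pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
def test_positivity_on_certified_grid(model):
    for props, fx in certified_grid_points():
        s = fluence_model(props, fx, model)
        z = np.linspace(0.0, 20.0, 1001)
        assert np.all(evaluate_fluence(s, z) >= 0.0)


@pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
def test_depth_concentration_shifts_shallow_with_fx(model, fig2_props):
    """The depth of 50% cumulative phi^2 strictly decreases 0 -> 0.2 -> 0.4
    mm^-1: higher frequencies concentrate photons near the surface."""
    def z50(fx):
        s = fluence_model(fig2_props, fx, model)
        from scipy.optimize import brentq
        return brentq(lambda dd: alpha_partial_volume(s, dd).alpha - 0.5, 1e-6, 50.0)

    zs = [z50(fx) for fx in (0.0, 0.2, 0.4)]
    assert zs[0] > zs[1] > zs[2]


def test_delta_p1_profiles_shallower_than_sda(fig2_props):
    """Both delta-P1 variants put more normalized fluence at the surface
    than the SDA for the reference medium."""
    def surf(model):
        s = fluence_model(fig2_props, 0.0, model)
        total = sum(a / k for a, k in s.terms)
        return evaluate_fluence(s, 0.0) / total

    assert surf(FluenceModelChoice.DELTA_P1) > surf(FluenceModelChoice.SDA)
    assert surf(FluenceModelChoice.MOD_DELTA_P1) > surf(FluenceModelChoice.SDA)


def test_singular_configuration_raises():
    """When mu_eff'(fx) crosses mu_tr* the collected amplitudes blow up; the
    model must refuse rather than return garbage."""
    props = OpticalProperties(0.1, 0.5, 0.7, 1.4)
    d = derive_transport_coefficients(props)
    fx_singular = math.sqrt(d.mu_tr_star**2 - d.mu_eff**2) / (2 * math.pi)
    with pytest.raises(SingularConfigurationError):
        delta_p1_fluence(props, fx_singular)
    with pytest.raises(SingularConfigurationError):
        mod_delta_p1_fluence(props, fx_singular)
    # +1e-6 mm^-1 perturbation moves off the singular point
    delta_p1_fluence(props, fx_singular + 1e-6)


def test_evaluate_fluence_basics():
    one = ExponentialSum(((1.0, 1.0),))
    assert evaluate_fluence(one, 0.0) == 1.0
    assert evaluate_fluence(one, math.log(2)) == pytest.approx(0.5, rel=1e-15)
    two = ExponentialSum(((1.0, 1.0), (-0.5, 2.0)))
    assert evaluate_fluence(two, 0.0) == pytest.approx(0.5)
    with pytest.raises(DomainError):
        evaluate_fluence(one, -1.0)
    with pytest.raises(DomainError):
        ExponentialSum(((1.0, -1.0),))
    with pytest.raises(DomainError):
        ExponentialSum(())


def test_dispatch_accepts_names(fig2_props):
    assert fluence_model(fig2_props, 0.1, "sda") == sda_fluence(fig2_props, 0.1)
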