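"""Closed-form depth-fluence models phi(z, fx)/P0 in the spatial frequency
domain.

Three models are implemented, each returning the same exponential-sum
representation so that downstream partial-volume integrals of phi^2 can be
evaluated analytically:

``sda_fluence``
    Standard diffusion approximation (SDA).  Two decaying exponentials at
    rates mu_tr and mu_eff'(fx), with amplitudes fixed by the particular
    solution of the 1-D diffusion equation and the partial-current boundary
    condition phi(0) = phi'(0) / (3 R mu_tr), R = (1-Reff)/(2(1+Reff)).

``delta_p1_fluence``
    The original spatial-frequency delta-P1 solution (AC diffuse fluence
    only, no collimated term), expanded and collected into two distinct
    rates mu_tr* and mu_eff'(fx).

``mod_delta_p1_fluence``
    The modified delta-P1 solution: delta-P1 governing equations driven by
    a sinusoidally modulated source and closed with the conservation-of-flux
    boundary condition
    [phi_d - (2/(3 mu_tr)) R' dphi_d/dz]_{z=0} = -(2/mu_tr) R' g* mu_s* q0,
    R' = (1+R1)/(1-R1), plus the collimated contribution exp(-mu_tr* z).

All fluences are normalized per unit delivered (post-specular) power P0;
specular reflectance is treated as unity-cancelled by reference-phantom
calibration.

Each model raises :class:`SingularConfigurationError` when mu_eff'(fx)
collides with the exponential source rate (denominators vanish at isolated
fx; perturb fx by ~1e-6 mm^-1 to move off the point).  Outside the
physiological parameter box on which the models are routinely validated
(mu_a in [0.01, 0.1], mu_s' in [0.5, 5], g in [0.7, 0.9], fx in [0, 0.5]),
a cheap positivity scan is run and a warning raised if phi dips negative.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SingularConfigurationError
from .optics_core import (
    DerivedCoefficients,
    OpticalProperties,
    derive_transport_coefficients,
    mu_eff_prime,
)

__all__ = [
    "ExponentialSum",
    "FluenceModelChoice",
    "sda_fluence",
    "delta_p1_fluence",
    "mod_delta_p1_fluence",
    "fluence_model",
    "evaluate_fluence",
    "CERTIFIED_GRID",
]

#: Relative tolerance below which |mu_eff' - rate| counts as singular.
SINGULARITY_EPS = 1e-9

#: Parameter box on which positivity and monotonicity are certified
#: (mu_a, mu_s_prime, g, fx values; n free).
CERTIFIED_GRID = {
    "mu_a": (0.01, 0.1),
    "mu_s_prime": (0.5, 5.0),
    "g": (0.7, 0.9),
    "fx": (0.0, 0.5),
}


@dataclass(frozen=True)
class ExponentialSum:
    """phi(z) = sum_i a_i exp(-k_i z) for z >= 0.

    ``terms`` is an ordered tuple of (amplitude, rate) pairs; every rate is
    strictly positive so the sum decays and phi^2 is integrable on [0, inf).
    """

    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise DomainError("ExponentialSum needs at least one term")
        for a, k in self.terms:
            if not (k > 0 and math.isfinite(k) and math.isfinite(a)):
                raise DomainError(f"invalid exponential term (a={a}, k={k}): rates must be finite and > 0")

    def __call__(self, z):
        return evaluate_fluence(self, z)

    def scaled(self, c: float) -> "ExponentialSum":
        return ExponentialSum(tuple((c * a, k) for a, k in self.terms))


class FluenceModelChoice(enum.Enum):
    """Closed menu of fluence models."""

    SDA = "sda"
    DELTA_P1 = "delta-p1"
    MOD_DELTA_P1 = "mod-delta-p1"


def evaluate_fluence(sum_: ExponentialSum, z):
    """Evaluate phi(z) = sum_i a_i exp(-k_i z); vectorized over z arrays."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise DomainError("depth z must be >= 0")
    out = np.zeros_like(z, dtype=float)
    for a, k in sum_.terms:
        out += a * np.exp(-k * z)
    return out if out.ndim else float(out)


def _check_singular(mu_eff_p: float, rate: float) -> None:
    if abs(mu_eff_p - rate) <= SINGULARITY_EPS * max(rate, 1.0):
        raise SingularConfigurationError(
            f"mu_eff'={mu_eff_p:.9g} mm^-1 collides with the source rate "
            f"{rate:.9g} mm^-1; perturb fx by ~1e-6 mm^-1"
        )


def _inside_certified(props: OpticalProperties, fx: float) -> bool:
    lo, hi = CERTIFIED_GRID["mu_a"]
    if not lo <= props.mu_a <= hi:
        return False
    lo, hi = CERTIFIED_GRID["mu_s_prime"]
    if not lo <= props.mu_s_prime <= hi:
        return False
    lo, hi = CERTIFIED_GRID["g"]
    if not lo <= props.g <= hi:
        return False
    lo, hi = CERTIFIED_GRID["fx"]
    return lo <= fx <= hi


def _warn_if_negative(sum_: ExponentialSum, model: str) -> None:
    z = np.linspace(0.0, 20.0, 41)
    if np.any(evaluate_fluence(sum_, z) < 0):
        warnings.warn(
            f"{model} fluence goes negative on [0, 20] mm outside the "
            "certified parameter box; treat alpha values with caution",
            RuntimeWarning,
            stacklevel=3,
        )


def sda_fluence(props: OpticalProperties, fx: float) -> ExponentialSum:
    """Standard-diffusion-approximation fluence in the SFD.

    phi/P0 = A exp(-mu_tr z) + C exp(-mu_eff' z) with
    A = 3 a' / (mu_eff'^2/mu_tr^2 - 1),  a' = mu_s'/mu_tr,
    C = -A (1 + 3R) / (mu_eff'/mu_tr + 3R),
    R = (1 - Reff) / (2 (1 + Reff)).
    """
    d = derive_transport_coefficients(props)
    mep = mu_eff_prime(d, fx)
    _check_singular(mep, d.mu_tr)
    a_prime = props.mu_s_prime / d.mu_tr
    ratio = mep / d.mu_tr
    big_a = 3.0 * a_prime / (ratio**2 - 1.0)
    big_c = -big_a * (1.0 + 3.0 * d.R_sda) / (ratio + 3.0 * d.R_sda)
    out = ExponentialSum(((big_a, d.mu_tr), (big_c, mep)))
    if not _inside_certified(props, fx):
        _warn_if_negative(out, "SDA")
    return out


def delta_p1_fluence(props: OpticalProperties, fx: float) -> ExponentialSum:
    """Original spatial-frequency delta-P1 AC fluence (no collimated term).

    phi_AC/P0 = C*/(mu_eff' - mu_tr*) [exp(-mu_tr* z) - exp(-mu_eff' z)]
              + C*/(mu_eff' + mu_tr*) [exp(-mu_tr* z) - exp(-mu_eff'(z + 2 zb))]
    with C* = 3 mu_tr mu_s* / (2 mu_eff') and
    zb = (2/(3 mu_tr)) (1 + R1)/(1 - R1), collected into two rates.
    """
    d = derive_transport_coefficients(props)
    mep = mu_eff_prime(d, fx)
    _check_singular(mep, d.mu_tr_star)
    c_star = 3.0 * d.mu_tr * d.mu_s_star / (2.0 * mep)
    zb = (2.0 / (3.0 * d.mu_tr)) * d.R_prime
    t1 = c_star / (mep - d.mu_tr_star)
    t2 = c_star / (mep + d.mu_tr_star)
    amp_tr = t1 + t2
    amp_eff = -t1 - t2 * math.exp(-2.0 * mep * zb)
    out = ExponentialSum(((amp_tr, d.mu_tr_star), (amp_eff, mep)))
    if not _inside_certified(props, fx):
        _warn_if_negative(out, "delta-P1")
    return out


def _mod_delta_p1_diffuse_amplitudes(d: DerivedCoefficients, mep: float) -> tuple[float, float]:
    """(A', C') of the modified delta-P1 diffuse fluence."""
    a_p = 3.0 * d.mu_s_star * (d.mu_tr_star + d.g_star * d.mu_a) / (mep**2 - d.mu_tr_star**2)
    h = 2.0 * d.R_prime / (3.0 * d.mu_tr)
    c_p = -(a_p * (1.0 + h * d.mu_tr_star) + 2.0 * d.R_prime * d.g_star * d.mu_s_star / d.mu_tr) \
        / (1.0 + h * mep)
    return a_p, c_p


def mod_delta_p1_fluence(props: OpticalProperties, fx: float) -> ExponentialSum:
    """Modified delta-P1 fluence: diffuse solution plus collimated term.

    phi/P0 = (1 + A') exp(-mu_tr* z) + C' exp(-mu_eff' z), with A', C'
    fixed by the flux-conservation boundary condition (R' = (1+R1)/(1-R1))
    and the "1" contributed by the collimated component exp(-mu_tr* z).
    """
    d = derive_transport_coefficients(props)
    mep = mu_eff_prime(d, fx)
    _check_singular(mep, d.mu_tr_star)
    a_p, c_p = _mod_delta_p1_diffuse_amplitudes(d, mep)
    out = ExponentialSum(((1.0 + a_p, d.mu_tr_star), (c_p, mep)))
    if not _inside_certified(props, fx):
        _warn_if_negative(out, "mod-delta-P1")
    return out


_DISPATCH = {
    FluenceModelChoice.SDA: sda_fluence,
    FluenceModelChoice.DELTA_P1: delta_p1_fluence,
    FluenceModelChoice.MOD_DELTA_P1: mod_delta_p1_fluence,
}


def fluence_model(props: OpticalProperties, fx: float,
                  model: FluenceModelChoice | str) -> ExponentialSum:
    """Dispatch to one of the three fluence models by choice or name."""
    if isinstance(model, str):
        model = FluenceModelChoice(model)
    return _DISPATCH[model](props, fx)
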