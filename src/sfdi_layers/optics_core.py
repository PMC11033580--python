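"""Domain types and derived radiative-transport coefficients.

All absorption/scattering coefficients are expressed in mm^-1, spatial
frequencies in mm^-1 and depths in mm, throughout the package.

The two boundary-reflection quantities are exposed behind swappable
functions:

``effective_reflection_coefficient``
    Reff(n), the effective reflection coefficient of the diffusion-theory
    partial-current boundary condition, from the published rational
    polynomial approximation ``0.0636 n + 0.668 + 0.710/n - 1.440/n^2``.

``fresnel_first_moment``
    R1(n), the first moment of the unpolarized Fresnel reflection
    coefficient, computed by direct adaptive quadrature of
    ``2 * integral_0^1 R_F(mu) mu dmu`` (cached per n).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from functools import lru_cache

from scipy.integrate import quad

from .errors import DomainError

__all__ = [
    "OpticalProperties",
    "DerivedCoefficients",
    "derive_transport_coefficients",
    "mu_eff_prime",
    "effective_reflection_coefficient",
    "fresnel_first_moment",
]

DEFAULT_G = 0.8
DEFAULT_N = 1.4


@dataclass(frozen=True)
class OpticalProperties:
    """One medium's optical properties at one wavelength band.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1 (>= 0).
    mu_s_prime : float
        Reduced scattering coefficient mu_s * (1 - g), mm^-1 (> 0).
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection angle), in [0, 1).
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s_prime: float
    g: float = DEFAULT_G
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        if not (self.mu_a >= 0 and math.isfinite(self.mu_a)):
            raise DomainError(f"mu_a must be finite and >= 0, got {self.mu_a}")
        if not (self.mu_s_prime > 0 and math.isfinite(self.mu_s_prime)):
            raise DomainError(f"mu_s_prime must be finite and > 0, got {self.mu_s_prime}")
        if not 0 <= self.g < 1:
            raise DomainError(f"g must lie in [0, 1), got {self.g}")
        if not (self.n >= 1 and math.isfinite(self.n)):
            raise DomainError(f"n must be finite and >= 1, got {self.n}")

    @property
    def mu_s(self) -> float:
        """Unreduced scattering coefficient mu_s' / (1 - g), mm^-1."""
        return self.mu_s_prime / (1.0 - self.g)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalProperties":
        return cls(
            mu_a=float(d["mu_a"]),
            mu_s_prime=float(d["mu_s_prime"]),
            g=float(d.get("g", DEFAULT_G)),
            n=float(d.get("n", DEFAULT_N)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "OpticalProperties":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class DerivedCoefficients:
    """Radiative-transport coefficients derived from one OpticalProperties.

    mu_tr = mu_a + mu_s'            transport coefficient, mm^-1
    mu_eff = sqrt(3 mu_a mu_tr)     effective attenuation, mm^-1
    mu_s_star = mu_s (1 - g^2)      delta-P1 reduced scattering, mm^-1
    mu_tr_star = mu_a + mu_s_star   delta-P1 transport coefficient, mm^-1
    g_star = g / (g + 1)            delta-P1 anisotropy
    R_eff, R1                       boundary reflection quantities from n
    R_sda = (1 - Reff)/(2 (1 + Reff))   diffusion boundary constant
    R_prime = (1 + R1)/(1 - R1)         delta-P1 boundary constant
    """

    mu_a: float
    mu_s_prime: float
    g: float
    n: float
    mu_tr: float
    mu_eff: float
    mu_s_star: float
    mu_tr_star: float
    g_star: float
    R_eff: float
    R1: float
    R_sda: float
    R_prime: float


def effective_reflection_coefficient(n: float) -> float:
    """Reff(n) via the published rational-polynomial approximation.

    Reff ~= 0.0636 n + 0.668 + 0.710/n - 1.440/n^2.  At n = 1 the fit
    returns 0.0016 rather than exactly 0 (documented fit residual).
    """
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def _fresnel_unpolarized(mu: float, n: float) -> float:
    """Unpolarized Fresnel reflectance for internal incidence cosine mu,
    medium index n against air (n_out = 1)."""
    if n == 1.0:
        return 0.0
    sin_i = math.sqrt(max(0.0, 1.0 - mu * mu))
    sin_t = n * sin_i
    if sin_t >= 1.0:  # total internal reflection
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    # internal ray (index n) refracting into air
    rs = (n * mu - cos_t) / (n * mu + cos_t)
    rp = (n * cos_t - mu) / (n * cos_t + mu)
    return 0.5 * (rs * rs + rp * rp)


@lru_cache(maxsize=128)
def fresnel_first_moment(n: float) -> float:
    """R1(n) = 2 * integral_0^1 R_F(mu) mu dmu of the unpolarized Fresnel
    reflectance, by adaptive quadrature (exact at n = 1: R1 = 0)."""
    if n == 1.0:
        return 0.0
    critical = math.sqrt(max(0.0, 1.0 - 1.0 / n**2))
    val, _ = quad(lambda mu: 2.0 * _fresnel_unpolarized(mu, n) * mu, 0.0, 1.0,
                  points=[critical], limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


def derive_transport_coefficients(props: OpticalProperties) -> DerivedCoefficients:
    """Compute every derived transport coefficient from one set of optical
    properties.  Pure and deterministic."""
    mu_tr = props.mu_a + props.mu_s_prime
    mu_eff = math.sqrt(3.0 * props.mu_a * mu_tr)
    mu_s = props.mu_s
    mu_s_star = mu_s * (1.0 - props.g**2)
    mu_tr_star = props.mu_a + mu_s_star
    g_star = props.g / (props.g + 1.0)
    r_eff = effective_reflection_coefficient(props.n)
    r1 = fresnel_first_moment(props.n)
    r_sda = (1.0 - r_eff) / (2.0 * (1.0 + r_eff))
    r_prime = (1.0 + r1) / (1.0 - r1)
    return DerivedCoefficients(
        mu_a=props.mu_a, mu_s_prime=props.mu_s_prime, g=props.g, n=props.n,
        mu_tr=mu_tr, mu_eff=mu_eff, mu_s_star=mu_s_star,
        mu_tr_star=mu_tr_star, g_star=g_star,
        R_eff=r_eff, R1=r1, R_sda=r_sda, R_prime=r_prime,
    )


def mu_eff_prime(derived: DerivedCoefficients, fx: float) -> float:
    """Frequency-modified effective attenuation sqrt(mu_eff^2 + (2 pi fx)^2).

    The projected patterns are 1-D sinusoids, so the transverse wavenumber
    is kx = 2 pi fx with ky = 0.  Strictly increasing in fx; equals mu_eff
    at fx = 0.
    """
    if fx < 0:
        raise DomainError(f"fx must be >= 0, got {fx}")
    k = 2.0 * math.pi * fx
    return math.sqrt(derived.mu_eff**2 + k * k)
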