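"""Two-layer modeled scattering coefficient mu_s_mod'(<fx>).

A thin top layer (thickness d, reduced scattering mu_s_top') over a
semi-infinite bottom layer (mu_s_bot'), matched refractive index.  The
homogeneous-equivalent scattering measured on such a target is modeled as
the fluence-squared-weighted linear mixture

    mu_s_mod'(<fx>) = alpha(d, <fx>) mu_s_top' + (1 - alpha) mu_s_bot'

where alpha comes from :mod:`sfdi_layers.partial_volume` with the fluence
computed — per the multi-frequency processing pipeline — from the
per-sub-set homogeneous-equivalent (mu_a, mu_s') measured on the layered
target itself, not from the layer properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError
from .fluence_models import FluenceModelChoice, fluence_model
from .optics_core import OpticalProperties
from .partial_volume import alpha_partial_volume

__all__ = ["TwoLayerPhantom", "ModelSeries", "modeled_scattering", "model_curve"]


@dataclass(frozen=True)
class TwoLayerPhantom:
    """Thin layer of thickness d (mm) on a semi-infinite substrate.

    Both layers must share the refractive index (matched-boundary
    assumption); the three free model parameters are d, top.mu_s_prime and
    bottom.mu_s_prime.
    """

    d: float
    top: OpticalProperties
    bottom: OpticalProperties
    label: str = ""

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise DomainError(f"top-layer thickness d must be > 0, got {self.d}")
        if self.top.n != self.bottom.n:
            raise DomainError(
                f"matched-index assumption violated: top n={self.top.n}, bottom n={self.bottom.n}")


@dataclass(frozen=True)
class ModelSeries:
    """Modeled scattering curve: (fx_mean, alpha, mu_s_mod) per sub-set."""

    model: FluenceModelChoice
    entries: tuple[tuple[float, float, float], ...]
    phantom_label: str = ""

    def __post_init__(self) -> None:
        fx = [e[0] for e in self.entries]
        if fx != sorted(fx):
            raise DomainError("ModelSeries entries must be sorted by fx_mean")

    @property
    def fx_means(self) -> list[float]:
        return [e[0] for e in self.entries]

    @property
    def alphas(self) -> list[float]:
        return [e[1] for e in self.entries]

    @property
    def mu_s_mod(self) -> list[float]:
        return [e[2] for e in self.entries]

    def to_frame(self, phantom: TwoLayerPhantom | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["fx_mean", "alpha", "mu_s_mod"])
        df.insert(0, "model", self.model.value)
        df.insert(0, "phantom_label", self.phantom_label)
        if phantom is not None:
            df["mu_s_top"] = phantom.top.mu_s_prime
            df["mu_s_bot"] = phantom.bottom.mu_s_prime
            df["d"] = phantom.d
        return df


def modeled_scattering(phantom: TwoLayerPhantom, homog_props: OpticalProperties,
                       fx_mean: float, model: FluenceModelChoice) -> tuple[float, float]:
    """One point of the two-layer curve: (alpha, mu_s_mod) at <fx>.

    ``homog_props`` are the homogeneous-equivalent properties estimated on
    the layered target for this sub-set (the fluence inputs), NOT the layer
    properties.
    """
    phi = fluence_model(homog_props, fx_mean, model)
    res = alpha_partial_volume(phi, phantom.d, fx=fx_mean, model=model)
    a = res.alpha
    mu_s_mod = a * phantom.top.mu_s_prime + (1.0 - a) * phantom.bottom.mu_s_prime
    lo = min(phantom.top.mu_s_prime, phantom.bottom.mu_s_prime)
    hi = max(phantom.top.mu_s_prime, phantom.bottom.mu_s_prime)
    assert lo <= mu_s_mod <= hi, "mu_s_mod escaped the layer-value interval"
    return a, mu_s_mod


def model_curve(phantom: TwoLayerPhantom, measurement, model: FluenceModelChoice) -> ModelSeries:
    """Evaluate the modeled curve at every sub-set of a measurement series.

    ``measurement`` is a :class:`~sfdi_layers.sfd_processing.MeasurementSeries`
    (or anything exposing ``entries`` of (fx_mean, mu_a, mu_s_prime)); g and
    n for the fluence come from the phantom's top-layer configuration since
    SFDI does not measure them.
    """
    entries = getattr(measurement, "entries", measurement)
    if len(entries) == 0:
        raise DomainError("measurement series is empty")
    out = []
    for fx_mean, mu_a, mu_s_prime in entries:
        props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s_prime,
                                  g=phantom.top.g, n=phantom.top.n)
        a, mu_s_mod = modeled_scattering(phantom, props, fx_mean, model)
        out.append((fx_mean, a, mu_s_mod))
    return ModelSeries(model=model, entries=tuple(out), phantom_label=phantom.label)
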