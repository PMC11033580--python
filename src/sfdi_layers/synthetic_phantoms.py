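"""Synthetic layered-phantom suite and acquisition emulator.

Emulates the physical validation set used to develop the method: a TiO2
(high-scattering, "new epithelium") thin layer in five thicknesses over an
Al2O3 ("wound bed") semi-infinite substrate, characterized at three visible
spectral bands, imaged with three-phase sinusoidal patterns at 11 spatial
frequencies (0 to 0.5 mm^-1 in 0.05 steps).

Three generators are provided:

``make_phantom_suite``
    the phantom specification (thicknesses + per-band layer properties);

``simulate_measurement_series``
    a self-consistent per-sub-set measurement curve built from the
    two-layer mixing model and a homogeneous-equivalent fixed point
    (a synthetic stand-in for processed instrument measurements);

``synthesize_pattern_stack``
    raw three-phase images with controlled noise, in the same in-memory
    (and on-disk) format the processing module consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, GeneratorError
from .fluence_models import FluenceModelChoice, fluence_model
from .layered_model import TwoLayerPhantom
from .optics_core import DEFAULT_G, DEFAULT_N, OpticalProperties
from .partial_volume import alpha_partial_volume
from .sfd_processing import (
    PHASES_DEG,
    FrequencyGrid,
    MeasurementSeries,
    ReflectanceStack,
    SubsetWindow,
    default_frequency_grid,
    split_subsets,
)

__all__ = [
    "PhantomSuite",
    "NoiseSpec",
    "make_phantom_suite",
    "simulate_measurement_series",
    "synthesize_pattern_stack",
    "THICKNESSES_MM",
    "LAYER_PROPERTIES",
]

#: top-layer thicknesses of the five thin TiO2 phantoms, mm
THICKNESSES_MM = (0.130, 0.269, 0.490, 0.675, 1.149)

#: (mu_a, mu_s_prime) per wavelength band, mm^-1 — thick-phantom characterization
LAYER_PROPERTIES = {
    "458": {"top": (0.0322, 3.4319), "bottom": (0.0215, 0.8675)},
    "536": {"top": (0.0370, 2.9269), "bottom": (0.0226, 0.8322)},
    "626": {"top": (0.0427, 2.3436), "bottom": (0.0242, 0.7830)},
}


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition noise: I -> I (1 + eps_mult) + eps_add, both Gaussian.

    Default 1% multiplicative noise is a testing convention, not an
    instrument characterization.  The seed is recorded in every output.
    """

    multiplicative_sigma: float = 0.01
    additive_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sigma < 0 or self.additive_sigma < 0:
            raise DomainError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class PhantomSuite:
    """Five two-layer phantoms x three wavelength bands."""

    thicknesses: tuple[float, ...]
    wavelength_labels: tuple[str, ...]
    top_batch: dict[str, OpticalProperties]
    bottom_batch: dict[str, OpticalProperties]

    def phantom(self, index: int, band: str) -> TwoLayerPhantom:
        """TwoLayerPhantom for thin-phantom ``index`` (0-based) at ``band``."""
        return TwoLayerPhantom(
            d=self.thicknesses[index],
            top=self.top_batch[band],
            bottom=self.bottom_batch[band],
            label=f"phantom{index + 1}",
        )

    def phantoms(self) -> dict[tuple[str, str], TwoLayerPhantom]:
        """All (phantom_label, band) -> TwoLayerPhantom."""
        return {(f"phantom{i + 1}", band): self.phantom(i, band)
                for i in range(len(self.thicknesses))
                for band in self.wavelength_labels}


def make_phantom_suite(thickness_overrides: dict[int, float] | None = None,
                       g: float = DEFAULT_G, n: float = DEFAULT_N) -> PhantomSuite:
    """Default suite with the characterized thicknesses and layer properties.

    ``thickness_overrides`` maps 0-based phantom index -> thickness in mm;
    g and n are configuration defaults (not measured by SFDI).
    """
    thicknesses = list(THICKNESSES_MM)
    for idx, d in (thickness_overrides or {}).items():
        thicknesses[idx] = d
    top = {band: OpticalProperties(*vals["top"], g=g, n=n)
           for band, vals in LAYER_PROPERTIES.items()}
    bottom = {band: OpticalProperties(*vals["bottom"], g=g, n=n)
              for band, vals in LAYER_PROPERTIES.items()}
    return PhantomSuite(
        thicknesses=tuple(thicknesses),
        wavelength_labels=tuple(LAYER_PROPERTIES),
        top_batch=top,
        bottom_batch=bottom,
    )


def _fixed_point_homog(phantom: TwoLayerPhantom, fx_mean: float,
                       model: FluenceModelChoice,
                       tol: float = 1e-8, max_iter: int = 100):
    """Self-consistent homogeneous-equivalent (mu_a, mu_s', alpha, mu_s_mod).

    Iterates: fluence from current (mu_a, mu_s') -> alpha from d ->
    alpha-weighted layer mixing for both coefficients, until the update is
    below ``tol``.  Synthetic closure rule, not a physical layered model.
    """
    mu_a = 0.5 * (phantom.top.mu_a + phantom.bottom.mu_a)
    mu_s = 0.5 * (phantom.top.mu_s_prime + phantom.bottom.mu_s_prime)
    for _ in range(max_iter):
        props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s,
                                  g=phantom.top.g, n=phantom.top.n)
        phi = fluence_model(props, fx_mean, model)
        a = alpha_partial_volume(phi, phantom.d, fx=fx_mean, model=model).alpha
        mu_s_new = a * phantom.top.mu_s_prime + (1 - a) * phantom.bottom.mu_s_prime
        mu_a_new = a * phantom.top.mu_a + (1 - a) * phantom.bottom.mu_a
        if abs(mu_s_new - mu_s) < tol and abs(mu_a_new - mu_a) < tol:
            return mu_a_new, mu_s_new, a, mu_s_new
        mu_a, mu_s = mu_a_new, mu_s_new
    raise GeneratorError(
        f"homogeneous-equivalent fixed point did not converge at fx={fx_mean} "
        f"(d={phantom.d} mm, model={model.value})")


def simulate_measurement_series(phantom: TwoLayerPhantom,
                                grid: FrequencyGrid | None = None,
                                model: FluenceModelChoice = FluenceModelChoice.MOD_DELTA_P1,
                                homog_props_rule=None,
                                window: int = 4) -> tuple[MeasurementSeries, list[dict]]:
    """Per-sub-set synthetic measurement curve with its generating record.

    Returns (series, ground_truth); ground_truth holds one dict per sub-set
    with the generating alpha and mu_s_mod so round-trip tests can compare.
    ``homog_props_rule``, if given, maps fx_mean -> (mu_a, mu_s') and
    replaces the default fixed-point closure.
    """
    grid = grid or default_frequency_grid()
    entries, truth = [], []
    for win in split_subsets(grid, window=window):
        fxm = win.fx_mean
        if homog_props_rule is not None:
            mu_a, mu_s = homog_props_rule(fxm)
            props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s,
                                      g=phantom.top.g, n=phantom.top.n)
            phi = fluence_model(props, fxm, model)
            a = alpha_partial_volume(phi, phantom.d, fx=fxm, model=model).alpha
            mu_s_mod = a * phantom.top.mu_s_prime + (1 - a) * phantom.bottom.mu_s_prime
        else:
            mu_a, mu_s, a, mu_s_mod = _fixed_point_homog(phantom, fxm, model)
        entries.append((fxm, mu_a, mu_s))
        truth.append({"fx_mean": fxm, "alpha": a, "mu_s_mod": mu_s_mod,
                      "model": model.value, "d": phantom.d})
    return MeasurementSeries(entries=tuple(entries)), truth


def synthesize_pattern_stack(rd_per_frequency, grid: FrequencyGrid,
                             noise: NoiseSpec | None = None,
                             image_shape: tuple[int, int] = (64, 64),
                             pixel_size_mm: float = 0.4,
                             source_intensity: float = 1000.0,
                             wavelength_label: str = "") -> tuple[ReflectanceStack, dict]:
    """Raw three-phase pattern images for a target of known Rd(fx).

    I_k(x) = S * 0.5 * Rd * (1 + cos(2 pi fx x pitch + phi_k)) with the
    modulation along image columns; fx = 0 frames follow the same formula
    (spatially flat, phase-sampled).  Returns the stack plus a ground-truth
    record (Rd values, frequencies, seed).
    """
    noise = noise or NoiseSpec(multiplicative_sigma=0.0)
    rd = np.atleast_1d(np.asarray(rd_per_frequency, dtype=float))
    if rd.shape[0] != len(grid):
        raise DomainError(f"need one Rd per frequency: got {rd.shape[0]} for {len(grid)}")
    h, w = image_shape
    nonzero = [f for f in grid.frequencies if f > 0]
    if nonzero:
        period_px = 1.0 / (min(nonzero) * pixel_size_mm)
        if w < period_px:
            raise DomainError(
                f"image width {w} px cannot hold one period ({period_px:.1f} px) "
                f"of fx={min(nonzero)} mm^-1 at {pixel_size_mm} mm/px")
    rng = np.random.default_rng(noise.seed)
    x_mm = np.arange(w) * pixel_size_mm
    images: dict[int, np.ndarray] = {}
    for i, fx in enumerate(grid.frequencies):
        frames = []
        for phase_deg in PHASES_DEG:
            pattern = 1.0 + np.cos(2.0 * math.pi * fx * x_mm + math.radians(phase_deg))
            frame = source_intensity * 0.5 * rd[i] * np.broadcast_to(pattern, (h, w)).copy()
            if noise.multiplicative_sigma > 0:
                frame = frame * (1.0 + rng.normal(0.0, noise.multiplicative_sigma, (h, w)))
            if noise.additive_sigma > 0:
                frame = frame + rng.normal(0.0, noise.additive_sigma, (h, w))
            frames.append(frame)
        images[i] = np.stack(frames)
    stack = ReflectanceStack(grid=grid, images=images,
                             wavelength_label=wavelength_label,
                             pixel_size_mm=pixel_size_mm)
    truth = {
        "rd": [float(v) for v in rd],
        "frequencies_mm^-1": list(grid.frequencies),
        "seed": noise.seed,
        "multiplicative_sigma": noise.multiplicative_sigma,
        "additive_sigma": noise.additive_sigma,
        "source_intensity": source_intensity,
        "pixel_size_mm": pixel_size_mm,
        "image_shape": list(image_shape),
    }
    return stack, truth
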