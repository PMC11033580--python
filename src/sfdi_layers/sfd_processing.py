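"""Raw pattern images -> calibrated diffuse reflectance -> per-sub-set
homogeneous-equivalent optical properties.

The multi-frequency pipeline:

1. three-phase demodulation of each spatial frequency's pattern images to
   an AC amplitude map (:func:`demodulate_ac`);
2. calibration against a reference phantom of known properties to diffuse
   reflectance Rd (:func:`calibrate_rd`), using the closed-form diffusion
   forward model (:func:`forward_rd`);
3. subdivision of the frequency grid into overlapping sub-sets
   (:func:`split_subsets`), each processed as if homogeneous
   (:func:`invert_homogeneous`) to give one (mu_a, mu_s') per sub-set.

The forward Rd model is the standard spatial-frequency-domain diffusion
reflectance; a tabulated Rd model (e.g. white Monte Carlo output) can be
plugged in through :class:`RdLookupTable` wherever a ``forward`` callable
is accepted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .errors import CalibrationError, DomainError, InversionError
from .optics_core import (
    OpticalProperties,
    derive_transport_coefficients,
    mu_eff_prime,
)

__all__ = [
    "FrequencyGrid",
    "SubsetWindow",
    "ReflectanceStack",
    "MeasurementSeries",
    "InversionResult",
    "RdLookupTable",
    "split_subsets",
    "demodulate_ac",
    "demodulate_dc",
    "calibrate_rd",
    "forward_rd",
    "invert_homogeneous",
    "penetration_depth",
    "roi_mean",
    "default_frequency_grid",
]

#: three-phase convention: equally spaced offsets, degrees
PHASES_DEG = (0.0, 120.0, 240.0)

#: inversion bounds, mm^-1
MU_A_BOUNDS = (1e-4, 1.0)
MU_S_PRIME_BOUNDS = (0.05, 10.0)
DEFAULT_INIT = (0.01, 1.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing spatial frequencies, mm^-1."""

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        f = self.frequencies
        if any(x < 0 for x in f):
            raise DomainError("spatial frequencies must be >= 0")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise DomainError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies)


def default_frequency_grid() -> FrequencyGrid:
    """The standard 11-frequency acquisition grid: 0 to 0.5 mm^-1 in 0.05 steps."""
    return FrequencyGrid(tuple(round(0.05 * i, 10) for i in range(11)))


@dataclass(frozen=True)
class SubsetWindow:
    """One contiguous group of frequencies with its mean <fx>."""

    indices: tuple[int, ...]
    fx_values: tuple[float, ...]

    @property
    def fx_mean(self) -> float:
        return float(np.mean(self.fx_values))


@dataclass
class ReflectanceStack:
    """Per-frequency three-phase images plus derived AC / Rd maps.

    ``images`` maps frequency index -> array of shape (3, H, W); ``ac`` and
    ``rd`` map frequency index -> (H, W).  Metadata records the wavelength
    band, the phase offsets and the pixel pitch in mm.
    """

    grid: FrequencyGrid
    images: dict[int, np.ndarray]
    ac: dict[int, np.ndarray] = field(default_factory=dict)
    rd: dict[int, np.ndarray] = field(default_factory=dict)
    wavelength_label: str = ""
    phases_deg: tuple[float, ...] = PHASES_DEG
    pixel_size_mm: float = 0.4
    clip_warnings: int = 0


@dataclass(frozen=True)
class MeasurementSeries:
    """Per-sub-set homogeneous-equivalent properties: (fx_mean, mu_a, mu_s')."""

    entries: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        fx = [e[0] for e in self.entries]
        if fx != sorted(fx):
            raise DomainError("MeasurementSeries entries must be sorted by fx_mean")
        for _, mu_a, mu_s in self.entries:
            if mu_a <= 0 or mu_s <= 0:
                raise DomainError("per-sub-set coefficients must be > 0")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["fx_mean", "mu_a", "mu_s_prime"])


def split_subsets(grid: FrequencyGrid, window: int = 4, stride: int = 1) -> list[SubsetWindow]:
    """Contiguous overlapping windows over the frequency grid.

    11 frequencies with window 4 and stride 1 give the 8 sub-sets of the
    multi-frequency scheme.
    """
    n = len(grid)
    if window < 2:
        raise DomainError(f"window must be >= 2, got {window}")
    if n < window:
        raise DomainError(f"grid of {n} frequencies is shorter than window {window}")
    if stride < 1:
        raise DomainError(f"stride must be >= 1, got {stride}")
    out = []
    for start in range(0, n - window + 1, stride):
        idx = tuple(range(start, start + window))
        out.append(SubsetWindow(indices=idx,
                                fx_values=tuple(grid.frequencies[i] for i in idx)))
    return out


def demodulate_ac(images: np.ndarray) -> np.ndarray:
    """Three-phase AC amplitude: (sqrt2/3) sqrt(sum of squared pairwise diffs).

    ``images`` has shape (3, H, W) with phase offsets 0/120/240 degrees.
    Exact for noise-free sinusoids and independent of the DC offset.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] != 3:
        raise DomainError(f"expected 3 phase images stacked on axis 0, got shape {images.shape}")
    i1, i2, i3 = images
    return (math.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2)


def demodulate_dc(images: np.ndarray) -> np.ndarray:
    """Planar (fx = 0) convention: average the three frames.

    For frames synthesized as 0.5 Rd (1 + cos(phi_k)) the phase terms cancel
    and the average equals the 0.5 Rd amplitude scale of the AC channel.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] != 3:
        raise DomainError(f"expected 3 phase images stacked on axis 0, got shape {images.shape}")
    return images.mean(axis=0)


def forward_rd(props: OpticalProperties, fx: float) -> float:
    """Closed-form diffusion diffuse reflectance in the SFD.

    Rd(fx) = 3 A a' / ((mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3 A)) with
    A = (1 - Reff)/(2 (1 + Reff)) and a' = mu_s'/mu_tr.  Strictly
    decreasing in fx; in (0, 1) for physical properties.
    """
    if fx < 0:
        raise DomainError(f"fx must be >= 0, got {fx}")
    d = derive_transport_coefficients(props)
    ratio = mu_eff_prime(d, fx) / d.mu_tr
    a_prime = props.mu_s_prime / d.mu_tr
    return 3.0 * d.R_sda * a_prime / ((ratio + 1.0) * (ratio + 3.0 * d.R_sda))


class RdLookupTable:
    """Tabulated Rd(mu_a, mu_s', fx) plug-in (e.g. white Monte Carlo output).

    Built from a long-format CSV with columns mu_a, mu_s_prime, fx, rd on a
    full rectangular grid; callable with the same signature as
    :func:`forward_rd`.
    """

    def __init__(self, table: pd.DataFrame, g: float = 0.8, n: float = 1.4):
        need = {"mu_a", "mu_s_prime", "fx", "rd"}
        if not need.issubset(table.columns):
            raise DomainError(f"lookup table must have columns {sorted(need)}")
        mu_a = np.sort(table["mu_a"].unique())
        mu_s = np.sort(table["mu_s_prime"].unique())
        fx = np.sort(table["fx"].unique())
        pivot = (table.set_index(["mu_a", "mu_s_prime", "fx"])["rd"]
                 .sort_index())
        if len(pivot) != len(mu_a) * len(mu_s) * len(fx):
            raise DomainError("lookup table is not a full rectangular grid")
        values = pivot.to_numpy().reshape(len(mu_a), len(mu_s), len(fx))
        self._interp = RegularGridInterpolator((mu_a, mu_s, fx), values,
                                               bounds_error=True)
        self.g, self.n = g, n

    @classmethod
    def from_csv(cls, path, **kw) -> "RdLookupTable":
        return cls(pd.read_csv(path, comment="#"), **kw)

    def __call__(self, props: OpticalProperties, fx: float) -> float:
        return float(self._interp([props.mu_a, props.mu_s_prime, fx])[0])


def calibrate_rd(ac_sample: np.ndarray, ac_reference: np.ndarray,
                 ref_props: OpticalProperties, fx: float,
                 forward=forward_rd, max_bad_fraction: float = 0.05,
                 clip: bool = True) -> np.ndarray:
    """Reference-phantom calibration: Rd = (AC_sample/AC_ref) Rd_model(ref).

    Raises :class:`CalibrationError` when more than ``max_bad_fraction`` of
    reference pixels are non-positive; out-of-[0, 1] results are clipped
    with a warning counting the affected pixels.
    """
    ac_sample = np.asarray(ac_sample, dtype=float)
    ac_reference = np.asarray(ac_reference, dtype=float)
    if ac_sample.shape != ac_reference.shape:
        raise DomainError(f"shape mismatch: sample {ac_sample.shape} vs reference {ac_reference.shape}")
    bad = ac_reference <= 0
    if bad.mean() > max_bad_fraction:
        raise CalibrationError(
            f"{bad.mean():.1%} of reference pixels non-positive (limit {max_bad_fraction:.0%})")
    rd_ref = forward(ref_props, fx)
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = np.where(bad, np.nan, ac_sample / np.where(bad, 1.0, ac_reference) * rd_ref)
    n_out = int(np.sum((rd < 0) | (rd > 1)))
    if clip and n_out:
        warnings.warn(f"clipped {n_out} Rd pixels outside [0, 1]", RuntimeWarning,
                      stacklevel=2)
        rd = np.clip(rd, 0.0, 1.0)
    return rd


@dataclass(frozen=True)
class InversionResult:
    mu_a: float
    mu_s_prime: float
    residual_norm: float
    boundary_pinned: bool
    n_frequencies: int


def invert_homogeneous(rd_values, fx_values, g: float = 0.8, n: float = 1.4,
                       init: tuple[float, float] | None = None,
                       forward=forward_rd) -> InversionResult:
    """Fit (mu_a, mu_s') of the homogeneous forward Rd model to measured Rd.

    Bounded trust-region least squares (mu_a in [1e-4, 1], mu_s' in
    [0.05, 10] mm^-1), deterministic for a given ``init`` (default
    mu_a = 0.01, mu_s' = 1).  Order of frequencies is immaterial.
    """
    rd_values = np.asarray(rd_values, dtype=float)
    fx_values = np.asarray(fx_values, dtype=float)
    if rd_values.shape != fx_values.shape or rd_values.ndim != 1:
        raise DomainError("rd_values and fx_values must be 1-D and aligned")
    if len(rd_values) < 2:
        raise DomainError("need Rd at >= 2 frequencies to separate mu_a from mu_s'")
    if np.any((rd_values <= 0) | (rd_values >= 1)):
        raise DomainError("measured Rd must lie strictly in (0, 1)")
    x0 = np.array(init if init is not None else DEFAULT_INIT, dtype=float)

    def resid(x):
        props = OpticalProperties(mu_a=x[0], mu_s_prime=x[1], g=g, n=n)
        model = np.array([forward(props, f) for f in fx_values])
        return model - rd_values

    lo = np.array([MU_A_BOUNDS[0], MU_S_PRIME_BOUNDS[0]])
    hi = np.array([MU_A_BOUNDS[1], MU_S_PRIME_BOUNDS[1]])
    sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise InversionError(f"least-squares failed: {sol.message}; "
                             f"residual norm {np.linalg.norm(sol.fun):.3g}")
    pinned = bool(np.any(np.isclose(sol.x, lo, rtol=1e-6)) or
                  np.any(np.isclose(sol.x, hi, rtol=1e-6)))
    return InversionResult(mu_a=float(sol.x[0]), mu_s_prime=float(sol.x[1]),
                           residual_norm=float(np.linalg.norm(sol.fun)),
                           boundary_pinned=pinned, n_frequencies=len(rd_values))


def penetration_depth(props: OpticalProperties, fx_mean: float) -> float:
    """Characteristic depth delta = 1/mu_eff'(<fx>), mm.

    A conventional estimate of how deep the modulated light samples;
    strictly decreasing in fx_mean.
    """
    d = derive_transport_coefficients(props)
    return 1.0 / mu_eff_prime(d, fx_mean)


def roi_mean(image: np.ndarray, fraction: float = 0.25) -> float:
    """Spatial mean over a centred rectangle covering ``fraction`` of the
    image area (homogeneous-target convention)."""
    if not 0 < fraction <= 1:
        raise DomainError(f"ROI fraction must be in (0, 1], got {fraction}")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    scale = math.sqrt(fraction)
    dh, dw = max(1, round(h * scale)), max(1, round(w * scale))
    r0, c0 = (h - dh) // 2, (w - dw) // 2
    return float(np.nanmean(image[r0:r0 + dh, c0:c0 + dw]))


def process_stack(sample: ReflectanceStack, reference: ReflectanceStack,
                  ref_props: OpticalProperties, window: int = 4, stride: int = 1,
                  g: float = 0.8, n: float = 1.4, roi_fraction: float = 0.25,
                  forward=forward_rd) -> MeasurementSeries:
    """Full homogeneous-processing chain on a pair of stacks.

    Demodulates (AC, or the planar DC convention at fx = 0), calibrates
    against the reference, ROI-averages each Rd map and inverts each
    frequency sub-set; returns one (fx_mean, mu_a, mu_s') per sub-set.
    """
    if sample.grid.frequencies != reference.grid.frequencies:
        raise DomainError("sample and reference stacks have different frequency grids")
    rd_mean: dict[int, float] = {}
    for i, fx in enumerate(sample.grid.frequencies):
        demod = demodulate_dc if fx == 0 else demodulate_ac
        ac_s = demod(sample.images[i])
        ac_r = demod(reference.images[i])
        rd_map = calibrate_rd(ac_s, ac_r, ref_props, fx, forward=forward)
        sample.ac[i] = ac_s
        sample.rd[i] = rd_map
        rd_mean[i] = roi_mean(rd_map, roi_fraction)
    entries = []
    for win in split_subsets(sample.grid, window=window, stride=stride):
        rd = [rd_mean[i] for i in win.indices]
        fit = invert_homogeneous(rd, win.fx_values, g=g, n=n, forward=forward)
        entries.append((win.fx_mean, fit.mu_a, fit.mu_s_prime))
    return MeasurementSeries(entries=tuple(entries))
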