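"""Model-vs-measurement scoring: RMSPE and comparison tables.

RMSPE = sqrt( (1/N) sum_i ((meas_i - mod_i)/meas_i)^2 ) * 100 over the N
sub-set frequency means; scale- and permutation-invariant over aligned
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .fluence_models import FluenceModelChoice
from .layered_model import TwoLayerPhantom, model_curve
from .optics_core import OpticalProperties

__all__ = ["ComparisonRecord", "rmspe", "scattering_contrast", "compare_models"]


@dataclass(frozen=True)
class ComparisonRecord:
    model: FluenceModelChoice
    phantom_label: str
    wavelength_label: str
    contrast: float
    rmspe: float
    n_points: int


def rmspe(measured, modeled) -> float:
    """Root-mean-square percentage error, percent applied outside the root."""
    measured = np.asarray(measured, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    if measured.shape != modeled.shape or measured.ndim != 1 or len(measured) < 1:
        raise DomainError("measured and modeled must be aligned non-empty 1-D series")
    if np.any(measured == 0):
        raise DomainError("measured values must be nonzero for a percentage error")
    rel = (measured - modeled) / measured
    return float(np.sqrt(np.mean(rel**2)) * 100.0)


def scattering_contrast(top: OpticalProperties, bottom: OpticalProperties) -> float:
    """Layer scattering contrast mu_s_top' / mu_s_bot'."""
    if bottom.mu_s_prime == 0:
        raise DomainError("bottom mu_s_prime must be nonzero")
    return top.mu_s_prime / bottom.mu_s_prime


def compare_models(phantom_suite, measurement_sets, models) -> list[ComparisonRecord]:
    """Score every model on every (phantom, wavelength) measurement set.

    ``phantom_suite`` maps (phantom_label, wavelength_label) ->
    TwoLayerPhantom and ``measurement_sets`` maps the same keys to
    MeasurementSeries; one record per model x phantom x wavelength.
    """
    records = []
    for key, phantom in phantom_suite.items():
        if key not in measurement_sets:
            continue
        series = measurement_sets[key]
        measured = [mu_s for _, _, mu_s in series.entries]
        for model in models:
            curve = model_curve(phantom, series, model)
            records.append(ComparisonRecord(
                model=model,
                phantom_label=key[0],
                wavelength_label=key[1],
                contrast=scattering_contrast(phantom.top, phantom.bottom),
                rmspe=rmspe(measured, curve.mu_s_mod),
                n_points=len(measured),
            ))
    return records


def records_to_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model": r.model.value, "phantom_label": r.phantom_label,
        "wavelength_label": r.wavelength_label, "contrast": r.contrast,
        "rmspe": r.rmspe, "n_points": r.n_points,
    } for r in records])
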