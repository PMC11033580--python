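"""Two-layer modeled scattering curves for the built-in phantom suite.

For each thin-layer thickness the modeled mu_s' starts near the bottom
layer's value at low mean spatial frequency and climbs toward the top
layer's value as frequency (and hence surface weighting) increases;
thicker layers sit closer to the top-layer value everywhere.
"""

from sfdi_layers import (
    FluenceModelChoice,
    MeasurementSeries,
    OpticalProperties,
    make_phantom_suite,
    model_curve,
    default_frequency_grid,
    split_subsets,
)

suite = make_phantom_suite()
band = "536"
top = suite.top_batch[band]
bot = suite.bottom_batch[band]
print(f"{band} nm layers: mu_s_top'={top.mu_s_prime} mm^-1, "
      f"mu_s_bot'={bot.mu_s_prime} mm^-1")

# constant homogeneous-equivalent properties stand in for per-sub-set
# measurements here; the processing pipeline supplies real ones
fx_means = [w.fx_mean for w in split_subsets(default_frequency_grid(), window=4)]
series = MeasurementSeries(tuple((f, 0.03, 1.5) for f in fx_means))

model = FluenceModelChoice.MOD_DELTA_P1
print(f"\nmu_s_mod'(<fx>) per thickness, {model.value} model (mm^-1)")
print("  <fx>: " + "".join(f"{f:>8.3f}" for f in fx_means))
for i, d in enumerate(suite.thicknesses):
    curve = model_curve(suite.phantom(i, band), series, model)
    print(f"d={d:5.3f}" + "".join(f"{v:>8.3f}" for v in curve.mu_s_mod))
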