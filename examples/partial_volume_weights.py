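"""Tabulate the top-layer weight alpha(d, fx).

alpha is the fraction of the fluence-squared (photon hitting density)
integral contained in the top d millimetres: the mixing weight of the
two-layer scattering model.  It grows with both layer thickness and
spatial frequency — high-frequency patterns barely see past a few tenths
of a millimetre.
"""

from sfdi_layers import FluenceModelChoice, OpticalProperties, alpha_partial_volume, fluence_model

props = OpticalProperties(mu_a=0.05, mu_s_prime=5.0, g=0.8, n=1.4)
model = FluenceModelChoice.MOD_DELTA_P1
thicknesses = (0.130, 0.269, 0.490, 0.675, 1.149)

print(f"alpha(d, fx) for the {model.value} fluence model")
header = "fx (mm^-1)" + "".join(f"  d={d:>5.3f}" for d in thicknesses)
print(header)
for fx in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
    phi = fluence_model(props, fx, model)
    row = "".join(f"  {alpha_partial_volume(phi, d).alpha:7.3f}" for d in thicknesses)
    print(f"{fx:>10.2f}{row}")
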