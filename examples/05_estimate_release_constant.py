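"""Estimate the Higuchi release constant from ointment-base properties.

The closed form kH = sqrt(2 * Cini * D * Cs) (initial drug loading,
diffusion coefficient in the base, solubility in the base) gives an a
priori estimate to compare with in-vivo fitted values.
"""

from ocupbpk import siepmann_khiguchi

# fluorometholone, 0.1% loading, lanolin-base diffusion estimate
kh_flm = siepmann_khiguchi(c_ini=1.0, diffusion_coeff=9.6e-9, c_s=0.0155)
fitted = 2.7e-6
print(f"fluorometholone: estimated kH = {kh_flm:.3g} mg/(s^1/2 cm^2)")
print(f"                 in-vivo fitted kH = {fitted:.1e}; "
      f"estimate is {kh_flm / fitted:.1f}x larger")
print("  -> liquid-solute diffusion coefficients overestimate release of a")
print("     drug that sits in the solid state inside a petrolatum base.")

# 6% acyclovir with a literature diffusion coefficient
kh_acv = siepmann_khiguchi(c_ini=60.0, diffusion_coeff=5.6e-8, c_s=1.4)
print(f"acyclovir 6%:    estimated kH = {kh_acv:.3g} mg/(s^1/2 cm^2)")
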