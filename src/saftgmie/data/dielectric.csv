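# Solvent coefficients of the density/temperature-explicit relative static
# permittivity model D = 1 + rho_solv * d_V * (d_T / T - 1).
# Water values fitted in this package to the static permittivity of saturated
# liquid water (87.90 at 273.15 K, 78.41 at 298.15 K, 55.58 at 373.15 K)
# using liquid densities from the present equation of state at 1 bar.
solvent,d_V_A3,d_T_K
water,588.02,1480.90
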