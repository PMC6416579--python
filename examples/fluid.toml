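# Maghemite / mineral-oil magnetic fluid, characterized by fluid magnetometry
# (M_s_fluid) and TEM sizing.  Carrier viscosity/density points are a
# surrogate triple for a mineral-oil carrier, not measured data.

[material]
M_d = "400 kA/m"
rho_m = "4860 kg/m^3"
M_s_fluid = "42.3 kA/m"

[groups]
grid = { d_min = "3.5 nm", d_max = "14.5 nm", step = "1 nm" }
distribution = { anchor_d = "7.5 nm", anchor_phi_percent = 1.611 }

[carrier]
viscosity_T_C = [20.0, 40.0, 60.0]
viscosity = ["75 mPa.s", "40 mPa.s", "24 mPa.s"]
density_T_C = [20.0, 40.0, 60.0]
density = [1105.0, 1090.0, 1075.0]

[field]
H = ["4.3 kA/m"]
f = ["395 kHz"]
mode = "alternating"

[options]
sar_convention = "per-magnetic-mass"
tau0 = "1 ns"
K_a = "47 kJ/m^3"
delta = "1 nm"
temperature_C = 25.0
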