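# Control-formulation input parameters (toast bread, no hydrocolloid).
# Units: SI throughout; temperatures kelvin; W0 dry-basis kg/kg.
formulation: control
P_sat: 98000.0        # water vapor pressure at saturation, Pa
RH: 10.0              # oven ambient relative humidity, %
T0: 293.0             # initial dough temperature, K
W0: 0.58              # initial moisture content, dry basis
r: 0.061              # bread radius, m
rho: 402.0            # initial dough density, kg/m^3
rho_s: 315.0          # density of solid matrix, kg/m^3
epsilon: 0.9          # surface emissivity
delta_const: 1.0      # delta-type function value (literal evaporation mode)
h: 10.0               # surface heat-transfer coefficient, W/(m^2 K)
lambda_v_ref: 2.33e6  # latent heat of evaporation, J/kg
D: 1.2e-4             # water diffusion coefficient, m^2/s
nu: 2.886e-5          # kinematic viscosity, m^2/s
alpha: 1.17e-7        # thermal diffusivity, m^2/s
Cp_meas: 2489.0       # measured specific heat of bread, J/(kg K)
k: 0.18               # bread thermal conductivity, W/(m K)
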