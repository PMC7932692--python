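# LB-default preset: fast growth in rich medium, 3-min imaging cadence,
# mean generation time ~34 min.  Structural parameters (cadence, mean rate,
# retentions, decay times) are fixed by design; noise magnitudes were set by
# the packaged coarse grid-search calibration (sistermem.calibrate) against
# the outcome statistics of the study conditions, with fixed seeds.
# The experiment size reproduces the study's ensemble scale: ~120 sister
# pairs (subsampled) and ~100 neighbour pairs at default tolerances.
# preset-version: 2
dt_min: 3.0
alpha_bar: 0.020386528
delta_bar: 2.0
sigma_delta_rel: 0.05
sigma_r: 0.025
phi_T: 0.925875
sigma_hT: 0.075
phi_L: 0.905724
sigma_hL: 0.26
kappa: 0.062
tau_c: 10.0
sigma_xi: 0.05
tau_xi: 5.0
sigma_env_static: 0.04
sigma_env_dyn: 0.065
tau_env: 34.0
f_bar: 100.0
sigma_f_intr: 10.0
tau_f: 34.0
beta_f: 3.0
sigma_meas_L: 0.01
sigma_meas_f: 0.02
n_traps: 700
n_generations: 30
frac_unrelated: 0.57
burn_in_generations: 10
seed: 0
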