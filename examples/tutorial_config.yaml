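# Reference single-subject design and synthetic truth for the CLI workflow:
#   pmxbayes simulate --config examples/tutorial_config.yaml --seed 3 --out events.csv
regimen:
  amount: 1200.0      # mg per bolus
  ii: 12.0            # h between doses
  n_doses: 14
  dense_obs_doses: [1, 2, 14]
  final_obs_times: [12.0, 18.0, 24.0]
truth:                # parameters used when simulating
  CL: 10.0            # L/h
  Q: 15.0             # L/h
  Vcent: 35.0         # L
  Vperi: 105.0        # L
  ka: 2.0             # 1/h
sigma: 0.2            # lognormal residual scale
ode:
  rtol: 1.0e-6
  atol: 1.0e-6
  max_num_step: 100000
hmc:
  target_accept: 0.8
  path_length: 1.2
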