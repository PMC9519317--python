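A: 0.02
alpha_star: 0.02
alpha_bar: 0.0
beta_star: 0.03
beta_bar: 0.0
xi_star: 0.05
xi_bar: 0.0
eta_star: 0.03
eta_bar: 0.0
epsilon: 0.02
gamma_star: 0.5
gamma_bar: 0.0
i0: 0.001
t_end: 30.0
dense_grid: 601
name: case2
sweep_param: beta_bar
sweep_values: [-0.01, -0.005, 0.0, 0.005, 0.01]
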