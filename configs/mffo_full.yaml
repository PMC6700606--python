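# Full-size MFFO settings (the package defaults, spelled out)
n_test: 16
tau_run: 3500.0
delta_k_sd: 2.5
F0: 0.9
w: 0.2
alpha: 0.03
m_cycle: 50
N_K: 16
N_win: 6
N_low: 4
random_k_range: [30.0, 60.0]
k_floor: 1.0
init_k_choices: [20.0, 40.0, 60.0, 80.0]
sample_every: 2000
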