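# Default model parameters: core channel values plus the calibrated
# spike-shape kinetics (neuron.spk_m, neuron.spk_h, neuron.ahp_m were
# fitted by prebotc.calibration against the published spike-height/AHP
# response curves; all other values are the standard set).
neuron.C = 36.0
neuron.g_Na = 150.0
neuron.g_K = 220.0
neuron.g_SPK = 0.0
neuron.g_AHP = 0.0
neuron.g_NaP = 3.33
neuron.g_Ca = 0.0
neuron.g_Leak = 3.5
neuron.g_Tonic = 0.0
neuron.na_m.x_half = -43.8
neuron.na_m.k_x = 6.0
neuron.na_m.tau_max = 0.25
neuron.na_m.tau_half = -43.8
neuron.na_m.k_tau = 14.0
neuron.na_h.x_half = -67.5
neuron.na_h.k_x = -11.8
neuron.na_h.tau_max = 8.46
neuron.na_h.tau_half = -67.5
neuron.na_h.k_tau = 12.8
neuron.k_rect.A_alpha = 0.011
neuron.k_rect.B_alpha = 44.0
neuron.k_rect.k_alpha = 5.0
neuron.k_rect.A_beta = 0.17
neuron.k_rect.B_beta = 49.0
neuron.k_rect.k_beta = 40.0
neuron.spk_m.x_half = -22.5
neuron.spk_m.k_x = 3.25
neuron.spk_m.tau_max = 0.1
neuron.spk_m.tau_half = -22.5
neuron.spk_m.k_tau = 14.0
neuron.spk_h.x_half = -26.0
neuron.spk_h.k_x = -11.8
neuron.spk_h.tau_max = 8.46
neuron.spk_h.tau_half = -26.0
neuron.spk_h.k_tau = 12.8
neuron.ahp_m.x_half = -26.5
neuron.ahp_m.k_x = 4.0
neuron.ahp_m.tau_max = 20.0
neuron.ahp_m.tau_half = -26.5
neuron.ahp_m.k_tau = 25.0
neuron.nap_m.x_half = -47.1
neuron.nap_m.k_x = 3.1
neuron.nap_m.tau_max = 1.0
neuron.nap_m.tau_half = -47.1
neuron.nap_m.k_tau = 6.2
neuron.nap_h.x_half = -60.0
neuron.nap_h.k_x = -9.0
neuron.nap_h.tau_max = 5000.0
neuron.nap_h.tau_half = -60.0
neuron.nap_h.k_tau = 9.0
neuron.ca_m.x_half = -27.5
neuron.ca_m.k_x = 5.7
neuron.ca_m.tau_max = 0.5
neuron.ca_m.tau_half = -27.5
neuron.ca_m.k_tau = 10.0
neuron.ca_h.x_half = -52.4
neuron.ca_h.k_x = -5.2
neuron.ca_h.tau_max = 18.0
neuron.ca_h.tau_half = -52.4
neuron.ca_h.k_tau = 10.0
env.Na_in = 15.0
env.Na_out = 120.0
env.K_in = 125.0
env.K_bath = 8.5
env.P_Na = 1.0
env.P_K = 42.0
env.temperature = 27.0
env.dV_half_Na = 0.0
env.E_syn = 0.0
env.E_Ca = 30.0
network.N = 100
network.p_syn = 0.13
network.W_max = 0.2
network.mu_NaP = 3.33
network.sigma_NaP = 0.75
network.rho = 0.8
network.sigma_leak_frac = 0.05
network.g_SPK_dist = 0.0
network.g_AHP_dist = 0.0
network.seed = None
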