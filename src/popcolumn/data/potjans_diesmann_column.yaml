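# Parameters of the 4-layer x 2-cell-type cortical column, transcribed from
# Potjans & Diesmann (2014), "The cell-type specific cortical microcircuit:
# relating structure and activity in a full-scale spiking network model",
# Cerebral Cortex 24:785-806, Tables 4 and 5, with two modifications used
# throughout this package:
#   * the L4e -> L2/3e connection probability is set to 0.088 (doubled from
#     0.044) so that a single synaptic weight serves all excitatory
#     projections while keeping the overall projection strength;
#   * the background drive is rescaled (rate / 8.54, weight x 8.54), which
#     preserves the mean background input but raises its variance and damps
#     the intrinsic oscillations of the original parameterization.
#
# Population order everywhere: [L2/3e, L2/3i, L4e, L4i, L5e, L5i, L6e, L6i]

populations: [L2/3e, L2/3i, L4e, L4i, L5e, L5i, L6e, L6i]

# Table 4, "Populations and inputs": neurons per population (full scale)
population_sizes: [20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948]

# Table 5, "Connectivity": connection probability, rows = target population,
# columns = source population.  Row 1, column 3 carries the 0.088 override
# (Table 5 prints 0.0437... here the doubled value replaces the doubled
# synaptic weight of the original model).
connection_probabilities:
  - [0.1009, 0.1689, 0.088,  0.0818, 0.0323, 0.0,    0.0076, 0.0]
  - [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0,    0.0042, 0.0]
  - [0.0077, 0.0059, 0.0497, 0.135,  0.0067, 0.0003, 0.0453, 0.0]
  - [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0,    0.1057, 0.0]
  - [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0]
  - [0.0548, 0.0269, 0.0257, 0.0022, 0.06,   0.3158, 0.0086, 0.0]
  - [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252]
  - [0.0364, 0.001,  0.0034, 0.0005, 0.0277, 0.008,  0.0658, 0.1443]

# Table 5, "Synapses": exponential PSC amplitude w (pA) and time constant
# tau_s (ms); Table 4 membrane capacitance C_m (pF) and time constant (ms).
# The charge-conserving voltage jump is w * tau_s / C_m = 0.1756 mV.
syn_current_exc_pA: 87.8
syn_kernel_tau_ms: 0.5
membrane_capacitance_pF: 250.0
membrane_tau_ms: 10.0
# threshold 15 mV above the reset/rest potential (Table 4: V_th -50 mV,
# V_reset = E_L = -65 mV); refractory period simplified to zero.
v_threshold_mV: 15.0

# inhibitory synaptic strength = -g * excitatory (Table 5, g = 4)
g_inh_ratio: 4.0

# Table 5, "Input": external (background) in-degrees per population and the
# per-source background rate; rescale divides the rate and multiplies the
# weight, leaving rate x weight invariant.
bg_in_degree: [1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100]
bg_rate_hz: 8.0
bg_rescale: 8.54

# Table 5, "Synapses": mean transmission delays by source type (ms)
delay_exc_ms: 1.5
delay_inh_ms: 0.75

# voltage-grid discretization of the density solver (solver choice, not part
# of the source tables): uniform 0.1 mV bins on [-15, 15] mV.  The lower bound
# sits ~14 rescaled-background jumps below reset: with the strong inhibition
# in this model, a shallower floor (e.g. -5 mV) measurably inflates the rates
# of the most inhibited populations (L6e by ~70%) relative to both a
# converged grid and the spiking-ensemble oracle.
grid_v_min_mV: -15.0
grid_n_bins: 300
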