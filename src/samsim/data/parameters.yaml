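# Canonical model-parameter file.
#
# One entry per constant of the reaction-diffusion model: the symbol used in
# the module docstrings, the default (wild-type) value, and the term of the
# model equations the constant enters.  All quantities are dimensionless;
# the set as a whole represents an equivalence class of settings — only
# qualitative behaviour is calibrated, so any rescaling within biologically
# sensible ranges is equally valid.
#
# This file is the single source of defaults: `samsim.model.load_parameters()`
# builds `ModelParameters` from it, and the test suite asserts the dataclass
# defaults agree with it.

parameters:
  # --- anchoring field: spatially varying WUS/facX conversion rate rho(c) ---
  peak:
    symbol: rho_max
    value: 0.013
    role: anchoring rate at the tip cell (maximum of the distribution)
  width:
    symbol: w_rho
    value: 2.75
    role: Gaussian decay width of the anchoring field, in cell hops from the tip
  floor:
    symbol: rho_min
    value: 0.0013
    role: anchoring rate far from the tip
  mode:
    symbol: anchoring mode
    value: distribution
    role: tip-peaked distribution (wild type) or constant rate (variant)
  constant_value:
    symbol: rho_const
    value: 0.006
    role: uniform rate used when the anchoring distribution is switched off
  noise_amplitude:
    symbol: eps_xi
    value: 0.002
    role: >
      half-width of the frozen uniform perturbation xi on rho(c), sampled
      once per cell at initialization; symmetry breaking for the
      activator-substrate pair

  # --- WUS / facX activator-substrate pair ---
  wus_basal:
    symbol: b_w
    value: 0.004
    role: basal offset in the autocatalysis A(u) = u^2/(1 + kappa u^2) + b_w
  wus_saturation:
    symbol: kappa
    value: 0.15
    role: saturation constant of WUS autocatalysis
  clv3_inhibition:
    symbol: k_r
    value: 0.74
    role: >
      inverse CLV3 threshold of the repressive response
      R = 1/(1 + (k_r (1 - c1_ko) [CLV3])^m_r) gating the facX->WUS
      conversion
  clv3_inhibition_hill:
    symbol: m_r
    value: 16.0
    role: >
      steepness of the CLV3 response; the sharp threshold separates the
      strongly repressed stem-cell neighbourhood from the organizing
      centre below it
  facx_basal:
    symbol: sigma_x
    value: 0.02
    role: constant basal production of the substrate facX in every cell

  # --- signal / stemness / CLV3 chain ---
  signal_production:
    symbol: k_y
    value: 0.05
    role: production of the WUS signal, proportional to [WUS]
  stemness_production:
    symbol: k_s
    value: 0.05
    role: maximal stemness production rate in competent cells
  stemness_threshold:
    symbol: K
    value: 1.6
    role: half-activation signal level of the stemness switch H(y)
  stemness_hill:
    symbol: n
    value: 10.0
    role: >
      large Hill exponent of the stemness switch; produces the sharp
      transition between stem cells and their neighbours
  clv3_production:
    symbol: k_c
    value: 0.2
    role: endogenous CLV3 production, proportional to [stemness]

  # --- degradation rates (one per species) ---
  deg_wus:      {symbol: d_w,  value: 0.01,   role: WUS degradation}
  deg_facx:
    symbol: d_x
    value: 0.001
    role: >
      facX degradation; deliberately slow so the substrate pool acts as
      the buffering reservoir of the circuit
  deg_signal:   {symbol: d_y,  value: 0.05,   role: WUS-signal degradation}
  deg_stemness: {symbol: d_s,  value: 0.05,   role: stemness decay}
  deg_clv3:     {symbol: d_c,  value: 0.05,   role: CLV3 degradation}

  # --- diffusion rates (WUS and stemness: weak leakage only) ---
  diff_wus:      {symbol: D_w, value: 0.002,  role: WUS leakage diffusion}
  diff_facx:     {symbol: D_x, value: 0.2,    role: facX free diffusion}
  diff_signal:   {symbol: D_y, value: 0.2,    role: WUS-signal free diffusion}
  diff_stemness: {symbol: D_s, value: 0.0002, role: stemness leakage diffusion}
  diff_clv3:
    symbol: D_c
    value: 0.02
    role: >
      CLV3 free diffusion; short-ranged relative to the WUS signal so the
      stem-cell domain represses its immediate neighbourhood but not the
      deeper organizing centre
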