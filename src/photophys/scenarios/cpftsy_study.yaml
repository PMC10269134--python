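# Packaged simulation scenario: diatom CpSRP-receptor knockout study.
#
# Truth values are the study conditions this package validates against:
# growth rates per line and light, HL +/- lincomycin endpoint fractions
# (30/40/52/96/~70 % of initial Fv/Fm), a 50 % mutant reduction of the
# ML electron flow, and reference log2 protein effects (PsaC, APE1).
# Photoinhibition rate constants are back-computed so the noise-free
# two-state damage/repair + sustained-quenching model passes exactly
# through the endpoint fractions (see docs/methods.md).
name: cpftsy_study
seed: 20230214
lines: [WT, cpftsy.1-25.7, cpftsy.2-2.8, cpftsy.2-4.8]
wild_type: WT
mutant_lines: [cpftsy.1-25.7, cpftsy.2-2.8, cpftsy.2-4.8]

fluor:
  F0: 700.0          # a.u., dark-adapted minimal fluorescence
  Fm: 2000.0         # a.u., dark-adapted maximal fluorescence (Fv/Fm = 0.65)
  NPQ_max: {WT: 1.2, default: 1.6}   # mutants quench harder under blue light
  k_ind: 0.01        # 1/s, NPQ induction rate
  f_fast: {WT: 0.85, default: 0.65}  # fast (qE) fraction of relaxation
  k_rel: 0.02        # 1/s, fast relaxation rate
  noise_cv: 0.03

rlc:
  alpha: {WT: 0.38, default: 0.33}     # rETR per umol photons m-2 s-1
  rETRmax: {WT: 60.0, default: 35.0}   # mutants saturate early
  FvFm: 0.65
  E_steps: [4, 8, 16, 32, 64, 96, 128, 192, 256, 384, 512, 768, 1088]
  noise_cv: 0.03

ecs:
  lines_measured: [WT, cpftsy.1-25.7, cpftsy.2-4.8]
  a1: 0.001          # delta-A per single charge per photosynthetic chain
  psii_psi_ratio: {WT: {LL: 1.2, ML: 1.0}, default: {LL: 1.1, ML: 0.8}}
  J: {WT: {LL: 60.0, ML: 160.0}, default: {LL: 50.0, ML: 80.0}}  # e- s-1 chain-1
  k_decay: 5.0       # 1/s, flash ECS decay
  drift: 0.0005      # delta-A s-1 baseline drift in the light
  noise_sd: 2.0e-05  # delta-A additive noise per wavelength
  cytc_amp: 0.0003   # delta-A amplitude of the cytochrome contamination

pigments:
  noise_cv: 0.05
  n_replicates: 3
  times_h: [0.0, 0.5, 6.0, 24.0, 168.0]
  # fmol per cell; cpftsy.2-2.8 carries ~1.3x pigment per cell, mutants shift
  # a larger fraction of the Ddx pool into Dtx at the later ML time points.
  means:
    WT:
      chla: [0.450, 0.440, 0.420, 0.380, 0.320]
      fx:   [0.500, 0.490, 0.460, 0.420, 0.360]
      ddx:  [0.042750, 0.037500, 0.048000, 0.059500, 0.066000]
      dtx:  [0.002250, 0.012500, 0.012000, 0.010500, 0.009000]
    cpftsy.1-25.7:
      chla: [0.450, 0.440, 0.420, 0.380, 0.320]
      fx:   [0.500, 0.490, 0.460, 0.420, 0.360]
      ddx:  [0.042750, 0.037960, 0.045500, 0.057600, 0.067500]
      dtx:  [0.002250, 0.014040, 0.019500, 0.022400, 0.022500]
    cpftsy.2-2.8:
      chla: [0.585, 0.572, 0.546, 0.494, 0.416]
      fx:   [0.650, 0.637, 0.598, 0.546, 0.468]
      ddx:  [0.055575, 0.049348, 0.059150, 0.074880, 0.087750]
      dtx:  [0.002925, 0.018252, 0.025350, 0.029120, 0.029250]
    cpftsy.2-4.8:
      chla: [0.450, 0.440, 0.420, 0.380, 0.320]
      fx:   [0.500, 0.490, 0.460, 0.420, 0.360]
      ddx:  [0.042750, 0.037960, 0.045500, 0.057600, 0.067500]
      dtx:  [0.002250, 0.014040, 0.019500, 0.022400, 0.022500]

growth:
  N0: 1.0e+05        # cells ml-1 at inoculation
  days: 3            # daily sampling at t = 0..3 d (4 samples)
  noise_cv: 0.03
  n_replicates: 3
  lag_days: 0.0
  carrying_capacity: 1.0e+09
  mu:                # divisions day-1, per line x light
    WT:            {LL: 1.42, ML: 1.95}
    cpftsy.1-25.7: {LL: 0.87, ML: 1.51}
    cpftsy.2-2.8:  {LL: 0.64, ML: 0.67}
    cpftsy.2-4.8:  {LL: 0.96, ML: 1.27}

photoinhibition:
  noise_cv: 0.05
  n_replicates: 3    # per line and arm; the three mutant lines pool to n = 9
  t_hl_min: 60.0
  t_recovery_min: 30.0
  dt_min: 10.0
  k_damage: 0.020066213405432267   # min-1, = -ln(0.30)/60, shared by all lines
  k_qind: 0.2        # min-1, build-up of sustained quenching during HL
  k_qrelax: 0.3      # min-1, relaxation of sustained quenching in dim light
  k_repair: {WT: 0.10, default: 0.02}
  # q at the end of the HL hour / residual quenching after dim light,
  # solved to full precision from the endpoint fractions above
  q_hl:     {WT: 0.3757488394958297, default: 0.2652832495627555}
  q_res:    {WT: 0.03190868809421622, default: 0.0666129136314003}

proteomics:
  groups_measured: [WT, cpftsy.1-25.7, cpftsy.2-4.8]
  n_prot: 1500
  n_rep: 5
  pi_diff: 0.05
  effect_min: 0.5    # |log2| effect magnitudes drawn uniformly
  effect_max: 2.5
  p_up: 0.8          # most regulated chloroplast proteins go up
  concordance: 1.0   # same-sign effect in both mutant lines
  sigma_protein: 1.5 # log2 spread of protein baselines
  sigma_rep: 0.25    # log2 replicate noise
  mu0: 20.0          # mean log2 baseline abundance
  mcar_p: 0.02
  mnar_mid: 16.0     # logistic midpoint of abundance-dependent missingness
  mnar_slope: 1.5
  peptide_lambda: 6.0
  # Printed reference effects used by the fold/percent conversion stage
  # (log2 mutant/WT in lines cpftsy.1-25.7 and cpftsy.2-4.8).
  reference_log2_ratios:
    PsaC: [-1.35, -1.96]
    APE1: [1.16, 1.58]
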