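# Canonical hJSMC parameter set.
# Units: mV, ms, pA, nS, pF, mM, litres, kelvin.
#
# Provenance key:
#   [reported]   value printed in the source publication's main text
#   [literature] taken from the cited source formulation (ten Tusscher
#                NaK/NCX saturation constants; Cox-style BK affinities)
#   [calibrated] free parameter fixed here so the assembled cell reproduces
#                the published whole-cell behaviour (rest -60 mV, amplitude
#                23 mV, free Ca2+ 94-250 nM, 6 cpm) and holds ion
#                homeostasis; this mirrors the source model's own procedure
#                for quantities without direct measurements.

membrane:
  C_m: 50.0              # pF [reported] within the measured 39-65 pF range

geometry:
  V_c: 2.0e-12           # L  [calibrated] cytosolic volume of a ~50 pF myocyte
  T: 310.0               # K  body temperature (not stated; configurable)

conductances:            # maximum conductances, nS
  G_CaL: 1.44            # [reported]
  G_CaT: 0.0425          # [reported]
  G_Kv: 1.0217           # [reported]
  G_BK: 80.0             # [reported]
  G_Na: 25.1             # [reported]
  G_NaLeak: 0.012        # [calibrated] leak split not published; total leak
  G_KLeak: 0.0016        # [calibrated] kept >= 45-fold below G_Kv [reported]

pumps:
  P_NaK: 11.6            # pA [calibrated] maximum NaK current; sized for
                         # ion homeostasis as in the source model
  k_NCX: 30000.0         # pA [calibrated] NCX scale; sized so NCX extrusion
                         # balances plateau Ca2+ entry
  K_mK: 1.0              # mM [literature] ten Tusscher NaK K half-saturation
  K_mNa: 40.0            # mM [literature] ten Tusscher NaK Na half-saturation
  gamma: 0.35            # -  [literature] NCX voltage-partition factor
  K_mNai: 87.5           # mM [literature] NCX intracellular Na constant
  K_mCa: 1.38            # mM [literature] NCX Ca constant
  k_sat: 0.1             # -  [literature] NCX saturation factor
  alpha_NCX: 0.86       # -  [calibrated] NCX outward-mode factor; places
                         # the exchanger equilibrium at the resting Ca2+

external:                # bath concentrations, mM (held constant)
  Na_o: 140.0            # physiological saline
  K_o: 5.4               # physiological saline
  Ca_o: 2.0              # physiological saline

buffers:                 # cytosolic Ca2+ buffering at equilibrium
  CaM:
    total: 0.025         # mM [calibrated] calmodulin binding-site pool
    Kd: 0.001            # mM dissociation constant
  CRT:
    total: 0.06          # mM [calibrated] calreticulin binding-site pool
    Kd: 0.005            # mM dissociation constant

initial:                 # default initial conditions (post-transient values)
  V0: -60.0              # mV [reported] resting membrane potential
  Na_i: 9.0              # mM [calibrated] limit-cycle mean
  K_i: 141.0             # mM [calibrated] limit-cycle mean
  Ca_total_i: 0.0031     # mM [calibrated] total Ca2+ giving ~94 nM free

gates:                   # HH gates: steady state = pedestal +
                         # (1-pedestal)/(1+exp(-(V-Vh)/k)) (k<0: inactivation)
                         # tau(V) = tau0 + tau_amp*exp(-((V-tau_mid)/tau_width)^2)
  m_CaT:                 # T-type activation, Cav3.1-like kinetics [calibrated]
    Vh: -45.0
    k: 5.5
    pedestal: 0.0
    tau0: 0.6
    tau_amp: 1.8
    tau_mid: -50.0
    tau_width: 25.0
  h_CaT:                 # T-type inactivation [calibrated]
    Vh: -72.0
    k: -6.0
    pedestal: 0.0
    tau0: 12.0
    tau_amp: 70.0
    tau_mid: -70.0
    tau_width: 20.0
  x_Kv:                  # Kv activation: shallow voltage dependence, slow
                         # activation so the wave peak rides on the resting
                         # Kv level [calibrated]
    Vh: 22.0
    k: 22.0
    pedestal: 0.0
    tau0: 100.0
    tau_amp: 300.0
    tau_mid: -30.0
    tau_width: 30.0
  y_Kv:                  # Kv inactivation; high pedestal -> the published
                         # "insignificant inactivation" [calibrated]
    Vh: -40.0
    k: -10.0
    pedestal: 0.92
    tau0: 600.0
    tau_amp: 0.0
    tau_mid: 0.0
    tau_width: 50.0

markov:                  # transition-rate coefficient tables (1/ms; mM)
  CaL:                   # Faber-topology L-type: C0-C1-C2-C3-O ladder,
                         # Iv (voltage) and Ica (Ca2+) inactivation [calibrated]
    a0: 1.15             # ladder forward rate at 0 mV
    sa: 16.0             # mV e-fold of forward rate
    b0: 0.006            # ladder backward rate at 0 mV
    sb: 16.0             # mV e-fold of backward rate
    kvi: 4.0             # O->Iv rate at 0 mV (fast, inactivation-limited window)
    svi: 1000.0          # mV e-fold of O->Iv (near voltage-independent)
    rv0: 0.02            # Iv->O recovery at 0 mV
    srv: 40.0            # mV e-fold of recovery
    kci_max: 0.45        # O->Ica maximum rate (Ca2+-dependent edge)
    Kci: 0.001           # mM half-saturation of Ca2+-dependent inactivation
    rci: 0.02            # Ica->O recovery
  BK:                    # Cox-allosteric BK: C0..C4 / O0..O4 [calibrated,
                         # affinity ratio per the Cox-style scheme]
    k_on: 500.0          # per mM per ms Ca2+ binding
    Kd_C: 0.011          # mM closed-tier dissociation constant
    Kd_O: 0.0011         # mM open-tier dissociation constant
    theta0: 0.8          # C->O rate at 0 mV, zero Ca2+ bound
    delta0: 2500.0        # O->C rate at 0 mV, zero Ca2+ bound
    q_f: 0.35            # effective forward gating charge (e)
    q_b: 0.35            # effective backward gating charge (e)
  Na:                    # six-state Nav1.5: C3-C2-C1-O-If-Is [calibrated]
    a0: 0.575            # activation forward rate at 0 mV
    sa: 12.0             # mV e-fold
    b0: 0.1              # activation backward rate at 0 mV
    sb: 12.0             # mV e-fold
    h1: 1.2              # O->If fast inactivation
    hr0: 1.0e-5          # If->O recovery at 0 mV
    shr: 20.0            # mV e-fold of recovery
    s1: 0.01             # If->Is slow inactivation
    s20: 0.02            # Is->If recovery at 0 mV
    ss2: 60.0            # mV e-fold of recovery

stimulus:                # phenomenological ICC slow wave + gap junction
  V_ICCrest: -57.0       # mV [reported]
  V_ICCamp: 23.5         # mV [reported magnitude]
  t_up: 300.0            # ms upstroke duration [reported]
  t_plat: 9700.0         # ms plateau duration [reported] -> 6 cpm
  k_up: 6.0              # upstroke sharpness (saturating exponential)
  p_plat: 0.89          # shape constant: plateau pedestal fraction
  c_fast: 0.04          # shape constant: fast-settle tau / t_plat
  c_fall: 0.30          # shape constant: terminal fall / t_plat
  G_couple: 0.34         # nS [calibrated] ICC-SMC gap-junction conductance
  t_start: 0.0           # ms stimulus onset
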