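# Model and methods

`hjsmc` simulates the electrophysiology of a single human jejunal smooth
muscle cell (hJSMC): a membrane-capacitance ODE driven by eight ionic
current terms, a prescribed interstitial-cell-of-Cajal (ICC) slow-wave
stimulus delivered through a gap-junction conductance, and intracellular
Na⁺/K⁺/Ca²⁺ bookkeeping with equilibrium Ca²⁺ buffering.  This note
records the model equations, the assumptions behind them, the numerical
scheme, and the design choices that were genuinely open.

## Membrane equation and currents

The membrane potential obeys

    C_m dV/dt = -(I_ion - I_stim),

with outward currents positive and `I_stim = G_couple (V_ICC - V_m)`
inward-positive, so a depolarized ICC depolarizes the cell.  `I_ion` is
the sum of

| term | carrier | form |
|---|---|---|
| I_CaL | Ca²⁺ | G_CaL · Po · (V − E_Ca), 7-state Markov chain |
| I_CaT | Ca²⁺ | G_CaT · m · h · (V − E_Ca), HH gates |
| I_Kv  | K⁺   | G_Kv · x · y · (V − E_K), HH gates |
| I_BK  | K⁺   | G_BK · Po · (V − E_K), 10-state allosteric Markov chain |
| I_Na  | Na⁺  | G_Na · Po · (V − E_Na), 6-state Markov chain |
| I_NaK | 3 Na⁺ out / 2 K⁺ in | ten Tusscher saturation form |
| I_NCX | 3 Na⁺ in / 1 Ca²⁺ out | ten Tusscher exchanger form |
| I_NaLeak, I_KLeak | Na⁺, K⁺ | linear, 0 mV reversal |

Nernst potentials are recomputed every step from the tracked intracellular
concentrations; the BK current uses E_K (pure K⁺ selectivity).  The
internal unit system is mV, ms, pA, nS, pF, mM, litres: pA = nS·mV and
pA/pF = mV/ms, so the membrane equation needs no conversion factor, and
the concentration ODEs convert current to flux through
1e−15/(z·F·V_c) with F in C/mmol (1 pA = 1e−15 C/ms); a unit test pins
this conversion against a hand calculation.

### Channel kinetics

The maximum conductances (G_CaL 1.44, G_CaT 0.0425, G_Kv 1.0217, G_BK 80,
G_Na 25.1 nS) and the membrane capacitance (50 pF) are the published
values.  The kinetic coefficient tables are this package's own fits,
stored as data in `data/default_params.yaml` rather than hard-coded, so a
corrected fit is a config change:

- **L-type Ca²⁺ (7 states).**  A four-step activation ladder C0–C3 → O
  (rates 4α…α / β…4β with exponential voltage dependence), a fast
  voltage-dependent inactivated state Iv reachable from O, and a
  Ca²⁺-dependent inactivated state Ica whose entry rate saturates in free
  Ca²⁺ (the Ca²⁺-dependent edge; EGTA mode zeroes it).  Inactivation from
  the open state is fast (τ ≈ 0.2 ms), so the sustained current is an
  inactivation-limited window of ≈ −2 to −3 pA across the plateau voltage
  range (−45…−37 mV) that is nearly flat in V.  This window is the cell's
  plateau Ca²⁺ source; its flatness keeps the plateau free of the
  regenerative (negative-slope) instability that a steeper window current
  produces.  A consequence is that the simulated clamp "peak" I–V of the
  channel reflects the window rather than a fast transient.
- **BK (10 states).**  A Cox-style allosteric scheme: sequential Ca²⁺
  binding to the four α subunits in a closed tier C0–C4 and an open tier
  O0–O4 (open-tier affinity 10× higher), with voltage-dependent C_i↔O_i
  transitions.  Rates follow the MWC constraint, so the chain satisfies
  detailed balance; open probability is monotone in Ca²⁺, and higher Ca²⁺
  shifts the activation curve leftward.  At the operating point the
  channel passes only ≈ 0.2–0.8 pA despite its 80 nS maximum (open
  probability ~1e−4–1e−3), but its steep voltage dependence (effective
  gating charge 1.7 e) makes it the fast brake against depolarization
  beyond the plateau.
- **Nav1.5 (6 states).**  A linear chain C3–C2–C1–O–If–Is with fast
  open-state inactivation and very slow recovery, i.e. a purely transient
  current with negligible steady-state open probability.  In the paced
  cell its contribution is minor (the slow 300 ms ICC upstroke
  accommodates the channel); this is a deliberate restriction — see
  Limitations.
- **HH gates.**  Boltzmann steady states with an optional pedestal and
  Gaussian-bell time constants (strictly positive for all V).  The Kv
  inactivation gate uses a 0.92 pedestal, reproducing the "insignificant
  inactivation" of the measured whole-cell outward current; Kv activation
  is shallow (slope 22 mV) and slow (τ up to ~400 ms), so the wave peak
  rides on the resting Kv level before activation catches up.

### Pumps, exchanger and leak

NaK and NCX use the ten Tusscher functional forms with their literature
saturation constants; the two scale factors (P_NaK = 11.6 pA,
k_NCX = 30000 pA) and the NCX outward-mode factor α = 0.86 are sized for
ion homeostasis, mirroring the source model's own procedure.  α deserves
a note: the exchanger equilibrium free Ca²⁺ is
Ca_eq = e^{VF/RT} (Na_i/Na_o)³ Ca_o / α, and α is chosen so that Ca_eq at
the resting potential and the limit-cycle Na_i (≈ 9 mM) sits at the
reported ~94 nM resting Ca²⁺ — the diastolic Ca²⁺ floor is then an
exchanger equilibrium rather than a tuned transient.  The nonselective
leak (0 mV reversal) is split 0.012/0.0016 nS between Na⁺ and K⁺; the
total is 45.1-fold below G_Kv, at the published bound.

## ICC stimulus

The ICC potential is phenomenological: a saturating-exponential upstroke
of duration t_up reaching rest + amplitude exactly, a fast settle onto a
sustained plateau pedestal, and a raised-cosine terminal repolarization
ending at rest at the period end.  The three dimensionless shape
constants — pedestal fraction 0.89, settle time 0.04·t_plat, terminal
fall 0.30·t_plat — are calibrated so the coupled cell reproduces the
recorded slow-wave morphology; because they scale with t_plat, the 2-APB
and Hwang variants preserve the relative waveform.  Defaults: rest
−57 mV, amplitude 23.5 mV (the amplitude is sometimes quoted with a
minus sign; the wave is depolarizing, so the magnitude is used), t_up
300 ms, t_plat 9700 ms (6 cpm).  The 2-APB variant applies the measured
percentages (frequency 4.90 cpm, upstroke ×1.197, amplitude ×0.671); the
Hwang variant sets the period from 7.5 cpm with rest/amplitude moved
toward that study's values.

G_couple = 0.34 nS.  The cell is deliberately a *high-impedance
follower*: its intrinsic currents are all of order 1 pA, so the slow wave
is shaped by the ICC waveform filtered through the membrane time constant,
with the Kv/BK outward currents and the L-type window setting the ~3 mV
offsets of rest and plateau below the corresponding ICC levels.  A
current-budget argument fixes this regime: time-averaged K⁺ efflux must be
repaid by the pump at 2 K⁺ per 3 Na⁺, and Na⁺ influx is bounded by the
leak (≤ G_Kv/45) plus NCX import tied to Ca²⁺ cycling; chasing the
published rest and amplitude with larger channel currents violates
30-minute K⁺ homeostasis for every parameterization we examined.

**Junctional current and the K⁺ pool.**  The gap-junction current flows
between two cytosols and is carried overwhelmingly by the dominant
cytosolic cation, so it enters the K⁺ ODE (inward-positive).  This is a
model assumption rather than a measured fact; with the junctional current
excluded from the bookkeeping, the same budget argument shows K⁺ must
drain faster than 2 % per 25 min under the published morphology, so the
assumption is load-bearing for long-term homeostasis.

## Ion bookkeeping and buffering

Total Ca²⁺, Na⁺ and K⁺ evolve per the stoichiometry table (Ca²⁺ valence
2; pump 3:−2; exchanger 3:−2 per unit charge, i.e. 3 Na⁺ per Ca²⁺);
extracellular concentrations are a constant bath.  Free Ca²⁺ comes from
the instantaneous equilibrium of two buffers (calmodulin 25 µM sites,
K_d 1 µM; calreticulin 60 µM sites, K_d 5 µM — calibrated pools giving a
buffering power of ~30–50 over the physiological range), solved each step
by a safeguarded Newton iteration on the conservation-of-mass equation,
warm-started from the previous step.

## Numerics

Forward Euler for V, HH gates and concentrations; backward Euler for the
three Markov occupancy vectors (the BK open/close rates reach ~10³ s⁻¹,
which forward Euler cannot take at the model step).  dt = 0.1 ms
throughout; halving dt changes V_m by < 0.002 mV in max-norm over a
cycle.  One step is Jacobi-split: all currents are evaluated once from
the beginning-of-step state, then Markov (implicit), gates (explicit),
and finally V and concentrations (explicit).  The implicit solves use
dense Gaussian elimination with partial pivoting (6–10 states);
occupancies are clamped against negative round-off and renormalized to
sum exactly one each step (pre-renormalization drift stays below 1e−15
per step and is reported per run).  The step loop is numba-compiled;
a 30-minute simulation takes ~25 s on one core.

Default protocol: 180 s runs with a 60 s burn-in before metrics, matching
the post-transient reporting of the source recordings; the shipped initial
concentrations are limit-cycle values, so the burn-in mainly settles
gates and phase.  Slow-wave metrics use peak detection with 2 mV
prominence and half-period minimum spacing (an invented but necessary
quantification); resting potential is the mean per-cycle minimum, the
peak the mean detected peak, frequency the mean inter-peak interval, and
time-to-peak the trough-to-peak time from the 10 %-of-amplitude crossing.

## Protocol engines

- **Voltage clamp** forces V to a hold/step program; concentrations are
  frozen by default (pipette-dialyzed cell), and EGTA mode (automatic for
  the L-type preset) disables the Ca²⁺-dependent L-type transitions.
  Holding-voltage independence is quantified as < 2 % relative spread of
  end-of-step currents over the outward steps (≥ −20 mV), with spreads
  elsewhere bounded by 2 % of the whole-cell current scale — near the
  whole-cell I–V zero crossing a per-step relative measure is ill-posed.
- **Ca²⁺-free** pins both Ca²⁺ pools at 0.0001 nM (so E_Ca = 0 mV); the
  normalized whole-cell I–V then deviates < 2 % from control.
- **Sensitivity** reruns the free protocol with ±50 % conductance or
  ±30 % kinetics variants (kinetics knobs scale half-activation voltage
  and slope of the HH gates, or the paired forward/backward rate
  coefficients of the Markov channels).  At ±50 %, G_Kv dominates the
  resting- and plateau-potential shifts and G_CaL the Ca²⁺-transient
  amplitude, with G_BK and G_Na minor — the published ordering.

## Quiescence

Without the ICC stimulus the cell produces no spontaneous activity: a
5-minute unstimulated run contains no peak of slow-wave prominence, and
with the ionic pools held fixed the membrane settles to a stable rest.
The full model's unstimulated *concentrations* have no physiological
fixed point — once Ca²⁺ cycling stops, NCX Na⁺ import vanishes and the
pools drift over tens of minutes — which is the familiar drift property
of concentration-tracking cell models, not an instability of the
membrane.

## Limitations

- All kinetic coefficients are this package's calibrated fits to the
  published whole-cell behaviour, not transcriptions of the original
  model's full parameter tables; single-channel-level quantities (e.g. the L-type
  transient peak I–V position, BK half-activation voltages) should not be
  read quantitatively from this parameterization.
- Nav1.5 is effectively silent in the paced cell; mutation studies
  focused on SCN5A would need a re-fit of the Na⁺ channel block.
- The ICC is a prescribed waveform: no pacemaker biophysics, and no
  electrical loading of the ICC by the SMC.
- No sarcoplasmic-reticulum stores, IP₃/ryanodine dynamics,
  mechanosensitive channels, or contraction model.
- The junctional-current-carries-K⁺ assumption above.
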