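# hjsmc — human jejunal smooth muscle cell electrophysiology

`hjsmc` is a biophysically based simulator of a single human jejunal
smooth muscle cell (hJSMC).  Jejunal motility is paced by slow waves:
rhythmic depolarizations generated by the interstitial cells of Cajal
(ICC) and passed to the smooth muscle through gap junctions.  Ion-channel
mutations found in these cells (notably in SCN5A) are candidate causes of
motility disorders of unknown etiology, and a quantitative cell model is
the tool for asking how a kinetic change at the channel level reshapes
the cellular slow wave.

The model solves

    C_m dV/dt = -(I_ion - I_stim),
    I_ion = I_CaL + I_CaT + I_Kv + I_BK + I_Na + I_NaK + I_NCX + I_leak,

with Hodgkin–Huxley gating for the T-type Ca²⁺ and Kv currents, Markov
occupancy chains for the L-type Ca²⁺ (activation ladder with voltage- and
Ca²⁺-dependent inactivation), BK (two-tier allosteric scheme with Ca²⁺
binding to the four α subunits) and Nav1.5 (six-state) channels, ten
Tusscher NaK-pump and Na⁺/Ca²⁺-exchanger forms, and a nonselective leak.
The ICC input is a prescribed periodic waveform `V_ICC(t)` coupled through
a constant conductance, `I_stim = G_couple (V_ICC − V_m)`.  Intracellular
Na⁺, K⁺ and total Ca²⁺ are tracked, with free Ca²⁺ obtained from the
calmodulin/calreticulin buffering equilibrium.  Time stepping is forward
Euler (dt = 0.1 ms) with backward-Euler updates for the stiff Markov
chains; the step loop is numba-compiled.  See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Simulate three minutes of paced activity and extract slow-wave metrics:

```sh
hjsmc run --duration 180s --out out/
```

```
rest -59.0 mV, amplitude 21.5 mV, 6.00 cpm
```

This writes `out/trace.csv` (time series of V_m, every current term, the
three Markov open probabilities, and the Na⁺/K⁺/Ca²⁺ concentrations at
1 ms resolution), `out/metrics.csv`, the effective parameter document and
a reproduction manifest.  The metrics row reads

```
resting_potential  peak_potential  amplitude  frequency  ca_min  ca_max
-59.04             -37.58          21.46      6.0        87.6    255.5
```

i.e. the cell rests near −59 mV between waves, depolarizes to −37.6 mV at
the plateau (21.5 mV amplitude) six times per minute, and the free Ca²⁺
transient swings from ~88 nM between waves to ~255 nM during the plateau
— the range that drives contraction.  The same machinery is available as
a library:

```python
import hjsmc

params = hjsmc.load_parameters()                 # documented defaults
stim = hjsmc.default_stimulus(params.document)   # 6 cpm ICC slow wave
trace = hjsmc.run_free(params, stim, duration=180_000.0)
print(hjsmc.analyze_trace(trace))
```

Other protocols:

```sh
hjsmc clamp --preset farrugia-wholecell   # voltage steps -80..+20 mV
hjsmc run --stimulus 2apb                 # slowed, attenuated ICC input
hjsmc sensitivity --fraction 0.5          # +/-50 % conductance sweep
```

Any constant can be overridden from a YAML config or the command line,
e.g. `--set conductances.G_Na=12.5` to halve the Na⁺ conductance.

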