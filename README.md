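# msping

A microsaccade-modulated excitatory–inhibitory (PING) spiking network model
of early visual cortex, with the full event-locked analysis stack needed to
study how fixational eye movements restructure cortical synchronization and
feedforward information transfer.

During fixation the eyes make a microsaccade (MS) every few hundred
milliseconds. Each MS splits cortical dynamics into two regimes: a
**transient** period (0–100 ms after onset) with broadband,
stimulus-insensitive synchrony, and a **sustained** period (~150–350 ms)
with narrow-band gamma whose phase locking is selective — it falls off with
cortical distance, with connection strength, and with the difference in
stimulus drive between sites, the signature of weakly coupled oscillators
(an Arnold tongue in detuning × coupling space). The two regimes also imply
different neural codes downstream: rate and latency in the transient,
synchrony and gamma phase in the sustained period. `msping` is for
computational neuroscientists who want to simulate, measure and perturb
this phenomenology at desk scale.

## Model

Izhikevich neurons with exponential synapses on a toroidal grid (1600
regular-spiking excitatory cells, 400 fast-spiking inhibitory cells):

    dV/dt = 0.04 V² + 5V + 140 − u + I(t)        V ≥ 30 mV:  V ← c,
    du/dt = a (bV − u)                                        u ← u + d,
    ds/dt = −s/τ_syn                                          s ← 1

with total input `I_i = Σ_j s_j g_ij (V_rev,j − V_i) + J_i ς(t) + η(t)`.
Connections are drawn per receiver with Gaussian distance profiles and fixed
in-degree; drive maps `J` come from smoothed noise, oriented bars, or image
patches, and `ς(t)` is the MS modulation — an impulse train convolved with a
biphasic kernel (presaccadic suppression, postsaccadic transient). Virtual
electrodes on a 10×10 grid read out a Gaussian-weighted sum of excitatory
membrane potentials; the analysis stack provides MS-triggered
time–frequency power, across-saccade phase-locking values

    PLV_xy = | (1/N) Σ_n exp(i(φ_n,y − φ_n,x)) |,

synaptically confined spike-triggered averages (synSTA, the effective
receptive field of a downstream neuron), a mutual-information decomposition
of what predicts transfer, and Arnold-tongue reconstruction from
per-electrode-pair detuning and coupling proxies. Details, defaults and
design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

Simulate the noise-driven network for 10 MS intervals and measure the
distance selectivity of sustained gamma locking:

```python
from msping.experiments import ExperimentConfig, run_fig2

cfg = ExperimentConfig(n_intervals=10, seed=1)
res = run_fig2(cfg)

print(f"sustained PLV peak: {res['peak_frequency']:.1f} Hz")
nb = res["pair_table"]["is_neighbor"].to_numpy()
mx = res["pair_table"]["is_max"].to_numpy()
print(f"gamma PLV, neighbours:    {res['gamma_sustained_plv'][nb].mean():.2f}")
print(f"gamma PLV, max distance:  {res['gamma_sustained_plv'][mx].mean():.2f}")
s = res["stats"]
print(f"PLV vs distance (sustained): r = {s['r_dist_sustained']:.2f}, "
      f"p = {s['p_dist_sustained']:.3f}")
```

Output:

```
sustained PLV peak: 29.3 Hz
gamma PLV, neighbours:    0.58
gamma PLV, max distance:  0.31
PLV vs distance (sustained): r = -0.62, p = 0.001
```

Sustained synchrony is narrow-band (peak ≈ 29 Hz), strong between
neighbouring electrodes, near the chance floor for maximally distant pairs,
and correlates negatively with electrode distance (permutation test on 4950
pairs): the network's gamma coherence is spatially confined rather than
global. The same experiments are available from the shell
(`msping fig2 --n-intervals 10 --seed 1 --out results/`), alongside
`fig1c`, `fig3`, `fig7`, `fig8`, `simulate` and `calibrate`.

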