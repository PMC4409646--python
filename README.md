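# copingsim

A system-level computational model of how the brain appraises the
controllability of a stressor and switches from **active** to **passive
coping**. The model explains a well-replicated microdialysis observation in
restrained rats: during the first ~40 min of an inescapable stressor,
norepinephrine (NE) in the ventromedial prefrontal cortex (vmPFC) and
dopamine (DA) in the nucleus accumbens (NAcc) surge together (active
coping, high motivational arousal); as the stressor persists, cortical NE
returns to baseline, cortical DA shows a second, larger and sustained rise,
and NAcc DA falls *below* its baseline (passive coping, motivational
withdrawal).

`copingsim` is for computational and behavioural neuroscientists who want
to simulate, perturb and refit this circuit: run depletion, lesion and
repeated-stress experiments in silico, emulate 20-min microdialysis
sampling, and search parameters with a genetic algorithm.

## The model

Ten neural populations (OFC/ACC, prelimbic PL and infralimbic IL cortex,
intercalated amygdala ITC, central amygdala CeA, locus coeruleus LC, dorsal
raphe DR, mesocortical and mesolimbic VTA DA cells, and the mesolimbic
GABAergic gate) are leaky rate units

    τ_j du_j/dt = −u_j + b_j + Σ_i w_ji a_i,        a_j = [tanh u_j]⁺

Extrasynaptic neuromodulator levels (vmPFC NE, vmPFC DA, NAcc DA, and a
5-HT proxy) follow a release/reuptake pool with a saturating reuptake term

    τ du/dt = −th·tanh(l) + (1 − d)·w·a_source

where the depletion coefficient `d` relaxes exponentially toward an
experimental target. Neuromodulators act on units multiplicatively (gating
the summed input by `(1 + Σ μ_e l)/(1 + Σ μ_d l)`) and additively
(`+ Σ α_e l − Σ α_d l`). A single threshold-gated Hebbian rule

    w_IL→PL ← w_IL→PL − η [a_PL − th_PL]⁺ [a_IL − th_IL]⁺

strengthens IL's inhibition of PL while the stressor persists; this is the
appraisal-of-uncontrollability memory. Two loops compete: a PL–CeA–LC–NE
self-feeding arousal loop that disinhibits NAcc DA through the amygdala's
double-inhibition of the mesolimbic VTA, and an IL–DR–mesocortical-DA loop
that shuts it down. The initial IL→PL weight encodes prior restraint
experience; near a critical value of about −1 the model switches
discontinuously from naive-like timing to an anticipated passive phase.

## Worked example

```python
from copingsim import Protocol
from copingsim.fitting import fitted_reference_circuit
from copingsim.protocols import run_experiment, dialysis_sample, phase_metrics

circuit = fitted_reference_circuit()      # committed GA fit
protocol = Protocol()                     # 60 min baseline + 240 min restraint
trace = run_experiment(circuit, protocol)
for analyte in ("vmPFC-NE", "vmPFC-DA", "NAcc-DA"):
    s = dialysis_sample(trace, analyte, protocol)
    m = phase_metrics(s, protocol.stress_onset)
    print(analyte, f"peak {m.peak_value:.0f}% at {m.peak_time:.0f} min,",
          f"below baseline at {m.below_baseline_onset} min")
```

prints

```
vmPFC-NE peak 395% at 40 min, below baseline at never min
vmPFC-DA peak 363% at 240 min, below baseline at never min
NAcc-DA peak 266% at 40 min, below baseline at 100.0 min
```

i.e. cortical NE peaks 40 min after stress onset and later returns to
baseline, cortical DA climbs to a sustained plateau, and accumbal DA shows
the biphasic signature with the passive phase starting 100 min into the
restraint. The same runs are available from the shell:

```bash
copingsim simulate --out-dir out/sham
copingsim predict --scenario da-depletion --out-dir out/da-depletion
copingsim fit --generations 40 --population 48 --out-dir out/fit
```

`predict` scenarios cover NE/DA depletion in vmPFC, short/medium/long prior
restraint experience, and PL–VTA / IL–VTA disconnections.

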