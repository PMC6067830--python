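# empathynet

Spiking neural-circuit models of empathically motivated caregiving.

`empathynet` simulates a limbic caregiving circuit — basolateral/basomedial
amygdala (BLMA⊖, BLMA⊕, BLMAi), anterior and posterior insula (AI, PI),
anterior midcingulate cortex (aMCC), medial prefrontal cortex (mPFC) and the
mPOA → VTA → NAc → VP caregiving pathway — as a network of Izhikevich point
neurons with fixed-weight, current-based synapses.  A phase-structured
current-injection protocol moves the network through distinct empathy-related
states:

* **empathy-states model** (11 regions): personal distress → weak empathic
  concern → strong empathic concern;
* **self-attachment model** (12 regions, adding mOFC → {AI, BLMAi, BLMA⊕}):
  personal distress → strong empathic concern → compassion.

The package is aimed at computational-psychiatry researchers who want to
reproduce, probe or extend these state transitions: every population size,
connection probability, weight and protocol rule is a config value, runs are
seed-reproducible end to end, and the analysis layer turns spike rasters into
windowed mean-firing-rate (MFR) summaries and rule-based state labels.

## Model

Each neuron follows the two-variable Izhikevich model

```
v' = 0.04 v² + 5v + 140 − u + I,   u' = a (b v − u)
```

with a spike at `v ≥ 30 mV` followed by `v ← c`, `u ← u + d`; regions use the
regular-spiking, fast-spiking (VP, interneurons) and intrinsically bursting
(dopaminergic VTA) presets.  The simulation grid is 1 ms over
`t = 1 … 30,000` (three phases of `p = 10,000` ms).

Stimulation uses proportional levels `L = 0.05`, `M = 0.1`, `H = 0.15`.  Each
stimulated group `G` has an injectable pool `g(G)` with `|g(G)| = ⌊|G|·H⌋`,
perturbed every millisecond by swapping 10% of its members; the injected
subset `c_t(G) ⊆ g_t(G)` has either a uniform random size in a band
`[|G|·lo, |G|·hi]` or a deterministic linearly ramped size, e.g. the
decreasing phase-2 ramp `|c_t| = (|G|(L−H))(t/p) + |G|(2H−L)`.  All
injections use a nominal 90 mA amplitude.  Self–other representations in the
mPFC lie on a ventral–dorsal axis: close-other targets follow a negative
binomial with `r = 7, p = 0.0025` (ventral) and distant-other targets one
with `r = 14, p = 0.035` (dorsal), and the mPFC's projections to the
caregiving pathway are sampled from the close-other distribution.

The connectivity parameters themselves are a calibrated set (see
`docs/methods.md` and the `calibration` module): they were searched so that
the simulated MFR table reproduces the reference values packaged in
`src/empathynet/data/reference_mfr.csv`.

## Worked example

```python
from empathynet import run_model, summarize, classify_state

result = run_model("self_attachment", seed=1)     # one 30-s run, ~10 s wall
summary = summarize(result)                        # MFR per region/subpop/phase
for t in (10.0, 20.0, 30.0):
    print(t, round(summary.mfr("VP", "inh", t), 2),
          round(summary.mfr("BLMA_neg", "exc", t), 2))
for label in classify_state(summary):
    print(label.phase_index, label.label)
```

prints (seed 1)

```
10.0 0.0 0.82
20.0 2.25 0.79
30.0 2.56 0.32
1 personal_distress
2 strong_empathic_concern
3 compassion
```

— the ventral-pallidum caregiving output is silent during personal distress,
rises as the self–other distinction strengthens, and is highest in the
compassion phase, while the negatively valent amygdala is progressively
silenced by the mOFC-driven interneuron pool.  The scripts in `examples/`
walk through the protocol algebra, the gradient sampling and both models'
full rate tables, and a thin CLI is included:

```
empathynet --model empathy --seed 1 --out runs/empathy
```

which writes the spike table, the rate summary and a run manifest.

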