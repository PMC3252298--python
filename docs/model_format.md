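# Declarative document dialect

All user-facing inputs — models, experiments, simulation configs — are
versioned YAML documents.  Unknown keys are rejected with their path.  All
values are SI unless the document declares otherwise in a `units:` block.

## Units

The optional top-level `units:` mapping declares, per physical dimension, the
unit used by the document's numeric fields.  Recognized dimensions and units:

| dimension | units (SI first) |
|---|---|
| `length` | m, cm, mm, um |
| `area` | m^2, cm^2, mm^2, um^2 |
| `voltage` | V, mV |
| `time` | s, ms, us |
| `current` | A, mA, uA, nA, pA |
| `conductance` | S, mS, uS, nS, pS |
| `conductance_density` | S/m^2, mS/cm^2, S/cm^2 |
| `capacitance_density` | F/m^2, uF/cm^2 |
| `axial_resistivity` | ohm\*m, ohm\*cm |
| `membrane_resistance` | ohm\*m^2, ohm\*cm^2, kohm\*cm^2 |
| `rate` | 1/s, 1/ms |

Documents written by `save_model` / `save_experiment` are canonical SI with no
units block, so load→save→load round-trips are lossless.

## Model document

```yaml
version: 1                 # mandatory
name: mycell
units: {voltage: mV}       # optional

channels:                  # channel types: products of gates
  na:
    gates:
      - name: m
        power: 3
        alpha: {family: exp_linear, A: 1.0e+5, V0: -40.0, K: 10.0}
        beta:  {family: exponential, A: 4000.0, V0: -65.0, K: -18.0}
      - name: h
        power: 1
        alpha: {family: exponential, A: 70.0, V0: -65.0, K: -20.0}
        beta:  {family: sigmoid, A: 1000.0, V0: -35.0, K: 10.0}

cells:                     # trees of segments; exactly one root per cell
  mycell:
    segments:
      soma:
        parent: null       # root
        length: 30.0e-6    # m
        diameter: 30.0e-6  # m
        RA: 1.0            # ohm*m axial resistivity
        RM: 0.3333         # ohm*m^2 specific membrane resistance
        CM: 0.01           # F/m^2 specific membrane capacitance
        Em: -54.4          # leak reversal (mV here, per units block)
        Vinit: -65.0       # optional initial potential (default: Em)
        spine_area: 0.0    # m^2 additional spine membrane
        channels:
          - {channel: na, density: 1200.0, Erev: 50.0}

populations:               # optional network section
  - {name: pop, cell: mycell, count: 10}

projections:
  - name: recurrent
    source: pop
    target: pop
    rule: {kind: probabilistic, p: 0.3, seed: 42}   # or {kind: all_to_all}
    weight: 5.0e-9         # S per delivered spike
    delay: 5.0e-3          # s
    pre: soma              # spike-source segment (default: root)
    post: soma             # synaptic target segment (default: root)
    threshold: 0.0         # V, spike detection threshold
    tau: 2.0e-3            # s, exponential synapse decay
    Esyn: 0.0              # V, synaptic reversal
    self_connections: false

algorithms:                # expansion-time algorithm references
  - {name: compartmentalize, params: {L_max: 0.1}}
```

Rate-law families (rates in 1/s as a function of membrane voltage V):

- `exp_linear`: `A (V − V0) / (1 − exp(−(V − V0)/K))`, limit `A·K` at `V = V0`
  (`A` carries dimension rate/voltage);
- `exponential`: `A exp((V − V0)/K)`;
- `sigmoid`: `A / (1 + exp(−(V − V0)/K))`;
- `constant`: `A`.

Segment membrane parameters may be omitted: the model stays loadable,
saveable, and geometrically queryable; `check_completeness` lists every
missing `(path, parameter)` and solver initialization refuses such models.

Identifier paths are slash-separated and case-sensitive: `/cellname/segment`
for stand-alone cells, `/population/i/segment` for instance `i` of a
population.  Variables are `Vm` plus one `channel.gate` entry per gate (e.g.
`na.m`).

## Experiment document

```yaml
version: 1
name: pulse
protocols:
  - {kind: pulse, target: /mycell/soma, delay: 5.0e-3, duration: 20.0e-3,
     amplitude: 0.3e-9, repeat_interval: 50.0e-3}   # repeat optional
  - kind: vclamp
    target: /mycell/soma
    gain: 1.0e-6           # S: clamp realized as I = gain (V_cmd − Vm)
    levels:
      - {start: 0.0, voltage: -70.0e-3}
      - {start: 10.0e-3, voltage: -20.0e-3}
outputs:
  - {path: /mycell/soma, variable: Vm, destination: out, stride: 1}
```

Experiments are model-independent: any protocol applies to any model on which
its target paths resolve.

## Simulation config

See the docstring of `arborsim.scheduler` for the full schema: model and
experiment paths, `dt` (seconds or `auto`), `t_end`, `seed`, `output_dir`,
`hdf5` mirror flag, model parameter `overrides`, `protocol_overrides`,
`checkpoint: {every: N}`, and an `iterate:` grid for batch runs.
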