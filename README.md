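# arborsim

A compartmental neuron and small-network simulation engine built as a
federation of independent components.  It is aimed at computational
neuroscientists who want morphologically detailed Hodgkin–Huxley models —
somata, branched dendrites, spines, small synaptically coupled networks —
described declaratively and simulated reproducibly, and at simulator
developers who want each concern (biology, numerics, experiment design,
control, scheduling) in a separately testable component.

## The model

Each cell is a tree of cylindrical segments obeying the branched cable
equation.  Per compartment *i*:

```
Cm_i dV_i/dt = -(V_i - E_leak,i) G_leak,i
               - Σ_ch  Gmax_ch Π_g x_g^p_g (V_i - E_ch)
               - g_syn,i (V_i - E_syn,i)
               + Σ_{j∈neighbors} (V_j - V_i)/Ra_ij  +  I_inj,i
```

with Hodgkin–Huxley gate variables `dx/dt = α(V)(1−x) − β(V)x`.  Intensive
membrane parameters (CM in F/m², RM in Ω·m², channel densities in S/m²) are
scaled to absolute values by the compartment's membrane area; spine membrane
area is included when scaling capacitance and leak but deliberately excluded
from channel conductances.  Long segments are split so that no compartment
exceeds a maximal electrotonic length `L/λ`, with `λ = sqrt(RM·d/(4·RA))`.

Time stepping is Crank–Nicolson (trapezoidal, second order, unconditionally
stable): gate variables advance by their exact exponential update with rates
read from shared lookup tables, then the branched-cable linear system is
solved in one O(n) sweep over the compartments in Hines (leaf-to-root) order,
which eliminates without fill-in.  Networks couple independent per-cell
solvers through a spike-event queue with per-connection delays and
exponential-conductance synapses.

## Architecture

Layers interact only through defined interfaces (and a test enforces it on
the import graph):

| layer | package | role |
|---|---|---|
| biology | `arborsim.model` | declarative documents, validation, queries, identifier resolution |
| biology | `arborsim.experiment` | stimulus protocols, outputs, event sequencing |
| bridge | `arborsim.binding` | discretization, Hines ordering, density scaling, connectivity translation |
| numerics | `arborsim.solver` | Crank–Nicolson cable solver, rate tables, command executor |
| numerics | `arborsim.control` | clock, back-end registry, spike queue, run/stop/reset |
| glue | `arborsim.scheduler`, `arborsim.cli` | config-driven wiring, batch grids, resume, output files |

## Worked example

Generate the classical squid-axon soma fixture and run a current-pulse
experiment (any model/experiment documents of the same dialect work the same
way; see `docs/model_format.md`):

```python
from pathlib import Path
from arborsim.fixtures import make_fixture
model, experiment = make_fixture("hh_soma")   # 0.3 nA pulse from 5 ms
Path("model.yaml").write_text(model)
Path("experiment.yaml").write_text(experiment)
```

```console
$ arborsim query surface-area --model model.yaml
membrane area of /cell: 2.827433e-09 m^2 (2827.4334 um^2)

$ arborsim query channels --model model.yaml
segment	channel	density/S m^-2	Erev/V
/cell/soma	k	360	-0.077
/cell/soma	na	1200	0.05

$ arborsim validate --model model.yaml --experiment experiment.yaml
model: valid, mathematically complete
experiment: all targets resolve

$ arborsim run --model model.yaml --experiment experiment.yaml \
      --t-end 0.03 --dt 1e-5 --output-dir demo --verbose
dt = 1e-05 s, 1 solver(s), config 5e2f8f22c127
demo/out.tsv
```

The output is a tab-separated time series (time in seconds, one column per
recorded variable, `#` header with provenance).  Reading it back:

```python
import numpy as np
from arborsim.outputs import read_tsv
t, cols = read_tsv("demo/out.tsv")
v = cols["/cell/soma:Vm"]
i = int(np.argmax(v))
print(f"peak Vm = {v[i]*1e3:.2f} mV at t = {t[i]*1e3:.2f} ms")
```

prints `peak Vm = 40.36 mV at t = 7.07 ms` — the first action potential of
the squid-axon soma, peaking ~2 ms after the 0.3 nA pulse begins, followed by
a second spike later in the pulse.  A JSON run record (`demo/run.json`) holds
the config hash, seed, and output paths; identical configs reproduce output
files byte for byte.

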