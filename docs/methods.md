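# Methods

## Scope and design

arborsim separates a simulator into independent components along two axes:
data versus control, and biological concepts versus numerical values.  The
biology side stores and validates models and experiments; the numerics side
integrates equations and routes events; a thin binding layer in between maps
each biological quantity to exactly one numerical one (no algorithms live in
the bindings).  Cross-layer imports outside this scheme are rejected by an
automated import-graph test, so the separation is a maintained invariant, not
a convention.  The model container keeps three synchronized faces of a model:
the in-memory biological tree, its serialized conceptual document, and the
expanded mathematical representation.  Expansion is recomputed on demand and
cached; any mutation through `set_parameter` invalidates the cache, which is
the simplest policy that can never serve a stale binding.

## Discretization

Segments are cylinders.  A segment whose electrotonic length `L/λ` exceeds
`L_max` is split into `ceil((L/λ)/L_max)` equal sub-segments, where
`λ = sqrt(RM·d/(4·RA))` is the infinite-cable length constant — the standard
definition, adopted here as the package's convention.  Splitting divides
length and spine area equally and inherits densities unchanged (they are
intensive), so total membrane area, total axial resistance along the segment,
and channel conductance per unit area are preserved exactly.
`L_max` is dimensionless; 0.05–0.2 is typical, and the fixtures use 0.1 where
they compartmentalize at all.  When a stimulus or output targets a segment
that was split, it is attached to the middle sub-segment.

Scaling to absolute values, per compartment with bare cylinder area
`A = π·d·L` and spine area `s`:

- capacitance `Cm = CM·(A + s)`;
- leak `G_leak = (A + s)/RM`;
- channel `Gmax = density·A` — spine area deliberately excluded, the usual
  convention for passive spines whose channels are not modeled;
- axial resistance to the parent `Ra = RA·L/(π(d/2)²)`.

Compartments are numbered leaf-to-root (post-order, children in declaration
order, root last), so each node's parent has a larger index.  Gaussian
elimination in ascending order then touches exactly one off-diagonal per row
and creates no fill-in; a brute-force symbolic-elimination oracle verifies
zero fill-in on random trees in the tests.

## Integration

The membrane equation is advanced with the trapezoidal (Crank–Nicolson) rule.
Conductances are frozen over each step after the gate update, giving the
linear system `[(2Cm/dt)I + D − A] V' = [(2Cm/dt)I − D + A] V + 2b` with `D`
the diagonal of total membrane conductance, `A` the symmetric axial coupling
matrix, and `b` the source vector (leak, channel and synaptic reversal
currents, clamp, injections).  The `2Cm/dt` coefficients are folded at
initialization, not per step.  The solve is one elimination/back-substitution
sweep in Hines order, O(n) per step.

Gate variables use the exact exponential update
`x' = x∞ + (x − x∞)·exp(−dt(α+β))` with rates evaluated at the step's
starting voltage.  This is unconditionally stable and confines `x` to [0, 1]
by construction.  Gating and voltage are staggered within the step, not
iterated: the scheme is exactly second order for the passive (linear)
problem — the test suite measures error-reduction factors of 4.00 per dt
halving — while for the coupled HH system the formal order of the interleave
is not claimed; accuracy there is established empirically against an
independent adaptive ODE integration (peak within ~4·10⁻⁴ mV and timing
within ~5·10⁻⁶ ms at dt = 2 µs for the squid-axon soma).

Rates come from tables sampled on a uniform voltage grid, by default 3000
divisions over [−100 mV, +50 mV] (both user-settable — they are the accuracy
knob).  Lookups interpolate linearly and are exact at grid nodes; voltages
outside the range clamp to the table ends.  Tables are registered under a
canonical hash of (rate-law family, coefficients, grid), so identical gate
parameterizations anywhere in a simulation share one table.  Sharing is purely
an aliasing optimization: runs with sharing disabled are bitwise identical,
and a test asserts it.

Initialization sets each compartment to its initial potential (`Vinit`,
defaulting to the leak reversal `Em`) and every gate to its steady state
α/(α+β) at that voltage.  A passive model at `Vinit = Em` is an exact fixed
point: the tests hold it to < 10⁻¹² V over 10⁵ steps.  The classical HH
membrane rests near −65 mV while its fitted leak reversal is −54.4 mV, which
is why `Vinit` exists as a separate field.  The default time step is 1% of
the fastest membrane time constant Cm/G_leak in the model (`dt: auto`);
spiking models want dt well below that — the acceptance comparisons use 2 µs.

## Events, stimuli, clamping

Protocols are unrolled by the sequencer bridge into a time-sorted command
list; ties preserve declaration order and the executor applies later
declarations last, so they win.  Events stamped at time `t` are applied
before the step advancing `t → t+dt`, making a pulse of duration `W` span
exactly `ceil(W/dt)` steps.  Voltage clamp is realized as a current source
`I = gain·(V_cmd − Vm)` folded implicitly into the step (it adds to `D` and
`b`), so the solver's input interface stays current-only and the clamp is
stable at any gain; 1 µS pins a soma to within ~10 µV.

## Networks

Each cell instance is one solver.  Projections expand to explicit ordered
pairs: `all_to_all` is the full product (the diagonal removable per
projection), `probabilistic(p, seed)` draws one Bernoulli sample per ordered
pair in source-major order from its own seeded generator — a fixed draw order
is what makes a network reproducible.  A spike is a strictly upward crossing
(`V_prev < θ ≤ V_now`) of the source compartment, one event per crossing.
Delivery happens before the update of step `k + ceil(delay/dt)` when the
crossing was detected at step `k`, so the synaptic effect begins exactly one
delay after the spike on the step grid; delays below one dt are rejected.
The synapse is a single-exponential conductance per target compartment
(increment `weight` on delivery, decay `exp(−dt/τ)`, reversal `Esyn`; defaults
τ = 2 ms, Esyn = 0 V — a generic fast excitatory synapse).  One compartment
carries one (τ, Esyn) pair; projections disagreeing on these for a shared
target are rejected rather than silently merged.

Within each controller step the order is: command executors, spike delivery,
solver updates in registry order, crossing detection, output sampling.  The
initial state is sampled once before the first step, so N steps at stride 1
yield N+1 samples.  Integer step counting is authoritative for time.  This
ordering is part of the reproducibility contract: identical configs and seeds
give bitwise-identical output files.

## Checkpointing

A solver checkpoint serializes every dynamic array plus dt and the step count
into a versioned container stamped with a structural fingerprint of the
binding; restoring checks version, fingerprint and shapes, and a restored run
continues bitwise-identically to an uninterrupted one.  The scheduler's
combined checkpoint adds the clock and pending spike-queue entries.  A resumed
run re-derives executor cursors from the step count; its output files cover
the resumed interval.

## Synthetic models

All test inputs are generated programmatically.  The Hodgkin–Huxley fixtures
use the classical squid-axon parameterization (CM = 1 µF/cm², gNa = 120,
gK = 36, leak = 0.3 mS/cm², ENa = +50 mV, EK = −77 mV, E_leak = −54.387 mV,
rest −65 mV), with the rate-law coefficients vendored as a data file.
Passive fixtures use RM = 1 Ω·m², CM = 0.01 F/m² (the canonical 10 ms
membrane time constant) and RA = 1 Ω·m, within the usual cytoplasmic range.
Random trees draw uniform geometry over physiological ranges with each node's
parent chosen uniformly among earlier nodes; random networks place HH somata
with probabilistic recurrent connectivity.  These generators emulate the
structural and dynamical properties the engine must handle — branching,
spines, kinetics duplication, delayed connectivity — but not the statistics
of reconstructed morphologies (no SWC ingestion), multi-channel dendritic
nonuniformity, calcium dynamics, or synaptic plasticity; green tests show the
engine solves its equations correctly, not that any particular biological
model is right.

## Verification problem sizes

The verification quantities in `scripts/acceptance.py` use: 5000 steps at
dt = τ/1000 for the passive step response; dt halvings τ/100 → τ/800 for the
order measurement; an 11-compartment cable run 30 τ to steady state; a 15000
step (dt = 2 µs, 30 ms) HH soma against LSODA at rtol 10⁻¹⁰; 100 random trees
for the fill-in oracle; 2000-step runs for the dedup/determinism bitwise
comparisons; a two-cell relay at dt = 10 µs for delay fidelity.  These sizes
give each measurement comfortable resolution on a single CPU in seconds.

## Known limitations

Serial execution only — the port/queue abstraction is the seam where a
parallel communication layer would plug in.  No adaptive or Runge–Kutta
integrators, Monte Carlo or kinetic-pathway back-ends, calcium dynamics, gap
junctions, or distance-dependent connection rules.  Voltage clamp is the
ideal-gain current-source form, not an electrode model.  The conceptual
representation stores algorithm references and parameters, never algorithm
results.
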