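# Methods

## Scope and design stance

`sparsespike` reproduces the *architecture* of two generations of
distributed spiking-network simulation kernels at desk scale: ranks and
threads are emulated inside one process, collective communication is a
list transposition/concatenation with the exact sectioning, flag and
buffer-growth protocol of the real collectives, and every data structure
(two-tier connection tables, packed target words, spike register, sparse
table) is implemented faithfully at the level of *counts and contents*.
Wall-clock performance of the emulation is meaningless and is never
asserted; phase timers (build / init / sim) are reported for orientation
only. What the emulation does make exactly testable is everything the
architecture claims about *what* is stored, sent and delivered: entry
counts, receive volumes, round protocols, and bit-level equivalence of
simulation results across kernels and partitions.

## Benchmark network

A balanced random network of `N` LIF neurons, 80 % excitatory and 20 %
inhibitory, each receiving exactly `K` randomly drawn incoming connections
(`round(0.8·K)` from the excitatory population, the rest inhibitory),
sampled uniformly with replacement; self-connections are allowed.
Inhibitory weights are `-g·J` with `g = 5`. Excitatory-excitatory
connections are plastic (STDP); all others static. Each neuron receives
independent external Poisson drive.

The numeric constants are *configurable defaults of this package*, not
architecture facts: neuron constants follow common LIF-alpha conventions
(`tau_m` = 10 ms, `C_m` = 250 pF, `E_L = V_reset` = −65 mV, `V_th` = −50 mV,
`t_ref` = 2 ms, `tau_syn` = 0.5 ms), `J` = 70 pA (alpha-PSC peak),
`d_min` = 1.5 ms, grid step `h` = 0.1 ms. The external drive
(3000 events/s per neuron at 70 pA) was chosen once so that the default
network settles into a sparse asynchronous-irregular state at a few
spikes/s — the regime such benchmark networks are operated in — and is not
tuned per experiment.

Connectivity is generated *globally* from one seed and partitioned
afterwards, unlike the per-process RNG streams of production simulators.
This makes the network a pure function of `(params, seed)`, which is what
allows cross-partition bit-equivalence tests at all. Global ids start at 0
and are distributed round-robin over virtual processes:
`vp = gid mod (M·T)`, `rank = vp mod M`, `thread = vp div M`.

## Neuron dynamics

Subthreshold dynamics (two alpha-current pairs, one per receptor sign, plus
the membrane equation) are linear; they are advanced by *exact integration*:
the affine one-step propagator is the matrix exponential of the augmented
6×6 system matrix, computed once per run with `scipy.linalg.expm`. A spike
with weight `w` adds `w·e/tau_syn` to the first current variable, producing
a postsynaptic current that peaks at `w` pA after `tau_syn`. Threshold
crossing at the end of a step emits a spike stamped `(step+1)·h`, resets
`V` to `V_reset` and clamps it there for `t_ref/h` steps (synaptic state
keeps evolving). All state updates are elementwise numpy operations, so a
neuron's trajectory is bit-identical regardless of how neurons are grouped
into ranks — the foundation of the equivalence guarantees.

Ring buffers hold accumulated input per future grid step; reading a slot
clears it, and a write at or before the read head raises a causality error
(it would mean a delay below `d_min`).

## Plasticity

The STDP rule is pair-based with exponential windows and optional power-law
weight dependence, evaluated lazily when a presynaptic spike is delivered:

* **facilitation** — every postsynaptic spike in the processing window is
  paired against the synapse's presynaptic trace `K_plus` (exponentially
  decayed sum over *all* earlier pre spikes, stored per connection):
  `w += λ · w_max · (1 − w/w_max)^{μ+} · K_plus · e^{−Δt/τ+}`;
* **depression** — the new pre spike is paired against the postsynaptic
  trace reconstructed from the target's spike archive (all post spikes
  strictly before `t_pre`):
  `w −= α · λ · w_max · (w/w_max)^{μ−} · Σ e^{−Δt/τ−}`;
* `w` is clipped to `[0, w_max]` after each contribution.

The transmission delay is treated as purely dendritic: a pre spike
delivered at emission time `t_pre` processes exactly the post spikes whose
synaptic arrival `t_post + dd` falls in `(t_last_pre + dd, t_pre + dd]`.
The dendritic shift cancels inside that window, so pairings use
emission-time differences. Because delivery happens after the interval
containing `t_pre` has been fully simulated, all post spikes `≤ t_pre` are
in the archive when needed — the min-delay causality argument applied to
plasticity. Per-connection state is `(w, t_last_pre, K_plus)`; storing the
last pre-spike time per connection (rather than once per source) is
precisely the memory cost the two-tier design accepts, and it is what makes
the optional source purge harmless.

Defaults (`τ± = 15/30 ms`, `λ = 0.01`, `α = 0.5`, `μ± = 0`,
`w_max = 2·J`) are additive-rule defaults chosen for visible but bounded
weight drift at the default activity level; they are configuration, not
claims.

## Canonical accumulation and bit-exact equivalence

Floating-point addition is not associative, and different kernels deliver
the same spikes in different orders. All variants therefore stage
deliveries per rank and apply them at the end of each communication
interval in one canonical order: ascending
`(arrival step, emission step, global connection id)`. The global
connection id (the row index in the generated connection list) is a
partition-independent total order that remains available after source gids
are purged; it refines the (source gid, synapse type) order that would
otherwise leave ties between same-source same-type connections. Under
this ordering the per-slot ring-buffer sums and the per-synapse STDP update
sequences are identical in every variant and partition, which upgrades the
usual "statistically equivalent" cross-kernel comparison to bit equality of
spike records and final weights.

External drive is generated per neuron from `default_rng([drive_seed, gid])`
— a counter-keyed stream independent of the partition.

## Communication emulation

Sectioned all-to-all and concatenating allgather are emulated with exact
transpose/concatenation semantics over per-rank buffers of
`(payload, flag)` entries. The 2-bit flag rides beside the payload
(0 default, 1 no-more-data, 2 end-of-valid, 3 skip-section); buffer sizes
are denominated in entries, start from a policy value (connectivity
exchange: sized by a collective max-count query first, capped by policy),
and double between rounds up to the policy maximum. Round loops continue
until every rank has drained its queues; conservation is guaranteed by
per-thread cursors plus `processed` flags on source entries (connectivity)
and by per-destination cursors (spikes). The presynaptic-construction
collocation assigns each thread a consecutive range of `ceil(M/T)`
destination ranks, which also defines the writer-thread dimension of the
4-D spike register `[source thread][writer thread][lag][entries]`.

The packed target word is 64 bits: rank 20, tid 10, syn_id 6, lcid 27,
status 1 (low to high: status, lcid, syn_id, tid, rank). Only the 8-byte
total is fixed by the design; this split covers ~10^6 ranks and 1.3·10^8
connections per (thread, type) container. The two source-entry flags are
given concrete semantics here: `processed` (emitted into the connectivity
exchange; makes multi-round collocation resumable) and `disabled`
(connection logically removed; never communicated or delivered).

## Memory model

See the README for the three-component formula. Decisions taken here:
`B_c`/`B_s` are entry counts (matching the entry-denominated emulation);
`ν_max` is interpreted as maximal spikes per neuron per communication
interval (it multiplies the spike-buffer entry count); the neuron term
`Mn` is a pluggable callable defaulting to a linear `a·N_M` form, since its
detailed composition belongs to neuron infrastructure outside this
package's scope. Default byte sizes describe this implementation's
idealised objects; a "paper-shaped" profile with 8-byte wire/table entries
is provided for qualitative curve shapes only. The model's count terms
(source entries `K·N_M`, per-type synapse splits, target-entry counts) are
validated exactly against live instrumented runs; byte totals are
configuration and never asserted against hardware measurements.

`max_network_size` bisects over multiples of `M` using the model's
monotonicity in `N`.

## Sparsity model

`Binomial(K, 1/M)` evaluated in log space. The pmf conditions on
out-degree exactly `K`; the benchmark generator fixes the *in*-degree, so
realised out-degrees are Binomial(`N·K`, 1/`N`) with mean `K`. The
Monte-Carlo agreement check therefore samples ideal out-degree-`K` neurons;
generator-based checks only assert the mean.

## What the emulation does and does not show

Passing tests demonstrate: exact routing correctness of both kernel
designs under arbitrary buffer caps and round counts; the directedness of
the two-tier exchange (every received entry has a local target); the
receive-volume asymmetry (allgather volume `M`·spikes vs constant
all-to-all volume — compared per spike entry this requires one synapse
type per source, since sorted mode emits one group head per type and
thread); and the analytic scale-invariance of the per-rank memory model.
They do not show anything about wall-clock performance, network latency,
allocator behaviour, or absolute memory on real hardware — the quantities
the original designs were ultimately judged on. The emulated rank loop is
sequential; race conditions of real shared-memory collocation are out of
reach by construction.

## Numerical and degenerate-input choices

* `t_sim` is rounded up to whole communication intervals; `t_sim = 0` is a
  valid degenerate run (empty spike record, initial weights reported).
* Delays are rounded to grid steps and must be `≥ d_min` (checked before
  the run starts).
* Simultaneous post spike and pre delivery (`t_post == t_pre`): the post
  spike facilitates (window is closed on the right) and does not depress
  (depression uses strictly earlier posts).
* Sorting is stable per `(thread, syn_type)` container, so equal source
  gids keep insertion order; the subsequent-same-source marker, not the
  gid, terminates the sorted delivery walk — delivery is unaffected by
  purging.
* Postsynaptic spike archives are kept whole for the run lengths used
  here; `PostTrace.truncate` bounds them for long runs (entries older than
  ~10·max(τ±) before any still-queryable time are negligible at double
  precision).

## Problem sizes

Equivalence checks run the default benchmark at `N = 1000`, `K = 100`,
1 s biological time on partitions up to 4 ranks, and smaller networks
(`N ≤ 200`) for construction-bijection sweeps; `scripts/acceptance.py`
uses `N = 300`, `K = 30`, 0.3 s for its equivalence quantities. These
sizes exercise every code path (multi-round exchange included) while
keeping a full suite run in the minutes range.
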