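# sparsespike

Desk-scale emulation of the connection infrastructures and spike-exchange
schemes used by distributed spiking-neuronal-network simulators — built so
that the architectural claims behind "two-tier + directed communication"
kernel designs can be tested exactly, on one workstation, without a
supercomputer.

## The problem

Simulators for networks of leaky integrate-and-fire (LIF) neurons
distribute neurons round-robin over `M` message-passing ranks with `T`
threads each, and exchange spikes at intervals of the minimal synaptic delay
`d_min`. With a fixed in-degree `K` per neuron, per-rank connectivity
becomes extremely sparse as `M` grows: the number of targets a neuron has on
a given rank is Binomial(`K`, 1/`M`), so beyond `M ≈ K` most spikes arriving
at a rank have no local target at all. Two kernel generations deal with
this differently:

* **Source-routed baseline ("4g")** — connections live only on the target's
  rank in a per-thread *sparse table* keyed by source gid (48 gids per
  group, one presence bit each). Spikes travel as source addresses via an
  allgather: every rank receives every spike and discards the irrelevant
  ones. Receive volume and lookup structures grow with total network size.
* **Two-tier kernel ("5g")** — the target rank keeps two parallel
  `[thread][syn_type][lcid]` tables (connections and their sources); the
  source's rank additionally keeps a *target table* of packed 8-byte
  `(rank, tid, syn_id, lcid)` words built by a sectioned all-to-all
  exchange. Spikes then travel *directed*: each rank receives only the
  connection handles it must deliver. Optionally, connections are sorted
  by source gid ("5g-sort") so one spike per thread covers all same-source
  connections, or source gids are purged after construction to save memory.

The package implements both kernels over *emulated* ranks, plus a serial
reference kernel, an analytic per-rank memory model

```
M(M,T,N) = M0 + Mn + Mc
M0 = Mb + min(Bc, N_M·min(K,MT))·m_td + min(Bs, N_M·ν_max·min(K,MT))·m_sd
Mc = K_stat·mc_stat + K_stdp·mc_stdp + K·N_M·m_s + N_M·min(K,MT)·m_t
```

(`N_M = N/M` neurons per rank), and the Binomial(`K`, 1/`M`) target-count
model. Dynamics are exact-integration LIF with alpha-shaped postsynaptic
currents and pair-based STDP on excitatory-excitatory connections. All
four kernel variants produce **bit-identical** spike records and final
plastic weights on every partition — floating-point accumulation and STDP
updates are applied in one canonical order everywhere.

## Worked example

```python
import sparsespike as sp
from sparsespike.simloop import run

spec = sp.generate_benchmark(sp.BenchmarkParams(N=1000, K=100), seed=1)
res = run(spec, "5g-sort", sp.PartitionConfig(2, 2), t_sim=1000.0, drive_seed=1)
print(res.counters["n_spikes"])                          # 3466
print(res.counters["spike_exchange"]["entries_sent"])    # 24893
print(res.counters["spike_exchange"]["entries_used"])    # 24893
```

A balanced random network (800 excitatory / 200 inhibitory neurons, 100
inputs per neuron, STDP on E→E) fires 3466 spikes in 1 s (≈3.5 spikes/s per
neuron, a sparse asynchronous state). The directed exchange put 24,893
spike entries on the wire and *every* received entry was used locally —
with sorting, one entry covers all same-source connections on a thread, so
this is far below the ≈350,000 spike-connection deliveries actually
performed. Running the same `spec` with `"serial"`, `"4g"` or
`"5g-nosort"`, or with other `(M, T)` partitions, reproduces `res.spikes`
and `res.weights` exactly, bit for bit.

The binomial sparsity model shows the regime change that motivates directed
exchange (`sparsespike sparsity --k 10000 --m-list 32,10000,100000`):

```
M       P0        P1        P_multi
32      1.3e-138  4.2e-136  1.0
10000   0.368     0.368     0.264
100000  0.905     0.090     0.005
```

With 32 ranks every neuron has many targets per rank; at 100,000 ranks a
neuron has *no* target on 90.5 % of ranks — exactly the waste the allgather
baseline pays for.

The CLI exposes the same machinery: `sparsespike simulate` (writes spike
GDF, weight TSV and an instrumentation JSON), `compare` (diffs two kernel
variants), `scaling weak|strong|maxfill`, `predict` (memory-model TSV) and
`sparsity`.

## Layout

| module | contents |
| --- | --- |
| `network` | partition arithmetic, benchmark generator, TSV/JSON I/O |
| `dynamics` | exact-integration LIF-alpha, ring buffers, STDP rule |
| `infra5g` | two-tier tables, 8-byte packed targets, sort, purge |
| `infra4g` | sparse-table baseline with 48-gid groups |
| `comm` | emulated all-to-all / allgather, section flags, buffer growth |
| `presyn` | construction of the presynaptic tier (multi-round exchange) |
| `simloop` | min-delay event loop, spike register, all kernel variants |
| `memory_model` | analytic per-rank memory model + live-count validation |
| `sparsity` | binomial target-count model |
| `cli` | `sparsespike` command-line front end |

See `docs/methods.md` for model details, parameter conventions and known
limitations.
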