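"""The min-delay event loop for all kernel variants.

Because every synaptic transmission delay is at least the minimal delay
``d_min``, neuron dynamics are decoupled over that horizon: all ranks
advance their neurons for one communication interval of ``d_min/h`` grid
steps, buffer the spikes that occurred, exchange them collectively, and
deliver them into ring buffers before the next interval starts.

Four kernel variants share one dynamics implementation and differ only in
routing:

* ``serial``   — single partition, direct source-to-targets delivery; the
                 reference oracle for all equivalence checks.
* ``4g``       — source-based AER: spikes travel as (gid, lag) via an
                 allgather; every thread looks gids up in its sparse table.
* ``5g-sort``  — target-based AER via the two-tier infrastructure with
                 connections sorted by source (one spike per thread per
                 source, expanded by the subsequent-same-source walk).
* ``5g-nosort``— as above without sorting: one spike entry per connection.

All variants apply deliveries in one canonical order — ascending
(arrival step, emission step, global connection id) per rank — so spike
records and final plastic weights are bit-identical across variants and
partitions for a fixed network and drive seed.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import network as net
from .comm import (BufferPolicy, CommCounters, SectionedBuffer, ProtocolError,
                   all_gather, all_to_all, finalize_section, grow_buffer, read_section)
from .dynamics import (LifAlphaPropagator, NeuronParams, NeuronPopulation, PostTrace,
                       RingBuffer, StdpParams, stdp_update_on_pre)
from .infra4g import SparseTable
from .infra5g import PostsynapticTables, TargetTable, unpack_target
from .network import (SYN_STATIC_INH, SYN_STDP_EE, BenchmarkParams, NetworkSpec,
                      PartitionConfig, assign_rank_thread, local_id)
from .presyn import build_presynaptic

__all__ = ["VARIANTS", "SimResult", "SpikeRegister", "run", "serial_reference",
           "writer_thread"]

VARIANTS = ("serial", "4g", "5g-sort", "5g-nosort")

N_SYN_TYPES = 3


def writer_thread(target_rank: int, P: PartitionConfig) -> int:
    """Thread that will collocate entries destined for ``target_rank``."""
    return target_rank // math.ceil(P.M / P.T)


class SpikeRegister:
    """4-D spike buffer: [source thread][writer thread][lag] -> target entries.

    Holds unpacked target locations between the moment a neuron spikes and
    the collocation of the MPI send buffer at the end of the communication
    interval; cleared after every interval.
    """

    def __init__(self, T: int, n_lags: int):
        self.T = T
        self.n_lags = n_lags
        self.entries: list[list[list[list]]] = [
            [[[] for _ in range(n_lags)] for _ in range(T)] for _ in range(T)]
        self.total_buffered = 0

    def buffer_spike(self, source_thread: int, targets, lag: int,
                     P: PartitionConfig) -> None:
        """Append a copy of each target of one spike at the right position."""
        for rank, tid, syn_id, lcid in targets:
            w = writer_thread(rank, P)
            self.entries[source_thread][w][lag].append((rank, tid, syn_id, lcid))
            self.total_buffered += 1

    def clear(self) -> None:
        for per_writer in self.entries:
            for per_lag in per_writer:
                for lst in per_lag:
                    lst.clear()

    def drain_for_writer(self, thread: int, P: PartitionConfig):
        """Per-destination queues of (tid, syn_id, lcid, lag) for one writer thread.

        Iteration order (source thread, then lag, then insertion) is fixed;
        it only affects wire order, never results, thanks to canonical
        delivery ordering.
        """
        queues: dict[int, list] = {}
        for src_thread in range(self.T):
            for lag in range(self.n_lags):
                for rank, tid, syn_id, lcid in self.entries[src_thread][thread][lag]:
                    queues.setdefault(rank, []).append((tid, syn_id, lcid, lag))
        return queues


@dataclass
class SimResult:
    """Spike record, final plastic weights and instrumentation of one run."""

    spikes: np.ndarray  # (n, 2): gid, spike time in ms; sorted by (time, gid)
    weights: np.ndarray  # (m, 2): global connection id, final weight; sorted
    counters: dict
    timers: dict  # build/init/sim wall-clock seconds (informational only)
    state: list = field(default_factory=list)  # per-rank runtime state (instrumentation)


class _RankState:
    """Everything one emulated rank owns at run time."""

    def __init__(self, rank: int, spec: NetworkSpec, P: PartitionConfig,
                 prop: LifAlphaPropagator, total_steps: int, ring_len: int,
                 drive_seed: int, h: float):
        self.rank = rank
        N = spec.params.N
        self.gids = np.arange(N, dtype=np.int64)
        r, t = assign_rank_thread(self.gids, P)
        mask = r == rank
        self.gids = self.gids[mask]  # ascending
        self.threads = t[mask]
        self.n_local = len(self.gids)
        self.pop = NeuronPopulation(self.n_local, prop)
        self.ring_ex = RingBuffer(max(self.n_local, 1), ring_len)
        self.ring_in = RingBuffer(max(self.n_local, 1), ring_len)
        self.post = [PostTrace() for _ in range(self.n_local)]
        params = spec.params
        lam = params.drive_rate * h * 1e-3
        drive = np.empty((self.n_local, total_steps), dtype=np.uint8)
        for i, gid in enumerate(self.gids):
            rng = np.random.default_rng([drive_seed, int(gid)])
            drive[i] = rng.poisson(lam, total_steps)
        self.drive = drive
        self.drive_weight = params.drive_weight
        # variant-specific routing structures filled during build
        self.post_tables: PostsynapticTables | None = None
        self.target_table: TargetTable | None = None
        self.unpacked_targets: list[list[list[tuple]]] | None = None
        self.sparse: list[SparseTable] | None = None
        self.serial_index = None
        self.register: SpikeRegister | None = None
        self.events: list = []
        self.deliveries = 0

    def local_row(self, gid: int) -> int:
        i = int(np.searchsorted(self.gids, gid))
        return i


def _build_post_tables(spec: NetworkSpec, P: PartitionConfig, ranks: list[_RankState],
                       delay_steps: np.ndarray) -> None:
    t_rank, t_thread = assign_rank_thread(spec.target, P)
    for gcid in range(spec.n_connections):
        rs = ranks[t_rank[gcid]]
        rs.post_tables.add_connection(
            tid=int(t_thread[gcid]), syn_id=int(spec.syn_type[gcid]),
            source_gid=int(spec.source[gcid]),
            tgt_local=rs.local_row(int(spec.target[gcid])),
            weight=float(spec.weight[gcid]), delay_steps=int(delay_steps[gcid]),
            gcid=gcid)


def _build_sparse_tables(spec: NetworkSpec, P: PartitionConfig, ranks: list[_RankState],
                         delay_steps: np.ndarray) -> None:
    t_rank, t_thread = assign_rank_thread(spec.target, P)
    N = spec.params.N
    for rs in ranks:
        rs.sparse = [SparseTable(N - 1) for _ in range(P.T)]
    for gcid in range(spec.n_connections):
        rs = ranks[t_rank[gcid]]
        rs.sparse[int(t_thread[gcid])].sparse_insert(
            int(spec.source[gcid]), int(spec.syn_type[gcid]),
            rs.local_row(int(spec.target[gcid])),
            float(spec.weight[gcid]), int(delay_steps[gcid]), gcid)


class _SerialIndex:
    """CSR map source gid -> (syn_id, lcid) list for direct delivery."""

    def __init__(self, spec: NetworkSpec, tables: PostsynapticTables):
        order = np.argsort(spec.source, kind="stable")
        self.sorted_sources = spec.source[order]
        # lcid of connection gcid within its (tid=0, syn) block = position
        # among connections of the same syn type, in gcid order
        syn = spec.syn_type
        lcid_of = np.zeros(len(syn), dtype=np.int64)
        for s in range(N_SYN_TYPES):
            m = syn == s
            lcid_of[m] = np.arange(int(m.sum()))
        self.syn = syn[order]
        self.lcid = lcid_of[order]

    def targets_of(self, gid: int):
        lo = np.searchsorted(self.sorted_sources, gid, side="left")
        hi = np.searchsorted(self.sorted_sources, gid, side="right")
        return [(0, int(self.syn[i]), int(self.lcid[i])) for i in range(lo, hi)]


def _unpack_target_table(rs: _RankState, P: PartitionConfig) -> None:
    table = rs.target_table
    rs.unpacked_targets = [
        [[unpack_target(w)[:4] for w in table.lookup_targets(t, l)]
         for l in range(len(table.entries[t]))]
        for t in range(P.T)]


def _stage_event(rs: _RankState, block, idx: int, syn_id: int, emission_step: int,
                 h: float) -> None:
    arrival = emission_step + int(block.delay_steps[idx])
    rs.events.append((arrival, emission_step, int(block.gcid[idx]), syn_id, block, idx))


def _apply_events(rs: _RankState, stdp: StdpParams, h: float) -> None:
    """Apply one interval's deliveries in canonical order.

    Sorting by (arrival step, emission step, gcid) fixes both the
    floating-point accumulation order in each ring-buffer slot and the
    sequence of STDP updates, independent of variant and partition.
    """
    rs.events.sort(key=lambda e: (e[0], e[1], e[2]))
    for arrival, emission_step, gcid, syn_id, block, idx in rs.events:
        row = int(block.tgt_local[idx])
        w = block.weight[idx]
        if syn_id == SYN_STDP_EE:
            t_pre = (emission_step + 1) * h
            dd = block.delay_steps[idx] * h
            w, k = stdp_update_on_pre(w, t_pre, block.t_last_pre[idx],
                                      rs.post[row].times, dd, stdp,
                                      K_plus=block.K_plus[idx])
            block.weight[idx] = w
            block.K_plus[idx] = k
            block.t_last_pre[idx] = t_pre
        ring = rs.ring_in if syn_id == SYN_STATIC_INH else rs.ring_ex
        ring.add(row, arrival, w)
        rs.deliveries += 1
    rs.events.clear()


def _exchange_spikes_5g(ranks: list[_RankState], P: PartitionConfig,
                        interval_start: int, capacity: int, policy: BufferPolicy,
                        counters: CommCounters, h: float,
                        sorted_mode: bool) -> int:
    """Collocate, exchange (with rounds), and stage deliveries for one interval."""
    queues = []  # per rank: list over threads of dict dest -> entries
    cursors = []
    for rs in ranks:
        per_thread = [rs.register.drain_for_writer(t, P) for t in range(P.T)]
        queues.append(per_thread)
        cursors.append([{dest: 0 for dest in q} for q in per_thread])
        rs.register.clear()

    def remaining(rank: int) -> int:
        return sum(len(q[dest]) - cur[dest]
                   for q, cur in zip(queues[rank], cursors[rank]) for dest in q)

    rounds = 0
    while True:
        sends = []
        for rank, rs in enumerate(ranks):
            send = SectionedBuffer(n_sections=P.M, entries_per_section=capacity)
            leftover = [False] * P.M
            for t in range(P.T):
                for dest, entries in queues[rank][t].items():
                    cur = cursors[rank][t][dest]
                    section = send.section(dest)
                    take = min(capacity - len(section), len(entries) - cur)
                    section.extend((e, 0) for e in entries[cur: cur + take])
                    cursors[rank][t][dest] = cur + take
                    if cursors[rank][t][dest] < len(entries):
                        leftover[dest] = True
            counters.entries_sent += sum(len(s) for s in send.sections)
            for r in range(P.M):
                send.sections[r] = finalize_section(send.sections[r], capacity,
                                                    sender_done=not leftover[r])
            sends.append(send)

        recvs = all_to_all(sends)
        rounds += 1
        for rank, rs in enumerate(ranks):
            for sender in range(P.M):
                payloads, _ = read_section(recvs[rank].section(sender))
                counters.entries_received += len(payloads)
                for tid, syn_id, lcid, lag in payloads:
                    counters.entries_used += 1
                    block = rs.post_tables.conn[tid][syn_id]
                    if lcid >= block.n:
                        raise ProtocolError("received handle outside local tables")
                    emission = interval_start + lag
                    _stage_event(rs, block, lcid, syn_id, emission, h)
                    if sorted_mode:
                        cur = lcid
                        while block.marker[cur]:
                            cur += 1
                            _stage_event(rs, block, cur, syn_id, emission, h)

        if not any(remaining(r) for r in range(P.M)):
            break
        capacity = grow_buffer(policy, capacity)
    counters.rounds += rounds
    counters.final_buffer_entries = capacity
    return capacity


def _exchange_spikes_4g(ranks: list[_RankState], P: PartitionConfig,
                        spikes_per_rank: list[list], interval_start: int,
                        capacity: int, policy: BufferPolicy,
                        counters: CommCounters, h: float) -> int:
    """Source-AER allgather of (gid, lag) with the same flag/round protocol."""
    cursors = [0] * P.M
    rounds = 0
    while True:
        sends = []
        done = []
        for rank in range(P.M):
            pend = spikes_per_rank[rank]
            cur = cursors[rank]
            take = min(capacity, len(pend) - cur)
            section = [(e, 0) for e in pend[cur: cur + take]]
            cursors[rank] = cur + take
            counters.entries_sent += take
            sender_done = cursors[rank] >= len(pend)
            done.append(sender_done)
            sends.append(finalize_section(section, capacity, sender_done=sender_done))

        recv = all_gather(sends)[0]  # identical on every rank
        rounds += 1
        for rs in ranks:
            for sender in range(P.M):
                section = recv[sender * capacity: (sender + 1) * capacity]
                payloads, _ = read_section(section)
                counters.entries_received += len(payloads)
                for gid, lag in payloads:
                    used = False
                    emission = interval_start + lag
                    for tid in range(P.T):
                        for syn_id, block, idx in rs.sparse[tid].deliver_4g(gid):
                            used = True
                            _stage_event(rs, block, idx, syn_id, emission, h)
                    if used:
                        counters.entries_used += 1

        if all(done):
            break
        capacity = grow_buffer(policy, capacity)
    counters.rounds += rounds
    counters.final_buffer_entries = capacity
    return capacity


def run(spec: NetworkSpec, variant: str = "serial",
        P: PartitionConfig | None = None, t_sim: float = 1000.0, *,
        h: float = 0.1, d_min: float = 1.5,
        neuron: NeuronParams | None = None, stdp: StdpParams | None = None,
        drive_seed: int = 0, spike_policy: BufferPolicy | None = None,
        conn_policy: BufferPolicy | None = None,
        purge_sources: bool = False, pre_sim_ms: float = 0.0) -> SimResult:
    """Simulate ``spec`` for ``t_sim`` ms with the chosen kernel variant.

    ``pre_sim_ms`` prepends a short settling simulation whose wall-clock time
    is accounted to the init phase (spikes are recorded throughout; the time
    axis is continuous).  ``t_sim`` is rounded up to whole communication
    intervals of ``d_min``.
    Deterministic given (spec, drive_seed): all variants and partitions
    produce bit-identical spike records and final weights.  ``purge_sources``
    drops the stored source gids of the 5g tables after presynaptic
    construction (connectivity becomes frozen; results are unchanged).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "serial":
        P = PartitionConfig(1, 1)
    elif P is None:
        P = PartitionConfig(1, 1)
    if purge_sources and not variant.startswith("5g"):
        raise ValueError("source purging exists only in the two-tier kernel")
    neuron = neuron or NeuronParams()
    stdp = stdp or StdpParams()
    spike_policy = spike_policy or BufferPolicy(initial_entries=64, max_entries=1 << 20)
    conn_policy = conn_policy or BufferPolicy(initial_entries=2, max_entries=1 << 20)

    D = int(round(d_min / h))
    if D < 1:
        raise ValueError("d_min must be at least one grid step")
    delay_steps = np.round(spec.delay / h).astype(np.int64)
    if np.any(delay_steps < D):
        raise ValueError("all delays must be >= d_min")
    n_pre = math.ceil(pre_sim_ms / d_min) if pre_sim_ms > 0 else 0
    n_main = max(1, math.ceil(t_sim / d_min)) if t_sim > 0 else 0
    n_intervals = n_pre + n_main
    total_steps = n_intervals * D
    ring_len = int(delay_steps.max(initial=D)) + D + 1

    prop = LifAlphaPropagator(neuron, h)
    timers = {}
    t0 = time.perf_counter()

    ranks = [_RankState(r, spec, P, prop, max(total_steps, 1), ring_len, drive_seed, h)
             for r in range(P.M)]
    sorted_mode = variant == "5g-sort"
    conn_counters = CommCounters()
    if variant in ("serial", "5g-sort", "5g-nosort"):
        for rs in ranks:
            rs.post_tables = PostsynapticTables(P.T, N_SYN_TYPES)
        _build_post_tables(spec, P, ranks, delay_steps)
    else:
        _build_sparse_tables(spec, P, ranks, delay_steps)
    timers["build_time"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if variant.startswith("5g"):
        if sorted_mode:
            for rs in ranks:
                rs.post_tables.sort_all()
        tables = [rs.post_tables for rs in ranks]
        target_tables, conn_counters = build_presynaptic(
            tables, P, spec.params.N, policy=conn_policy, sorted_mode=sorted_mode)
        for rs, tt in zip(ranks, target_tables):
            rs.target_table = tt
            _unpack_target_table(rs, P)
            rs.register = SpikeRegister(P.T, D)
        if purge_sources:
            for rs in ranks:
                rs.post_tables.purge_sources()
    elif variant == "serial":
        ranks[0].serial_index = _SerialIndex(spec, ranks[0].post_tables)
        ranks[0].post_tables.freeze()
    timers["init_time"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    spike_counters = CommCounters()
    spike_capacity = spike_policy.initial_entries
    spikes_out: list[tuple[int, float]] = []

    for interval in range(n_intervals):
        if n_pre and interval == n_pre:
            # settling phase accounted to init, per the three-phase convention
            timers["init_time"] += time.perf_counter() - t0
            t0 = time.perf_counter()
        interval_start = interval * D
        spikes_4g: list[list] = [[] for _ in range(P.M)]
        for rs in ranks:
            for lag in range(D):
                s = interval_start + lag
                input_ex = rs.ring_ex.take(s)
                input_in = rs.ring_in.take(s)
                if rs.n_local == 0:
                    continue
                input_ex = input_ex + rs.drive[:, s] * rs.drive_weight
                spiked = rs.pop.step(input_ex, input_in)
                for row in np.flatnonzero(spiked):
                    gid = int(rs.gids[row])
                    t_spike = (s + 1) * h
                    spikes_out.append((gid, t_spike))
                    rs.post[row].append(t_spike)
                    if variant.startswith("5g"):
                        tid = int(rs.threads[row])
                        lid = int(local_id(gid, P))
                        rs.register.buffer_spike(tid, rs.unpacked_targets[tid][lid],
                                                 lag, P)
                    elif variant == "4g":
                        spikes_4g[rs.rank].append((gid, lag))
                    else:  # serial: direct delivery staging
                        for tid, syn_id, lcid in rs.serial_index.targets_of(gid):
                            block = rs.post_tables.conn[tid][syn_id]
                            _stage_event(rs, block, lcid, syn_id, s, h)

        if variant.startswith("5g"):
            spike_capacity = _exchange_spikes_5g(
                ranks, P, interval_start, spike_capacity, spike_policy,
                spike_counters, h, sorted_mode)
        elif variant == "4g":
            spike_capacity = _exchange_spikes_4g(
                ranks, P, spikes_4g, interval_start, spike_capacity, spike_policy,
                spike_counters, h)

        for rs in ranks:
            _apply_events(rs, stdp, h)
    timers["sim_time"] = time.perf_counter() - t0

    spikes_out.sort(key=lambda e: (e[1], e[0]))
    spikes = np.array(spikes_out, dtype=float).reshape(-1, 2)

    # final plastic weights keyed by global connection id
    pairs = []
    for rs in ranks:
        if rs.post_tables is not None:
            blocks = [(s, rs.post_tables.conn[t][s]) for t in range(P.T)
                      for s in range(N_SYN_TYPES)]
        else:
            blocks = [(syn_id, conn.block)
                      for table in rs.sparse for g in table.groups
                      for c in g.connectors.values()
                      for syn_id, conn in c.by_type.items()]
        for syn_id, block in blocks:
            if syn_id != SYN_STDP_EE:
                continue
            for i in range(block.n):
                pairs.append((int(block.gcid[i]), float(block.weight[i])))
    pairs.sort()
    weights = np.array(pairs, dtype=float).reshape(-1, 2)

    counters = {
        "variant": variant,
        "M": P.M, "T": P.T,
        "deliveries": sum(rs.deliveries for rs in ranks),
        "register_entries": sum(rs.register.total_buffered for rs in ranks
                                if rs.register is not None),
        "spike_exchange": spike_counters.as_dict(),
        "connectivity_exchange": conn_counters.as_dict(),
        "n_spikes": len(spikes_out),
    }
    return SimResult(spikes=spikes, weights=weights, counters=counters,
                     timers=timers, state=ranks)


def serial_reference(spec: NetworkSpec, t_sim: float, **kwargs) -> SimResult:
    """Single-partition direct-delivery oracle with identical dynamics."""
    return run(spec, "serial", PartitionConfig(1, 1), t_sim, **kwargs)
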