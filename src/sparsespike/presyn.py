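"""Construction of the presynaptic tier from the postsynaptic tables.

After the postsynaptic build phase, every rank knows the connections whose
*targets* live locally; the ranks of the corresponding *sources* need that
information to route spikes.  It is exchanged with the sectioned all-to-all:
each thread scans all local source entries and is responsible for a
consecutive range of ``ceil(M/T)`` source ranks, emitting one TargetData
record per connection (nosort) or per sorted group head (sort) into the
section of the source's rank.  An initial collective query sizes the first
buffer to the maximal pairwise entry count, capped by policy; if capped,
`processed` flags on the source entries together with per-thread cursors
make the scan resumable, and further doubled-buffer rounds run until every
rank has signalled completion via the flag protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .comm import (BufferPolicy, CommCounters, SectionedBuffer, ProtocolError,
                   all_gather, all_to_all, finalize_section, grow_buffer, read_section)
from .infra5g import ConnectionHandle, PostsynapticTables, TargetTable, pack_target
from .network import PartitionConfig, assign_rank_thread, local_id

__all__ = ["TargetData", "CollocationState", "thread_rank_range",
           "collocate_target_data", "build_presynaptic"]


@dataclass(frozen=True)
class TargetData:
    """One communicated record: where a source neuron lives and where one of
    its connections sits on the target rank."""

    source_thread: int
    source_lid: int
    target_rank: int
    handle: ConnectionHandle


def thread_rank_range(thread: int, P: PartitionConfig) -> range:
    """Consecutive range of source ranks thread ``thread`` collocates for."""
    width = math.ceil(P.M / P.T)
    return range(thread * width, min((thread + 1) * width, P.M))


def _is_group_head(tables: PostsynapticTables, tid: int, syn_id: int, lcid: int) -> bool:
    # After sorting, an entry is the head of its same-source run iff its
    # predecessor does not carry the subsequent-same-source marker.  Without
    # sorting no markers are set and every entry is a head.
    block = tables.conn[tid][syn_id]
    return lcid == 0 or not block.marker[lcid - 1]


@dataclass
class CollocationState:
    """Resumable round state of one rank's collocation.

    ``queues[thread][rank]`` lists the (tid, syn_id, lcid, source gid)
    records thread ``thread`` still has to emit towards ``rank``, in scan
    order; ``cursors`` index the next unemitted record.  Built by a single
    scan over the source table, honouring `disabled` flags and skipping
    already-`processed` entries.
    """

    queues: list[list[list[tuple[int, int, int, int]]]]
    cursors: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cursors:
            self.cursors = [[0] * len(per_rank) for per_rank in self.queues]

    @classmethod
    def scan(cls, tables: PostsynapticTables, P: PartitionConfig) -> "CollocationState":
        queues = [[[] for _ in range(P.M)] for _ in range(P.T)]
        owner = [0] * P.M  # rank -> collocating thread
        for t in range(P.T):
            for r in thread_rank_range(t, P):
                owner[r] = t
        for tid in range(tables.n_threads):
            for syn_id in range(tables.n_syn_types):
                gids = tables.src_gid[tid][syn_id]
                disabled = tables.src_disabled[tid][syn_id]
                processed = tables.src_processed[tid][syn_id]
                for lcid, gid in enumerate(gids):
                    if disabled[lcid] or processed[lcid]:
                        continue
                    if not _is_group_head(tables, tid, syn_id, lcid):
                        continue
                    src_rank, _ = assign_rank_thread(gid, P)
                    queues[owner[src_rank]][src_rank].append((tid, syn_id, lcid, gid))
        return cls(queues=queues)

    def remaining(self) -> int:
        return sum(len(q) - c for per_rank, per_cur in zip(self.queues, self.cursors)
                   for q, c in zip(per_rank, per_cur))


def collocate_target_data(tables: PostsynapticTables, P: PartitionConfig,
                          my_rank: int, thread: int, capacity: int,
                          send: SectionedBuffer, state: CollocationState) -> list[bool]:
    """Fill thread ``thread``'s share of the rank's send buffer for one round.

    Emits up to ``capacity`` records into each section of the thread's
    assigned rank range, marking emitted source entries `processed`; records
    that do not fit stay queued for the next round (never silent loss).
    Returns per-destination leftover flags.
    """
    leftover = [False] * P.M
    for dest in thread_rank_range(thread, P):
        queue = state.queues[thread][dest]
        cursor = state.cursors[thread][dest]
        section = send.section(dest)
        room = capacity - len(section)
        take = min(room, len(queue) - cursor)
        for tid, syn_id, lcid, gid in queue[cursor: cursor + take]:
            record = TargetData(
                source_thread=assign_rank_thread(gid, P)[1],
                source_lid=int(local_id(gid, P)),
                target_rank=my_rank,
                handle=ConnectionHandle(tid=tid, syn_id=syn_id, lcid=lcid),
            )
            section.append((record, 0))
            tables.src_processed[tid][syn_id][lcid] = True
        state.cursors[thread][dest] = cursor + take
        if state.cursors[thread][dest] < len(queue):
            leftover[dest] = True
    return leftover


def build_presynaptic(post_tables: list[PostsynapticTables], P: PartitionConfig,
                      N: int, policy: BufferPolicy | None = None,
                      sorted_mode: bool = False,
                      max_rounds: int = 100_000) -> tuple[list[TargetTable], CommCounters]:
    """Run the sectioned exchange until every rank holds its target table.

    ``post_tables`` holds one postsynaptic table per rank; in sorted mode the
    tables must already be sorted by source.  Returns per-rank target tables
    plus aggregated instrumentation counters.  Ends the build phase of the
    postsynaptic tables.
    """
    if len(post_tables) != P.M:
        raise ValueError("need one postsynaptic table per rank")
    if sorted_mode and any(not t.sorted_by_source and t.n_connections() > 0
                           for t in post_tables):
        raise ProtocolError("sorted mode requires sort_connections_by_source first")
    policy = policy or BufferPolicy(initial_entries=2, max_entries=1 << 20)

    # reset any stale construction flags so rebuilding is idempotent
    for tables in post_tables:
        for per_syn in tables.src_processed:
            for flags in per_syn:
                for i in range(len(flags)):
                    flags[i] = False

    n_local = [[len(range(r + t * P.M, N, P.V)) for t in range(P.T)] for r in range(P.M)]
    target_tables = [TargetTable(P.T, n_local[r]) for r in range(P.M)]
    counters = CommCounters()

    states = [CollocationState.scan(tables, P) for tables in post_tables]

    # collective sizing query: max entries between any pair of ranks
    per_rank_counts = [[sum(len(state.queues[t][r]) for t in range(P.T))
                        for r in range(P.M)] for state in states]
    gathered = all_gather([[row] for row in per_rank_counts])
    max_pairwise = max((c for row in gathered[0] for c in row), default=0)
    capacity = policy.clamp(max(max_pairwise, 1))

    rounds = 0
    while any(state.remaining() for state in states) or rounds == 0:
        if rounds >= max_rounds:
            raise ProtocolError("presynaptic construction did not converge")
        sends = []
        for rank, (tables, state) in enumerate(zip(post_tables, states)):
            send = SectionedBuffer(n_sections=P.M, entries_per_section=capacity)
            leftover = [False] * P.M
            for thread in range(P.T):
                thread_left = collocate_target_data(tables, P, rank, thread,
                                                    capacity, send, state)
                leftover = [a or b for a, b in zip(leftover, thread_left)]
            counters.entries_sent += sum(len(s) for s in send.sections)
            for r in range(P.M):
                send.sections[r] = finalize_section(send.sections[r], capacity,
                                                    sender_done=not leftover[r])
            sends.append(send)

        recvs = all_to_all(sends)
        for rank in range(P.M):
            recv = recvs[rank]
            table = target_tables[rank]
            for sender in range(P.M):
                payloads, _done = read_section(recv.section(sender))
                counters.entries_received += len(payloads)
                for record in payloads:
                    counters.entries_used += 1
                    word = pack_target(record.target_rank, record.handle.tid,
                                       record.handle.syn_id, record.handle.lcid)
                    table.add_entry(record.source_thread, record.source_lid, word)

        rounds += 1
        if any(state.remaining() for state in states):
            capacity = grow_buffer(policy, capacity)

    counters.rounds = rounds
    counters.final_buffer_entries = capacity

    for tables, table in zip(post_tables, target_tables):
        for per_syn in tables.src_processed:
            for flags in per_syn:
                for i in range(len(flags)):
                    flags[i] = False
        tables.freeze()
        table.constructed = True
    return target_tables, counters
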