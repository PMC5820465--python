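"""Two-tier connection infrastructure (the "5g" design).

Postsynaptic side, on the rank of the target neuron: two parallel 3-D
resizable arrays indexed ``[thread][syn_type][lcid]`` — the *connection
table* holding the synapse objects and the *source table* holding the
corresponding source gids with two construction flags.  The triple
``(tid, syn_id, lcid)`` uniquely identifies a connection on a rank and is the
unit of target-based address-event representation.

Presynaptic side, on the rank of the source neuron: the *target table*
stores, per thread-local neuron, the packed locations of all its targets,
each squeezed into a single 64-bit word.

The sort-by-source optimisation orders each ``[thread][syn_type]`` container
by source gid (stable) so that one received spike can walk all consecutive
connections of the same source; the walk is terminated by a per-connection
"subsequent same source" marker, which keeps working after the stored source
gids have optionally been purged to save memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RANK_BITS", "TID_BITS", "SYN_BITS", "LCID_BITS",
    "MAX_RANK", "MAX_TID", "MAX_SYN_ID", "MAX_LCID",
    "ConnectionHandle", "ConnectionBlock", "PostsynapticTables", "TargetTable",
    "PhaseError", "ConnectivityFrozenError", "PackingError",
    "pack_target", "unpack_target",
]

# Bit layout of a packed target entry, low to high:
# status(1) | lcid(27) | syn_id(6) | tid(10) | rank(20) = 64 bits.
# Only the 8-byte total is architecturally fixed; this split admits 2^20
# ranks (covering the largest deployed machines) and 128 Mi connections per
# (thread, type) container.
STATUS_BITS = 1
LCID_BITS = 27
SYN_BITS = 6
TID_BITS = 10
RANK_BITS = 20
assert STATUS_BITS + LCID_BITS + SYN_BITS + TID_BITS + RANK_BITS == 64

MAX_RANK = (1 << RANK_BITS) - 1
MAX_TID = (1 << TID_BITS) - 1
MAX_SYN_ID = (1 << SYN_BITS) - 1
MAX_LCID = (1 << LCID_BITS) - 1

_LCID_SHIFT = STATUS_BITS
_SYN_SHIFT = _LCID_SHIFT + LCID_BITS
_TID_SHIFT = _SYN_SHIFT + SYN_BITS
_RANK_SHIFT = _TID_SHIFT + TID_BITS


class PackingError(OverflowError):
    pass


class PhaseError(RuntimeError):
    """Operation not allowed in the current build/simulate phase."""


class ConnectivityFrozenError(RuntimeError):
    """Connectivity query after the source gids have been purged."""


def pack_target(rank: int, tid: int, syn_id: int, lcid: int, status: int = 0) -> int:
    """Pack a target location into one 64-bit word (8 bytes exactly)."""
    for name, value, limit in (("rank", rank, MAX_RANK), ("tid", tid, MAX_TID),
                               ("syn_id", syn_id, MAX_SYN_ID), ("lcid", lcid, MAX_LCID),
                               ("status", status, 1)):
        if not 0 <= value <= limit:
            raise PackingError(f"field {name}={value} outside [0, {limit}]")
    return (rank << _RANK_SHIFT) | (tid << _TID_SHIFT) | (syn_id << _SYN_SHIFT) \
        | (lcid << _LCID_SHIFT) | status


def unpack_target(word: int) -> tuple[int, int, int, int, int]:
    """Inverse of :func:`pack_target`: ``(rank, tid, syn_id, lcid, status)``."""
    if not 0 <= word < (1 << 64):
        raise PackingError("word is not a 64-bit value")
    return (
        (word >> _RANK_SHIFT) & MAX_RANK,
        (word >> _TID_SHIFT) & MAX_TID,
        (word >> _SYN_SHIFT) & MAX_SYN_ID,
        (word >> _LCID_SHIFT) & MAX_LCID,
        word & 1,
    )


@dataclass(frozen=True)
class ConnectionHandle:
    """(thread, synapse type, local connection id): a connection's address on a rank."""

    tid: int
    syn_id: int
    lcid: int


class ConnectionBlock:
    """Growable struct-of-arrays holding the synapses of one (thread, type).

    The growth factor mirrors the 50 % resizing strategy of the reference
    design; it only affects amortised copying, never content.  Plasticity
    state (last presynaptic spike time and the presynaptic trace) is carried
    per connection, as required once connections are no longer grouped by
    source.
    """

    __slots__ = ("n", "capacity", "growth", "tgt_local", "weight", "delay_steps",
                 "gcid", "marker", "t_last_pre", "K_plus")

    def __init__(self, growth: float = 1.5):
        self.n = 0
        self.capacity = 8
        self.growth = growth
        self.tgt_local = np.empty(8, dtype=np.int64)
        self.weight = np.empty(8)
        self.delay_steps = np.empty(8, dtype=np.int64)
        self.gcid = np.empty(8, dtype=np.int64)
        self.marker = np.zeros(8, dtype=bool)  # subsequent-same-source
        self.t_last_pre = np.empty(8)
        self.K_plus = np.empty(8)

    def _grow(self) -> None:
        new_cap = max(self.capacity + 1, int(self.capacity * self.growth))
        for name in ("tgt_local", "weight", "delay_steps", "gcid", "marker",
                     "t_last_pre", "K_plus"):
            old = getattr(self, name)
            new = np.empty(new_cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            if name == "marker":
                new[self.n:] = False
            setattr(self, name, new)
        self.capacity = new_cap

    def append(self, tgt_local: int, weight: float, delay_steps: int, gcid: int) -> int:
        if self.n == self.capacity:
            self._grow()
        i = self.n
        self.tgt_local[i] = tgt_local
        self.weight[i] = weight
        self.delay_steps[i] = delay_steps
        self.gcid[i] = gcid
        self.marker[i] = False
        self.t_last_pre[i] = -np.inf
        self.K_plus[i] = 0.0
        self.n += 1
        return i

    def permute(self, order: np.ndarray) -> None:
        n = self.n
        for name in ("tgt_local", "weight", "delay_steps", "gcid", "marker",
                     "t_last_pre", "K_plus"):
            arr = getattr(self, name)
            arr[:n] = arr[:n][order]


class PostsynapticTables:
    """Connection table plus parallel source table for one emulated rank."""

    def __init__(self, n_threads: int, n_syn_types: int, growth: float = 1.5):
        if n_syn_types - 1 > MAX_SYN_ID:
            raise PackingError("synapse-type count exceeds packing limit")
        self.n_threads = n_threads
        self.n_syn_types = n_syn_types
        self.conn: list[list[ConnectionBlock]] = [
            [ConnectionBlock(growth) for _ in range(n_syn_types)] for _ in range(n_threads)]
        # source table: parallel arrays of gids and the two construction flags
        self.src_gid: list[list[list[int]]] = [
            [[] for _ in range(n_syn_types)] for _ in range(n_threads)]
        self.src_processed: list[list[list[bool]]] = [
            [[] for _ in range(n_syn_types)] for _ in range(n_threads)]
        self.src_disabled: list[list[list[bool]]] = [
            [[] for _ in range(n_syn_types)] for _ in range(n_threads)]
        self.build_phase = True
        self.sorted_by_source = False
        self.purged = False

    # -- build phase ------------------------------------------------------

    def add_connection(self, tid: int, syn_id: int, source_gid: int,
                       tgt_local: int, weight: float, delay_steps: int,
                       gcid: int) -> ConnectionHandle:
        """Append one connection; source entry goes to the same lcid."""
        if not self.build_phase:
            raise PhaseError("cannot add connections after presynaptic construction")
        if tid >= self.n_threads or tid > MAX_TID:
            raise PackingError(f"tid {tid} out of range")
        block = self.conn[tid][syn_id]
        if block.n > MAX_LCID:
            raise PackingError("lcid would exceed packing limit")
        lcid = block.append(tgt_local, weight, delay_steps, gcid)
        self.src_gid[tid][syn_id].append(source_gid)
        self.src_processed[tid][syn_id].append(False)
        self.src_disabled[tid][syn_id].append(False)
        return ConnectionHandle(tid=tid, syn_id=syn_id, lcid=lcid)

    def sort_connections_by_source(self, tid: int, syn_id: int) -> np.ndarray:
        """Stable-sort one container by source gid; returns the permutation.

        Applies the identical permutation to the connection block and sets
        the subsequent-same-source marker on every connection whose successor
        shares its source gid.
        """
        if not self.build_phase:
            raise PhaseError("sorting is a build-phase operation")
        gids = np.asarray(self.src_gid[tid][syn_id], dtype=np.int64)
        order = np.argsort(gids, kind="stable")
        gids_sorted = gids[order]
        self.src_gid[tid][syn_id] = gids_sorted.tolist()
        self.src_processed[tid][syn_id] = [self.src_processed[tid][syn_id][i] for i in order]
        self.src_disabled[tid][syn_id] = [self.src_disabled[tid][syn_id][i] for i in order]
        block = self.conn[tid][syn_id]
        block.permute(order)
        n = block.n
        if n:
            block.marker[: n - 1] = gids_sorted[1:] == gids_sorted[:-1]
            block.marker[n - 1] = False
        self.sorted_by_source = True
        return order

    def sort_all(self) -> None:
        for tid in range(self.n_threads):
            for syn_id in range(self.n_syn_types):
                self.sort_connections_by_source(tid, syn_id)

    def freeze(self) -> None:
        """End the build phase (called once the presynaptic tier exists)."""
        self.build_phase = False

    # -- queries ----------------------------------------------------------

    def n_connections(self, tid: int | None = None, syn_id: int | None = None) -> int:
        total = 0
        for t in range(self.n_threads) if tid is None else [tid]:
            for s in range(self.n_syn_types) if syn_id is None else [syn_id]:
                total += self.conn[t][s].n
        return total

    def sources(self, tid: int, syn_id: int) -> list[int]:
        if self.purged:
            raise ConnectivityFrozenError(
                "source gids were purged; connectivity can no longer be queried")
        return list(self.src_gid[tid][syn_id])

    def source_entry_count(self) -> int:
        if self.purged:
            return 0
        return sum(len(self.src_gid[t][s])
                   for t in range(self.n_threads) for s in range(self.n_syn_types))

    def purge_sources(self) -> None:
        """Release source-gid storage (§-level trade-off: memory vs. queryability).

        Only legal after the presynaptic tier has been built; afterwards the
        sorted delivery walk relies exclusively on the subsequent-same-source
        markers, so simulation results are unchanged.
        """
        if self.build_phase:
            raise PhaseError("cannot purge sources before presynaptic construction")
        self.src_gid = [[[] for _ in range(self.n_syn_types)] for _ in range(self.n_threads)]
        self.src_processed = [[[] for _ in range(self.n_syn_types)] for _ in range(self.n_threads)]
        self.src_disabled = [[[] for _ in range(self.n_syn_types)] for _ in range(self.n_threads)]
        self.purged = True

    def debug_dump(self) -> dict:
        """JSON-serialisable dump of both postsynaptic tables."""
        out: dict = {"threads": []}
        for t in range(self.n_threads):
            thread: dict = {"syn_types": []}
            for s in range(self.n_syn_types):
                block = self.conn[t][s]
                thread["syn_types"].append({
                    "syn_id": s,
                    "sources": None if self.purged else list(self.src_gid[t][s]),
                    "targets_local": block.tgt_local[: block.n].tolist(),
                    "weights": block.weight[: block.n].tolist(),
                    "gcid": block.gcid[: block.n].tolist(),
                    "marker": block.marker[: block.n].tolist(),
                })
            out["threads"].append(thread)
        return out


class TargetTable:
    """Presynaptic tier of one rank: packed target words per local neuron.

    Indexed ``[thread][thread-local neuron id]``; entries are kept in
    insertion order.  In sorted mode there is at most one entry per
    (source neuron, rank, tid, syn_id) group head; in nosort mode exactly one
    per outgoing connection.
    """

    def __init__(self, n_threads: int, n_local_per_thread: list[int]):
        if len(n_local_per_thread) != n_threads:
            raise ValueError("need one neuron count per thread")
        self.n_threads = n_threads
        self.entries: list[list[list[int]]] = [
            [[] for _ in range(n_local_per_thread[t])] for t in range(n_threads)]
        self.constructed = False

    def add_entry(self, tid: int, local_id: int, word: int) -> None:
        self.entries[tid][local_id].append(word)

    def lookup_targets(self, tid: int, local_id: int) -> list[int]:
        """All packed target words of one thread-local neuron, insertion order."""
        if not self.constructed:
            raise PhaseError("presynaptic tier not yet constructed")
        return self.entries[tid][local_id]

    def entry_count(self) -> int:
        return sum(len(lst) for per_thread in self.entries for lst in per_thread)

    def debug_dump(self) -> dict:
        return {
            "threads": [
                [[list(unpack_target(w)) for w in lst] for lst in per_thread]
                for per_thread in self.entries
            ]
        }
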