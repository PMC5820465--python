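"""Baseline purely-postsynaptic connection infrastructure (the "4g" design).

Each thread owns a *sparse table* keyed by source gid: the gid space is cut
into groups of 48 consecutive gids, each group storing one presence bit per
gid plus, for present gids, a reference to a *connector* holding that
source's thread-local connections.  Spikes arrive as source gids via an
allgather, and every thread looks each gid up in its sparse table — the cost
of skipping sources without local targets is the scalability bottleneck this
structure is the baseline for.

Connector fidelity is deliberately reduced: a heterogeneous wrapper maps
synapse-type id to one homogeneous growable container, since the fixed- vs.
variable-size container distinction only affects memory constants.
"""

from __future__ import annotations

import numpy as np

from .infra5g import ConnectionBlock

__all__ = ["GROUP_SIZE", "HomogeneousConnector", "Connector", "SparseTable"]

GROUP_SIZE = 48  # gids per sparse group: one presence bit each


class HomogeneousConnector:
    """Connections of a single synapse type from one source on one thread."""

    __slots__ = ("syn_id", "block")

    def __init__(self, syn_id: int):
        self.syn_id = syn_id
        self.block = ConnectionBlock()

    @property
    def n(self) -> int:
        return self.block.n


class Connector:
    """Heterogeneous wrapper: one homogeneous container per type in use."""

    __slots__ = ("by_type",)

    def __init__(self):
        self.by_type: dict[int, HomogeneousConnector] = {}

    def homogeneous(self, syn_id: int) -> HomogeneousConnector:
        conn = self.by_type.get(syn_id)
        if conn is None:
            conn = HomogeneousConnector(syn_id)
            self.by_type[syn_id] = conn
        return conn

    @property
    def n(self) -> int:
        return sum(c.n for c in self.by_type.values())


class _SparseGroup:
    __slots__ = ("bits", "connectors")

    def __init__(self):
        self.bits = np.zeros(GROUP_SIZE, dtype=bool)
        self.connectors: dict[int, Connector] = {}  # in-group offset -> connector


class SparseTable:
    """Per-thread map from source gid to local connection container.

    ``max_gid`` bounds the addressable gid range; lookups outside raise
    IndexError.  The presence bit for a gid is set iff at least one local
    connection from that source exists on this thread.
    """

    def __init__(self, max_gid: int):
        self.max_gid = max_gid
        n_groups = (max_gid + GROUP_SIZE) // GROUP_SIZE
        self.groups = [_SparseGroup() for _ in range(n_groups)]

    @staticmethod
    def group_index(source_gid: int) -> tuple[int, int]:
        return source_gid // GROUP_SIZE, source_gid % GROUP_SIZE

    def _check(self, source_gid: int) -> None:
        if not 0 <= source_gid <= self.max_gid:
            raise IndexError(f"gid {source_gid} outside sparse-table range 0..{self.max_gid}")

    def sparse_insert(self, source_gid: int, syn_id: int, tgt_local: int,
                      weight: float, delay_steps: int, gcid: int) -> None:
        """Set the presence bit and append to the (possibly new) connector."""
        self._check(source_gid)
        gi, off = self.group_index(source_gid)
        group = self.groups[gi]
        group.bits[off] = True
        connector = group.connectors.get(off)
        if connector is None:
            connector = Connector()
            group.connectors[off] = connector
        connector.homogeneous(syn_id).block.append(tgt_local, weight, delay_steps, gcid)

    def sparse_lookup(self, source_gid: int) -> Connector | None:
        """Connector of a source, or None when the presence bit is clear."""
        self._check(source_gid)
        gi, off = self.group_index(source_gid)
        group = self.groups[gi]
        if not group.bits[off]:
            return None
        return group.connectors[off]

    def present_gids(self) -> list[int]:
        out = []
        for gi, group in enumerate(self.groups):
            for off in np.flatnonzero(group.bits):
                out.append(gi * GROUP_SIZE + int(off))
        return out

    def n_connections(self) -> int:
        return sum(c.n for g in self.groups for c in g.connectors.values())

    def deliver_4g(self, source_gid: int):
        """Yield ``(syn_id, block, index)`` for every local connection of a source.

        A source without local targets yields nothing — the "skipping spikes"
        path that dominates at scale.  Connections are yielded per type in
        ascending type id and per container in insertion order; the caller
        canonicalises accumulation order across sources.
        """
        connector = self.sparse_lookup(source_gid)
        if connector is None:
            return
        for syn_id in sorted(connector.by_type):
            block = connector.by_type[syn_id].block
            for i in range(block.n):
                yield syn_id, block, i

    def debug_dump(self) -> dict:
        out: dict = {"max_gid": self.max_gid, "sources": {}}
        for gid in self.present_gids():
            connector = self.sparse_lookup(gid)
            out["sources"][str(gid)] = {
                str(syn_id): {
                    "targets_local": conn.block.tgt_local[: conn.block.n].tolist(),
                    "weights": conn.block.weight[: conn.block.n].tolist(),
                    "gcid": conn.block.gcid[: conn.block.n].tolist(),
                }
                for syn_id, conn in connector.by_type.items()
            }
        return out
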