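"""Emulated collective exchanges over M ranks.

Two collectives are provided with the semantics of their MPI namesakes:

* ``all_to_all`` — every rank's send buffer is split into M equally sized
  sections, one per destination; receive buffers are the transpose
  (``recv[r][s] = send[s][r]``), so per-rank receive volume is independent
  of M for a fixed section size.
* ``all_gather`` — every rank receives the concatenation of all equally
  sized send buffers; receive volume grows proportionally to M.

Entries carry a 2-bit sidecar flag used by the multi-round protocol
(0: default, 1: no more data to send, 2: end of valid data in section,
3: skip this section).  When one round cannot carry everything, buffers are
doubled up to a policy maximum and further rounds are run; the protocol
conserves the multiset of payloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FLAG_DEFAULT", "FLAG_COMPLETE", "FLAG_END_OF_VALID", "FLAG_SKIP_SECTION",
    "BufferPolicy", "SectionedBuffer", "ProtocolError", "CommCounters",
    "all_to_all", "all_gather", "grow_buffer", "finalize_section", "read_section",
]

FLAG_DEFAULT = 0
FLAG_COMPLETE = 1  # no more data to send (attached to the last valid entry)
FLAG_END_OF_VALID = 2  # first entry after the valid ones
FLAG_SKIP_SECTION = 3  # section contains no data at all


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class BufferPolicy:
    """Buffer sizing in *entries* per section.

    ``max_entries`` plays the role of the user-defined cap (B_c for
    connectivity data, B_s for spike data); the default growth factor of 2
    realises buffer doubling between rounds.
    """

    initial_entries: int = 2
    max_entries: int = 1 << 20
    growth_factor: int = 2

    def __post_init__(self) -> None:
        if self.initial_entries < 1 or self.max_entries < 1:
            raise ValueError("buffer sizes must be at least one entry")
        if self.initial_entries > self.max_entries:
            raise ValueError("initial size exceeds maximum")

    def clamp(self, wanted: int) -> int:
        return max(self.initial_entries, min(wanted, self.max_entries))


def grow_buffer(policy: BufferPolicy, current: int) -> int:
    """Next buffer size after an exhausted round: doubled, capped at the max."""
    return min(current * policy.growth_factor, policy.max_entries)


@dataclass
class SectionedBuffer:
    """M equally sized sections of (payload, flag) pairs."""

    n_sections: int
    entries_per_section: int
    sections: list[list[tuple[object, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sections:
            self.sections = [[] for _ in range(self.n_sections)]

    def section(self, r: int) -> list[tuple[object, int]]:
        return self.sections[r]


def finalize_section(section: list[tuple[object, int]], capacity: int,
                     sender_done: bool) -> list[tuple[object, int]]:
    """Flag a section's entries for the wire and pad it to capacity.

    ``section`` holds the valid payloads (flags ignored).  Valid entries get
    flag 0, except the last one, which carries flag 1 iff the sender has
    nothing further to send in later rounds.  If space remains, the entry
    after the last valid one is flagged 2; an entirely empty section is a
    single flag-3 marker (plus padding).
    """
    valid = len(section)
    if valid > capacity:
        raise ProtocolError("section exceeds its capacity")
    out: list[tuple[object, int]] = []
    if valid == 0:
        out.append((None, FLAG_SKIP_SECTION))
    else:
        for i, (payload, _) in enumerate(section):
            last = i == valid - 1
            out.append((payload, FLAG_COMPLETE if (last and sender_done) else FLAG_DEFAULT))
        if valid < capacity:
            out.append((None, FLAG_END_OF_VALID))
    while len(out) < capacity:
        out.append((None, FLAG_DEFAULT))
    return out


def read_section(section: list[tuple[object, int]]) -> tuple[list[object], bool]:
    """Recover the valid payloads of a wire section and the sender-done bit."""
    payloads: list[object] = []
    done = False
    for payload, flag in section:
        if flag == FLAG_SKIP_SECTION:
            break
        if flag == FLAG_END_OF_VALID:
            break
        payloads.append(payload)
        if flag == FLAG_COMPLETE:
            done = True
            break
    return payloads, done


@dataclass
class CommCounters:
    """Instrumentation of one exchange stream (counts, never wall-clock)."""

    entries_sent: int = 0  # valid payload entries placed on the wire
    entries_received: int = 0  # wire entries scanned on the receive side
    entries_used: int = 0  # received entries with local use
    rounds: int = 0
    final_buffer_entries: int = 0

    def as_dict(self) -> dict:
        return {
            "entries_sent": self.entries_sent,
            "entries_received": self.entries_received,
            "entries_used": self.entries_used,
            "rounds": self.rounds,
            "final_buffer_entries": self.final_buffer_entries,
        }


def all_to_all(sends: list[SectionedBuffer]) -> list[SectionedBuffer]:
    """Transpose semantics: ``recv[r] section s = send[s] section r``, bit-exact."""
    M = len(sends)
    sizes = {b.entries_per_section for b in sends}
    if len(sizes) != 1:
        raise ProtocolError("all ranks must use identical section sizes")
    for b in sends:
        if b.n_sections != M:
            raise ProtocolError("send buffer must have one section per rank")
    size = sizes.pop()
    recvs = []
    for r in range(M):
        recv = SectionedBuffer(n_sections=M, entries_per_section=size)
        for s in range(M):
            recv.sections[s] = list(sends[s].sections[r])
        recvs.append(recv)
    return recvs


def all_gather(sends: list[list]) -> list[list]:
    """Every rank receives the concatenation of all send buffers in rank order."""
    sizes = {len(b) for b in sends}
    if len(sizes) != 1:
        raise ProtocolError("all ranks must send equally sized buffers")
    concatenated = [entry for buf in sends for entry in buf]
    return [list(concatenated) for _ in sends]
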