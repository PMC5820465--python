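"""Analytic per-rank memory-usage model of the two-tier kernel.

Per-rank memory is split into three components,

    M(M, T, N) = M0(M, T, N) + Mn(M, N) + Mc(M, T, N),

with N_M := N/M neurons per rank and K the fixed in-degree:

* ``M0`` — base footprint plus the two MPI buffers, each capped by policy:
  ``Mb + min(Bc, N_M * min(K, M*T)) * m_td + min(Bs, N_M * nu_max * min(K, M*T)) * m_sd``
* ``Mn`` — neuron and neuronal-infrastructure memory, delegated to a
  pluggable term (a linear default ``a * N_M + b`` stands in for the
  detailed model of prior kernel generations).
* ``Mc`` — connection memory:
  ``K_stat * mc_stat + K_stdp * mc_stdp + K * N_M * m_s + N_M * min(K, M*T) * m_t``
  with ``K_stat + K_stdp = K * N_M`` split by the network's type mix.

The ``min(K, M*T)`` factor is the sort-by-source compression: a neuron needs
at most one target entry (and one spike copy) per virtual process.  No term
grows with the total network size N at fixed N_M, nor with M alone — the
model-level statement of the kernel's scalability.

Byte-size defaults describe this implementation's own objects measured in
idealised bytes; a "paper-shaped" profile with 8-byte entries reproduces the
qualitative curves of the reference design, not absolute hardware values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

__all__ = ["MemoryParams", "MemoryBreakdown", "memory_total", "max_network_size",
           "measure_actual", "paper_shaped_params"]


def _linear_neuron_term(a: float = 1500.0, b: float = 0.0) -> Callable[[int, int], float]:
    def term(M: int, N: int) -> float:
        return a * (N / M) + b
    return term


@dataclass(frozen=True)
class MemoryParams:
    """Symbols of the per-rank memory model (sizes in bytes, caps in entries)."""

    M_b: float = 0.0  # empirically measured base usage
    m_td: float = 16.0  # per connectivity-exchange buffer entry
    m_sd: float = 8.0  # per spike buffer entry
    m_s: float = 8.0  # per source entry
    m_t: float = 8.0  # per packed target entry
    mc_stat: float = 48.0  # per static synapse object
    mc_stdp: float = 72.0  # per STDP synapse object (stores last pre-spike time)
    B_c: float = float(128 * 2 ** 20 // 16)  # connectivity-buffer cap (entries; 128 MB default)
    B_s: float = float(1 << 30)  # spike-buffer cap (entries)
    nu_max: float = 1.0  # max spikes per neuron per communication interval
    stdp_fraction: float = 0.64  # share of synapses that are plastic (E->E: 0.8^2)
    neuron_term: Callable[[int, int], float] = field(default_factory=_linear_neuron_term)


def paper_shaped_params() -> MemoryParams:
    """Profile with 8-byte wire/table entries for qualitative curve shapes."""
    return MemoryParams(M_b=0.0, m_td=8.0, m_sd=8.0, m_s=4.0, m_t=8.0,
                        mc_stat=32.0, mc_stdp=40.0)


@dataclass(frozen=True)
class MemoryBreakdown:
    """Per-term output of the model, in bytes plus the underlying counts."""

    m0: float
    mn: float
    mc_objects: float
    mc_sources: float
    mc_targets: float
    K_M_stat: float
    K_M_stdp: float
    target_count: float

    @property
    def mc(self) -> float:
        return self.mc_objects + self.mc_sources + self.mc_targets

    @property
    def total(self) -> float:
        return self.m0 + self.mn + self.mc

    def as_dict(self) -> dict:
        return {"m0": self.m0, "mn": self.mn, "mc_objects": self.mc_objects,
                "mc_sources": self.mc_sources, "mc_targets": self.mc_targets,
                "total": self.total}


def memory_total(M: int, T: int, N: int, K: int, p: MemoryParams) -> MemoryBreakdown:
    """Evaluate the three-component model for one configuration."""
    if M < 1 or T < 1 or N < M:
        raise ValueError("require M >= 1, T >= 1 and at least one neuron per rank")
    N_M = N / M
    fan = min(K, M * T)
    m0 = (p.M_b
          + min(p.B_c, N_M * fan) * p.m_td
          + min(p.B_s, N_M * p.nu_max * fan) * p.m_sd)
    K_M = K * N_M
    K_M_stdp = p.stdp_fraction * K_M
    K_M_stat = K_M - K_M_stdp
    target_count = N_M * fan
    mc_objects = K_M_stat * p.mc_stat + K_M_stdp * p.mc_stdp
    mc_sources = K_M * p.m_s
    mc_targets = target_count * p.m_t
    mn = p.neuron_term(M, N)
    return MemoryBreakdown(m0=m0, mn=mn, mc_objects=mc_objects,
                           mc_sources=mc_sources, mc_targets=mc_targets,
                           K_M_stat=K_M_stat, K_M_stdp=K_M_stdp,
                           target_count=target_count)


def max_network_size(M: int, T: int, K: int, budget_per_rank: float,
                     p: MemoryParams) -> int:
    """Largest N (multiple of M) whose predicted per-rank usage fits the budget.

    Found by bisection over multiples of M; the model is non-decreasing in N
    for fixed (M, T, K).  Raises if even one neuron per rank does not fit.
    """
    lo = 1  # in units of neurons per rank
    if memory_total(M, T, M * lo, K, p).total > budget_per_rank:
        raise ValueError("budget too small: one neuron per rank already exceeds it")
    hi = 2
    while memory_total(M, T, M * hi, K, p).total <= budget_per_rank:
        lo = hi
        hi *= 2
        if hi > 1 << 60:
            raise OverflowError("budget admits unreasonably large networks")
    # invariant: f(lo) <= budget < f(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if memory_total(M, T, M * mid, K, p).total <= budget_per_rank:
            lo = mid
        else:
            hi = mid
    return M * lo


def measure_actual(ranks, variant: str) -> list[dict]:
    """Exact live counts from a finished run, one dict per rank.

    The count terms (synapses per type, source entries, target entries) are
    what the model's byte terms multiply; they must match the model exactly
    for the benchmark network.  Byte sizes themselves are configuration.
    """
    out = []
    for rs in ranks:
        counts: dict = {"rank": rs.rank, "variant": variant}
        if rs.post_tables is not None:
            tables = rs.post_tables
            per_type = [tables.n_connections(syn_id=s) for s in range(tables.n_syn_types)]
            counts["synapses_per_type"] = per_type
            counts["n_synapses"] = sum(per_type)
            counts["source_entries"] = tables.source_entry_count()
            counts["sources_purged"] = tables.purged
        elif rs.sparse is not None:
            n = sum(t.n_connections() for t in rs.sparse)
            counts["n_synapses"] = n
            counts["source_entries"] = 0
            counts["sources_purged"] = False
        if rs.target_table is not None:
            counts["target_entries"] = rs.target_table.entry_count()
        out.append(counts)
    return out
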