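"""Benchmark network definition and round-robin partitioning.

The benchmark is a balanced random network of two recurrently connected
populations, excitatory and inhibitory, at a 4:1 ratio.  Every neuron draws a
fixed number of incoming connections ``K`` (the in-degree), sampled uniformly
with replacement from the two populations, independent of the network size.
Inhibitory connections are stronger than excitatory ones by a factor ``g``;
excitatory-excitatory connections may carry spike-timing dependent plasticity
while all other connections are static.

Neurons carry consecutive global ids (gids) starting at 0 and are distributed
round-robin over ``M * T`` virtual processes: ``vp = gid mod (M*T)``,
``rank = vp mod M``, ``thread = vp div M``.  Connectivity is generated
globally from a single seed and only afterwards partitioned, so the network
is a pure function of ``(params, seed)`` — identical bytes for every (M, T).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SYN_STATIC_EXC",
    "SYN_STATIC_INH",
    "SYN_STDP_EE",
    "SYN_NAMES",
    "PartitionConfig",
    "BenchmarkParams",
    "NetworkSpec",
    "assign_rank_thread",
    "assign_vp",
    "local_id",
    "generate_benchmark",
    "write_connections_tsv",
    "read_connections_tsv",
    "write_network_json",
    "read_network_json",
]

# Synapse-type ids; kept small so they fit the 6-bit field of packed targets.
SYN_STATIC_EXC = 0
SYN_STATIC_INH = 1
SYN_STDP_EE = 2
SYN_NAMES = {SYN_STATIC_EXC: "static_exc", SYN_STATIC_INH: "static_inh", SYN_STDP_EE: "stdp_ee"}
_SYN_IDS = {v: k for k, v in SYN_NAMES.items()}


@dataclass(frozen=True)
class PartitionConfig:
    """Emulated machine partition: ``M`` ranks with ``T`` threads each."""

    M: int
    T: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.T < 1:
            raise ValueError("partition requires M >= 1 and T >= 1")

    @property
    def V(self) -> int:
        """Total number of virtual processes."""
        return self.M * self.T


def assign_vp(gid: int | np.ndarray, P: PartitionConfig):
    return gid % P.V


def assign_rank_thread(gid: int | np.ndarray, P: PartitionConfig):
    """Round-robin home of a neuron: ``gid -> (rank, thread)``.

    Neurons are dealt over virtual processes by creation order; the vp index
    is split into a rank (fast axis) and a thread (slow axis).  Vectorises
    over numpy arrays of gids.
    """
    if np.any(np.asarray(gid) < 0):
        raise ValueError("gid must be non-negative")
    vp = gid % P.V
    return vp % P.M, vp // P.M


def local_id(gid: int | np.ndarray, P: PartitionConfig):
    """Thread-local neuron index: position of gid within its virtual process."""
    return gid // P.V


@dataclass(frozen=True)
class BenchmarkParams:
    """Parameters of the balanced random benchmark network.

    The numeric defaults (J, g, delay, drive) are configurable defaults of
    this package, not values fixed by the architecture; they are chosen to
    produce sparse asynchronous-irregular activity at a few spikes/s.
    """

    N: int
    K: int
    exc_fraction: float = 0.8
    g: float = 5.0  # inhibitory weight scale: w_inh = -g * J
    J: float = 70.0  # excitatory weight (pA peak of the alpha PSC)
    delay: float = 1.5  # transmission delay (ms); must be >= d_min
    drive_rate: float = 3000.0  # external Poisson rate per neuron (spikes/s)
    drive_weight: float = 70.0  # weight of one external drive event (pA)
    stdp_on_ee: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 < self.exc_fraction < 1.0:
            raise ValueError("exc_fraction must lie strictly between 0 and 1")
        if self.K > self.N:
            raise ValueError("K must not exceed N")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.delay <= 0.0:
            raise ValueError("delay must be positive")

    @property
    def n_exc(self) -> int:
        """Size of the excitatory population (gids 0..n_exc-1)."""
        return int(round(self.exc_fraction * self.N))

    @property
    def n_inh(self) -> int:
        return self.N - self.n_exc

    def is_excitatory(self, gid: int | np.ndarray):
        return np.asarray(gid) < self.n_exc


@dataclass
class NetworkSpec:
    """A fully instantiated network: parameters plus the connection list.

    Connections are stored as parallel numpy arrays ordered by creation; the
    row index is the *global connection id* (gcid), which provides a
    partition-independent total order used for canonical accumulation.
    """

    params: BenchmarkParams
    source: np.ndarray  # int64 gids
    target: np.ndarray  # int64 gids
    syn_type: np.ndarray  # int8 synapse-type ids
    weight: np.ndarray  # float64 initial weights
    delay: np.ndarray  # float64 ms
    seed: int = 0

    @property
    def n_connections(self) -> int:
        return len(self.source)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.target, minlength=self.params.N)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.source, minlength=self.params.N)

    def validate(self) -> None:
        deg = self.in_degrees()
        if not np.all(deg == self.params.K):
            raise ValueError("in-degree invariant violated: every neuron must receive exactly K connections")
        lens = {len(self.source), len(self.target), len(self.syn_type), len(self.weight), len(self.delay)}
        if len(lens) != 1:
            raise ValueError("connection arrays must have equal lengths")


def generate_benchmark(params: BenchmarkParams, seed: int) -> NetworkSpec:
    """Draw the balanced random network with fixed in-degree ``K``.

    For every neuron, ``round(exc_fraction * K)`` sources are drawn uniformly
    with replacement from the excitatory population and the remaining
    ``K - round(exc_fraction * K)`` from the inhibitory population.
    Self-connections are permitted.  Generation never consults the partition,
    so the result is bit-identical for any (M, T).
    """
    rng = np.random.default_rng(seed)
    N, K = params.N, params.K
    n_exc = params.n_exc
    k_exc = int(round(params.exc_fraction * K))
    k_inh = K - k_exc
    if n_exc == 0 and k_exc > 0:
        raise ValueError("excitatory in-degree requested but no excitatory neurons exist")
    if params.n_inh == 0 and k_inh > 0:
        raise ValueError("inhibitory in-degree requested but no inhibitory neurons exist")

    # Draw all sources at once: one (N, K) block, exc columns then inh columns.
    src = np.empty((N, K), dtype=np.int64)
    if k_exc:
        src[:, :k_exc] = rng.integers(0, n_exc, size=(N, k_exc))
    if k_inh:
        src[:, k_exc:] = rng.integers(n_exc, N, size=(N, k_inh))
    tgt = np.repeat(np.arange(N, dtype=np.int64), K)
    src = src.reshape(-1)

    src_exc = src < n_exc
    tgt_exc = tgt < n_exc
    syn = np.where(src_exc, SYN_STATIC_EXC, SYN_STATIC_INH).astype(np.int8)
    if params.stdp_on_ee:
        syn[src_exc & tgt_exc] = SYN_STDP_EE
    weight = np.where(src_exc, params.J, -params.g * params.J)
    delay = np.full(N * K, params.delay)

    return NetworkSpec(params=params, source=src, target=tgt, syn_type=syn,
                       weight=weight, delay=delay, seed=seed)


# ---------------------------------------------------------------------------
# External formats: TSV connection lists and a compact JSON descriptor.

def write_connections_tsv(spec: NetworkSpec, path) -> None:
    df = pd.DataFrame({
        "source": spec.source,
        "target": spec.target,
        "syn_type": [SYN_NAMES[int(s)] for s in spec.syn_type],
        "weight": spec.weight,
        "delay": spec.delay,
    })
    df.to_csv(path, sep="\t", index=False)


def read_connections_tsv(path, params: BenchmarkParams, seed: int = 0) -> NetworkSpec:
    df = pd.read_csv(path, sep="\t")
    syn = np.array([_SYN_IDS[s] for s in df["syn_type"]], dtype=np.int8)
    return NetworkSpec(
        params=params,
        source=df["source"].to_numpy(np.int64),
        target=df["target"].to_numpy(np.int64),
        syn_type=syn,
        weight=df["weight"].to_numpy(np.float64),
        delay=df["delay"].to_numpy(np.float64),
        seed=seed,
    )


def write_network_json(spec: NetworkSpec, path) -> None:
    doc = {
        "params": asdict(spec.params),
        "seed": spec.seed,
        "connections": {
            "source": spec.source.tolist(),
            "target": spec.target.tolist(),
            "syn_type": spec.syn_type.tolist(),
            "weight": spec.weight.tolist(),
            "delay": spec.delay.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_network_json(path) -> NetworkSpec:
    with open(path) as fh:
        doc = json.load(fh)
    conns = doc["connections"]
    return NetworkSpec(
        params=BenchmarkParams(**doc["params"]),
        source=np.asarray(conns["source"], dtype=np.int64),
        target=np.asarray(conns["target"], dtype=np.int64),
        syn_type=np.asarray(conns["syn_type"], dtype=np.int8),
        weight=np.asarray(conns["weight"], dtype=np.float64),
        delay=np.asarray(conns["delay"], dtype=np.float64),
        seed=doc["seed"],
    )
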