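"""Single-neuron dynamics: LIF with alpha-shaped PSCs, ring buffers, STDP.

Subthreshold dynamics are linear and are advanced on a fixed grid of step
``h`` by *exact integration*: the propagator of the coupled
(current, membrane) system is the matrix exponential of the system matrix,
computed once per run.  Synaptic events enter as impulses on the alpha-current
state; a spike with weight ``w`` produces a postsynaptic current with peak
amplitude ``w`` (in pA) at ``t = tau_syn`` after its arrival.

The ring buffer accumulates weights of spikes due to arrive at future grid
steps; reading a slot clears it.  Writes at or before the read position are a
causality violation (they would mean a transmission delay below the minimal
delay that sets the communication interval).

The STDP rule is pair-based with exponential windows and optional power-law
weight dependence, evaluated lazily at presynaptic spike delivery.
Facilitation pairs each postsynaptic spike with the presynaptic trace (all
previous pre spikes); depression pairs the new pre spike with the
postsynaptic trace reconstructed from the target's spike archive.  The
transmission delay is treated as purely dendritic: a post spike at ``t_post``
takes effect at the synapse at ``t_post + dendritic_delay``, and a pre spike
delivered at emission time ``t_pre`` processes exactly the post spikes whose
synaptic arrival falls in ``(t_last_pre + dd, t_pre + dd]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from bisect import bisect_left, bisect_right

import numpy as np
from scipy.linalg import expm

__all__ = [
    "NeuronParams",
    "StdpParams",
    "LifAlphaPropagator",
    "NeuronPopulation",
    "RingBuffer",
    "CausalityError",
    "stdp_update_on_pre",
]


class CausalityError(RuntimeError):
    """A ring-buffer write at or before the current read position."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire constants (configurable defaults, mV/pA/pF/ms)."""

    tau_m: float = 10.0  # membrane time constant (ms)
    C_m: float = 250.0  # membrane capacitance (pF)
    E_L: float = -65.0  # resting potential (mV)
    V_th: float = -50.0  # spike threshold (mV)
    V_reset: float = -65.0  # post-spike reset (mV)
    t_ref: float = 2.0  # absolute refractory period (ms)
    tau_syn_ex: float = 0.5  # excitatory alpha-PSC time constant (ms)
    tau_syn_in: float = 0.5  # inhibitory alpha-PSC time constant (ms)
    I_e: float = 0.0  # constant external current (pA)


class LifAlphaPropagator:
    """Exact one-step propagator of the 5-variable linear subsystem.

    State per neuron: (y1e, y2e, y1i, y2i, V).  y1/y2 realise the alpha
    kernel per receptor sign; V couples to y2e + y2i.  The constant terms
    (leak reversal, DC current) are folded in via an augmented matrix
    exponential, so a single affine update advances the state exactly.
    """

    def __init__(self, p: NeuronParams, h: float):
        if h <= 0:
            raise ValueError("h must be positive")
        self.params = p
        self.h = h
        A = np.zeros((6, 6))
        A[0, 0] = -1.0 / p.tau_syn_ex
        A[1, 0] = 1.0
        A[1, 1] = -1.0 / p.tau_syn_ex
        A[2, 2] = -1.0 / p.tau_syn_in
        A[3, 2] = 1.0
        A[3, 3] = -1.0 / p.tau_syn_in
        A[4, 1] = 1.0 / p.C_m
        A[4, 3] = 1.0 / p.C_m
        A[4, 4] = -1.0 / p.tau_m
        A[4, 5] = p.E_L / p.tau_m + p.I_e / p.C_m
        self.P = expm(A * h)
        self.refractory_steps = int(round(p.t_ref / h))
        # impulse scaling: unit weight -> alpha current peaking at 1 pA
        self.impulse_ex = math.e / p.tau_syn_ex
        self.impulse_in = math.e / p.tau_syn_in


class NeuronPopulation:
    """State arrays for a set of neurons advanced together.

    All updates are elementwise, so per-neuron trajectories are bit-identical
    regardless of how neurons are grouped into populations — the property
    that makes cross-partition equivalence checks meaningful.
    """

    def __init__(self, n: int, prop: LifAlphaPropagator):
        self.n = n
        self.prop = prop
        p = prop.params
        self.y1e = np.zeros(n)
        self.y2e = np.zeros(n)
        self.y1i = np.zeros(n)
        self.y2i = np.zeros(n)
        self.V = np.full(n, p.E_L)
        self.refr = np.zeros(n, dtype=np.int64)

    def step(self, input_ex: np.ndarray, input_in: np.ndarray) -> np.ndarray:
        """Advance all neurons by one grid step.

        ``input_ex``/``input_in`` are the summed weights arriving at this
        step (ring-buffer read plus external drive).  Returns a boolean mask
        of neurons that spiked at the end of the step.
        """
        prop = self.prop
        P = prop.P
        if not (np.all(np.isfinite(self.V))):
            raise FloatingPointError("non-finite membrane potential")
        # impulse at step start
        y1e = self.y1e + prop.impulse_ex * input_ex
        y1i = self.y1i + prop.impulse_in * input_in
        y2e, y2i, V = self.y2e, self.y2i, self.V
        # affine exact update; scalars from the augmented propagator
        self.y1e = P[0, 0] * y1e
        self.y2e = P[1, 0] * y1e + P[1, 1] * y2e
        self.y1i = P[2, 2] * y1i
        self.y2i = P[3, 2] * y1i + P[3, 3] * y2i
        V_new = (P[4, 0] * y1e + P[4, 1] * y2e + P[4, 2] * y1i + P[4, 3] * y2i
                 + P[4, 4] * V + P[4, 5])
        refractory = self.refr > 0
        V_new = np.where(refractory, prop.params.V_reset, V_new)
        self.refr = np.where(refractory, self.refr - 1, 0)
        spiked = (~refractory) & (V_new >= prop.params.V_th)
        V_new = np.where(spiked, prop.params.V_reset, V_new)
        self.refr = np.where(spiked, prop.refractory_steps, self.refr)
        self.V = V_new
        return spiked


class RingBuffer:
    """Per-population circular buffer of future synaptic input.

    One row per neuron, ``length`` slots.  ``take(step)`` returns and clears
    the column for the given absolute step; ``add`` accumulates a weight at a
    strictly future step.  The caller is responsible for presenting
    simultaneous arrivals in canonical order (floating-point addition is not
    associative).
    """

    def __init__(self, n_neurons: int, length: int):
        if length < 2:
            raise ValueError("ring buffer needs at least two slots")
        self.length = length
        self.slots = np.zeros((n_neurons, length))
        self.read_step = 0  # next step to be read

    def add(self, neuron: int, arrival_step: int, w: float) -> None:
        if arrival_step < self.read_step:
            raise CausalityError(
                f"write at step {arrival_step} not after read position {self.read_step - 1}")
        if arrival_step >= self.read_step + self.length:
            raise ValueError("arrival beyond ring-buffer horizon")
        self.slots[neuron, arrival_step % self.length] += w

    def take(self, step: int) -> np.ndarray:
        """Read and clear the input column for ``step`` (must be the read head)."""
        if step != self.read_step:
            raise ValueError("ring buffer must be read in step order")
        col = self.slots[:, step % self.length].copy()
        self.slots[:, step % self.length] = 0.0
        self.read_step = step + 1
        return col


@dataclass(frozen=True)
class StdpParams:
    """Pair-based STDP with exponential windows (configurable defaults).

    mu_plus/mu_minus interpolate between additive (0) and multiplicative (1)
    weight dependence; alpha scales depression relative to facilitation.
    """

    tau_plus: float = 15.0  # ms
    tau_minus: float = 30.0  # ms
    lam: float = 0.01  # learning rate (dimensionless)
    alpha: float = 0.5  # depression asymmetry
    w_max: float = 140.0  # weight bound (pA)
    mu_plus: float = 0.0
    mu_minus: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if not (0.0 <= self.mu_plus <= 1.0 and 0.0 <= self.mu_minus <= 1.0):
            raise ValueError("mu exponents must lie in [0, 1]")


def stdp_update_on_pre(
    w: float,
    t_pre: float,
    t_last_pre: float,
    post_history,
    dendritic_delay: float,
    p: StdpParams,
    K_plus: float = 0.0,
) -> tuple[float, float]:
    """Process one presynaptic spike on a plastic synapse.

    Applies, in synaptic-time order, facilitation for every post spike in the
    window ``t_post + dd in (t_last_pre + dd, t_pre + dd]`` (paired against
    the presynaptic trace ``K_plus``, which sums exponentially decayed
    contributions of all earlier pre spikes) and then depression of the new
    pre spike against the postsynaptic trace (all post spikes strictly before
    ``t_pre``).  Returns ``(w', K_plus')`` with ``w'`` clipped to
    ``[0, w_max]``; the caller stores ``t_pre`` as the new last-pre-spike
    time alongside the synapse.

    ``post_history`` must be sorted ascending; ``t_pre`` must exceed
    ``t_last_pre``.  Use ``t_last_pre = -inf`` and ``K_plus = 0`` for the
    first spike ever seen by the synapse.
    """
    if not t_pre > t_last_pre:
        raise ValueError("t_pre must be strictly greater than t_last_pre")
    hist = list(post_history)
    if any(b < a for a, b in zip(hist, hist[1:])):
        raise ValueError("post_history must be sorted ascending")

    # window (t_last_pre, t_pre]: the dendritic delay shifts both ends alike
    lo = bisect_right(hist, t_last_pre)
    hi = bisect_right(hist, t_pre)
    w_max = p.w_max
    for t_post in hist[lo:hi]:
        if math.isfinite(t_last_pre):
            trace = K_plus * math.exp(-(t_post - t_last_pre) / p.tau_plus)
        else:
            trace = 0.0
        w = w + p.lam * w_max * (1.0 - w / w_max) ** p.mu_plus * trace
        w = min(w, w_max)

    # depression: post trace at t_pre over all posts strictly before t_pre
    n_before = bisect_left(hist, t_pre)
    K_minus = 0.0
    for t_post in hist[:n_before]:
        K_minus += math.exp(-(t_pre - t_post) / p.tau_minus)
    w = w - p.alpha * p.lam * w_max * (w / w_max) ** p.mu_minus * K_minus
    w = min(max(w, 0.0), w_max)

    if math.isfinite(t_last_pre):
        K_plus = K_plus * math.exp(-(t_pre - t_last_pre) / p.tau_plus) + 1.0
    else:
        K_plus = 1.0
    return w, K_plus


class PostTrace:
    """Postsynaptic spike archive of one neuron with trace evaluation.

    Keeps an ascending list of spike times; entries older than
    ``cutoff_window`` before the oldest time still queried may be dropped by
    ``truncate`` without measurable effect at double precision.
    """

    __slots__ = ("times",)

    def __init__(self):
        self.times: list[float] = []

    def append(self, t: float) -> None:
        self.times.append(t)

    def window(self, t_lo: float, t_hi: float) -> list[float]:
        lo = bisect_right(self.times, t_lo)
        hi = bisect_right(self.times, t_hi)
        return self.times[lo:hi]

    def truncate(self, keep_from: float) -> None:
        cut = bisect_left(self.times, keep_from)
        if cut:
            del self.times[:cut]
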