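"""Exact integration of the LIF-alpha neuron, ring buffers, and the STDP rule."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sparsespike.dynamics import (CausalityError, LifAlphaPropagator, NeuronParams,
                                  NeuronPopulation, RingBuffer, StdpParams,
                                  stdp_update_on_pre)


def _single(prop):
    return NeuronPopulation(1, prop)


def test_rest_is_fixed_point():
    prop = LifAlphaPropagator(NeuronParams(), h=0.1)
    pop = _single(prop)
    zero = np.zeros(1)
    for _ in range(100):
        pop.step(zero, zero)
    assert pop.V[0] == pytest.approx(prop.params.E_L, abs=1e-12)


def test_constant_current_matches_closed_form():
    """V(n*h) = E_L + I0*tau_m/C_m * (1 - exp(-n*h/tau_m)) without synaptic input."""
    p = NeuronParams(I_e=100.0, V_th=1e9)  # threshold out of reach
    h = 0.1
    prop = LifAlphaPropagator(p, h)
    pop = _single(prop)
    zero = np.zeros(1)
    for n in (1, 7, 50, 500):
        pop2 = _single(prop)
        for _ in range(n):
            pop2.step(zero, zero)
        expected = p.E_L + (p.I_e * p.tau_m / p.C_m) * (1 - math.exp(-n * h / p.tau_m))
        assert pop2.V[0] == pytest.approx(expected, abs=1e-10)


def test_threshold_reset_and_refractory_clamp():
    p = NeuronParams(I_e=500.0)  # strong drive: spikes repeatedly
    h = 0.1
    prop = LifAlphaPropagator(p, h)
    pop = _single(prop)
    zero = np.zeros(1)
    spiked_at = None
    for n in range(2000):
        if pop.step(zero, zero)[0]:
            spiked_at = n
            break
    assert spiked_at is not None
    assert pop.V[0] == p.V_reset
    # V stays clamped at reset for t_ref/h steps
    for _ in range(prop.refractory_steps):
        assert pop.V[0] == p.V_reset
        pop.step(zero, zero)
    # after the refractory period, drive depolarises again
    for _ in range(5):
        pop.step(zero, zero)
    assert pop.V[0] > p.V_reset


def test_exact_propagator_converges_to_fine_euler():
    """The one-step propagator equals the ODE solution: an explicit Euler
    oracle at decreasing step sizes converges to it at O(h_oracle)."""
    p = NeuronParams(I_e=37.0, V_th=1e9)
    h = 0.5
    prop = LifAlphaPropagator(p, h)
    pop = _single(prop)
    pop.y1e[0], pop.y2e[0], pop.y1i[0], pop.y2i[0], pop.V[0] = 3.0, 1.0, -2.0, -0.5, -60.0
    state0 = (3.0, 1.0, -2.0, -0.5, -60.0)
    pop.step(np.zeros(1), np.zeros(1))

    def euler(n_sub):
        dt = h / n_sub
        y1e, y2e, y1i, y2i, V = state0
        for _ in range(n_sub):
            dy1e = -y1e / p.tau_syn_ex
            dy2e = y1e - y2e / p.tau_syn_ex
            dy1i = -y1i / p.tau_syn_in
            dy2i = y1i - y2i / p.tau_syn_in
            dV = -(V - p.E_L) / p.tau_m + (y2e + y2i + p.I_e) / p.C_m
            y1e, y2e, y1i, y2i, V = (y1e + dt * dy1e, y2e + dt * dy2e,
                                     y1i + dt * dy1i, y2i + dt * dy2i, V + dt * dV)
        return V

    errors = [abs(euler(n) - pop.V[0]) for n in (100, 1000, 10000)]
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 1e-4


def test_alpha_psc_peaks_at_weight_after_tau_syn():
    """A unit-weight impulse produces a current peaking at ~w when t = tau_syn."""
    p = NeuronParams(V_th=1e9)
    h = 0.01
    prop = LifAlphaPropagator(p, h)
    pop = _single(prop)
    inp = np.zeros(1)
    w = 2.5
    pop.step(np.array([w]), inp)
    peak, argmax = -1.0, None
    for n in range(1, 300):
        pop.step(inp, inp)
        if pop.y2e[0] > peak:
            peak, argmax = pop.y2e[0], n
    assert peak == pytest.approx(w, rel=1e-3)
    assert (argmax + 1) * h == pytest.approx(p.tau_syn_ex, rel=0.02)


class TestRingBuffer:
    def test_accumulate_and_clear(self):
        ring = RingBuffer(1, 8)
        ring.add(0, 3, 0.5)
        ring.add(0, 3, 0.25)
        for s in range(4):
            col = ring.take(s)
        assert col[0] == 0.75
        # slot was zeroed: one lap later it reads 0
        for s in range(4, 12):
            col = ring.take(s)
        assert col[0] == 0.0

    def test_delay_arithmetic(self):
        # a spike at step s with delay d_min arrives at slot s + d_min/h
        h, d_min, s = 0.1, 1.5, 7
        ring = RingBuffer(1, 32)
        arrival = s + int(round(d_min / h))
        for step in range(s + 1):
            ring.take(step)
        ring.add(0, arrival, 1.0)
        for step in range(s + 1, arrival):
            assert ring.take(step)[0] == 0.0
        assert ring.take(arrival)[0] == 1.0

    def test_two_adds_commute_bitwise(self):
        # IEEE addition of two summands is commutative bit-for-bit, so a
        # canonical order over pairs is enough for reproducible slot values
        a = RingBuffer(1, 4)
        b = RingBuffer(1, 4)
        a.add(0, 2, 0.1), a.add(0, 2, 1e-17)
        b.add(0, 2, 1e-17), b.add(0, 2, 0.1)
        a.take(0), a.take(1)
        b.take(0), b.take(1)
        assert a.take(2)[0] == b.take(2)[0]

    def test_three_adds_require_fixed_order(self):
        # with three or more summands, grouping matters: the canonical order
        # is what makes cross-kernel accumulation reproducible
        vals = [0.1, 0.2, 0.3]
        fwd = sum_seq = 0.0
        for v in vals:
            sum_seq += v
        rev = 0.0
        for v in reversed(vals):
            rev += v
        assert sum_seq != rev  # motivates canonical ordering

    def test_write_into_past_is_causality_violation(self):
        ring = RingBuffer(1, 8)
        ring.take(0)
        ring.take(1)
        with pytest.raises(CausalityError):
            ring.add(0, 1, 1.0)  # at or before the read position


class TestStdp:
    P = StdpParams(tau_plus=15.0, tau_minus=30.0, lam=0.01, alpha=0.5,
                   w_max=100.0, mu_plus=0.0, mu_minus=0.0)

    def test_no_pairing_keeps_weight(self):
        w, k = stdp_update_on_pre(40.0, 10.0, -math.inf, [], 1.5, self.P)
        assert w == 40.0
        assert k == 1.0

    def test_facilitation_closed_form(self):
        """Single pre-post pair at dt = tau_plus, additive rule, no depression:
        increment is exactly lam * w_max * e^-1."""
        p = StdpParams(tau_plus=15.0, tau_minus=30.0, lam=0.01, alpha=0.0,
                       w_max=100.0, mu_plus=0.0, mu_minus=0.0)
        t0 = 5.0
        t_post = t0 + p.tau_plus
        w, _ = stdp_update_on_pre(40.0, t_post + 1.0, t0, [t_post], 1.5, p,
                                  K_plus=1.0)
        assert w - 40.0 == pytest.approx(p.lam * p.w_max * math.exp(-1.0), abs=1e-12)

    def test_depression_closed_form_and_floor(self):
        """Post-then-pre at dt = tau_minus: decrement alpha*lam*w_max*e^-1,
        clipped at zero for small weights."""
        p = self.P
        t_post = 3.0
        t_pre = t_post + p.tau_minus
        w, _ = stdp_update_on_pre(40.0, t_pre, -math.inf, [t_post], 1.5, p)
        expected = p.alpha * p.lam * p.w_max * math.exp(-1.0)
        assert 40.0 - w == pytest.approx(expected, abs=1e-12)
        w_floor, _ = stdp_update_on_pre(1e-6, t_pre, -math.inf, [t_post], 1.5, p)
        assert w_floor == 0.0

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            stdp_update_on_pre(1.0, 5.0, 6.0, [], 1.5, self.P)
        with pytest.raises(ValueError):
            stdp_update_on_pre(1.0, 10.0, 0.0, [3.0, 2.0], 1.5, self.P)

    @given(st.lists(st.floats(0.1, 99.0), max_size=8), st.floats(1.0, 50.0))
    def test_zero_learning_rate_is_noop(self, posts, w):
        p = StdpParams(lam=0.0, w_max=100.0)
        w2, _ = stdp_update_on_pre(w, 200.0, -math.inf, sorted(posts), 1.5, p)
        assert w2 == w
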