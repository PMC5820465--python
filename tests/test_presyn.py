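"""Presynaptic-tier construction: thread ranges, bijection, round resumability."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sparsespike as sp
from sparsespike.comm import BufferPolicy, ProtocolError
from sparsespike.infra5g import PhaseError, PostsynapticTables, unpack_target
from sparsespike.network import assign_rank_thread, local_id
from sparsespike.presyn import build_presynaptic, thread_rank_range
from sparsespike.simloop import N_SYN_TYPES


def _build_tables(spec, P):
    """Postsynaptic tables per rank, appended in global connection order."""
    ranks = [PostsynapticTables(P.T, N_SYN_TYPES) for _ in range(P.M)]
    local_rows = [{} for _ in range(P.M)]
    t_rank, t_thread = assign_rank_thread(spec.target, P)
    for gcid in range(spec.n_connections):
        r = int(t_rank[gcid])
        tgt = int(spec.target[gcid])
        row = local_rows[r].setdefault(tgt, len(local_rows[r]))
        ranks[r].add_connection(int(t_thread[gcid]), int(spec.syn_type[gcid]),
                                int(spec.source[gcid]), row, 1.0, 15, gcid)
    return ranks


def _expected_entries(spec, P, sorted_mode):
    """Brute-force oracle: expected packed-entry multiset per (source thread, lid).

    Recomputes lcids independently: connections arrive at each
    (rank, thread, syn) container in global connection order; sorting
    reorders them by (source gid, arrival position), and only the first of
    each same-source run is communicated.
    """
    per_container: dict[tuple, list] = {}
    t_rank, t_thread = assign_rank_thread(spec.target, P)
    for gcid in range(spec.n_connections):
        key = (int(t_rank[gcid]), int(t_thread[gcid]), int(spec.syn_type[gcid]))
        per_container.setdefault(key, []).append((int(spec.source[gcid]), gcid))
    expected: dict[tuple, list] = {}
    for (rank, tid, syn), conns in per_container.items():
        order = sorted(range(len(conns)), key=lambda i: (conns[i][0], i)) \
            if sorted_mode else range(len(conns))
        prev_src = None
        for lcid, i in enumerate(order):
            src = conns[i][0]
            head = (not sorted_mode) or src != prev_src
            prev_src = src
            if not head:
                continue
            s_rank, s_thread = assign_rank_thread(src, P)
            expected.setdefault((s_rank, s_thread, int(local_id(src, P))), []).append(
                (rank, tid, syn, lcid))
    return {key: sorted(entries) for key, entries in expected.items()}


def _actual_entries(target_tables, P):
    """Entry multiset per neuron (insertion order is a wire artefact)."""
    actual = {}
    for rank, table in enumerate(target_tables):
        for tid in range(P.T):
            for lid, words in enumerate(table.entries[tid]):
                if words:
                    actual[(rank, tid, lid)] = sorted(unpack_target(w)[:4]
                                                      for w in words)
    return actual


@pytest.mark.parametrize("M,T,expected", [
    (4, 2, [{0, 1}, {2, 3}]),
    (4, 1, [{0, 1, 2, 3}]),
    (2, 4, [{0}, {1}, set(), set()]),
])
def test_thread_rank_range_partition(M, T, expected):
    P = sp.PartitionConfig(M, T)
    assert [set(thread_rank_range(t, P)) for t in range(T)] == expected


@given(M=st.integers(1, 9), T=st.integers(1, 9))
def test_thread_ranges_cover_all_ranks_disjointly(M, T):
    P = sp.PartitionConfig(M, T)
    ranges = [list(thread_rank_range(t, P)) for t in range(T)]
    flat = [r for rng in ranges for r in rng]
    assert sorted(flat) == list(range(M))  # union = [0, M), pairwise disjoint


def test_single_connection_network_emits_one_record():
    params = sp.BenchmarkParams(N=1, K=1)
    spec = sp.generate_benchmark(params, seed=0)
    P = sp.PartitionConfig(1, 1)
    tables = _build_tables(spec, P)
    tts, counters = build_presynaptic(tables, P, spec.params.N)
    assert counters.entries_sent == 1
    assert tts[0].entry_count() == 1


@pytest.mark.parametrize("sorted_mode", [False, True])
@pytest.mark.parametrize("M,T", [(1, 1), (2, 2), (3, 1), (2, 3)])
def test_target_table_matches_bruteforce_oracle(small_spec, M, T, sorted_mode):
    P = sp.PartitionConfig(M, T)
    tables = _build_tables(small_spec, P)
    if sorted_mode:
        for t in tables:
            t.sort_all()
    tts, counters = build_presynaptic(tables, P, small_spec.params.N,
                                      sorted_mode=sorted_mode)
    assert _actual_entries(tts, P) == _expected_entries(small_spec, P, sorted_mode)
    if not sorted_mode:
        # bijection: exactly one record per connection
        assert counters.entries_sent == small_spec.n_connections
        assert counters.entries_used == small_spec.n_connections


def test_capped_buffer_gives_identical_table_with_more_rounds(small_spec):
    P = sp.PartitionConfig(2, 2)
    uncapped, _ = build_presynaptic(_build_tables(small_spec, P), P,
                                    small_spec.params.N)
    capped, counters = build_presynaptic(
        _build_tables(small_spec, P), P, small_spec.params.N,
        policy=BufferPolicy(initial_entries=2, max_entries=2))
    assert counters.rounds > 1
    assert _actual_entries(capped, P) == _actual_entries(uncapped, P)


def test_construction_is_idempotent(small_spec):
    P = sp.PartitionConfig(2, 1)
    tables = _build_tables(small_spec, P)
    first, _ = build_presynaptic(tables, P, small_spec.params.N)
    for t in tables:
        t.build_phase = True  # re-open explicitly; no new connections added
    second, _ = build_presynaptic(tables, P, small_spec.params.N)
    assert [t.entries for t in first] == [t.entries for t in second]


def test_build_ends_build_phase(small_spec):
    P = sp.PartitionConfig(1, 1)
    tables = _build_tables(small_spec, P)
    build_presynaptic(tables, P, small_spec.params.N)
    with pytest.raises(PhaseError):
        tables[0].add_connection(0, 0, 0, 0, 1.0, 15, 99)


def test_sorted_mode_requires_prior_sorting(small_spec):
    P = sp.PartitionConfig(1, 1)
    tables = _build_tables(small_spec, P)
    with pytest.raises(ProtocolError):
        build_presynaptic(tables, P, small_spec.params.N, sorted_mode=True)
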