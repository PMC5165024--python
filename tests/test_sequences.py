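"""Sequence chaining, tie reordering, connection matrix, constraints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spikeprop as sp
from .conftest import make_dataset, random_event_stream


def chain_oracle(times, leader_window=50.0, chain_gap=15.0, min_length=5):
    """Naive re-statement of the chaining rules, kept independent of the
    implementation: repeatedly scan forward from each leader, testing both
    windows from scratch, until a terminating spike closes the candidate.
    """
    groups = []
    i = 0
    n = len(times)
    while i < n:
        leader_t = times[i]
        members = [i]
        j = i + 1
        while j < n:
            gap_from_leader = times[j] - leader_t
            gap_from_prev = times[j] - times[members[-1]]
            if gap_from_leader <= leader_window:
                members.append(j)
            elif gap_from_prev <= chain_gap:
                members.append(j)
            else:
                break
            j += 1
        groups.append(members)
        i = j
    return [g for g in groups if len(g) >= min_length]


class TestExtractRawSequences:
    def test_chain_gap_extends_past_leader_window(self, ds_factory):
        # 58-45=13<=15 and 70-58=12<=15 keep the chain alive past 50 ms
        ds = ds_factory([1, 2, 3, 4, 5, 6], [0, 20, 45, 58, 70, 200],
                        sampling_rate=1000)
        seqs = sp.extract_raw_sequences(ds, sp.ExtractionConfig())
        assert len(seqs) == 1
        assert len(seqs[0]) == 5
        assert seqs[0].latencies.tolist() == [0, 20, 45, 58, 70]

    def test_short_candidate_discarded(self, ds_factory):
        ds = ds_factory([1, 2, 3, 4, 5], [0, 20, 40, 60, 300])
        assert sp.extract_raw_sequences(ds, sp.ExtractionConfig()) == []

    def test_leader_window_boundary_inclusive(self, ds_factory):
        ds = ds_factory([1, 2], [0, 50])
        cfg = sp.ExtractionConfig(min_length=2)
        seqs = sp.extract_raw_sequences(ds, cfg)
        assert len(seqs) == 1 and len(seqs[0]) == 2

    def test_empty_input(self, grid8):
        ds = sp.SpikeDataset(pd.DataFrame({"channel_id": pd.Series(dtype=int),
                                           "time_ms": pd.Series(dtype=float)}), 0.0)
        assert sp.extract_raw_sequences(ds, sp.ExtractionConfig()) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_oracle_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_event_stream(rng, int(rng.integers(5, 120)))
        cfg = sp.ExtractionConfig()
        got = [s.event_ids.tolist() for s in sp.extract_raw_sequences(ds, cfg)]
        want = chain_oracle(ds.times)
        assert got == want

    def test_partition_of_events_before_filter(self):
        # with min_length=2 and dense events, every event lands in a sequence
        rng = np.random.default_rng(1)
        ds = random_event_stream(rng, 80, t_max=500.0)
        seqs = sp.extract_raw_sequences(ds, sp.ExtractionConfig(min_length=2))
        ids = np.concatenate([s.event_ids for s in seqs]) if seqs else []
        assert len(ids) == len(set(ids))  # no event in two sequences

    def test_chain_gap_widening_can_shift_leaders(self):
        """Widening the chain gap is not monotone in kept spikes.

        Keeping an extra event alive moves subsequent leaders earlier, which
        can make the leader window reject later events it would otherwise
        accept.  Here gap 15 -> 20 ms drops the kept-spike count from 6 to 5
        because event 52 stays attached to the leader at 0 and the chain
        then breaks at 100.  This pins the greedy single-pass semantics.
        """
        times = [0, 35, 52, 100, 101, 102, 103, 104]
        kept = {}
        for gap in (15.0, 20.0):
            ds = sp.from_events(range(1, 9), times, sampling_rate=1000)
            seqs = sp.extract_raw_sequences(ds, sp.ExtractionConfig(chain_gap_ms=gap))
            kept[gap] = sum(len(s) for s in seqs)
        assert kept == {15.0: 6, 20.0: 5}


class TestReorderTiedSpikes:
    def _map(self, positions):
        n = len(positions)
        return sp.ElectrodeMap(pd.DataFrame({
            "channel_id": np.arange(1, n + 1), "label": ["e"] * n,
            "x_mm": [p[0] for p in positions], "y_mm": [p[1] for p in positions]}))

    def test_tied_run_sorted_by_distance_to_anchor(self):
        # anchor ch1 at (0,0); tied ch2 at (30,0) and ch3 at (10,0)
        emap = self._map([(0, 0), (30, 0), (10, 0)])
        ds = make_dataset([1, 2, 3], [0.0, 100.0, 100.0])
        out = sp.reorder_tied_spikes(ds, emap)
        assert out.channels.tolist() == [1, 3, 2]  # nearer first

    def test_singleton_runs_unchanged(self):
        emap = self._map([(0, 0), (30, 0), (10, 0)])
        ds = make_dataset([1, 2, 3], [0.0, 100.0, 200.0])
        out = sp.reorder_tied_spikes(ds, emap)
        assert out.channels.tolist() == [1, 2, 3]

    def test_equidistant_breaks_by_channel_id(self):
        emap = self._map([(0, 0), (10, 0), (-10, 0)])
        ds = make_dataset([1, 3, 2], [0.0, 50.0, 50.0])
        out = sp.reorder_tied_spikes(ds, emap)
        assert out.channels.tolist() == [1, 2, 3]

    def test_run_opening_record_uses_following_anchor(self):
        # tied pair opens the record; anchor is the later singleton at (0,0)
        emap = self._map([(0, 0), (30, 0), (10, 0)])
        ds = make_dataset([2, 3, 1], [0.0, 0.0, 100.0])
        out = sp.reorder_tied_spikes(ds, emap)
        assert out.channels.tolist() == [3, 2, 1]

    def test_all_tied_warns_and_keeps_channel_order(self):
        emap = self._map([(0, 0), (30, 0), (10, 0)])
        ds = make_dataset([1, 2, 3], [50.0, 50.0, 50.0], minutes=1.0)
        with pytest.warns(UserWarning, match="tied"):
            out = sp.reorder_tied_spikes(ds, emap)
        assert out.channels.tolist() == [1, 2, 3]

    def test_times_and_event_ids_preserved(self, grid8):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.integers(1, 65, 200),
                          np.sort(rng.integers(0, 100, 200) * 5.0))
        out = sp.reorder_tied_spikes(ds, grid8)
        assert sorted(out.events.index) == sorted(ds.events.index)
        assert np.all(np.diff(out.times) >= 0)
        assert sorted(out.times) == sorted(ds.times)


class TestConnectionMatrix:
    def test_single_path(self, grid8, seq_factory):
        s = seq_factory([(1, 0.0), (2, 10.0), (3, 20.0)])
        C = sp.build_connection_matrix([s], grid8)
        i, j, k = grid8.index_of([1, 2, 3])
        assert C.matrix[i, j] == 1 and C.matrix[j, k] == 1
        assert C.matrix.sum() == 2

    def test_counts_accumulate_across_sequences(self, grid8, seq_factory):
        seqs = [seq_factory([(4, 0.0), (7, 10.0), (9, 20.0)]) for _ in range(6)]
        seqs += [seq_factory([(4, 0.0), (9, 10.0)]) for _ in range(94)]
        C = sp.build_connection_matrix(seqs, grid8)
        i, j = grid8.index_of([4, 7])
        assert C.matrix[i, j] == 6

    def test_empty_and_self_transitions(self, grid8, seq_factory):
        assert sp.build_connection_matrix([], grid8).matrix.sum() == 0
        s = seq_factory([(1, 0.0), (1, 5.0), (2, 10.0)])
        C = sp.build_connection_matrix([s], grid8)
        i, j = grid8.index_of([1, 2])
        assert C.matrix[i, i] == 0 and C.matrix[i, j] == 1


class TestSpatialConstraints:
    @pytest.fixture()
    def setup(self, grid8):
        parts = sp.auto_partition(grid8)  # 16 blocks of 2x2
        cfg = sp.ExtractionConfig()
        return grid8, parts, cfg

    def _constmatrix(self, grid8, pairs_counts):
        n = grid8.n_channels
        C = np.zeros((n, n), int)
        for (src, dst), c in pairs_counts.items():
            i, j = grid8.index_of([src, dst])
            C[i, j] = c
        return sp.ConnectionMatrix(grid8.channel_ids, C)

    def test_adjacent_partition_hops_unchanged(self, setup, seq_factory):
        grid8, parts, cfg = setup
        # channels 1,2,9,10 = one 2x2 block; 3 sits in the adjacent block
        s = seq_factory([(1, 0.0), (2, 5.0), (10, 10.0), (3, 15.0), (11, 20.0)])
        C = self._constmatrix(grid8, {})
        out = sp.apply_spatial_constraints([s], parts, C, cfg, grid8)
        assert len(out) == 1
        assert out[0].channels.tolist() == s.channels.tolist()

    def test_frequent_long_jump_retained(self, setup, seq_factory):
        grid8, parts, cfg = setup
        # 1 -> 64 crosses the whole grid; make it carry 6% of channel 1's output
        s = seq_factory([(1, 0.0), (64, 5.0), (63, 10.0), (55, 15.0), (56, 20.0)])
        C = self._constmatrix(grid8, {(1, 64): 6, (1, 2): 94})
        out = sp.apply_spatial_constraints([s], parts, C, cfg, grid8)
        assert len(out) == 1 and len(out[0]) == 5

    def test_infrequent_long_jump_split_and_dropped(self, setup, seq_factory):
        grid8, parts, cfg = setup
        s = seq_factory([(1, 0.0), (64, 5.0), (63, 10.0), (55, 15.0), (56, 20.0)])
        C = self._constmatrix(grid8, {(1, 64): 4, (1, 2): 96})  # 4% < 5%
        out = sp.apply_spatial_constraints([s], parts, C, cfg, grid8)
        # head candidate has 1 spike, tail candidate 4: both below min_length
        assert out == []

    def test_interleaved_discharges_disentangle(self, setup, seq_factory):
        grid8, parts, cfg = setup
        # alternate corners: spikes from the 1-corner and the 64-corner interleave
        s = seq_factory([(1, 0.0), (64, 2.0), (2, 5.0), (63, 7.0), (9, 10.0),
                         (56, 12.0), (10, 15.0), (55, 17.0), (3, 20.0), (48, 22.0)])
        C = self._constmatrix(grid8, {})
        out = sp.apply_spatial_constraints([s], parts, C, cfg, grid8)
        chan_sets = sorted(tuple(sorted(o.channels)) for o in out)
        assert chan_sets == [(1, 2, 3, 9, 10), (48, 55, 56, 63, 64)]

    def test_strict_mode_terminates_instead_of_splitting(self, setup, seq_factory):
        grid8, parts, _ = setup
        cfg = sp.ExtractionConfig(split_rejected=False, min_length=2)
        s = seq_factory([(1, 0.0), (2, 2.0), (64, 5.0), (63, 7.0)])
        C = self._constmatrix(grid8, {})
        out = sp.apply_spatial_constraints([s], parts, C, cfg, grid8)
        # the rejected jump closes {1,2}; {64,63} forms its own chain
        assert [o.channels.tolist() for o in out] == [[1, 2], [64, 63]]

    def test_zero_row_sum_never_frequent(self, setup, seq_factory):
        grid8, parts, cfg = setup
        s = seq_factory([(1, 0.0), (64, 5.0)])
        C = self._constmatrix(grid8, {})
        assert not C.frequent(1, 64, cfg.freq_threshold)

    def test_every_retained_pair_satisfies_adjacency_or_frequency(self, setup):
        grid8, parts, cfg = setup
        rng = np.random.default_rng(8)
        ds = random_event_stream(rng, 400, n_channels=64, t_max=20_000.0)
        ds = sp.reorder_tied_spikes(ds, grid8)
        raw = sp.extract_raw_sequences(ds, sp.ExtractionConfig(min_length=2))
        C = sp.build_connection_matrix(raw, grid8)
        out = sp.apply_spatial_constraints(raw, parts, C, sp.ExtractionConfig(min_length=2),
                                           grid8)
        for s in out:
            ch = s.channels
            for a, b in zip(ch[:-1], ch[1:]):
                assert parts.same_or_adjacent(int(a), int(b)) or \
                    C.frequent(int(a), int(b), cfg.freq_threshold)
            assert np.all(np.diff(s.times) >= 0)
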