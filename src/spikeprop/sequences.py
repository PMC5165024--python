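"""Multichannel spike-sequence extraction and propagation constraints.

The chaining algorithm walks the time-sorted event stream once.  The first
event opens a candidate sequence as its "leader"; each later event joins the
open candidate when it falls within the leader window (default 50 ms, the
range over which interictal spikes are known to propagate) OR within the
chain gap (default 15 ms) of the previous spike, which lets unexpectedly
long discharges keep growing.  An event violating both windows is the
"terminating spike": it closes the candidate and leads the next one.
Candidates shorter than ``min_length`` (default 5) are discarded as likely
false positives.  Both window comparisons are inclusive (<=).

Two propagation constraints are then applied:

* tied events (equal quantized peak time, an artifact of the modest 200 Hz
  acquisition rate) are re-ordered by spatial proximity to the nearest
  non-tied event, since transmission probability falls with distance;
* each step of a sequence must stay within the same or an adjacent
  partition of ~4-8 neighboring electrodes, unless the channel-to-channel
  connection is "frequent" (observed in more than ``freq_threshold`` of
  all transitions out of the source channel, default 5%).  A step that
  fails both rules is split off to seed a new, possibly temporally
  overlapping, candidate (distinct discharges can interleave in time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geometry import ElectrodeMap, Partitioning
from .spike_data import SpikeDataset


@dataclass(frozen=True)
class ExtractionConfig:
    leader_window_ms: float = 50.0
    chain_gap_ms: float = 15.0
    min_length: int = 5
    freq_threshold: float = 0.05
    #: when False, a constraint-violating spike terminates the current chain
    #: (strict mode) instead of seeding a concurrent candidate
    split_rejected: bool = True

    def __post_init__(self):
        if not (self.leader_window_ms >= self.chain_gap_ms > 0):
            raise ValidationError("need leader_window >= chain_gap > 0")
        if self.min_length < 2:
            raise ValidationError("min_length must be >= 2")
        if not (0 < self.freq_threshold < 1):
            raise ValidationError("freq_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SpikeSequence:
    """An ordered multichannel discharge.

    ``events`` keeps the originating event ids as index; ``latencies`` are
    offsets (ms) from the sequence's own leader (first spike).
    """

    events: pd.DataFrame  # columns channel_id, time_ms; index = event ids

    def __post_init__(self):
        if len(self.events) == 0:
            raise ValidationError("empty spike sequence")
        t = self.events["time_ms"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise ValidationError("sequence times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def channels(self) -> np.ndarray:
        return self.events["channel_id"].to_numpy(int)

    @property
    def times(self) -> np.ndarray:
        return self.events["time_ms"].to_numpy(float)

    @property
    def leader(self) -> tuple[int, float]:
        return int(self.channels[0]), float(self.times[0])

    @property
    def latencies(self) -> np.ndarray:
        t = self.times
        return t - t[0]

    @property
    def event_ids(self) -> np.ndarray:
        return self.events.index.to_numpy()

    def as_points(self, emap: ElectrodeMap) -> np.ndarray:
        """(n, 3) array of (x_mm, y_mm, latency_ms) — the trajectory points."""
        xy = emap.positions(self.channels)
        return np.column_stack([xy, self.latencies])


def extract_raw_sequences(ds: SpikeDataset, cfg: ExtractionConfig) -> list[SpikeSequence]:
    """Single-pass greedy chaining of the sorted event stream (see module docs).

    Every input event belongs to exactly one candidate before the
    ``min_length`` filter; the returned list preserves temporal order.
    """
    times = ds.times
    seqs: list[SpikeSequence] = []
    if len(times) == 0:
        return seqs
    start = 0  # candidate leader position
    prev = 0
    for k in range(1, len(times)):
        within_leader = times[k] - times[start] <= cfg.leader_window_ms
        within_gap = times[k] - times[prev] <= cfg.chain_gap_ms
        if within_leader or within_gap:
            prev = k
        else:
            if prev - start + 1 >= cfg.min_length:
                seqs.append(SpikeSequence(ds.events.iloc[start:prev + 1]))
            start = prev = k
    if prev - start + 1 >= cfg.min_length:
        seqs.append(SpikeSequence(ds.events.iloc[start:prev + 1]))
    return seqs


def reorder_tied_spikes(ds: SpikeDataset, emap: ElectrodeMap) -> SpikeDataset:
    """Re-order runs of equal-time ("tied") events by spatial proximity.

    Each maximal run of events sharing a quantized time is permuted into
    ascending Euclidean distance from its anchor: the nearest preceding
    non-tied event, or — when the run opens the record — the nearest
    following one.  Remaining ties break by channel id.  If every event in
    the record is tied there is no anchor; the run stays in channel-id
    order and a warning is issued.
    """
    if ds.n_events == 0:
        return ds
    times = ds.times
    channels = ds.channels
    coords = emap.positions(channels)
    # run starts: positions where time changes
    boundaries = np.concatenate([[0], np.where(np.diff(times) != 0)[0] + 1, [len(times)]])
    runs = [(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]
    singleton = [b - a == 1 for a, b in runs]
    order = np.arange(len(times))
    if not any(singleton) and len(runs) >= 1 and any(b - a > 1 for a, b in runs):
        warnings.warn("all events tied; keeping channel-id order", stacklevel=2)
    for r, (a, b) in enumerate(runs):
        if b - a == 1:
            continue
        anchor = None
        for rr in range(r - 1, -1, -1):
            if singleton[rr]:
                anchor = runs[rr][0]
                break
        if anchor is None:
            for rr in range(r + 1, len(runs)):
                if singleton[rr]:
                    anchor = runs[rr][0]
                    break
        if anchor is None:
            continue  # no non-tied event anywhere
        dist = np.linalg.norm(coords[a:b] - coords[anchor], axis=1)
        perm = np.lexsort((channels[a:b], dist))
        order[a:b] = a + perm
    ev = ds.events.iloc[order]
    return SpikeDataset(ev, ds.analyzed_minutes, ds.sampling_rate, ds.patient_id)


@dataclass(frozen=True)
class ConnectionMatrix:
    """C[i, j] = number of times a spike propagated from channel i to j
    (consecutive pairs within raw sequences; self-transitions excluded)."""

    channel_ids: np.ndarray
    matrix: np.ndarray  # (N, N) int counts

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def frequent(self, src: int, dst: int, threshold: float) -> bool:
        """True when src->dst carries more than ``threshold`` of src's output.

        A channel with no outgoing transitions has no frequent connections.
        """
        pos = pd.Series(np.arange(len(self.channel_ids)), index=self.channel_ids)
        i, j = pos[src], pos[dst]
        total = self.matrix[i].sum()
        if total == 0:
            return False
        return self.matrix[i, j] / total > threshold


def build_connection_matrix(seqs: list[SpikeSequence], emap: ElectrodeMap) -> ConnectionMatrix:
    n = emap.n_channels
    pos = pd.Series(np.arange(n), index=emap.channel_ids)
    C = np.zeros((n, n), dtype=int)
    for s in seqs:
        idx = pos.loc[s.channels].to_numpy()
        for i, j in zip(idx[:-1], idx[1:]):
            if i != j:  # detector re-fires on one channel are not propagation
                C[i, j] += 1
    return ConnectionMatrix(emap.channel_ids, C)


def apply_spatial_constraints(seqs: list[SpikeSequence], partitions: Partitioning,
                              C: ConnectionMatrix, cfg: ExtractionConfig,
                              emap: ElectrodeMap) -> list[SpikeSequence]:
    """Enforce the partition-adjacency / frequent-connection rule.

    Walks each raw sequence in time order.  A spike is accepted after a
    predecessor when the two channels share a partition, sit in adjacent
    partitions, or form a frequent connection in ``C``.  A rejected spike
    seeds a new concurrent candidate; later spikes try open candidates
    most-recently-extended first, so interleaved discharges disentangle
    into temporally overlapping chains.  In strict mode
    (``split_rejected=False``) a rejected spike instead terminates the
    current candidate.  All resulting chains are re-filtered to
    ``min_length``; spike times are untouched and each chain's latencies
    restart from its own leader.
    """
    pos = pd.Series(np.arange(len(C.channel_ids)), index=C.channel_ids)
    row_tot = C.matrix.sum(axis=1)

    def accept(prev_ch: int, cur_ch: int) -> bool:
        if partitions.same_or_adjacent(prev_ch, cur_ch):
            return True
        i, j = pos[prev_ch], pos[cur_ch]
        return row_tot[i] > 0 and C.matrix[i, j] / row_tot[i] > cfg.freq_threshold

    out: list[SpikeSequence] = []
    for s in seqs:
        chans = s.channels
        chains: list[list[int]] = [[0]]  # row positions within s
        active = [True]
        for k in range(1, len(chans)):
            # most recently extended open chain first
            candidates = sorted(
                (c for c in range(len(chains)) if active[c]),
                key=lambda c: chains[c][-1], reverse=True)
            placed = False
            for c in candidates:
                if accept(int(chans[chains[c][-1]]), int(chans[k])):
                    chains[c].append(k)
                    placed = True
                    break
            if not placed:
                if not cfg.split_rejected:
                    for c in candidates:
                        active[c] = False
                chains.append([k])
                active.append(True)
        for rows in chains:
            if len(rows) >= cfg.min_length:
                out.append(SpikeSequence(s.events.iloc[rows]))
    return out


def sequences_to_jsonl(seqs: list[SpikeSequence], patient_id: str = "") -> str:
    """Serialize sequences as JSON-lines (one object per sequence)."""
    import json

    lines = []
    for sid, s in enumerate(seqs):
        lat = s.latencies
        lines.append(json.dumps({
            "seq_id": sid,
            "patient_id": patient_id,
            "spikes": [
                {"channel_id": int(c), "time_ms": float(t), "latency_ms": float(l)}
                for c, t, l in zip(s.channels, s.times, lat)
            ],
        }, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")
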