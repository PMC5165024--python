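"""Recruitment-latency maps and cumulative probability distributions.

A channel's recruitment latency in a sequence is its offset (ms) from the
sequence's leader, taken at the channel's first occurrence (its recruitment
moment; detector re-fires later in the same discharge are ignored).  The
recruitment-latency map is the per-channel mean of those latencies across
all cleaned sequences — "source" regions carry low means, "sink" regions
high means.  Channels that never join a sequence are excluded rather than
zero-filled (a zero would fabricate early recruitment); the downstream
Moran Index restricts itself to the included channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geometry import ElectrodeMap
from .sequences import SpikeSequence


@dataclass(frozen=True)
class RecruitmentLatencyMap:
    """Per-channel mean recruitment latency (ms) and appearance counts."""

    table: pd.DataFrame  # columns channel_id, mean_latency_ms, n_appearances

    @property
    def channel_ids(self) -> np.ndarray:
        return self.table["channel_id"].to_numpy(int)

    @property
    def mean_latency(self) -> pd.Series:
        return self.table.set_index("channel_id")["mean_latency_ms"]


def _first_occurrence_latencies(seqs: list[SpikeSequence]) -> pd.DataFrame:
    """Long table (channel_id, latency_ms): one row per channel per sequence."""
    rows = []
    for s in seqs:
        lat = pd.DataFrame({"channel_id": s.channels, "latency_ms": s.latencies})
        rows.append(lat.drop_duplicates("channel_id", keep="first"))
    return pd.concat(rows, ignore_index=True)


def recruitment_latency_map(seqs: list[SpikeSequence], emap: ElectrodeMap,
                            min_count: int = 1) -> RecruitmentLatencyMap:
    """Mean first-occurrence latency per channel over all sequences.

    Channels with fewer than ``min_count`` appearances are excluded.
    """
    if not seqs:
        raise ValidationError("no sequences: recruitment map undefined")
    long = _first_occurrence_latencies(seqs)
    grouped = long.groupby("channel_id")["latency_ms"].agg(["mean", "size"])
    grouped = grouped[grouped["size"] >= min_count]
    known = np.isin(grouped.index.to_numpy(), emap.channel_ids)
    if not known.all():
        raise ValidationError("sequences reference channels missing from the map")
    table = grouped.reset_index().rename(
        columns={"mean": "mean_latency_ms", "size": "n_appearances"})
    return RecruitmentLatencyMap(table)


@dataclass(frozen=True)
class LatencyCPD:
    """Empirical cumulative latency distribution per channel on a fixed grid.

    ``probs[g, c]`` = fraction of channel c's recruitment latencies <= grid
    point g.  Each column is nondecreasing; a channel recruited only as
    leader has CPD(0) = 1.
    """

    grid_ms: np.ndarray
    probs: pd.DataFrame  # index grid_ms, one column per channel_id


DEFAULT_CPD_GRID = np.arange(0.0, 105.0, 5.0)


def latency_cpd(seqs: list[SpikeSequence], emap: ElectrodeMap,
                grid_ms: np.ndarray | None = None) -> LatencyCPD:
    if not seqs:
        raise ValidationError("no sequences: CPD undefined")
    grid = DEFAULT_CPD_GRID if grid_ms is None else np.asarray(grid_ms, float)
    long = _first_occurrence_latencies(seqs)
    cols = {}
    for ch, sub in long.groupby("channel_id"):
        lat = np.sort(sub["latency_ms"].to_numpy())
        cols[int(ch)] = np.searchsorted(lat, grid, side="right") / lat.size
    probs = pd.DataFrame(cols, index=pd.Index(grid, name="latency_ms"))
    return LatencyCPD(grid, probs)


def sequence_frequency(seqs: list[SpikeSequence], analyzed_minutes: float) -> float:
    """Multichannel discharge rate: sequences per analyzed minute."""
    if analyzed_minutes <= 0:
        raise ValidationError("analyzed_minutes must be positive")
    return len(seqs) / analyzed_minutes
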