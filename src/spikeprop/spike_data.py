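"""Detector-output ingestion, interictal segmentation, spike-frequency maps.

The upstream spike detector emits a two-column event stream (channel index,
peak time).  This module turns that stream into a validated, time-sorted
:class:`SpikeDataset`, cuts it into fixed-size 10,000-spike segments for
unbiased cross-patient sampling, and summarizes the per-channel spike
distribution as a frequency map with Lorenz-curve / Gini concentration
statistics.

Times are stored in milliseconds quantized to the acquisition step (5 ms at
the default 200 Hz); events sharing a quantized time are "tied" and are later
reordered spatially (see :mod:`spikeprop.sequences`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, FormatError, ValidationError
from .geometry import ElectrodeMap

DEFAULT_SAMPLING_RATE_HZ = 200.0


def _quantize(times_ms: np.ndarray, sampling_rate: float) -> np.ndarray:
    step = 1000.0 / sampling_rate
    return np.round(np.asarray(times_ms, float) / step) * step


@dataclass(frozen=True)
class SpikeDataset:
    """Time-sorted spike events with analyzed-duration metadata.

    ``events`` has columns ``channel_id`` and ``time_ms``; the index is a
    stable per-event id that survives reordering and sequence extraction,
    so ground-truth bookkeeping on synthetic data is exact.
    """

    events: pd.DataFrame
    analyzed_minutes: float
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    patient_id: str = ""

    def __post_init__(self):
        ev = self.events
        if list(ev.columns[:2]) != ["channel_id", "time_ms"] and not (
                "channel_id" in ev.columns and "time_ms" in ev.columns):
            raise FormatError("events need channel_id and time_ms columns")
        if len(ev) and (ev["time_ms"].to_numpy() < 0).any():
            raise ValidationError("negative spike times")
        if len(ev) and np.any(np.diff(ev["time_ms"].to_numpy()) < 0):
            raise ValidationError("events must be non-decreasing in time")
        if self.analyzed_minutes <= 0 and len(ev):
            raise ValidationError("analyzed_minutes must be positive")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return self.events["time_ms"].to_numpy(float)

    @property
    def channels(self) -> np.ndarray:
        return self.events["channel_id"].to_numpy(int)

    @property
    def time_step_ms(self) -> float:
        return 1000.0 / self.sampling_rate


@dataclass(frozen=True)
class SamplingConfig:
    """Fixed-size interictal segmentation: blocks of ``spikes_per_segment``
    consecutive spikes, of which ``n_segments`` are drawn at random."""

    spikes_per_segment: int = 10_000
    n_segments: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.spikes_per_segment < 1 or self.n_segments < 1:
            raise ValidationError("segment counts must be >= 1")


def read_detections(path, emap: ElectrodeMap, analyzed_minutes: float | None = None,
                    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
                    patient_id: str = "") -> SpikeDataset:
    """Read a detector CSV (``channel_id,time_ms``; header auto-detected).

    Events are quantized to the acquisition step, then sorted by time with
    ascending channel id breaking ties (the detector's default order before
    spatial tie reordering).  ``analyzed_minutes`` defaults to the recorded
    span of the events.
    """
    try:
        first = pd.read_csv(path, header=None, nrows=1)
    except pd.errors.EmptyDataError:
        return SpikeDataset(pd.DataFrame({"channel_id": pd.Series(dtype=int),
                                          "time_ms": pd.Series(dtype=float)}),
                            analyzed_minutes if analyzed_minutes else 0.0,
                            sampling_rate, patient_id)
    has_header = not np.issubdtype(np.asarray(first.iloc[0, 0]).dtype, np.number)
    raw = pd.read_csv(path, header=0 if has_header else None)
    raw = raw.iloc[:, :2]
    raw.columns = ["channel_id", "time_ms"]
    try:
        channels = raw["channel_id"].astype(int).to_numpy()
        times = raw["time_ms"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric detection rows in {path}: {exc}") from exc
    unknown = ~np.isin(channels, emap.channel_ids)
    if unknown.any():
        rows = np.where(unknown)[0][:20]
        raise ValidationError(
            f"unknown channel ids at rows {rows.tolist()}: "
            f"{sorted(set(channels[unknown].tolist()))}")
    if (times < 0).any():
        raise ValidationError(f"negative times at rows {np.where(times < 0)[0][:20].tolist()}")
    times = _quantize(times, sampling_rate)
    ev = pd.DataFrame({"channel_id": channels, "time_ms": times})
    ev = ev.sort_values(["time_ms", "channel_id"], kind="mergesort").reset_index(drop=True)
    if analyzed_minutes is None:
        analyzed_minutes = float(times.max() - times.min()) / 60_000.0 if len(ev) else 0.0
    return SpikeDataset(ev, analyzed_minutes, sampling_rate, patient_id)


def from_events(channels, times_ms, analyzed_minutes: float | None = None,
                sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
                patient_id: str = "") -> SpikeDataset:
    """Build a dataset from in-memory arrays (quantizes, sorts, ties by channel)."""
    times = _quantize(np.asarray(times_ms, float), sampling_rate)
    ev = pd.DataFrame({"channel_id": np.asarray(channels, int), "time_ms": times})
    ev = ev.sort_values(["time_ms", "channel_id"], kind="mergesort").reset_index(drop=True)
    if analyzed_minutes is None:
        analyzed_minutes = float(times.max() - times.min()) / 60_000.0 if len(ev) else 0.0
    return SpikeDataset(ev, analyzed_minutes, sampling_rate, patient_id)


def segment_and_sample(ds: SpikeDataset, cfg: SamplingConfig) -> SpikeDataset:
    """Cut into consecutive ``spikes_per_segment`` blocks and sample blocks.

    The trailing incomplete block is discarded.  ``min(n_segments, available)``
    blocks are drawn uniformly without replacement with the configured seed
    and concatenated in chronological order (so the result stays sorted);
    ``analyzed_minutes`` becomes the summed recorded span of the selected
    blocks.  Segments are chosen without regard to time of day or state.
    """
    n_blocks = ds.n_events // cfg.spikes_per_segment
    if n_blocks == 0:
        raise ValidationError(
            f"{ds.n_events} events yield no complete {cfg.spikes_per_segment}-spike segment")
    rng = np.random.default_rng(cfg.seed)
    take = min(cfg.n_segments, n_blocks)
    chosen = np.sort(rng.choice(n_blocks, size=take, replace=False))
    parts = []
    span_ms = 0.0
    for b in chosen:
        block = ds.events.iloc[b * cfg.spikes_per_segment:(b + 1) * cfg.spikes_per_segment]
        span_ms += float(block["time_ms"].iloc[-1] - block["time_ms"].iloc[0])
        parts.append(block)
    ev = pd.concat(parts)
    return SpikeDataset(ev, max(span_ms / 60_000.0, np.finfo(float).tiny),
                        ds.sampling_rate, ds.patient_id)


@dataclass(frozen=True)
class FrequencyMap:
    """Per-channel spike frequency (spikes/min) over every channel of the map."""

    rates: pd.Series  # index channel_id, values spikes/min
    analyzed_minutes: float
    n_channels: int

    @property
    def f_avg(self) -> float:
        return float(self.rates.mean())

    @property
    def spike_density(self) -> float:
        """Spikes per channel per minute — total count / (N * minutes)."""
        return float(self.rates.sum() / self.n_channels)

    def to_frame(self) -> pd.DataFrame:
        return self.rates.rename("spikes_per_min").rename_axis("channel_id").reset_index()


def spike_frequency_map(ds: SpikeDataset, emap: ElectrodeMap) -> FrequencyMap:
    """F_i = spike count of channel i / analyzed minutes (0 for silent channels)."""
    if ds.analyzed_minutes <= 0:
        raise ValidationError("analyzed_minutes must be positive for frequency maps")
    counts = pd.Series(ds.channels).value_counts()
    counts = counts.reindex(emap.channel_ids, fill_value=0).sort_index()
    return FrequencyMap(counts / ds.analyzed_minutes, ds.analyzed_minutes, emap.n_channels)


@dataclass(frozen=True)
class LorenzSummary:
    """Lorenz curve of the spike distribution and its Gini coefficient.

    ``points`` runs from (0, 0) to (1, 1): after sorting channels by
    ascending frequency, point k is (fraction of channels, fraction of
    spikes) accounted for by the k poorest channels.  ``gini`` is the
    population form sum_ij |F_i - F_j| / (2 N^2 F_avg), i.e. twice the area
    between the Lorenz curve and the equality line; 0 iff all channels
    spike equally, 1 - 1/N when a single channel holds everything.
    """

    points: np.ndarray  # (N+1, 2)
    gini: float


def lorenz_gini(fm: FrequencyMap) -> LorenzSummary:
    f = np.sort(fm.rates.to_numpy(float))
    total = f.sum()
    if total <= 0:
        raise DegenerateInputError("all channel frequencies are zero; Gini undefined")
    n = f.size
    cum = np.concatenate([[0.0], np.cumsum(f)]) / total
    points = np.column_stack([np.arange(n + 1) / n, cum])
    # population Gini via the sorted-rank identity (== pairwise |Fi-Fj| form)
    gini = float((2.0 * np.sum(np.arange(1, n + 1) * f)) / (n * total) - (n + 1) / n)
    return LorenzSummary(points, gini)
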