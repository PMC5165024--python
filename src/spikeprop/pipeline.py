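"""End-to-end orchestration: detections -> maps -> sequences -> statistics.

``run_analysis`` executes the full in-memory chain on a dataset:

    segment_and_sample -> spike_frequency_map / lorenz_gini
    -> reorder_tied_spikes -> extract_raw_sequences
    -> build_connection_matrix -> apply_spatial_constraints
    -> similarity_matrix -> classify_and_clean
    -> recruitment_latency_map / latency_cpd / sequence_frequency
    -> moran_index on both maps

``run_pipeline`` wraps it with file IO: it loads the detections and
electrode map named in a :class:`RunConfig` (usually parsed from YAML),
writes every intermediate artifact to the output directory, and returns a
:class:`RunReport`.  All randomness (segment sampling, k-means restarts,
permutation nulls) is split from one root seed with
``numpy.random.SeedSequence.spawn`` in a fixed order, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cleaning import CleaningConfig, classify_and_clean, similarity_matrix
from .exceptions import SpikePropError, ValidationError
from .geometry import (ElectrodeMap, Partitioning, auto_partition,
                       load_electrode_map, partition_from_labels, spatial_weights)
from .recruitment import latency_cpd, recruitment_latency_map, sequence_frequency
from .sequences import (ExtractionConfig, apply_spatial_constraints,
                        build_connection_matrix, extract_raw_sequences,
                        reorder_tied_spikes, sequences_to_jsonl)
from .spatial_stats import moran_index
from .spike_data import (SamplingConfig, SpikeDataset, lorenz_gini,
                         read_detections, spike_frequency_map)


@dataclass(frozen=True)
class RunConfig:
    detections_path: str
    electrode_map_path: str
    out_dir: str = "spikeprop_out"
    partition_adjacency_path: str | None = None
    analyzed_minutes: float | None = None
    sampling: SamplingConfig | None = None  # None = use the stream as-is
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    moran_radius_mm: float = 15.0
    min_count: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sampling" in kwargs and kwargs["sampling"] is not None:
            kwargs["sampling"] = SamplingConfig(**kwargs["sampling"])
        if "extraction" in kwargs:
            kwargs["extraction"] = ExtractionConfig(**kwargs["extraction"])
        if "cleaning" in kwargs:
            kwargs["cleaning"] = CleaningConfig(**kwargs["cleaning"])
        return cls(**kwargs)


def derive_seeds(root_seed: int, n: int = 3) -> list[int]:
    """Per-stage seeds from one root seed (order: sampling, kmeans, permutation)."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


@dataclass
class RunReport:
    patient_id: str
    n_spikes_in: int
    n_segments_used: int
    n_spikes_analyzed: int
    analyzed_minutes: float
    gini: float
    spike_density: float
    n_raw_sequences: int
    n_constrained_sequences: int
    n_clean_sequences: int
    sequence_frequency: float
    frequency_moran: float
    latency_moran: float
    cleaning_skipped: bool
    seed: int
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


def run_analysis(ds: SpikeDataset, emap: ElectrodeMap,
                 partitions: Partitioning | None = None,
                 sampling: SamplingConfig | None = None,
                 extraction: ExtractionConfig | None = None,
                 cleaning: CleaningConfig | None = None,
                 moran_radius_mm: float = 15.0, min_count: int = 1,
                 seed: int = 0) -> tuple[RunReport, dict]:
    """Full in-memory analysis; returns the report and the stage artifacts."""
    extraction = extraction or ExtractionConfig()
    sample_seed, kmeans_seed, _ = derive_seeds(seed)
    if cleaning is None:
        cleaning = CleaningConfig(seed=kmeans_seed)
    if partitions is None:
        partitions = (partition_from_labels(emap) if emap.has_partitions
                      else auto_partition(emap, seed=seed))

    n_in = ds.n_events
    n_segments = 1
    if sampling is not None:
        sampling = SamplingConfig(sampling.spikes_per_segment, sampling.n_segments,
                                  seed=sample_seed)
        n_blocks = ds.n_events // sampling.spikes_per_segment
        from .spike_data import segment_and_sample
        ds = segment_and_sample(ds, sampling)
        n_segments = min(sampling.n_segments, n_blocks)

    fmap = spike_frequency_map(ds, emap)
    lorenz = lorenz_gini(fmap)

    ds = reorder_tied_spikes(ds, emap)
    raw = extract_raw_sequences(ds, extraction)
    C = build_connection_matrix(raw, emap)
    constrained = apply_spatial_constraints(raw, partitions, C, extraction, emap)

    if len(constrained) >= 2:
        S = similarity_matrix(constrained, cleaning, emap)
        clean, classification = classify_and_clean(constrained, S, cleaning)
    else:
        S, classification = None, None
        clean = list(constrained)

    weights = spatial_weights(emap, moran_radius_mm)
    freq_moran = moran_index(fmap.rates, weights)
    if clean:
        rmap = recruitment_latency_map(clean, emap, min_count=min_count)
        cpd = latency_cpd(clean, emap)
        lat_moran = moran_index(rmap.mean_latency, weights)
        seq_freq = sequence_frequency(clean, ds.analyzed_minutes)
    else:
        raise SpikePropError("no sequences survived constraints/cleaning; "
                             "recruitment analysis undefined")

    report = RunReport(
        patient_id=ds.patient_id,
        n_spikes_in=n_in,
        n_segments_used=n_segments,
        n_spikes_analyzed=ds.n_events,
        analyzed_minutes=float(ds.analyzed_minutes),
        gini=lorenz.gini,
        spike_density=fmap.spike_density,
        n_raw_sequences=len(raw),
        n_constrained_sequences=len(constrained),
        n_clean_sequences=len(clean),
        sequence_frequency=seq_freq,
        frequency_moran=freq_moran.I,
        latency_moran=lat_moran.I,
        cleaning_skipped=bool(classification.skipped) if classification else True,
        seed=seed,
        version=__version__,
    )
    artifacts = {
        "dataset": ds, "frequency_map": fmap, "lorenz": lorenz,
        "raw_sequences": raw, "connection_matrix": C,
        "constrained_sequences": constrained, "similarity": S,
        "classification": classification, "clean_sequences": clean,
        "recruitment_map": rmap, "cpd": cpd, "partitions": partitions,
        "freq_moran": freq_moran, "latency_moran": lat_moran,
    }
    return report, artifacts


def run_pipeline(cfg: RunConfig) -> RunReport:
    """File-based pipeline run: load inputs, analyze, write artifacts."""
    emap = load_electrode_map(cfg.electrode_map_path)
    ds = read_detections(cfg.detections_path, emap,
                         analyzed_minutes=cfg.analyzed_minutes)
    partitions = None
    if emap.has_partitions:
        partitions = partition_from_labels(emap, cfg.partition_adjacency_path)
    report, art = run_analysis(
        ds, emap, partitions=partitions, sampling=cfg.sampling,
        extraction=cfg.extraction, cleaning=cfg.cleaning,
        moran_radius_mm=cfg.moran_radius_mm, min_count=cfg.min_count,
        seed=cfg.seed)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art["frequency_map"].to_frame().to_csv(out / "frequency_map.csv", index=False)
    (out / "lorenz.json").write_text(json.dumps({
        "gini": art["lorenz"].gini,
        "points": art["lorenz"].points.tolist(),
    }, sort_keys=True))
    (out / "sequences.jsonl").write_text(
        sequences_to_jsonl(art["clean_sequences"], report.patient_id))
    np.savetxt(out / "connection_matrix.csv",
               art["connection_matrix"].matrix, fmt="%d", delimiter=",")
    if art["similarity"] is not None:
        np.savetxt(out / "similarity.csv", art["similarity"].S,
                   fmt="%.6f", delimiter=",")
        art["classification"].to_frame().to_csv(out / "classification.csv", index=False)
    art["recruitment_map"].table.to_csv(out / "recruitment_map.csv", index=False)
    art["cpd"].probs.to_csv(out / "cpd.csv")
    (out / "report.json").write_text(report.to_json())
    return report


def plot_channel_map(values: pd.Series, emap: ElectrodeMap, path,
                     title: str = "", invert: bool = False) -> None:
    """Export a per-channel scalar field as a PNG heat map (warm = high,
    or warm = low/early when ``invert`` is set, the recruitment convention)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = emap.positions(values.index.to_numpy())
    fig, ax = plt.subplots(figsize=(6, 5))
    v = -values.to_numpy(float) if invert else values.to_numpy(float)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=v, cmap="jet", s=120,
                    edgecolors="k", linewidths=0.3)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
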