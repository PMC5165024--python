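# spikeprop

Spatiotemporal mapping of interictal spike propagation on intracranial
electrode arrays.

## The problem

Interictal spikes — transient high-amplitude discharges between seizures —
are routinely detected on subdural grid/strip recordings during the
presurgical evaluation of intractable epilepsy. A spike is often not a
local event: it appears on several electrodes with millisecond-scale
latencies, i.e. it *propagates* across the cortex. This package turns raw
spike-detector output (a two-column stream of channel index and peak time)
into:

1. **multichannel spike sequences** — chains of detections attributed to a
   single propagating discharge;
2. per-channel **spike-frequency maps** (the traditional density view) and
   **recruitment-latency maps** (each channel's mean temporal position, in
   ms from the sequence leader — the propagation view);
3. a single global statistic of each map's spatial organization, the
   **Moran Index**, plus nonparametric comparisons between outcome groups.

It is aimed at researchers quantifying epileptogenic-zone organization
from IEEG/ECoG event streams, without access to raw signal data.

## The method

**Sequence extraction.** Events are time-sorted (equal 5 ms-quantized
"tied" times re-ordered by spatial proximity to the nearest non-tied
event). The first event leads a candidate sequence; a later event joins
while it is within 50 ms of the leader *or* within 15 ms of the previous
spike; an event violating both windows terminates the candidate and leads
the next one. Candidates with fewer than 5 spikes are discarded. Each
consecutive step must stay within the same or an adjacent partition of
4–8 neighboring electrodes, unless that channel pair is a *frequent
connection*, i.e. `C(i,j) / Σ_j C(i,j) > 0.05` where `C` counts observed
i→j transitions.

**Trajectory cleaning.** Sequences are points `(x, y, latency)`. For a
(reference, test) pair, each reference point scores
`sim_point = 1 − d_match/ss_thresh` against the nearest test point within
15 mm and 15 ms (0 if none); the mean over reference points fills the
non-symmetric similarity matrix `S`. Sequences are ranked by degree
centrality in `S` and split into Low/Mid/High classes by 1-D k-means
(k = 3); Low-Degree sequences — artifact-like trajectories overlapping
almost nothing else — are removed.

**Spatial statistics.** For a per-channel field F with weights
`w_ij = 1/d_ij` when `d_ij ≤ 1.5 cm` (else 0),

```
I = N / ΣΣ w_ij · [ ΣΣ w_ij (F_i − F̄)(F_j − F̄) ] / [ Σ (F_i − F̄)² ]
```

ranges from −1 (neighbors anti-correlated) to +1 (values cluster in
space). Outcome groups are compared with the Wilcoxon rank-sum test
(exact mid-rank enumeration for small groups) under a Bonferroni-adjusted
threshold 0.05/2.

A seeded synthetic-data generator plants traveling wavefronts, Poisson
background spikes and single-frame artifact bursts with exact per-event
ground truth, so every stage is testable without any recording.

## Worked example

Simulate an 8-minute recording on an 8×8 grid (10 mm pitch) with two
discharge sources, background spikes and a few artifact bursts, then run
the full pipeline:

```python
import spikeprop as sp
from spikeprop.pipeline import run_analysis

emap = sp.ElectrodeMap.from_grid(8, 8)
cfg = sp.SimulationConfig(
    emap=emap, sources=((0.0, 0.0), (70.0, 70.0)), velocity_mm_per_ms=1.0,
    latency_jitter_sd_ms=1.0, background_rate_per_min=1.0,
    artifact_burst_rate_per_hour=6.0, discharge_rate_per_min=3.0,
    recruit_window_ms=50.0, duration_minutes=8.0, seed=21)
ds, truth = sp.simulate_recording(cfg)   # 1,284 events: 684 planted,
                                         # 548 background, 52 artifact
report, artifacts = run_analysis(ds, emap, seed=3)
print(report.to_json())
```

prints (abridged):

```
"n_raw_sequences": 30,          # candidates after the 50/15 ms chaining
"n_constrained_sequences": 30,  # after partition / frequent-connection rule
"n_clean_sequences": 28,        # two artifact-driven sequences removed
"sequence_frequency": 3.5,      # discharges per analyzed minute
"gini": 0.192,                  # spikes spread fairly evenly here
"frequency_moran": 0.529,       # spike-density map is spatially organized
"latency_moran": 0.574,         # propagation map is organized too
```

The two Moran Indices summarize the spatial organization of the
frequency and recruitment-latency maps; on real cohorts it is the
*latency*-map index that separates seizure-free from seizure-persistent
patients. The same pipeline runs from the shell:

```bash
spikeprop simulate --rows 8 --cols 8 --seed 21 --out sim/
spikeprop stats sim/detections.csv sim/electrode_map.csv --analyzed-minutes 10
spikeprop reproduce-tables   # group stats from the packaged cohort tables
```

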