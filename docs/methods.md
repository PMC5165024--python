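# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `spikeprop`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Input model

The package consumes spike-*detector* output, not raw EEG: a two-column
event stream (channel index, peak time) plus a 2D electrode map in mm.
Times are stored as floats quantized to the acquisition step (5 ms at the
default 200 Hz sampling rate). Events sharing a quantized time are
"tied"; ties are a direct consequence of the modest acquisition rate, and
all tie handling downstream assumes exactly this quantization. The 2D map
is a deliberate simplification — electrode distances along the cortical
surface are not captured; inter-grid/strip gaps must be expressed by the
map's coordinates (and, where hand-drawn partitions exist, by the
`partition` column, which always overrides automatic partitioning).

## Segmentation and sampling

Cross-patient comparability is achieved by fixed-size spike blocks, not
fixed-duration windows: the stream is cut into consecutive blocks of
10,000 spikes (trailing remainder discarded), and 10 blocks (or all, if
fewer exist) are drawn uniformly without replacement with an explicit
seed, then concatenated in chronological order. "Analyzed minutes" is
defined as the summed recorded span of the selected blocks; whether the
original analyses used that span or the full interictal duration is not
determinable, so the definition is configurable (`analyzed_minutes` can
be supplied directly).

## Sequence extraction

Greedy single pass over the sorted stream. Append event *e* to the open
candidate when `t_e − t_leader ≤ 50 ms` **or** `t_e − t_prev ≤ 15 ms`;
otherwise *e* is the terminating spike: the candidate closes and *e*
leads the next one. Both comparisons are inclusive (`≤`), resolving the
boundary in favor of appending. Candidates shorter than 5 spikes are
dropped. The 50 ms window reflects the 10–50 ms range over which
interictal spikes are known to propagate; the 15 ms gap captures
unexpectedly long discharges.

Two properties of this greedy rule are worth knowing:

* every event belongs to exactly one candidate before the length filter;
* the rule is **not monotone** in the chain gap: keeping one extra event
  alive can move subsequent leaders earlier, and the leader window then
  rejects events it would otherwise have accepted (pinned by a
  regression test with times 0, 35, 52, 100..104 ms, where widening the
  gap from 15 to 20 ms reduces the kept-spike count from 6 to 5).

**Tie reordering.** Each maximal run of equal-time events is permuted
into ascending Euclidean distance from its anchor — the nearest preceding
non-tied event, or the nearest following one when the run opens the
record — with channel id breaking exact distance ties. If every event in
the record is tied there is no anchor; channel-id order is kept and a
warning issued.

**Constraints (two-pass).** The channel-transition matrix `C` must exist
before the frequent-connection rule can be evaluated, so `C` is built
from the pass-1 (raw) sequences and constraints are applied in pass 2. A
spike is accepted after a predecessor when the channels share a
partition, sit in adjacent partitions, or `C(i,j)/row_i > 0.05` (a
channel with no outgoing transitions has no frequent connections). A
rejected spike seeds a new *concurrent* candidate, because near-zero
latencies at remote sites indicate separate but temporally overlapping
discharges; later spikes try open candidates most-recently-extended
first. A strict mode (`split_rejected=False`), in which rejection
terminates the current candidate, is provided for sensitivity analysis.
The ≥5-spike filter is re-applied after pass 2.

**Partitions.** Default automatic partitioning tiles each connected
component (15 mm adjacency) of the array with 2×2 lattice blocks and
merges undersized tiles into their nearest neighbor, preferring merges
that stay within the 4–8 band; at most one remainder partition per
component may fall outside the band. Partitions never span channels
farther than 15 mm apart, so separate strips partition separately. The
procedure is deterministic; manual partition labels always win.

## Trajectory cleaning

Sequences are point sets `(x, y, latency-from-leader)`; latency, not
absolute time, so two occurrences of the same trajectory at different
times are identical. The directed score of test against reference
averages `1 − d_match/15 mm` over reference points (0 where no test point
lies within 15 mm and 15 ms), giving the non-symmetric matrix `S` in
O(M²) pairs. Degree centrality defaults to in-plus-out similarity
(row + column sums, diagonal excluded); row-only is available via
`degree_mode="row"`. 1-D k-means with fixed k = 3 (seeded, 10 restarts,
best inertia) splits the degrees; clusters are relabeled by ascending
centroid so "Low" is well defined, and Low-Degree sequences are removed.

Guard rails: with fewer than 10 sequences or fewer than 3 distinct degree
values, k-means on the degree distribution is meaningless; cleaning is
skipped with a warning and everything is kept (this also covers the case
of an empty Low cluster).

**Known limitation.** Degree centrality flags trajectories that overlap
*nothing else*. Recurrent artifact with similar statistics (e.g. several
bursts each spanning a large channel fraction at near-zero latency)
mutually validates: burst-derived sequences score moderately against each
other and can rise into the Mid cluster. In synthetic sweeps this caps
the artifact-removal rate around 0.85–0.97 depending on how often bursts
co-occur within a recording; isolated bursts are removed reliably.

## Recruitment maps

A channel's latency in a sequence is taken at its *first* occurrence
(its recruitment moment; detector re-fires are ignored). The map is the
per-channel mean over all cleaned sequences; channels never recruited are
**excluded**, not zero-filled — a zero would fabricate early recruitment —
and the Moran computation restricts itself to included channels
(recomputing N, the mean and the weight sums on that subset). A
`min_count` reliability floor (default 1) is configurable. The CPD is
the empirical CDF of those latencies per channel on a fixed 0–100 ms grid
with 5 ms steps.

## Spatial statistics

Moran's I with inverse-distance weights cut off at 15 mm (rook and
diagonal neighbors on a 10 mm grid; 1.5 cm ≡ 15 mm internally — the mm is
the single internal distance unit). Coincident electrodes are an error
(1/d undefined) rather than an infinite weight. I is invariant to affine
transforms of the field and to uniform weight scaling (property-tested);
its permutation-null expectation is −1/(N−1), checked by a seeded
permutation routine that reports the null mean, SD and upper-tail
empirical p with the (1 + hits)/(n_perm + 1) convention.

Group comparisons use the two-sided Wilcoxon rank-sum test. For groups of
at most 10 the p-value is computed by exact enumeration of the rank-sum
distribution over all group relabelings using mid-ranks for ties
(dynamic programming over doubled ranks, so tied values are handled
exactly); larger samples use the tie-corrected normal approximation with
continuity correction. With no ties the null distribution is symmetric,
so the symmetric-deviation and doubled-tail two-sided conventions
coincide.

**Cohort-table reproduction.** The packaged 18-patient tables are inputs
with printed (rounded) precision. Derived cells (spike density =
spikes/(electrodes×minutes); sequence frequency = sequences/minutes) are
checked with an error-propagation tolerance — the printed minutes carry
±0.005, so a derived cell may drift by `value·(0.005/minutes)` beyond
half its own printed ulp — under which all 36 derived cells reproduce.
Group means of 9 half-ulp-rounded values carry a ±0.001 propagated bound.
One printed p-value (0.667) sits one ulp from the exact 0.66647,
consistent with a double rounding; the assertion allows one ulp there and
half an ulp for the other eight.

## Synthetic data

The generator emulates the study conditions: traveling wavefronts from
point sources at 0.5–1 mm/ms (10–50 ms latencies between 10 mm
neighbors), Gaussian latency jitter, Bernoulli detection misses, per-
channel Poisson background, and artifact bursts placing all their events
in a single 5 ms frame across ≥30% of channels — the signature the
cleaning stage must catch. Quantization to 5 ms is applied *last* so ties
arise naturally. Default rates (2 discharges/min, 1 background
spike/min/channel, 2 bursts/h over 10 min) sit inside the per-patient
ranges of the reference cohort (0.13–26 sequences/min, 0.38–10.7
spikes/channel/min).

What it does **not** model: waveform morphology, detector bias toward
high-amplitude events, state-dependent (sleep/wake) rate modulation,
3D geometry, or spatially correlated background. Passing recovery tests
therefore demonstrates correctness of the event-level pipeline under the
stated generative model, not detector performance on real EEG.

Scoring is exact event-id bookkeeping: a planted discharge counts as
recovered when ≥80% of its emitted events land in a single extracted
sequence; precision is the planted fraction of all events inside
extracted sequences; artifact leakage counts artifact-labeled events
inside the kept set.

## Problem sizes and determinism

Test and acceptance runs use an 8×8 grid with 4–10 minute simulated
recordings, 50-replicate sweeps for the stochastic rates, 10,000
permutations for null calibration, and 1,000 random small streams for the
chaining-oracle check. All randomness flows from explicit seeds; the
pipeline derives per-stage seeds (sampling, k-means, permutations) from
one root seed via `numpy.random.SeedSequence.spawn`, and reruns with the
same configuration are byte-identical. On a noise-free single-source
simulation the spike-frequency map is a recruited-region indicator and is
itself strongly spatially organized, so no ordering between the
frequency-map and latency-map Moran Indices should be expected there; the
discriminative value of the latency map is a cohort-level, not
single-recording, statement.
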