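"""Outlier-sequence elimination via pairwise trajectory similarity.

False-positive detections during EEG artifact (motor movement, ambient
electrical noise) masquerade as propagating sequences but share little
spatiotemporal structure with the genuine discharges of a recording.  To
remove them without manual review, every sequence is compared with every
other: each trajectory is a set of (x, y, latency-from-leader) points, and
for a (reference, test) pair each reference point scores
``sim_point = 1 - d_match / ss_thresh`` against the spatially nearest test
point lying within ``ss_thresh`` (15 mm) and ``tt_thresh`` (15 ms), or 0
when no such match exists.  The mean over reference points is the
similarity score in [0, 1]; collected over all ordered pairs it forms the
non-symmetric sequence-by-sequence matrix S.

Sequences are then ranked by degree centrality in S (in- plus
out-similarity by default), split into Low / Mid / High degree classes by
1-D k-means with a fixed k = 3, and the Low-Degree class — trajectories
overlapping almost nothing else — is discarded as suspected artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .exceptions import ValidationError
from .geometry import ElectrodeMap
from .sequences import SpikeSequence

LABELS = ("Low", "Mid", "High")


@dataclass(frozen=True)
class CleaningConfig:
    ss_thresh_mm: float = 15.0
    tt_thresh_ms: float = 15.0
    k: int = 3
    seed: int = 0
    restarts: int = 10
    #: "both" = row + column sums of S (in- plus out-similarity);
    #: "row" = out-similarity only
    degree_mode: str = "both"
    #: below this many sequences (or with <3 distinct degrees) cleaning is
    #: skipped: k-means on a handful of points is meaningless
    min_sequences: int = 10

    def __post_init__(self):
        if self.ss_thresh_mm <= 0 or self.tt_thresh_ms <= 0:
            raise ValidationError("similarity thresholds must be positive")
        if self.k != 3:
            raise ValidationError("degree classification uses a fixed k = 3")
        if self.degree_mode not in ("both", "row"):
            raise ValidationError("degree_mode must be 'both' or 'row'")


def _directed_sim(rp: np.ndarray, tp: np.ndarray, cfg: CleaningConfig) -> float:
    """Mean per-point score of test points ``tp`` against reference ``rp``."""
    d = cdist(rp[:, :2], tp[:, :2])
    dt = np.abs(rp[:, 2:3] - tp[:, 2:3].T)
    ok = (d <= cfg.ss_thresh_mm) & (dt <= cfg.tt_thresh_ms)
    d_masked = np.where(ok, d, np.inf)
    d_match = d_masked.min(axis=1)
    sim = np.where(np.isfinite(d_match), 1.0 - d_match / cfg.ss_thresh_mm, 0.0)
    return float(sim.mean())


def sequence_similarity(ref: SpikeSequence, test: SpikeSequence,
                        cfg: CleaningConfig, emap: ElectrodeMap) -> float:
    """Directed similarity of ``test`` to ``ref`` (see module docs); in [0, 1]."""
    if len(ref) == 0 or len(test) == 0:
        raise ValidationError("cannot compare empty sequences")
    return _directed_sim(ref.as_points(emap), test.as_points(emap), cfg)


@dataclass(frozen=True)
class SimilarityMatrix:
    """S[i, j] = similarity of sequence j (test) to sequence i (reference)."""

    S: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S, float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValidationError("S must be square")
        if (S < -1e-12).any() or (S > 1 + 1e-12).any():
            raise ValidationError("similarity scores must lie in [0, 1]")
        object.__setattr__(self, "S", S)

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def degrees(self, mode: str = "both") -> np.ndarray:
        diag = np.diag(self.S)
        if mode == "row":
            return self.S.sum(axis=1) - diag
        return self.S.sum(axis=1) + self.S.sum(axis=0) - 2 * diag


def similarity_matrix(seqs: list[SpikeSequence], cfg: CleaningConfig,
                      emap: ElectrodeMap) -> SimilarityMatrix:
    """All ordered pairwise similarities (diagonal is identically 1)."""
    if len(seqs) < 2:
        raise ValidationError("need at least 2 sequences for a similarity matrix")
    pts = [s.as_points(emap) for s in seqs]
    m = len(seqs)
    S = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            S[i, j] = 1.0 if i == j else _directed_sim(pts[i], pts[j], cfg)
    return SimilarityMatrix(S)


@dataclass(frozen=True)
class DegreeClassification:
    degree: np.ndarray
    labels: np.ndarray  # "Low" | "Mid" | "High" per sequence
    kept: np.ndarray  # boolean mask, kept = (label != "Low")
    skipped: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "seq_id": np.arange(len(self.degree)),
            "degree": self.degree,
            "label": self.labels,
            "kept": self.kept,
        })


def classify_and_clean(seqs: list[SpikeSequence], sim: SimilarityMatrix,
                       cfg: CleaningConfig) -> tuple[list[SpikeSequence], DegreeClassification]:
    """Split degrees into Low/Mid/High by seeded k-means and drop Low.

    Clusters are relabeled by ascending centroid so "Low" is well defined.
    With fewer than ``min_sequences`` sequences or fewer than 3 distinct
    degree values the step is skipped (all sequences kept, with a warning).
    """
    if sim.n != len(seqs):
        raise ValidationError("similarity matrix does not match sequence list")
    deg = sim.degrees(cfg.degree_mode)
    if len(seqs) < cfg.min_sequences or np.unique(deg).size < 3:
        warnings.warn("too few sequences or degenerate degrees; cleaning skipped",
                      stacklevel=2)
        cls = DegreeClassification(deg, np.array(["Mid"] * len(seqs)),
                                   np.ones(len(seqs), bool), skipped=True)
        return list(seqs), cls
    km = KMeans(n_clusters=cfg.k, n_init=cfg.restarts, random_state=cfg.seed)
    raw_labels = km.fit_predict(deg.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())  # ascending centroid
    rank_of = np.empty(cfg.k, int)
    rank_of[order] = np.arange(cfg.k)
    labels = np.array([LABELS[rank_of[l]] for l in raw_labels])
    kept = labels != "Low"
    return [s for s, keep in zip(seqs, kept) if keep], DegreeClassification(deg, labels, kept)
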