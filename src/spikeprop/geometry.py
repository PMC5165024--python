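"""Electrode-array geometry: coordinates, distances, spatial weights, partitions.

Subdural grids and strips are represented as a flat table of channels with
2D Cartesian coordinates in millimetres (standard 10 mm inter-electrode
pitch).  All spatial rules downstream — inverse-distance weights for the
Moran Index, the 1.5 cm adjacency radius, spatially contiguous partitions
of 4–8 neighboring electrodes — are derived from these coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .exceptions import FormatError, ValidationError

#: Adjacency radius in mm: electrodes within this distance (rook or diagonal
#: neighbors on a 10 mm grid) count as immediately adjacent.
ADJACENCY_RADIUS_MM = 15.0

REQUIRED_MAP_COLUMNS = ("channel_id", "label", "x_mm", "y_mm")


@dataclass(frozen=True)
class ElectrodeMap:
    """Channel ids with 2D coordinates (mm) and optional partition labels.

    Parameters
    ----------
    table:
        DataFrame with columns ``channel_id`` (unique integers >= 1),
        ``label`` (free text), ``x_mm``, ``y_mm`` (finite floats) and
        optionally ``partition`` (manual partition labels).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in REQUIRED_MAP_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"electrode map missing columns: {missing}")
        if len(t) < 2:
            raise ValidationError("electrode map needs at least 2 channels")
        if t["channel_id"].duplicated().any():
            dups = sorted(t.loc[t["channel_id"].duplicated(), "channel_id"].unique())
            raise ValidationError(f"duplicate channel ids: {dups}")
        coords = t[["x_mm", "y_mm"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite electrode coordinates")
        if (t["channel_id"] < 1).any():
            raise ValidationError("channel ids must be >= 1")
        t = t.reset_index(drop=True)
        t["channel_id"] = t["channel_id"].astype(int)
        object.__setattr__(self, "table", t)

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def channel_ids(self) -> np.ndarray:
        return self.table["channel_id"].to_numpy()

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 2) array of x/y in mm, row order matching :attr:`channel_ids`."""
        return self.table[["x_mm", "y_mm"]].to_numpy(float)

    @property
    def has_partitions(self) -> bool:
        return "partition" in self.table.columns and self.table["partition"].notna().all()

    def index_of(self, channel_ids) -> np.ndarray:
        """Row positions of the given channel ids (raises on unknown ids)."""
        lookup = pd.Series(np.arange(self.n_channels), index=self.table["channel_id"])
        ids = np.atleast_1d(np.asarray(channel_ids))
        unknown = ids[~np.isin(ids, lookup.index)]
        if unknown.size:
            raise ValidationError(f"unknown channel ids: {sorted(set(unknown.tolist()))}")
        return lookup.loc[ids].to_numpy()

    def positions(self, channel_ids) -> np.ndarray:
        return self.coordinates[self.index_of(channel_ids)]

    def pairwise_distances(self) -> np.ndarray:
        """(N, N) Euclidean distance matrix in channel-id row order."""
        return squareform(pdist(self.coordinates))

    @classmethod
    def from_grid(cls, rows: int, cols: int, pitch_mm: float = 10.0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> "ElectrodeMap":
        """Regular ``rows x cols`` grid at the given pitch, ids 1..rows*cols.

        Channel k (0-based) sits at column ``k % cols``, row ``k // cols`` —
        the usual left-to-right, top-to-bottom grid numbering.
        """
        ids = np.arange(1, rows * cols + 1)
        x = origin[0] + (ids - 1) % cols * pitch_mm
        y = origin[1] + (ids - 1) // cols * pitch_mm
        return cls(pd.DataFrame({
            "channel_id": ids,
            "label": [f"G{int(i):02d}" for i in ids],
            "x_mm": x.astype(float),
            "y_mm": y.astype(float),
        }))


def load_electrode_map(path) -> ElectrodeMap:
    """Read an electrode map CSV (``channel_id,label,x_mm,y_mm[,partition]``)."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot parse electrode map {path}: {exc}") from exc
    missing = [c for c in REQUIRED_MAP_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"electrode map {path} missing columns: {missing}")
    return ElectrodeMap(table)


@dataclass(frozen=True)
class SpatialWeights:
    """Inverse-distance spatial weights with a hard cutoff radius.

    ``matrix[i, j] = 1 / d_ij`` when ``0 < d_ij <= radius_mm``, else 0;
    the diagonal is 0.  Row order matches ``channel_ids``.
    """

    channel_ids: np.ndarray
    matrix: np.ndarray
    radius_mm: float

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.channel_ids),) * 2:
            raise ValidationError("weight matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValidationError("weights must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("weight diagonal must be zero")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "channel_ids", np.asarray(self.channel_ids, int))

    def subset(self, channel_ids) -> "SpatialWeights":
        """Restrict to the given channels (order preserved as given)."""
        ids = np.asarray(channel_ids, int)
        pos = pd.Series(np.arange(len(self.channel_ids)), index=self.channel_ids)
        unknown = ids[~np.isin(ids, pos.index)]
        if unknown.size:
            raise ValidationError(f"channels not in weights: {sorted(set(unknown.tolist()))}")
        idx = pos.loc[ids].to_numpy()
        return SpatialWeights(ids, self.matrix[np.ix_(idx, idx)], self.radius_mm)


def spatial_weights(emap: ElectrodeMap, radius_mm: float = ADJACENCY_RADIUS_MM) -> SpatialWeights:
    """Build inverse-distance weights ``w_ij = 1/d_ij`` for ``d_ij <= radius_mm``.

    On a 10 mm grid the default 15 mm radius admits both rook neighbors
    (d = 10, w = 0.1) and diagonal neighbors (d = 10*sqrt(2), w ~ 0.0707).
    Coincident electrodes are rejected: 1/d is undefined at d = 0.
    """
    if radius_mm <= 0:
        raise ValidationError("radius_mm must be positive")
    d = emap.pairwise_distances()
    off = ~np.eye(emap.n_channels, dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValidationError(
            f"coincident electrodes {emap.channel_ids[i]} and {emap.channel_ids[j]}")
    w = np.zeros_like(d)
    inside = off & (d <= radius_mm)
    w[inside] = 1.0 / d[inside]
    return SpatialWeights(emap.channel_ids, w, radius_mm)


@dataclass(frozen=True)
class Partitioning:
    """Assignment of every channel to one spatially contiguous partition.

    ``adjacency`` holds unordered pairs of distinct partition ids whose
    member channels come within :data:`ADJACENCY_RADIUS_MM` of each other.
    """

    assignment: dict  # channel_id -> partition_id
    adjacency: frozenset  # of frozenset({p, q}) pairs, p != q

    def __post_init__(self):
        for pair in self.adjacency:
            if len(pair) != 2:
                raise ValidationError("adjacency pairs must join two distinct partitions")
        object.__setattr__(self, "adjacency", frozenset(frozenset(p) for p in self.adjacency))

    @property
    def partition_ids(self) -> list:
        return sorted(set(self.assignment.values()))

    def sizes(self) -> dict:
        out: dict = {}
        for p in self.assignment.values():
            out[p] = out.get(p, 0) + 1
        return out

    def partition_of(self, channel_id: int):
        return self.assignment[channel_id]

    def same_or_adjacent(self, channel_a: int, channel_b: int) -> bool:
        pa, pb = self.assignment[channel_a], self.assignment[channel_b]
        return pa == pb or frozenset((pa, pb)) in self.adjacency


def _partition_adjacency(emap: ElectrodeMap, assignment: dict,
                         radius_mm: float = ADJACENCY_RADIUS_MM) -> frozenset:
    ids = emap.channel_ids
    parts = np.array([assignment[c] for c in ids], dtype=object)
    d = emap.pairwise_distances()
    pairs = set()
    close = np.argwhere((d > 0) & (d <= radius_mm))
    for i, j in close:
        if parts[i] != parts[j]:
            pairs.add(frozenset((parts[i], parts[j])))
    return frozenset(pairs)


def partition_from_labels(emap: ElectrodeMap, adjacency_path=None) -> Partitioning:
    """Partitioning from the map's manual ``partition`` column.

    Adjacency is computed from the 15 mm rule unless an explicit JSON list
    of pairs (``[["A","B"], ...]``) is supplied.
    """
    if "partition" not in emap.table.columns:
        raise ValidationError("electrode map has no partition column")
    if emap.table["partition"].isna().any():
        raise ValidationError("partition column has missing values")
    assignment = dict(zip(emap.table["channel_id"], emap.table["partition"]))
    if adjacency_path is not None:
        pairs = json.loads(Path(adjacency_path).read_text())
        adjacency = frozenset(frozenset(p) for p in pairs)
        known = set(assignment.values())
        for pair in adjacency:
            if not pair <= known:
                raise ValidationError(f"adjacency references unknown partition: {set(pair)}")
    else:
        adjacency = _partition_adjacency(emap, assignment)
    return Partitioning(assignment, adjacency)


def auto_partition(emap: ElectrodeMap, target_size: tuple[int, int] = (4, 8),
                   seed: int = 0) -> Partitioning:
    """Tile the array into spatially contiguous partitions of ~4-8 electrodes.

    The array is first split into connected components under the 15 mm
    adjacency radius (separate grids/strips never share a partition).  Each
    component's bounding lattice is tiled with 2x2 blocks; undersized tiles
    are merged into their nearest neighboring tile within the component,
    preferring merges that stay within the size band.  The procedure is
    deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic stages.

    Disconnected arrays are handled per component (with a warning when a
    component is smaller than the lower size bound).
    """
    lo, hi = target_size
    if not (1 <= lo <= hi):
        raise ValidationError("invalid target_size band")
    del seed  # deterministic tie-breaks; kept for a stable call signature
    d = emap.pairwise_distances()
    adj = (d > 0) & (d <= ADJACENCY_RADIUS_MM)
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"electrode array splits into {n_comp} components at "
            f"{ADJACENCY_RADIUS_MM} mm; partitioning each separately",
            stacklevel=2)

    ids = emap.channel_ids
    coords = emap.coordinates
    assignment: dict = {}
    next_pid = 0
    for c in range(n_comp):
        members = np.where(comp == c)[0]
        if len(members) < lo:
            warnings.warn(f"component of {len(members)} channel(s) below "
                          f"partition size band", stacklevel=2)
        xy = coords[members]
        # snap to the component's lattice using its nearest-neighbor pitch
        if len(members) > 1:
            dd = d[np.ix_(members, members)]
            pitch = dd[dd > 0].min()
        else:
            pitch = 10.0
        ix = np.round((xy[:, 0] - xy[:, 0].min()) / pitch).astype(int)
        iy = np.round((xy[:, 1] - xy[:, 1].min()) / pitch).astype(int)
        tiles: dict = {}
        for k, m in enumerate(members):
            tiles.setdefault((ix[k] // 2, iy[k] // 2), []).append(m)

        # merge undersized tiles into their nearest tile (by centroid),
        # preferring merges that keep the result within the band
        def centroid(rows):
            return coords[rows].mean(axis=0)

        changed = True
        while changed and len(tiles) > 1:
            changed = False
            for key in sorted(tiles):
                if len(tiles[key]) >= lo:
                    continue
                others = [k for k in sorted(tiles) if k != key]
                c0 = centroid(tiles[key])
                others.sort(key=lambda k: (
                    len(tiles[key]) + len(tiles[k]) > hi,  # prefer in-band result
                    float(np.linalg.norm(centroid(tiles[k]) - c0)),
                    k,
                ))
                target = others[0]
                tiles[target] = tiles[target] + tiles[key]
                del tiles[key]
                changed = True
                break

        for key in sorted(tiles):
            pid = f"P{next_pid:02d}"
            next_pid += 1
            for m in tiles[key]:
                assignment[int(ids[m])] = pid

    return Partitioning(assignment, _partition_adjacency(emap, assignment))
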