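"""Uniform angle index: nearest-neighbour regularity of a stem map.

For each reference tree the four nearest neighbours are found and the four
circular gaps between their azimuth-sorted directions computed.  The
per-tree index W_i is the fraction of those gaps smaller than the standard
angle alpha0 = 72 deg (360/5), so W_i takes values {0, 0.25, 0.5, 0.75, 1}.
The stand mean W-bar classifies the spatial pattern: below 0.475 regular,
above 0.517 clumped, in between random.

Edge correction uses a buffer strip: only trees inside the reduced window
(the plot inset by the buffer width) serve as reference trees, while buffer
trees still count as neighbours, so no reference has a censored
neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .stemmap import PlotGeometry, Stage, StemMap

#: Standard angle (degrees): a fifth of the circle.
DEFAULT_ALPHA0 = 72.0

#: W-bar band of a random (Poisson) pattern; below = regular, above = clumped.
RANDOM_BOUNDS = (0.475, 0.517)

DEFAULT_K = 4

Pattern = Literal["regular", "random", "clumped"]


@dataclass(frozen=True)
class UniformAngleResult:
    per_tree: dict  # reference tree_id -> W_i
    mean_w: float
    n_reference: int
    classification: Pattern


def reduced_window(geometry: PlotGeometry) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) of the plot inset by the buffer width on all sides."""
    b = geometry.buffer_width
    return (b, b, geometry.width - b, geometry.height - b)


def azimuths(reference: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Compass bearings (degrees in [0, 360)) from a reference point to each
    neighbour; 0 = north (+y), 90 = east (+x)."""
    d = np.atleast_2d(neighbors) - np.asarray(reference)
    return np.degrees(np.arctan2(d[:, 0], d[:, 1])) % 360.0


def adjacent_gaps(az: Sequence[float]) -> np.ndarray:
    """Circular gaps between azimuth-sorted directions (degrees, sum 360)."""
    a = np.sort(np.asarray(az, dtype=float) % 360.0)
    return np.diff(np.append(a, a[0] + 360.0))


def w_index(gaps: Sequence[float], alpha0: float = DEFAULT_ALPHA0) -> float:
    """Fraction of the gaps strictly smaller than the standard angle."""
    g = np.asarray(gaps, dtype=float)
    return float(np.mean(g < alpha0))


def classify_mean_w(
    mean_w: float, bounds: tuple[float, float] = RANDOM_BOUNDS
) -> Pattern:
    lo, hi = bounds
    if mean_w < lo:
        return "regular"
    if mean_w > hi:
        return "clumped"
    return "random"


def _check_coincident(coords: np.ndarray, ids: Sequence) -> None:
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    same = np.all(coords[order[1:]] == coords[order[:-1]], axis=1)
    if same.any():
        i = int(np.flatnonzero(same)[0])
        a, b = ids[order[i]], ids[order[i + 1]]
        raise ValueError(f"coincident coordinates for trees {a!r} and {b!r}")


def neighbor_indices(
    coords: np.ndarray,
    ref_idx: np.ndarray,
    candidate_idx: np.ndarray,
    k: int = DEFAULT_K,
) -> np.ndarray:
    """Indices (into ``coords``) of the k nearest candidates to each reference.

    Distance ties are broken by candidate position in ``candidate_idx``,
    which callers pre-sort by tree id, so the result is deterministic.
    A reference also present among the candidates never counts as its own
    neighbour.
    """
    if len(candidate_idx) < k + 1:
        raise ValueError(
            f"need at least {k + 1} trees to find {k} neighbours, "
            f"got {len(candidate_idx)}"
        )
    dist = cdist(coords[ref_idx], coords[candidate_idx])
    # mask self-pairs (same index in the full array)
    self_mask = ref_idx[:, None] == candidate_idx[None, :]
    dist[self_mask] = np.inf
    # stable sort keeps candidate (id) order among exact distance ties
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return candidate_idx[nearest]


def four_nearest(
    reference_id,
    stemmap: StemMap,
    k: int = DEFAULT_K,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates and ids of the k nearest neighbours of one tree.

    Neighbours are drawn from the whole stem map (reduced window plus
    buffer).  Returns (neighbor_coords, neighbor_ids) ordered nearest-first.
    """
    df = stemmap.trees.reset_index(drop=True)
    coords = df[["x", "y"]].to_numpy(float)
    ids = df["tree_id"].to_numpy()
    _check_coincident(coords, ids)
    matches = np.flatnonzero(ids == reference_id)
    if len(matches) != 1:
        raise KeyError(f"tree {reference_id!r} not found")
    order = np.argsort(ids, kind="stable")  # id-sorted candidates for tie-break
    nn = neighbor_indices(coords, matches, order, k=k)[0]
    return coords[nn], ids[nn]


def w_values(
    coords: np.ndarray,
    ref_idx: np.ndarray,
    candidate_idx: np.ndarray,
    k: int = DEFAULT_K,
    alpha0: float = DEFAULT_ALPHA0,
) -> np.ndarray:
    """W_i for each reference point, vectorised over the whole stand."""
    nn = neighbor_indices(coords, ref_idx, candidate_idx, k=k)
    d = coords[nn] - coords[ref_idx][:, None, :]  # (n_ref, k, 2)
    az = np.degrees(np.arctan2(d[..., 0], d[..., 1])) % 360.0
    az.sort(axis=1)
    gaps = np.diff(np.concatenate([az, az[:, :1] + 360.0], axis=1), axis=1)
    return (gaps < alpha0).mean(axis=1)


def mean_uniform_angle(
    stemmap: StemMap,
    species: str | None = None,
    stage: Stage | None = None,
    conspecific_neighbors: bool = False,
    k: int = DEFAULT_K,
    alpha0: float = DEFAULT_ALPHA0,
    bounds: tuple[float, float] = RANDOM_BOUNDS,
) -> UniformAngleResult:
    """Stand (or subset) mean uniform angle index with buffer edge correction.

    Reference trees are those of the requested species/stage lying inside
    the reduced window.  Neighbours are by default drawn from *all* trees —
    the index then describes the stand structure around each population;
    ``conspecific_neighbors=True`` restricts neighbours to the same subset
    instead, describing the subset's own pattern.
    """
    df = stemmap.trees.reset_index(drop=True)
    coords = df[["x", "y"]].to_numpy(float)
    ids = df["tree_id"].to_numpy()
    _check_coincident(coords, ids)

    sub = np.ones(len(df), dtype=bool)
    if species is not None:
        sub &= (df["species"] == species).to_numpy()
    if stage is not None:
        sub &= (df["stage"] == stage).to_numpy()

    x0, y0, x1, y1 = reduced_window(stemmap.geometry)
    in_window = (
        (coords[:, 0] >= x0)
        & (coords[:, 0] <= x1)
        & (coords[:, 1] >= y0)
        & (coords[:, 1] <= y1)
    )
    ref_idx = np.flatnonzero(sub & in_window)
    if len(ref_idx) == 0:
        raise ValueError(
            "no reference trees in the reduced window for "
            f"species={species!r}, stage={stage!r}"
        )
    cand_mask = sub if conspecific_neighbors else np.ones(len(df), dtype=bool)
    cand_idx = np.flatnonzero(cand_mask)
    cand_idx = cand_idx[np.argsort(ids[cand_idx], kind="stable")]

    w = w_values(coords, ref_idx, cand_idx, k=k, alpha0=alpha0)
    mean_w = float(w.mean())
    return UniformAngleResult(
        per_tree=dict(zip(ids[ref_idx], w)),
        mean_w=mean_w,
        n_reference=len(ref_idx),
        classification=classify_mean_w(mean_w, bounds),
    )


def mean_uniform_angle_points(
    points: np.ndarray,
    geometry: PlotGeometry,
    k: int = DEFAULT_K,
    alpha0: float = DEFAULT_ALPHA0,
    bounds: tuple[float, float] = RANDOM_BOUNDS,
) -> UniformAngleResult:
    """Uniform angle index of a bare point set (no species/DBH marks).

    Convenience entry for simulated point patterns: references are the
    points in the reduced window, neighbours all points.
    """
    coords = np.asarray(points, dtype=float)
    ids = np.arange(len(coords))
    _check_coincident(coords, ids)
    x0, y0, x1, y1 = reduced_window(geometry)
    ref_idx = np.flatnonzero(
        (coords[:, 0] >= x0)
        & (coords[:, 0] <= x1)
        & (coords[:, 1] >= y0)
        & (coords[:, 1] <= y1)
    )
    if len(ref_idx) == 0:
        raise ValueError("no points in the reduced window")
    w = w_values(coords, ref_idx, ids, k=k, alpha0=alpha0)
    mean_w = float(w.mean())
    return UniformAngleResult(
        per_tree=dict(zip(ref_idx, w)),
        mean_w=mean_w,
        n_reference=len(ref_idx),
        classification=classify_mean_w(mean_w, bounds),
    )
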