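"""Sulcal width: median bridge distance across the boundary edge loop.

Every vertex of the loop encircling a sulcus lies mid-way between the crowns
of the adjacent gyri and the sulcal fundus.  For each loop vertex the nearest
loop vertex *not neighboring in the loop* is found in 3-D; a straight line
between the two bridges across the sulcus.  Because that nearest vertex is
not necessarily the closest point of the opposite wall, an exhaustive walk of
up to ``walk_steps`` loop positions (default 4) around it refines the match.
The sulcal width is the median of the refined bridge distances.

"Not neighboring in the loop" is formalized as a cyclic exclusion window:
candidates within ``exclusion_window`` loop positions of the source vertex
are excluded.  The default (5 positions) suits typical FreeSurfer meshes;
recovery studies on regular synthetic meshes should set it so the excluded
arc length exceeds the largest plausible width (see docs).  Distances are
straight-line Euclidean in mm; no projection is applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .freesurfer_io import SurfaceMesh
from .sulcus_mesh import EdgeLoop, SulcusRegion

#: Failure string when the loop is too short to bridge.
LOOP_TOO_SHORT = "loop-too-short"


@dataclasses.dataclass
class WidthOptions:
    """Tunables of the bridge search.

    walk_steps:
        cyclic steps explored on either side of the initial nearest vertex
        (0 disables refinement).
    exclusion_window:
        loop positions on either side of the source vertex excluded from its
        nearest-vertex search.
    min_loop_size:
        shortest loop worth estimating; defaults to ``2*exclusion_window + 2``
        (the smallest loop with any admissible candidate).
    """

    walk_steps: int = 4
    exclusion_window: int = 5
    min_loop_size: int | None = None

    def __post_init__(self):
        if self.walk_steps < 0:
            raise ValueError("walk_steps must be >= 0")
        if self.exclusion_window < 1:
            raise ValueError("exclusion_window must be >= 1")
        if self.min_loop_size is None:
            self.min_loop_size = 2 * self.exclusion_window + 2


@dataclasses.dataclass
class Bridge:
    """One source->matched pair of loop vertices and their distance in mm."""

    source_position: int
    source_vertex: int
    matched_position: int
    matched_vertex: int
    distance: float


@dataclasses.dataclass
class WidthResult:
    """Median width in mm plus the full bridge set (for QC), or a failure."""

    width: float | None
    bridges: list[Bridge]
    failure: str | None = None

    def __bool__(self) -> bool:
        return self.failure is None


def cyclic_distance(i, j, n: int):
    """Cyclic distance between loop positions i and j on a loop of length n."""
    a = np.abs(np.asarray(i) - np.asarray(j)) % n
    return np.minimum(a, n - a)


def loop_coordinates(mesh: SurfaceMesh, loop: EdgeLoop) -> np.ndarray:
    """Coordinates of the loop vertices in loop order, shape (len(loop), 3)."""
    return mesh.vertices[loop.vertices]


def _pick(dists, cyc, vids, candidates) -> int:
    """Deterministic argmin over ``candidates``: smallest distance, ties broken
    toward smaller cyclic loop-distance, then smaller vertex id."""
    d = dists[candidates]
    best = candidates[d == d.min()]
    if len(best) > 1:
        c = cyc[best]
        best = best[c == c.min()]
        if len(best) > 1:
            v = vids[best]
            best = best[v == v.min()]
    return int(best[0])


def nearest_opposite_vertex(
    loop: EdgeLoop, coords: np.ndarray, i: int, opts: WidthOptions
) -> int | None:
    """Loop position nearest to position ``i`` outside the exclusion window.

    Returns ``None`` when the window leaves no candidates (loop too short).
    """
    n = len(loop)
    cyc = cyclic_distance(np.arange(n), i, n)
    candidates = np.flatnonzero(cyc > opts.exclusion_window)
    if len(candidates) == 0:
        return None
    dists = np.linalg.norm(coords - coords[i], axis=1)
    return _pick(dists, cyc, loop.vertices, candidates)


def walk_refine(
    loop: EdgeLoop, coords: np.ndarray, i: int, j0: int, opts: WidthOptions
) -> tuple[int, float]:
    """Exhaustively evaluate loop positions within ``walk_steps`` of ``j0``.

    Both directions are explored, still respecting the exclusion window
    around ``i``; returns the minimizing position and its distance in mm.
    With ``walk_steps=0`` this is the identity on ``j0``.
    """
    n = len(loop)
    window = (j0 + np.arange(-opts.walk_steps, opts.walk_steps + 1)) % n
    cyc = cyclic_distance(window, i, n)
    keep = window[cyc > opts.exclusion_window]
    candidates = np.unique(keep)
    dists = np.linalg.norm(coords - coords[i], axis=1)
    cyc_all = cyclic_distance(np.arange(n), i, n)
    j = _pick(dists, cyc_all, loop.vertices, candidates)
    return j, float(dists[j])


def compute_width(
    region: SulcusRegion, loop: EdgeLoop, opts: WidthOptions | None = None
) -> WidthResult:
    """Median bridge distance across the sulcus, in mm.

    Every loop vertex contributes a bridge (robustness is delegated to the
    median); an even bridge count takes the midpoint of the central pair.
    A loop shorter than ``min_loop_size`` yields a failed result, not an
    exception.
    """
    opts = opts or WidthOptions()
    n = len(loop)
    if n < opts.min_loop_size:
        return WidthResult(
            None, [], failure=LOOP_TOO_SHORT + f" ({n} < {opts.min_loop_size})"
        )
    coords = loop_coordinates(region.parent, loop)
    bridges: list[Bridge] = []
    for i in range(n):
        j0 = nearest_opposite_vertex(loop, coords, i, opts)
        if j0 is None:
            return WidthResult(None, [], failure=LOOP_TOO_SHORT + " (no candidates)")
        j, dist = walk_refine(loop, coords, i, j0, opts)
        bridges.append(
            Bridge(i, int(loop.vertices[i]), j, int(loop.vertices[j]), dist)
        )
    width = float(np.median([b.distance for b in bridges]))
    return WidthResult(width, bridges)


def bridges_to_table(bridges: list[Bridge]):
    """Bridge set as a pandas DataFrame (QC export)."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(b) for b in bridges])
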