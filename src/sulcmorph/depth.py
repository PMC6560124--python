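"""Sulcal depth: median distance from the fundus to the outer smoothed surface.

The sulcal fundus is taken as the ``n_fundus`` (default 100) vertices of the
sulcus region most extreme in the convexity overlay (``?h.sulc``); for each,
the shortest Euclidean distance to the smoothed enclosing surface
(``?h.pial-outer-smoothed``, produced by the gyrification analysis) is
computed, and the median of those distances is the sulcal depth in mm.
Straight-line distance underestimates the true along-wall depth of curved
sulci, but is robust.

Two distance modes are provided: exact point-to-triangle (default; the outer
surface is coarse, and vertex-only distance overestimates) and
point-to-vertex, retained for comparison.  Both are exhaustive exact
minimizations (no spatial index); point-to-triangle <= point-to-vertex on
every query.

Overlay sign conventions differ across toolchains, so the deep-end selector
is configurable, and the result carries a warning flag when the selected
fundus is *not* farther from the outer surface on average than the rest of
the region — the signature of a silently inverted overlay.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .freesurfer_io import ScalarOverlay, SurfaceMesh
from .sulcus_mesh import SulcusRegion

#: Result flags.
FUNDUS_SHORTFALL = "fundus-shortfall"
SIGN_CONVENTION_SUSPECT = "sign-convention-suspect"
EMPTY_REGION = "empty-region"


@dataclasses.dataclass
class DepthOptions:
    """Tunables of the fundus/depth computation.

    n_fundus:
        number of deepest vertices defining the fundus (default 100).
    fundus_direction:
        which overlay extreme marks the fundus: ``"lowest"`` (default) or
        ``"highest"`` for sign-flipped overlays.
    distance_mode:
        ``"point-to-triangle"`` (default, exact) or ``"point-to-vertex"``.
    """

    n_fundus: int = 100
    fundus_direction: str = "lowest"
    distance_mode: str = "point-to-triangle"

    def __post_init__(self):
        if self.n_fundus < 1:
            raise ValueError("n_fundus must be >= 1")
        if self.fundus_direction not in ("lowest", "highest"):
            raise ValueError("fundus_direction must be 'lowest' or 'highest'")
        if self.distance_mode not in ("point-to-triangle", "point-to-vertex"):
            raise ValueError(
                "distance_mode must be 'point-to-triangle' or 'point-to-vertex'"
            )


@dataclasses.dataclass
class FundusSet:
    """Selected fundus vertices, their overlay values and distances (mm)."""

    vertex_ids: np.ndarray
    overlay_values: np.ndarray
    distances: np.ndarray | None = None
    shortfall: bool = False


@dataclasses.dataclass
class DepthResult:
    """Median fundus distance in mm plus the fundus set, or a failure."""

    depth: float | None
    fundus: FundusSet | None
    failure: str | None = None
    flags: list[str] = dataclasses.field(default_factory=list)

    def __bool__(self) -> bool:
        return self.failure is None


def select_fundus(
    region: SulcusRegion, sulcmap: ScalarOverlay, opts: DepthOptions | None = None
) -> FundusSet:
    """The ``n_fundus`` region vertices most extreme in the overlay.

    Ties at the cutoff are broken toward the smaller vertex id.  A region
    with fewer than ``n_fundus`` vertices uses all of them and is flagged.
    """
    opts = opts or DepthOptions()
    sulcmap.validate(region.parent.n_vertices)
    vids = region.vertex_ids
    vals = sulcmap.values[vids]
    key = vals if opts.fundus_direction == "lowest" else -vals
    order = np.lexsort((vids, key))  # stable: value first, then vertex id
    n = min(opts.n_fundus, len(vids))
    sel = order[:n]
    return FundusSet(
        vertex_ids=vids[sel],
        overlay_values=vals[sel],
        shortfall=len(vids) < opts.n_fundus,
    )


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each query point.

    ``points``: (P, 3); ``tri``: (T, 3, 3).  Returns distances of shape
    (P, T).  Standard barycentric-region case analysis, fully vectorized.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]  # (T, 3)
    ab = b - a
    ac = c - a
    p = points[:, None, :]  # (P, 1, 3)
    ap = p - a  # (P, T, 3)
    d1 = np.einsum("tj,ptj->pt", ab, ap)
    d2 = np.einsum("tj,ptj->pt", ac, ap)
    bp = p - b
    d3 = np.einsum("tj,ptj->pt", ab, bp)
    d4 = np.einsum("tj,ptj->pt", ac, bp)
    cp = p - c
    d5 = np.einsum("tj,ptj->pt", ab, cp)
    d6 = np.einsum("tj,ptj->pt", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    # interior projection (default), then overwrite edge/vertex regions
    closest = a + v_in[..., None] * ab + w_in[..., None] * ac

    on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    closest = np.where(on_bc[..., None], b + w_bc[..., None] * (c - b), closest)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[..., None], a + w_ac[..., None] * ac, closest)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[..., None], a + v_ab[..., None] * ab, closest)
    at_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(at_c[..., None], np.broadcast_to(c, closest.shape), closest)
    at_b = (d3 >= 0) & (d4 <= d3)
    closest = np.where(at_b[..., None], np.broadcast_to(b, closest.shape), closest)
    at_a = (d1 <= 0) & (d2 <= 0)
    closest = np.where(at_a[..., None], np.broadcast_to(a, closest.shape), closest)

    return np.linalg.norm(closest - p, axis=-1)


def points_to_surface_distances(
    points: np.ndarray, outer: SurfaceMesh, opts: DepthOptions | None = None
) -> np.ndarray:
    """Shortest Euclidean distance from each point to the outer surface (mm).

    Exhaustive exact minimization over all faces (or all vertices in
    point-to-vertex mode); query points are chunked to bound memory.
    """
    opts = opts or DepthOptions()
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if opts.distance_mode == "point-to-vertex":
        out = np.empty(len(points))
        for s in range(0, len(points), 1024):
            chunk = points[s : s + 1024]
            d = np.linalg.norm(chunk[:, None, :] - outer.vertices[None], axis=-1)
            out[s : s + 1024] = d.min(axis=1)
        return out
    tri = outer.vertices[outer.faces]  # (T, 3, 3)
    # chunk so P*T stays ~2e6 pairs
    step = max(1, int(2e6 / max(1, len(tri))))
    out = np.empty(len(points))
    for s in range(0, len(points), step):
        out[s : s + step] = _closest_on_triangles(points[s : s + step], tri).min(axis=1)
    return out


def point_to_surface_distance(
    p, outer: SurfaceMesh, opts: DepthOptions | None = None
) -> float:
    """Distance of a single 3-D point to the outer surface, in mm."""
    return float(points_to_surface_distances(np.asarray(p)[None], outer, opts)[0])


def compute_depth(
    region: SulcusRegion,
    sulcmap: ScalarOverlay,
    outer: SurfaceMesh,
    opts: DepthOptions | None = None,
) -> DepthResult:
    """Median distance of the fundus vertices to the outer surface, in mm.

    Flags a shortfall when the region is smaller than ``n_fundus`` and a
    suspect sign convention when the selected fundus is on average *closer*
    to the outer surface than the rest of the region.
    """
    opts = opts or DepthOptions()
    if region.is_empty:
        return DepthResult(None, None, failure=EMPTY_REGION)
    outer.validate()
    fundus = select_fundus(region, sulcmap, opts)
    fundus.distances = points_to_surface_distances(
        region.parent.vertices[fundus.vertex_ids], outer, opts
    )
    flags = []
    if fundus.shortfall:
        flags.append(FUNDUS_SHORTFALL)
    rest = np.setdiff1d(region.vertex_ids, fundus.vertex_ids, assume_unique=True)
    if len(rest):
        # deterministic subsample keeps the sanity check cheap on big regions
        if len(rest) > 256:
            rest = rest[:: max(1, len(rest) // 256)]
        rest_d = points_to_surface_distances(region.parent.vertices[rest], outer, opts)
        if fundus.distances.mean() <= rest_d.mean():
            flags.append(SIGN_CONVENTION_SUSPECT)
    return DepthResult(float(np.median(fundus.distances)), fundus, flags=flags)
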