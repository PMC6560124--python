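"""Isolating a labeled sulcus as a submesh and extracting its boundary edge loop.

The width estimator needs the closed chain of mesh edges separating a sulcus
from its adjacent gyri.  This module isolates the faces of one Destrieux
label, finds the region's boundary edges (edges incident to exactly one
region face), and chains them into a single cyclic edge loop.

Regions that FreeSurfer parcellates as two or more discontinuous patches, or
whose boundary is not a single simple cycle, cannot be encircled by one loop;
for those the extraction returns a :class:`LoopFailure` *value* (the cohort
pipeline must count failures, not crash).
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .errors import UnknownLabelError, ValidationError
from .freesurfer_io import ParcellationAnnotation, SurfaceMesh


@dataclasses.dataclass
class SulcusRegion:
    """The face subset of one labeled sulcus, with mapping back to the parent.

    ``face_ids`` indexes faces of ``parent`` whose three vertices all carry
    the target label; ``local_to_parent`` maps region-local vertex indices to
    parent vertex ids (a bijection onto the vertices used by ``face_ids``).
    """

    parent: SurfaceMesh
    face_ids: np.ndarray
    local_to_parent: np.ndarray
    label_name: str

    @property
    def is_empty(self) -> bool:
        return len(self.face_ids) == 0

    @property
    def n_faces(self) -> int:
        return len(self.face_ids)

    @property
    def vertex_ids(self) -> np.ndarray:
        """Parent vertex ids used by the region's faces."""
        return self.local_to_parent

    @property
    def faces(self) -> np.ndarray:
        """Region faces in parent vertex ids, shape (n_faces, 3)."""
        return self.parent.faces[self.face_ids]


@dataclasses.dataclass
class EdgeLoop:
    """Closed cyclic sequence of parent vertex ids encircling a region."""

    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.vertices)

    def edge_multiset(self) -> Counter:
        """Multiset of consecutive (sorted) vertex pairs, including last->first."""
        v = self.vertices
        nxt = np.roll(v, -1)
        return Counter(
            (int(a), int(b)) if a < b else (int(b), int(a)) for a, b in zip(v, nxt)
        )


#: Machine-readable edge-loop failure reasons.
DISCONTINUOUS_REGION = "discontinuous-region"
MULTIPLE_LOOPS = "multiple-loops"
NON_MANIFOLD_BOUNDARY = "non-manifold-boundary"
EMPTY_REGION = "empty-region"


@dataclasses.dataclass
class LoopFailure:
    """Why a single encircling edge loop could not be extracted."""

    reason: str
    detail: str = ""

    def __bool__(self) -> bool:  # failures are falsy, loops truthy
        return False


def isolate_sulcus(
    mesh: SurfaceMesh, annot: ParcellationAnnotation, label_name: str
) -> SulcusRegion:
    """Isolate the faces of one labeled sulcus as a region submesh.

    A face belongs to the region iff **all three** of its vertices carry the
    target label, so the region boundary lies between labels.  A label that
    exists in the table but covers no face yields an *empty* region (a
    distinct outcome, not an exception); an unknown name raises
    :class:`UnknownLabelError`.
    """
    annot.validate(mesh.n_vertices)
    if label_name not in annot.table:
        raise UnknownLabelError(label_name, annot.table.keys())
    target = annot.table[label_name]
    vertex_in = annot.labels == target
    face_mask = vertex_in[mesh.faces].all(axis=1)
    face_ids = np.flatnonzero(face_mask)
    used = np.unique(mesh.faces[face_ids])
    return SulcusRegion(mesh, face_ids, used, label_name)


def _require_nonempty(region: SulcusRegion) -> None:
    if region.is_empty:
        raise ValidationError(
            f"region for {region.label_name!r} is empty (label absent on surface)"
        )


def boundary_edges(region: SulcusRegion) -> set[tuple[int, int]]:
    """Edges incident to exactly one region face, as sorted parent-id pairs.

    This is the brute-force definition of the region boundary and serves as
    the oracle the loop extraction is tested against.
    """
    _require_nonempty(region)
    counts: Counter = Counter()
    for a, b, c in region.faces:
        for u, v in ((a, b), (b, c), (a, c)):
            counts[(int(u), int(v)) if u < v else (int(v), int(u))] += 1
    return {e for e, n in counts.items() if n == 1}


def connected_components(region: SulcusRegion) -> tuple[int, np.ndarray]:
    """Number of edge-connected face components and a per-face component id.

    Faces are connected iff they share an *edge*; patches touching at a
    single vertex count as separate components.
    """
    _require_nonempty(region)
    edge_faces: dict[tuple[int, int], list[int]] = defaultdict(list)
    for fi, (a, b, c) in enumerate(region.faces):
        for u, v in ((a, b), (b, c), (a, c)):
            edge_faces[(int(u), int(v)) if u < v else (int(v), int(u))].append(fi)
    rows, cols = [], []
    for flist in edge_faces.values():
        for i in range(len(flist)):
            for j in range(i + 1, len(flist)):
                rows.append(flist[i])
                cols.append(flist[j])
    n = region.n_faces
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, face_comp = _cc(adj, directed=False)
    return int(n_comp), face_comp


def get_edge_loop(region: SulcusRegion) -> EdgeLoop | LoopFailure:
    """Chain the region's boundary edges into a single closed loop.

    Starts at the smallest boundary vertex id and follows the unused boundary
    edge at each step, tie-breaking toward the smaller vertex id, so the
    output is deterministic.  Returns a :class:`LoopFailure` when the region
    is discontinuous, when a boundary vertex has more than two incident
    boundary edges (pinch point), or when the boundary forms several loops
    (e.g. an annulus); the same region always yields the same outcome.
    """
    if region.is_empty:
        return LoopFailure(EMPTY_REGION, "label covers no face of the surface")
    n_comp, _ = connected_components(region)
    if n_comp > 1:
        return LoopFailure(
            DISCONTINUOUS_REGION,
            f"label {region.label_name!r} comprises {n_comp} discontinuous regions",
        )
    edges = boundary_edges(region)
    neighbors: dict[int, list[int]] = defaultdict(list)
    for u, v in edges:
        neighbors[u].append(v)
        neighbors[v].append(u)
    bad = [v for v, ns in neighbors.items() if len(ns) != 2]
    if bad:
        return LoopFailure(
            NON_MANIFOLD_BOUNDARY,
            f"{len(bad)} boundary vertices have boundary-degree != 2 "
            f"(first: vertex {min(bad)})",
        )
    start = min(neighbors)
    loop = [start]
    prev, cur = None, start
    while True:
        options = sorted(n for n in neighbors[cur] if n != prev)
        if not options:  # both neighbors equal prev: 2-vertex degenerate cycle
            break
        nxt = options[0]
        if nxt == start:
            break
        loop.append(nxt)
        prev, cur = cur, nxt
    if len(loop) < len(edges):
        return LoopFailure(
            MULTIPLE_LOOPS,
            f"boundary forms more than one loop ({len(loop)} of {len(edges)} "
            "edges chained from the start vertex)",
        )
    return EdgeLoop(np.array(loop, dtype=np.int64))
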