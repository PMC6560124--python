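"""Independent oracles and random-region helpers for the acceptance script.

These mirror the brute-force definitions used by the test suite: the width
oracle enumerates every admissible (source, match) pair in plain Python, and
the random-region generator produces labeled blobs on a grid mesh.
"""

from __future__ import annotations

import numpy as np

from sulcmorph import (
    NO_LABEL,
    ParcellationAnnotation,
    SulcusRegion,
    SurfaceMesh,
    isolate_sulcus,
)
from sulcmorph.sulcus_mesh import EdgeLoop
from sulcmorph.width import WidthOptions


def grid_mesh(n: int, spacing: float = 1.0) -> SurfaceMesh:
    xs = np.arange(n + 1) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    faces = []
    for i in range(n):
        for j in range(n):
            v00, v10 = i * (n + 1) + j, (i + 1) * (n + 1) + j
            v01, v11 = i * (n + 1) + j + 1, (i + 1) * (n + 1) + j + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return SurfaceMesh(vertices, np.asarray(faces))


def random_grid_region(rng: np.random.Generator, n: int = 12):
    mesh = grid_mesh(n)
    xs, ys = mesh.vertices[:, 0], mesh.vertices[:, 1]
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    for _ in range(rng.integers(1, 3)):
        cx, cy = rng.uniform(2, n - 2, 2)
        r = rng.uniform(1.5, n / 2)
        mask |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
    labels = np.where(mask, 1, NO_LABEL)
    annot = ParcellationAnnotation(labels, {"S_central": 1})
    return isolate_sulcus(mesh, annot, "S_central")


def loop_region(coords: np.ndarray):
    mesh = SurfaceMesh(coords, np.array([[0, 1, 2]]))
    region = SulcusRegion(mesh, np.array([0]), np.arange(len(coords)), "S_central")
    return region, EdgeLoop(np.arange(len(coords)))


def _cyc(i: int, j: int, n: int) -> int:
    a = abs(i - j) % n
    return min(a, n - a)


def _bf_pick(coords, vids, i, candidates, n):
    best, best_key = None, None
    for j in candidates:
        d = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
        key = (d, _cyc(i, j, n), int(vids[j]))
        if best_key is None or key < best_key:
            best, best_key = j, key
    return best, best_key[0]


def brute_force_width(coords, vids, opts: WidthOptions):
    n = len(coords)
    if n < opts.min_loop_size:
        return None
    dists = []
    for i in range(n):
        candidates = [j for j in range(n) if _cyc(i, j, n) > opts.exclusion_window]
        if not candidates:
            return None
        j0, _ = _bf_pick(coords, vids, i, candidates, n)
        walk = {
            (j0 + s) % n
            for s in range(-opts.walk_steps, opts.walk_steps + 1)
            if _cyc(i, (j0 + s) % n, n) > opts.exclusion_window
        }
        _, d = _bf_pick(coords, vids, i, sorted(walk), n)
        dists.append(d)
    return float(np.median(dists))
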