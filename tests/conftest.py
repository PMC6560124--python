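"""Shared fixtures and independent oracles for the sulcmorph test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sulcmorph import (
    NO_LABEL,
    ParcellationAnnotation,
    SulcusRegion,
    SurfaceMesh,
    SulcusSpec,
    isolate_sulcus,
)
from sulcmorph.synthetic import build_box_sulcus
from sulcmorph.width import WidthOptions


# ---------------------------------------------------------------------------
# mesh helpers


def grid_mesh(n: int, spacing: float = 1.0) -> SurfaceMesh:
    """A flat (n+1)x(n+1) vertex grid plate at z=0."""
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


def region_from_vertex_mask(mesh: SurfaceMesh, mask: np.ndarray, name="S_central"):
    """Isolate the region of faces whose vertices are all inside ``mask``."""
    labels = np.where(mask, 1, NO_LABEL)
    annot = ParcellationAnnotation(labels, {name: 1})
    return isolate_sulcus(mesh, annot, name)


def random_grid_region(rng: np.random.Generator, n: int = 12):
    """A random labeled blob (sometimes two) on a grid mesh.

    Produces a mix of loopable regions and legitimate failures, for the
    loop-vs-boundary-oracle property.
    """
    mesh = grid_mesh(n)
    xs = mesh.vertices[:, 0]
    ys = mesh.vertices[:, 1]
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    for _ in range(rng.integers(1, 3)):
        cx, cy = rng.uniform(2, n - 2, 2)
        r = rng.uniform(1.5, n / 2)
        mask |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
    return region_from_vertex_mask(mesh, mask)


def loop_region(coords: np.ndarray):
    """Wrap explicit loop coordinates in a minimal region + EdgeLoop pair."""
    from sulcmorph.sulcus_mesh import EdgeLoop

    mesh = SurfaceMesh(coords, np.array([[0, 1, 2]]))
    region = SulcusRegion(mesh, np.array([0]), np.arange(len(coords)), "S_central")
    loop = EdgeLoop(np.arange(len(coords)))
    return region, loop


# ---------------------------------------------------------------------------
# brute-force width oracle (plain python; enumerates all admissible pairs)


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
    """Median bridge distance by exhaustive enumeration of the exclusion
    window + walk definition.  Independent of the vectorized implementation."""
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


# ---------------------------------------------------------------------------
# session-scoped synthetic subjects


@pytest.fixture(scope="session")
def box_subject():
    """One clean in-memory box-canyon subject (width 2, depth 10, h=0.5)."""
    spec = SulcusSpec(
        true_width=2.0, true_depth=10.0, mesh_spacing=0.5, length=50.0, seed=1
    )
    return spec, build_box_sulcus(spec)


@pytest.fixture(scope="session")
def subjects_dir(tmp_path_factory):
    """A subjects directory holding one written box subject."""
    from sulcmorph.synthetic import make_box_sulcus

    root = tmp_path_factory.mktemp("subjects")
    spec = SulcusSpec(
        true_width=2.0, true_depth=10.0, mesh_spacing=0.5, length=50.0, seed=1
    )
    sdir, truth = make_box_sulcus(spec, root, subject="synth01")
    return root, spec, sdir, truth


@pytest.fixture(scope="session")
def failure_fixtures(tmp_path_factory):
    from sulcmorph.synthetic import make_failure_fixtures

    root = tmp_path_factory.mktemp("failures")
    return make_failure_fixtures(root)
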