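"""Synthetic FreeSurfer subjects with analytically known sulcal geometry.

Real cortical surfaces give no ground truth: the true width and depth of a
sulcus are unknown.  This module generates complete fake subjects in
standard FreeSurfer layout (``surf/`` + ``label/``) whose geometry *is*
known: a flat cortical plate with a U-shaped box-canyon fold — two parallel
walls separated by ``true_width`` mm descending ``true_depth`` mm below the
plate, joined by a flat fundus floor.  The fold interior carries a chosen
Destrieux label, the ``?h.sulc`` overlay encodes signed depth, and the
``?h.pial-outer-smoothed`` surface is the plate's plane spanning the fold
mouth.  True width/depth are therefore exact, and every intermediate
quantity (interior faces, boundary loop, deepest vertices) is recorded as
:class:`GroundTruth`.

The fold is embedded in a flat plate rather than a closed brain-like
surface: closed-surface realism adds nothing testable, while the plate keeps
truth analytic.  Optional deviations from the ideal box canyon: wall tilt
(converging walls), fundus curvature (a hook-shaped canyon whose along-wall,
i.e. geodesic, depth exceeds the straight-line depth — the configuration
under which Euclidean depth is a known underestimate), and Gaussian vertex
jitter.  All generation is deterministic given the seed, to the byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import freesurfer_io as fsio
from .errors import ValidationError
from .freesurfer_io import NO_LABEL, ParcellationAnnotation, ScalarOverlay, SurfaceMesh
from .registry import SUPPORTED_SULCI


@dataclasses.dataclass
class SulcusSpec:
    """Geometry of one synthetic box-canyon sulcus (all lengths in mm)."""

    true_width: float = 3.0
    true_depth: float = 10.0
    length: float = 50.0
    mesh_spacing: float = 0.5
    wall_tilt: float = 0.0  # degrees; > 0 -> walls converge with depth
    fundus_curvature: float = 0.0  # 1/mm; > 0 -> hook-shaped canyon
    noise_sd: float = 0.0  # mm vertex jitter
    seed: int = 0
    label_name: str = "S_central"
    hemi: str = "lh"
    plate_margin: float = 5.0
    #: +1: deeper vertices have lower overlay values (the convention the
    #: depth module expects by default); -1: sign-flipped overlay.
    overlay_sign: int = 1

    def validate(self) -> None:
        for field in ("true_width", "true_depth", "length", "mesh_spacing", "plate_margin"):
            if getattr(self, field) <= 0:
                raise ValidationError(f"{field} must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.overlay_sign not in (-1, 1):
            raise ValidationError("overlay_sign must be +1 or -1")
        if not (0 <= self.wall_tilt < 45):
            raise ValidationError("wall_tilt must be in [0, 45) degrees")
        tilt_shift = np.tan(np.radians(self.wall_tilt)) * self.true_depth
        if self.true_width - 2 * tilt_shift <= self.mesh_spacing:
            raise ValidationError("walls meet before reaching true_depth (tilt too large)")
        if self.fundus_curvature * self.true_depth >= np.pi / 2:
            raise ValidationError("fundus_curvature * true_depth must be < pi/2")


@dataclasses.dataclass
class GroundTruth:
    """Exact by-construction answers for one synthetic subject."""

    true_width: float
    true_depth: float  # geodesic (along-wall) depth = wall arc length
    euclidean_fundus_depth: float  # straight-line fundus-to-plate distance
    mesh_spacing: float
    label_name: str
    hemi: str
    interior_face_ids: list[int]
    boundary_vertex_ids: list[int]
    deepest_vertex_ids: list[int]  # the deepest-100 (or fewer) fold vertices
    n_fold_vertices: int

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, sort_keys=True, indent=0)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            return cls(**json.load(f))


def _default_table() -> dict[str, int]:
    return {name: i + 1 for i, name in enumerate(SUPPORTED_SULCI)}


def _fold_profile(spec: SulcusSpec):
    """Cross-section polyline in the x-z plane: (x, z, is_fold) per point."""
    h = spec.mesh_spacing
    W, D, M = spec.true_width, spec.true_depth, spec.plate_margin
    kappa = spec.fundus_curvature
    tilt = np.tan(np.radians(spec.wall_tilt))

    n_wall = max(2, round(D / h))
    s = np.linspace(0.0, D, n_wall + 1)  # arc length from rim, incl. endpoints
    if kappa > 0:
        dx_curv = (1 - np.cos(kappa * s)) / kappa
        z_wall = -np.sin(kappa * s) / kappa
    else:
        dx_curv = np.zeros_like(s)
        z_wall = -s
    x1 = M + dx_curv + tilt * s  # wall 1 (left), converging inward
    x2 = M + W + dx_curv - tilt * s  # wall 2 (right)

    floor_w = x2[-1] - x1[-1]
    n_floor = max(1, round(floor_w / h))
    floor_x = np.linspace(x1[-1], x2[-1], n_floor + 1)[1:-1]

    n_plate = max(2, round(M / h))
    left_x = np.linspace(0.0, M, n_plate + 1)[:-1]
    right_x = np.linspace(M + W, M + W + M, n_plate + 1)[1:]

    xs, zs, fold = [], [], []
    xs += list(left_x); zs += [0.0] * len(left_x); fold += [False] * len(left_x)
    xs += list(x1); zs += list(z_wall); fold += [True] * len(x1)
    xs += list(floor_x); zs += [z_wall[-1]] * len(floor_x); fold += [True] * len(floor_x)
    xs += list(x2[::-1]); zs += list(z_wall[::-1]); fold += [True] * len(x2)
    xs += list(right_x); zs += [0.0] * len(right_x); fold += [False] * len(right_x)
    return np.array(xs), np.array(zs), np.array(fold), float(-z_wall[-1])


def build_box_sulcus(spec: SulcusSpec):
    """Build the meshes/annotation/overlay for one subject, in memory.

    Returns ``(pial, annot, overlay, outer, truth)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h = spec.mesh_spacing
    xs, zs, fold, eucl_depth = _fold_profile(spec)
    n_p = len(xs)
    n_y = max(2, round(spec.length / h)) + 1
    ys = np.linspace(0.0, spec.length, n_y)

    # vertex id = profile index * n_y + row index
    X = np.repeat(xs, n_y)
    Y = np.tile(ys, n_p)
    Z = np.repeat(zs, n_y)
    vertices = np.column_stack([X, Y, Z])
    if spec.noise_sd > 0:
        vertices = vertices + rng.normal(0.0, spec.noise_sd, vertices.shape)

    faces = []
    for i in range(n_p - 1):
        for j in range(n_y - 1):
            v00 = i * n_y + j
            v10 = (i + 1) * n_y + j
            v01 = i * n_y + j + 1
            v11 = (i + 1) * n_y + j + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    faces = np.asarray(faces, dtype=np.int64)
    pial = SurfaceMesh(vertices, faces)

    table = _default_table()
    if spec.label_name not in table:
        table[spec.label_name] = max(table.values()) + 1
    target = table[spec.label_name]
    vertex_fold = np.repeat(fold, n_y)
    labels = np.where(vertex_fold, target, NO_LABEL)
    annot = ParcellationAnnotation(labels, table)

    overlay = ScalarOverlay(spec.overlay_sign * vertices[:, 2])

    # outer smoothed surface: the plate's plane, spanning the fold mouth
    outer = _flat_plate(
        x_extent=(0.0, xs.max()), y_extent=(0.0, spec.length), n=8, z=0.0
    )

    # ground truth, by construction
    fold_idx = np.flatnonzero(fold)
    i0, i1 = fold_idx[0], fold_idx[-1]
    interior = np.flatnonzero(vertex_fold[faces].all(axis=1))
    boundary_vids = sorted(
        {i0 * n_y + j for j in range(n_y)}
        | {i1 * n_y + j for j in range(n_y)}
        | {i * n_y + 0 for i in fold_idx}
        | {i * n_y + (n_y - 1) for i in fold_idx}
    )
    fold_vids = np.flatnonzero(vertex_fold)
    vals = overlay.values[fold_vids]
    key = vals if spec.overlay_sign == 1 else -vals
    order = np.lexsort((fold_vids, key))
    deepest = fold_vids[order[: min(100, len(fold_vids))]]
    truth = GroundTruth(
        true_width=spec.true_width,
        true_depth=spec.true_depth,
        euclidean_fundus_depth=eucl_depth,
        mesh_spacing=h,
        label_name=spec.label_name,
        hemi=spec.hemi,
        interior_face_ids=[int(i) for i in interior],
        boundary_vertex_ids=[int(v) for v in boundary_vids],
        deepest_vertex_ids=[int(v) for v in deepest],
        n_fold_vertices=int(len(fold_vids)),
    )
    return pial, annot, overlay, outer, truth


def _flat_plate(x_extent, y_extent, n: int, z: float = 0.0) -> SurfaceMesh:
    """A coarse flat rectangular plate mesh at height ``z``."""
    xs = np.linspace(*x_extent, n + 1)
    ys = np.linspace(*y_extent, n + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
    faces = []
    for i in range(n):
        for j in range(n):
            v00 = i * (n + 1) + j
            v10 = (i + 1) * (n + 1) + j
            v01 = i * (n + 1) + j + 1
            v11 = (i + 1) * (n + 1) + j + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return SurfaceMesh(vertices, np.asarray(faces, dtype=np.int64))


def write_subject(
    subjects_dir,
    subject: str,
    pial: SurfaceMesh,
    annot: ParcellationAnnotation,
    overlay: ScalarOverlay,
    outer: SurfaceMesh,
    hemi: str = "lh",
    truth: GroundTruth | None = None,
) -> Path:
    """Write a subject in FreeSurfer layout; returns the subject directory."""
    sdir = Path(subjects_dir) / subject
    (sdir / "surf").mkdir(parents=True, exist_ok=True)
    (sdir / "label").mkdir(parents=True, exist_ok=True)
    fsio.write_surface(pial, sdir / "surf" / f"{hemi}.pial")
    fsio.write_surface(outer, sdir / "surf" / f"{hemi}.pial-outer-smoothed")
    fsio.write_overlay(overlay, sdir / "surf" / f"{hemi}.sulc")
    fsio.write_annotation(annot, sdir / "label" / f"{hemi}.aparc.a2009s.annot")
    if truth is not None:
        truth.to_json(sdir / "ground_truth.json")
    return sdir


def make_box_sulcus(
    spec: SulcusSpec, subjects_dir, subject: str = "synth01"
) -> tuple[Path, GroundTruth]:
    """Generate and write one box-canyon subject; returns (dir, ground truth)."""
    pial, annot, overlay, outer, truth = build_box_sulcus(spec)
    sdir = write_subject(
        subjects_dir, subject, pial, annot, overlay, outer, hemi=spec.hemi, truth=truth
    )
    return sdir, truth


# ---------------------------------------------------------------------------
# failure fixtures


def _write_flat_subject(subjects_dir, subject, vertices, faces, labels, table, hemi="lh"):
    mesh = SurfaceMesh(vertices, faces)
    annot = ParcellationAnnotation(labels, table)
    overlay = ScalarOverlay(vertices[:, 2].copy())
    outer = _flat_plate(
        (vertices[:, 0].min(), vertices[:, 0].max()),
        (vertices[:, 1].min(), vertices[:, 1].max()),
        n=4,
        z=float(vertices[:, 2].max()),
    )
    return write_subject(subjects_dir, subject, mesh, annot, overlay, outer, hemi=hemi)


def make_failure_fixtures(subjects_dir, label_name: str = "S_central") -> dict[str, Path]:
    """Emit the three canonical failure/edge-case subjects.

    * ``split-label`` — the target label on two edge-disjoint patches, so no
      single loop can encircle it (the discontinuous-parcellation failure),
    * ``annulus`` — a labeled ring whose boundary is two loops,
    * ``undersized`` — a fold with fewer vertices than the default fundus
      count, exercising the shortfall path.
    """
    table = _default_table()
    target = table[label_name]
    out: dict[str, Path] = {}

    # (a) split label: 21x21 flat grid, two labeled patches with a gap
    n = 21
    xs = np.arange(n, dtype=float)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00, v10 = i * n + j, (i + 1) * n + j
            v01, v11 = i * n + j + 1, (i + 1) * n + j + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    faces = np.asarray(faces, dtype=np.int64)
    ix, iy = vertices[:, 0], vertices[:, 1]
    in_a = (ix >= 2) & (ix <= 6) & (iy >= 2) & (iy <= 6)
    in_b = (ix >= 10) & (ix <= 14) & (iy >= 2) & (iy <= 6)
    labels = np.where(in_a | in_b, target, NO_LABEL)
    out["split-label"] = _write_flat_subject(
        subjects_dir, "synth-split", vertices, faces, labels, table
    )

    # (b) annulus: structured polar ring, every vertex labeled -> boundary is
    # exactly the inner and outer circles (two clean loops)
    n_r, n_t = 6, 48
    rs = np.linspace(4.0, 8.0, n_r)
    ts = np.linspace(0.0, 2 * np.pi, n_t, endpoint=False)
    R, T = np.meshgrid(rs, ts, indexing="ij")
    vertices = np.column_stack(
        [(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), np.zeros(R.size)]
    )
    faces = []
    for i in range(n_r - 1):
        for j in range(n_t):
            jn = (j + 1) % n_t
            v00, v10 = i * n_t + j, (i + 1) * n_t + j
            v01, v11 = i * n_t + jn, (i + 1) * n_t + jn
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    faces = np.asarray(faces, dtype=np.int64)
    labels = np.full(len(vertices), target, dtype=np.int64)
    out["annulus"] = _write_flat_subject(
        subjects_dir, "synth-annulus", vertices, faces, labels, table
    )

    # (c) undersized region: a coarse shallow fold with < 100 fold vertices
    spec = SulcusSpec(
        true_width=2.0,
        true_depth=2.0,
        length=6.0,
        mesh_spacing=1.0,
        plate_margin=3.0,
        label_name=label_name,
        seed=0,
    )
    sdir, _ = make_box_sulcus(spec, subjects_dir, subject="synth-undersized")
    out["undersized"] = sdir
    return out


# ---------------------------------------------------------------------------
# cohorts


@dataclasses.dataclass
class CohortEffects:
    """Linear age-effect model for cohort generation.

    Defaults are tuned to realistic adult-lifespan magnitudes: mean width
    3 mm widening 0.02 mm/yr, mean depth 10 mm shallowing 0.06 mm/yr, with
    between-subject spread chosen so the generating age correlations are
    +0.5 (width) and -0.5 (depth) for ages uniform over a 60-year range
    (age SD 60/sqrt(12); slope*SD_age / total SD = 0.5).
    """

    width_mean: float = 3.0
    width_age_slope: float = 0.02  # mm/yr
    width_between_sd: float = 0.60  # = 0.02 * (60/sqrt(12)) * sqrt(3)
    width_within_sd: float = 0.0  # per-session
    depth_mean: float = 10.0
    depth_age_slope: float = -0.06
    depth_between_sd: float = 1.80
    depth_within_sd: float = 0.0
    width_floor: float = 0.9  # clip: meshes need a physically open fold
    depth_floor: float = 3.0


def sample_cohort_truth(
    n_subjects: int,
    age_range=(20.0, 80.0),
    effects: CohortEffects | None = None,
    n_sessions: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample the generating truth table (no meshes): one row per
    subject x session with age, true and per-session width/depth, and two
    covariates (mean cortical thickness, ventricle volume) drawn
    independently of the sulcal measures."""
    if n_subjects < 2:
        raise ValidationError("n_subjects must be >= 2")
    eff = effects or CohortEffects()
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, n_subjects)
    mid = np.mean(age_range)
    w_true = (
        eff.width_mean
        + eff.width_age_slope * (ages - mid)
        + rng.normal(0, eff.width_between_sd, n_subjects)
    )
    d_true = (
        eff.depth_mean
        + eff.depth_age_slope * (ages - mid)
        + rng.normal(0, eff.depth_between_sd, n_subjects)
    )
    w_true = np.maximum(w_true, eff.width_floor)
    d_true = np.maximum(d_true, eff.depth_floor)
    thickness = rng.normal(2.5, 0.15, n_subjects)
    ventricles = rng.normal(30000.0, 8000.0, n_subjects)
    rows = []
    for s in range(n_sessions):
        w_ses = w_true + rng.normal(0, eff.width_within_sd, n_subjects)
        d_ses = d_true + rng.normal(0, eff.depth_within_sd, n_subjects)
        w_ses = np.maximum(w_ses, eff.width_floor)
        d_ses = np.maximum(d_ses, eff.depth_floor)
        for i in range(n_subjects):
            rows.append(
                {
                    "subject": f"sub{i:03d}",
                    "session": s + 1,
                    "age": ages[i],
                    "true_width": w_true[i],
                    "true_depth": d_true[i],
                    "session_width": w_ses[i],
                    "session_depth": d_ses[i],
                    "thickness": thickness[i],
                    "ventricle_volume": ventricles[i],
                }
            )
    return pd.DataFrame(rows)


def make_qc_cohort(
    subjects_dir,
    n_subjects: int = 20,
    n_split: int = 3,
    seed: int = 0,
    mesh_spacing: float = 1.0,
    length: float = 30.0,
) -> list[Path]:
    """Cohort for exercising the >10% failure-rate QC rule.

    Every subject carries a measurable ``S_central`` fold plus a flat
    ``S_postcentral`` plate patch (always measurable); in the first
    ``n_split`` subjects the fold label is interrupted by an unlabeled band,
    splitting it into two discontinuous patches so its edge loop fails.
    With ``n_split / n_subjects`` above 0.10 the QC report must flag
    ``S_central`` — and only ``S_central``.
    """
    rng = np.random.default_rng(seed)
    dirs: list[Path] = []
    for i in range(n_subjects):
        spec = SulcusSpec(
            true_width=3.0,
            true_depth=8.0,
            length=length,
            mesh_spacing=mesh_spacing,
            label_name="S_central",
            seed=int(rng.integers(2**31 - 1)),
        )
        pial, annot, overlay, outer, truth = build_box_sulcus(spec)
        # flat patch on the right plate labeled as a second, always-good sulcus
        x, y = pial.vertices[:, 0], pial.vertices[:, 1]
        x_hi = x.max()
        patch = (
            (annot.labels == NO_LABEL)
            & (x >= x_hi - 4 * mesh_spacing)
            & (x <= x_hi - mesh_spacing)
            & (y >= length / 3)
            & (y <= 2 * length / 3)
        )
        labels = annot.labels.copy()
        labels[patch] = annot.table["S_postcentral"]
        if i < n_split:
            fold = labels == annot.table["S_central"]
            band = np.abs(y - length / 2) <= 1.6 * mesh_spacing
            labels[fold & band] = NO_LABEL
        annot = ParcellationAnnotation(labels, annot.table)
        dirs.append(
            write_subject(
                subjects_dir, f"qc{i:03d}", pial, annot, overlay, outer, truth=truth
            )
        )
    return dirs


def make_cohort(
    subjects_dir,
    n_subjects: int,
    age_range=(20.0, 80.0),
    effects: CohortEffects | None = None,
    n_sessions: int = 1,
    seed: int = 0,
    label_name: str = "S_central",
    mesh_spacing: float = 1.0,
    length: float = 30.0,
    hemi: str = "lh",
) -> pd.DataFrame:
    """Emit a full synthetic cohort and return its truth table.

    Each subject x session becomes one FreeSurfer-layout directory named
    ``sub{i}-ses{s}`` whose fold realizes that session's width/depth.  The
    truth table is also written to ``<subjects_dir>/cohort_truth.csv``.
    Deterministic given the seed.
    """
    truth = sample_cohort_truth(n_subjects, age_range, effects, n_sessions, seed)
    dirs = []
    for _, row in truth.iterrows():
        subject = f"{row['subject']}-ses{int(row['session']):02d}"
        spec = SulcusSpec(
            true_width=float(row["session_width"]),
            true_depth=float(row["session_depth"]),
            length=length,
            mesh_spacing=mesh_spacing,
            label_name=label_name,
            hemi=hemi,
            seed=seed,
        )
        sdir, _ = make_box_sulcus(spec, subjects_dir, subject=subject)
        dirs.append(str(sdir))
    truth = truth.assign(subject_dir=dirs)
    truth.to_csv(Path(subjects_dir) / "cohort_truth.csv", index=False)
    return truth
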