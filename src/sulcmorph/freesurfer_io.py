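"""Reading and writing the FreeSurfer binary file families the estimator consumes.

Three formats are supported, each through :mod:`nibabel.freesurfer.io` with
strict up-front validation of the magic bytes so that unsupported dialects are
rejected rather than misparsed:

* triangle surface files (``?h.pial``, ``?h.pial-outer-smoothed``) — the
  binary *triangle* dialect only; the legacy quad dialects are rejected,
* annotation files with an embedded color table (``?h.aparc.a2009s.annot``),
* per-vertex scalar ("curv"-family) files in the *new* binary dialect
  (``?h.sulc``); the old dialect is rejected.

Vertex indices are 0-based everywhere in memory.  Coordinates are kept in the
surface's native RAS frame in mm; no volume geometry is applied, since all
downstream measures are relative distances.

Label ids round-trip through annotation files by packing ``id + 1`` into the
color-table RGB triple (FreeSurfer's annotation value); value 0 and rows named
``unknown`` denote unlabeled vertices, which carry :data:`NO_LABEL` in memory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel.freesurfer.io as fsio
import numpy as np

from .errors import ConsistencyError, FormatError, ValidationError

#: Label id carried by vertices with no (or an "unknown") parcellation label.
NO_LABEL = -1

_TRIANGLE_MAGIC = b"\xff\xff\xfe"
_QUAD_MAGIC = b"\xff\xff\xff"
_NEW_QUAD_MAGIC = b"\xff\xff\xfd"
_NEW_CURV_MAGIC = b"\xff\xff\xff"

# Fixed creation stamp so emitted files are byte-identical across runs.
_CREATE_STAMP = "created by sulcmorph"


@dataclasses.dataclass
class SurfaceMesh:
    """A triangle mesh: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")
        if self.n_vertices < 3:
            raise ValidationError(f"mesh needs >= 3 vertices, got {self.n_vertices}")
        if self.n_faces < 1:
            raise ValidationError("mesh needs >= 1 face")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=0) >= self.n_vertices:
            raise ValidationError("face index out of range [0, n_vertices)")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise ValidationError("faces must have three distinct vertex indices")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("vertex coordinates must be finite")


@dataclasses.dataclass
class ParcellationAnnotation:
    """Per-vertex label assignment with a name <-> id table.

    ``labels`` holds one integer id per mesh vertex (:data:`NO_LABEL` for
    unlabeled vertices); ``table`` maps label name to id.
    """

    labels: np.ndarray
    table: dict[str, int]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def validate(self, n_vertices: int | None = None) -> None:
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D array")
        if n_vertices is not None and len(self.labels) != n_vertices:
            raise ConsistencyError(
                f"annotation has {len(self.labels)} labels but mesh has "
                f"{n_vertices} vertices"
            )
        present = set(np.unique(self.labels)) - {NO_LABEL}
        known = set(self.table.values())
        if not present <= known:
            raise ValidationError(
                f"label ids {sorted(present - known)} present on vertices but "
                "missing from the name table"
            )
        for name, lid in self.table.items():
            if lid < 0:
                raise ValidationError(f"label id for {name!r} must be >= 0")


@dataclasses.dataclass
class ScalarOverlay:
    """One scalar per vertex (FreeSurfer convexity/"sulc" units)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    def validate(self, n_vertices: int | None = None) -> None:
        if self.values.ndim != 1:
            raise ValidationError("overlay values must be a 1-D array")
        if not np.isfinite(self.values).all():
            raise ValidationError("overlay values must all be finite")
        if n_vertices is not None and len(self.values) != n_vertices:
            raise ConsistencyError(
                f"overlay has {len(self.values)} values but mesh has "
                f"{n_vertices} vertices"
            )


def _check_magic(path: Path, expected: bytes, kind: str) -> None:
    try:
        with open(path, "rb") as f:
            magic = f.read(3)
    except OSError as e:
        raise FormatError(path, f"cannot read: {e}") from e
    if len(magic) < 3:
        raise FormatError(path, "truncated file (fewer than 3 bytes)", offset=0)
    if magic != expected:
        detail = f"bad magic {magic!r}, expected {expected!r} for a {kind} file"
        if kind == "triangle surface" and magic in (_QUAD_MAGIC, _NEW_QUAD_MAGIC):
            detail += " (legacy quad surface dialect is not supported)"
        raise FormatError(path, detail, offset=0)


def read_surface(path) -> SurfaceMesh:
    """Read a FreeSurfer binary *triangle* surface file.

    Coordinates are returned exactly as stored (surface RAS, mm); no
    transform is applied.
    """
    path = Path(path)
    _check_magic(path, _TRIANGLE_MAGIC, "triangle surface")
    try:
        coords, faces = fsio.read_geometry(path)
    except Exception as e:
        raise FormatError(path, f"failed to parse triangle surface: {e}") from e
    mesh = SurfaceMesh(coords, faces)
    mesh.validate()
    return mesh


def write_surface(mesh: SurfaceMesh, path) -> None:
    """Write a triangle surface; ``read_surface`` reproduces it exactly
    (coordinates are stored as float32)."""
    mesh.validate()
    fsio.write_geometry(str(path), mesh.vertices, mesh.faces, create_stamp=_CREATE_STAMP)


def _pack_rgb(value: int) -> tuple[int, int, int]:
    return value & 0xFF, (value >> 8) & 0xFF, (value >> 16) & 0xFF


def read_annotation(path) -> ParcellationAnnotation:
    """Read a FreeSurfer annotation file.

    The embedded color table is required (name-based sulcus lookup is
    impossible without it).  Vertices whose annotation value is 0, matches no
    color-table entry, or matches an entry named ``unknown`` are mapped to
    :data:`NO_LABEL`.
    """
    path = Path(path)
    try:
        idx, ctab, names = fsio.read_annot(str(path))
    except Exception as e:
        raise FormatError(path, f"failed to parse annotation: {e}") from e
    if ctab is None or len(names) == 0:
        raise FormatError(path, "annotation has no embedded color table")
    names = [n.decode("utf-8") if isinstance(n, bytes) else str(n) for n in names]
    # annotation value packed in the RGB columns; id = value - 1
    values = (
        ctab[:, 0].astype(np.int64)
        + ctab[:, 1].astype(np.int64) * 256
        + ctab[:, 2].astype(np.int64) * 65536
    )
    row_ids = values - 1  # value 0 -> id -1 (unlabeled)
    table: dict[str, int] = {}
    for name, rid, val in zip(names, row_ids, values):
        if val == 0 or name.lower() == "unknown":
            continue
        table[name] = int(rid)
    labels = np.full(len(idx), NO_LABEL, dtype=np.int64)
    valid = idx >= 0
    labels[valid] = row_ids[idx[valid]]
    for name, rid in [(n, r) for n, r, v in zip(names, row_ids, values) if v == 0 or n.lower() == "unknown"]:
        labels[labels == rid] = NO_LABEL
    annot = ParcellationAnnotation(labels, table)
    annot.validate()
    return annot


def write_annotation(annot: ParcellationAnnotation, path) -> None:
    """Write an annotation file with an embedded color table.

    Label ids are encoded as annotation value ``id + 1`` so that arbitrary
    ids survive a round trip; unlabeled vertices are written with value 0 via
    a color-table row named ``unknown``.
    """
    annot.validate()
    names = sorted(annot.table, key=annot.table.get)
    ids = [annot.table[n] for n in names]
    if len(set(ids)) != len(ids):
        raise ValidationError("label ids in the name table must be unique")
    # row 0: the unlabeled entry with annotation value 0
    all_names = ["unknown"] + names
    ctab = np.zeros((len(all_names), 5), dtype=np.int64)
    for row, lid in enumerate(ids, start=1):
        r, g, b = _pack_rgb(lid + 1)
        ctab[row, :4] = (r, g, b, 0)
        ctab[row, 4] = lid + 1
    id_to_row = {lid: row for row, lid in enumerate(ids, start=1)}
    id_to_row[NO_LABEL] = 0
    try:
        rows = np.array([id_to_row[int(l)] for l in annot.labels], dtype=np.int64)
    except KeyError as e:
        raise ValidationError(f"label id {e} missing from the name table") from e
    fsio.write_annot(str(path), rows, ctab, [n.encode() for n in all_names], fill_ctab=False)


def read_overlay(path, expected_n_vertices: int | None = None) -> ScalarOverlay:
    """Read a per-vertex scalar file in the new ("curv") binary dialect.

    If ``expected_n_vertices`` is given, a length mismatch raises
    :class:`ConsistencyError`.
    """
    path = Path(path)
    _check_magic(path, _NEW_CURV_MAGIC, "new-dialect scalar overlay")
    try:
        values = fsio.read_morph_data(str(path))
    except Exception as e:
        raise FormatError(path, f"failed to parse scalar overlay: {e}") from e
    overlay = ScalarOverlay(values)
    overlay.validate(expected_n_vertices)
    return overlay


def write_overlay(overlay: ScalarOverlay, path) -> None:
    """Write a scalar overlay (values stored as float32)."""
    overlay.validate()
    fsio.write_morph_data(str(path), overlay.values)
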