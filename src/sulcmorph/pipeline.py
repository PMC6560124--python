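"""Batch orchestration: per-subject measurement over a FreeSurfer subjects
directory, cohort assembly, and QC reporting.

For each requested (hemisphere, sulcus) the pipeline isolates the labeled
region, extracts its boundary edge loop, and estimates width (median bridge
distance) and depth (median fundus-to-outer-surface distance).  Failures are
recorded per measure — a discontinuous parcellation or an unloopable
boundary never aborts the run — and the cohort QC report flags any sulcus
whose failure rate exceeds 10% as unsupported for the cohort at hand.

Depth does not require the edge loop, so by default it is still computed
when width fails; ``strict=True`` fails both together for users matching the
original per-sulcus exclusion behavior.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import freesurfer_io as fsio
from .depth import DepthOptions, compute_depth
from .errors import ConfigurationError, UnknownLabelError
from .registry import EXPERIMENTAL_SULCI, HEMISPHERES, SUPPORTED_SULCI
from .stats import summarize_cohort
from .sulcus_mesh import (
    DISCONTINUOUS_REGION,
    SulcusRegion,
    connected_components,
    get_edge_loop,
    isolate_sulcus,
)
from .width import WidthOptions, compute_width

log = logging.getLogger("sulcmorph")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    subjects_dir: str
    subjects: list[str] | None = None  # None -> auto-discover
    hemispheres: tuple[str, ...] = HEMISPHERES
    sulci: tuple[str, ...] = SUPPORTED_SULCI
    width_options: WidthOptions = dataclasses.field(default_factory=WidthOptions)
    depth_options: DepthOptions = dataclasses.field(default_factory=DepthOptions)
    experimental: bool = False
    strict: bool = False
    allow_largest_component: bool = False
    annot_name: str = "aparc.a2009s"

    def __post_init__(self):
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise ConfigurationError(f"unknown hemisphere {h!r}")
        known = set(SUPPORTED_SULCI) | set(EXPERIMENTAL_SULCI)
        for s in self.sulci:
            if s not in known:
                raise ConfigurationError(
                    f"unknown sulcus {s!r}; supported: {', '.join(SUPPORTED_SULCI)}"
                )
            if s in EXPERIMENTAL_SULCI and not self.experimental:
                raise ConfigurationError(
                    f"{s!r} is experimental (fails the closed-loop criterion at "
                    ">10% in cohort use); pass experimental=True to measure it"
                )
        if self.experimental:
            for s in self.sulci:
                if s in EXPERIMENTAL_SULCI:
                    log.warning("measuring experimental sulcus %s", s)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["subjects_dir"] = str(d["subjects_dir"])
        return d


@dataclasses.dataclass
class SulcalMeasure:
    """One (subject, hemisphere, sulcus) measurement record.

    Exactly one of (value, failure reason) is populated per metric.
    """

    subject: str
    hemi: str
    sulcus: str
    width: float | None = None
    width_failure: str | None = None
    depth: float | None = None
    depth_failure: str | None = None
    n_bridges: int = 0
    n_fundus: int = 0
    flags: list[str] = dataclasses.field(default_factory=list)


def discover_subjects(subjects_dir) -> list[str]:
    """Subject ids: subdirectories containing a ``surf/`` directory."""
    root = Path(subjects_dir)
    if not root.is_dir():
        raise ConfigurationError(f"subjects_dir {root} does not exist")
    return sorted(p.name for p in root.iterdir() if (p / "surf").is_dir())


def _required_files(config: RunConfig, subject: str, hemi: str) -> dict[str, Path]:
    sdir = Path(config.subjects_dir) / subject
    return {
        "pial": sdir / "surf" / f"{hemi}.pial",
        "outer": sdir / "surf" / f"{hemi}.pial-outer-smoothed",
        "sulc": sdir / "surf" / f"{hemi}.sulc",
        "annot": sdir / "label" / f"{hemi}.{config.annot_name}.annot",
    }


def _largest_component(region: SulcusRegion) -> SulcusRegion:
    _, face_comp = connected_components(region)
    best = np.bincount(face_comp).argmax()
    keep = region.face_ids[face_comp == best]
    used = np.unique(region.parent.faces[keep])
    return SulcusRegion(region.parent, keep, used, region.label_name)


def run_subject(config: RunConfig, subject: str) -> list[SulcalMeasure]:
    """Measure every requested (hemisphere, sulcus) of one subject.

    Missing required files raise :class:`ConfigurationError` naming every
    missing path (the outer surface is a gyrification-pipeline prerequisite);
    per-sulcus measurement failures are recorded and do not raise.
    """
    measures: list[SulcalMeasure] = []
    for hemi in config.hemispheres:
        paths = _required_files(config, subject, hemi)
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise ConfigurationError(
                f"subject {subject!r} hemi {hemi}: missing required files "
                f"(run FreeSurfer recon + gyrification analysis first): "
                + ", ".join(missing)
            )
        pial = fsio.read_surface(paths["pial"])
        outer = fsio.read_surface(paths["outer"])
        annot = fsio.read_annotation(paths["annot"])
        sulcmap = fsio.read_overlay(paths["sulc"], expected_n_vertices=pial.n_vertices)
        for sulcus in config.sulci:
            m = SulcalMeasure(subject, hemi, sulcus)
            try:
                region = isolate_sulcus(pial, annot, sulcus)
            except UnknownLabelError:
                m.width_failure = m.depth_failure = "label-not-in-table"
                measures.append(m)
                log.warning("%s %s %s: label not in annotation table", subject, hemi, sulcus)
                continue
            if region.is_empty:
                m.width_failure = m.depth_failure = "label-absent"
                measures.append(m)
                log.warning("%s %s %s: label absent on surface", subject, hemi, sulcus)
                continue
            loop = get_edge_loop(region)
            width_region = region
            if not loop and config.allow_largest_component and loop.reason == DISCONTINUOUS_REGION:
                width_region = _largest_component(region)
                loop = get_edge_loop(width_region)
                m.flags.append("largest-component")
            if loop:
                wres = compute_width(width_region, loop, config.width_options)
                if wres:
                    m.width = wres.width
                    m.n_bridges = len(wres.bridges)
                else:
                    m.width_failure = wres.failure
            else:
                m.width_failure = loop.reason
            if config.strict and m.width_failure is not None:
                m.depth_failure = "strict-width-failed"
            else:
                dres = compute_depth(region, sulcmap, outer, config.depth_options)
                if dres:
                    m.depth = dres.depth
                    m.n_fundus = len(dres.fundus.vertex_ids)
                    m.flags.extend(dres.flags)
                else:
                    m.depth_failure = dres.failure
            if m.width_failure:
                log.warning("%s %s %s: width failed (%s)", subject, hemi, sulcus, m.width_failure)
            else:
                log.info("%s %s %s: width %.3f mm", subject, hemi, sulcus, m.width)
            if m.depth_failure:
                log.warning("%s %s %s: depth failed (%s)", subject, hemi, sulcus, m.depth_failure)
            else:
                log.info("%s %s %s: depth %.3f mm", subject, hemi, sulcus, m.depth)
            measures.append(m)
    return measures


def measures_to_long(measures: list[SulcalMeasure]) -> pd.DataFrame:
    """Long-format table: one row per (subject, hemi, sulcus, metric).

    Failed measures carry NaN values and the failure reason as status, so no
    sentinel numbers can leak into analysis.
    """
    rows = []
    for m in measures:
        rows.append(
            {
                "subject": m.subject,
                "hemi": m.hemi,
                "sulcus": m.sulcus,
                "metric": "width",
                "value": np.nan if m.width is None else m.width,
                "status": m.width_failure or "ok",
                "n_support": m.n_bridges,
                "flags": ";".join(m.flags),
            }
        )
        rows.append(
            {
                "subject": m.subject,
                "hemi": m.hemi,
                "sulcus": m.sulcus,
                "metric": "depth",
                "value": np.nan if m.depth is None else m.depth,
                "status": m.depth_failure or "ok",
                "n_support": m.n_fundus,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows)


def run_cohort(
    config: RunConfig, out_prefix=None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run every subject; returns (long table, wide table, QC report).

    Any single-subject error is caught, recorded in the QC report, and the
    run continues.  With ``out_prefix`` the long CSV, wide CSV and QC JSON
    are written to ``<prefix>_long.csv`` / ``<prefix>_wide.csv`` /
    ``<prefix>_qc.json``.
    """
    subjects = config.subjects or discover_subjects(config.subjects_dir)
    if not subjects:
        raise ConfigurationError(f"no subjects found under {config.subjects_dir}")
    all_measures: list[SulcalMeasure] = []
    subject_errors: dict[str, str] = {}
    for subject in subjects:
        try:
            all_measures.extend(run_subject(config, subject))
        except Exception as e:  # crash isolation: one subject cannot abort the run
            subject_errors[subject] = str(e)
            log.error("subject %s skipped: %s", subject, e)
    long_df = measures_to_long(all_measures)
    if long_df.empty:
        wide_df, qc = pd.DataFrame(), {"failure_rates": {}, "flagged_sulci": []}
    else:
        wide_df, qc = summarize_cohort(long_df, sulci=config.sulci)
    qc["subject_errors"] = subject_errors
    qc["n_subjects_requested"] = len(subjects)
    qc["n_subjects_measured"] = len(subjects) - len(subject_errors)
    qc["config"] = config.echo()
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        long_df.to_csv(f"{out_prefix}_long.csv", index=False)
        wide_df.to_csv(f"{out_prefix}_wide.csv")
        with open(f"{out_prefix}_qc.json", "w") as f:
            json.dump(qc, f, indent=2, sort_keys=True)
    return long_df, wide_df, qc
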