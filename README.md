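# sulcmorph

Per-sulcus **width** and **depth** estimation from FreeSurfer cortical
surface reconstructions, with a synthetic-subject generator that makes the
estimator verifiable against analytic ground truth.

Cortical morphology is usually summarized by volume, thickness, surface area
or gyrification; the shape of individual sulci — how wide a fold has opened
and how deep it reaches — is rarely quantified, even though it changes
markedly with aging and disease. `sulcmorph` measures both quantities
directly from the meshes a standard FreeSurfer run already produces
(`?h.pial`, `?h.aparc.a2009s.annot`, `?h.sulc`, `?h.pial-outer-smoothed`),
using the same Destrieux-atlas boundaries as the rest of the FreeSurfer
pipeline. It is intended for researchers analyzing FreeSurfer cohorts who
want sulcal morphometry without bringing in a second surface-analysis
toolchain with inconsistent landmark definitions.

## Method

For a labeled sulcus *S* on the pial mesh:

* **Width.** The faces whose three vertices all carry the label of *S* are
  isolated as a submesh; the edges incident to exactly one of those faces
  form the region's boundary, which is chained into a single closed edge
  loop encircling the sulcus (vertices mid-way between the adjacent gyral
  crowns and the fundus). For each loop vertex *v*, the nearest loop vertex
  in 3-D that is not neighboring in the loop (outside a cyclic exclusion
  window, default 5 positions) is found, then refined by an exhaustive walk
  of up to 4 loop positions around the initial match; the segment *v*–*match*
  bridges across the fold. The sulcal width is

  &nbsp;&nbsp;&nbsp;&nbsp;*w(S)* = median over loop vertices of ‖v − match(v)‖ (mm).

  Labels parcellated as two or more discontinuous patches, or whose boundary
  is not a single simple cycle, are reported as failed measures (reason
  `discontinuous-region`, `multiple-loops` or `non-manifold-boundary`), and a
  cohort in which a sulcus fails in more than 10% of subjects gets that
  sulcus flagged as unsupported.

* **Depth.** The fundus is taken as the 100 region vertices most extreme in
  the `?h.sulc` convexity overlay; for each, the shortest Euclidean distance
  to the smoothed enclosing surface (`?h.pial-outer-smoothed`, from the
  gyrification analysis) is computed by exact point-to-triangle
  minimization, and

  &nbsp;&nbsp;&nbsp;&nbsp;*d(S)* = median over fundus vertices of dist(v, outer) (mm).

  Straight-line distance deliberately underestimates the along-wall depth of
  curved sulci; it is robust and avoids landmark ambiguity.

* **Statistics.** Test–retest reliability as ICC(1,1) — the one-way
  random-effects intraclass correlation for single measurements,
  (MSB − MSW)/(MSB + (k−1)·MSW), with an F-based 95% CI — plus Pearson and
  residual-method partial correlations, per-subject means over the 16
  per-hemisphere sulci, and cohort QC.

Eight Destrieux sulci are supported per hemisphere: `S_central`,
`S_postcentral`, `S_front_sup`, `S_front_inf`, `S_parieto_occipital`,
`S_oc-temp_med&Lingual`, `S_oc_middle&Lunatus`, `S_cingul-Marginalis`.
The superior/inferior temporal and intraparietal sulci fail the closed-loop
criterion too often and are available only behind `--experimental`.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Because no external dataset ships with the package, the example measures a
*synthetic* subject whose geometry is known exactly — a cortical plate with a
U-shaped fold 3 mm wide and 10 mm deep, written in standard FreeSurfer
layout (`examples/01_measure_synthetic_subject.py`):

```text
subject written to /tmp/.../synth01
region: 9200 faces; boundary loop: 292 vertices
estimated width: 3.00 mm (true 3.0)
estimated depth: 10.00 mm (true 10.0)
bridges: 292, fundus vertices: 100
```

The estimator recovered the generating width and depth exactly: every one of
the 292 loop vertices contributed a bridge across the fold (median 3.00 mm),
and the 100 fundus vertices all sit 10.00 mm below the outer plate. The other
examples demonstrate failure modes and QC flagging (`02`), a cohort-level
aging analysis (`03`), and test–retest ICC (`04`).

On real data the entry point is the CLI:

```bash
sulcmorph run --subjects-dir $SUBJECTS_DIR --out results
sulcmorph stats --table results_wide.csv --corr age,mean_width
```

which writes a long-format CSV (one row per subject x hemisphere x sulcus x
metric, failures explicit), a wide per-subject table with 16-sulcus means,
and a QC report in JSON.

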