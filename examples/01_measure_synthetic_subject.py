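"""Measure sulcal width and depth on one synthetic subject.

Generates a box-canyon subject with known geometry (width 3 mm, depth
10 mm) in FreeSurfer layout, then runs the full estimator on the written
files: isolate the labeled sulcus, extract its boundary edge loop, bridge
across it for width, and measure the fundus-to-outer-surface distance for
depth.  The printed estimates should match the generating truth to within
one mesh spacing (0.5 mm).
"""

import tempfile
from pathlib import Path

import sulcmorph as sm

tmp = Path(tempfile.mkdtemp())
spec = sm.SulcusSpec(true_width=3.0, true_depth=10.0, mesh_spacing=0.5,
                     length=50.0, seed=7)
sdir, truth = sm.make_box_sulcus(spec, tmp)
print(f"subject written to {sdir}")

pial = sm.read_surface(sdir / "surf" / "lh.pial")
outer = sm.read_surface(sdir / "surf" / "lh.pial-outer-smoothed")
annot = sm.read_annotation(sdir / "label" / "lh.aparc.a2009s.annot")
sulc = sm.read_overlay(sdir / "surf" / "lh.sulc", pial.n_vertices)

region = sm.isolate_sulcus(pial, annot, "S_central")
loop = sm.get_edge_loop(region)
print(f"region: {region.n_faces} faces; boundary loop: {len(loop)} vertices")

# window sized so the excluded arc (15 x 0.5 mm) exceeds the sulcal width
wres = sm.compute_width(region, loop, sm.WidthOptions(exclusion_window=15))
dres = sm.compute_depth(region, sulc, outer)
print(f"estimated width: {wres.width:.2f} mm (true {truth.true_width})")
print(f"estimated depth: {dres.depth:.2f} mm (true {truth.true_depth})")
print(f"bridges: {len(wres.bridges)}, fundus vertices: {len(dres.fundus.vertex_ids)}")
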