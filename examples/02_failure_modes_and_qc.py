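"""Edge-loop failure modes and the cohort QC threshold.

A sulcus parcellated as two discontinuous patches (or any region whose
boundary is not a single simple cycle) cannot be encircled by one edge
loop; the estimator reports these as per-measure failures rather than
crashing.  A cohort where one sulcus fails in more than 10% of subjects
gets that sulcus flagged as unsupported.
"""

import tempfile
from pathlib import Path

import sulcmorph as sm
from sulcmorph.pipeline import RunConfig, run_cohort
from sulcmorph.synthetic import make_qc_cohort

tmp = Path(tempfile.mkdtemp())

# the three canonical edge cases
for name, sdir in sm.make_failure_fixtures(tmp / "fixtures").items():
    pial = sm.read_surface(sdir / "surf" / "lh.pial")
    annot = sm.read_annotation(sdir / "label" / "lh.aparc.a2009s.annot")
    region = sm.isolate_sulcus(pial, annot, "S_central")
    loop = sm.get_edge_loop(region)
    outcome = f"loop of {len(loop)} vertices" if loop else f"FAILED: {loop.reason}"
    print(f"{name:12s} -> {outcome}")

# 20-subject cohort with the fold label split in 3 subjects (15% > 10%)
make_qc_cohort(tmp / "cohort", n_subjects=20, n_split=3, seed=3)
config = RunConfig(subjects_dir=str(tmp / "cohort"), hemispheres=("lh",),
                   sulci=("S_central", "S_postcentral"))
long_df, _, qc = run_cohort(config)
rate = qc["failure_rates"]["lh_S_central_width"]["failure_rate"]
print(f"\nS_central width failure rate: {rate:.0%}")
print(f"flagged sulci (>10% rule): {qc['flagged_sulci']}")
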