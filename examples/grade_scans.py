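"""Grade a directory of synthetic scans end to end.

Writes ten synthetic knees (.pts landmark files plus colour-coded osteophyte
mask PNGs) to a temporary directory, runs the directory-level grader, and
prints the per-scan composite results. Each row shows the measured medial
mJSW, the JSN grade it implies, the weighted sum score and the 0-4 rKOA
grade.
"""

import tempfile
from pathlib import Path

import numpy as np

from kneedxa import GraderConfig, Site, run_grade, synth_knee, write_mask, write_pts

cfg = GraderConfig()
rng = np.random.default_rng(21)

with tempfile.TemporaryDirectory() as tmp:
    scans = Path(tmp)
    for i in range(10):
        areas = {Site.MEDIAL_FEMUR: float(rng.uniform(5, 40))} if i % 3 == 0 else None
        lm, anns = synth_knee(
            float(rng.uniform(1.8, 4.6)), float(rng.uniform(3.0, 5.0)),
            areas, 0.25, seed=i, subject_id=f"S{i:04d}", cfg=cfg,
        )
        write_pts(lm, scans / f"S{i:04d}.pts")
        if anns:
            write_mask(anns, cfg, anns[0].mask.shape, scans / f"S{i:04d}.png")

    df, manifest = run_grade(scans, cfg, scans / "grades.csv")

cols = ["subject_id", "medial_mjsw_mm", "jsn_grade",
        "area_medial_femur_mm2", "sum_score", "rkoa_grade"]
print(df[cols].round(3).to_string(index=False))
print(f"\n{manifest.n_ok} scans graded, {len(manifest.failures)} failures")
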