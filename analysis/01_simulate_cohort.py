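"""Simulate the study cohort and write its file-format export.

Generates the default synthetic cohort (81 unilateral-lesion participants,
41 behavioural scores in 5 domains, 26 parcels in 13 networks/hemisphere),
summarizes its structure, and exports the cohort directory (TSV/JSON plus
NIfTI lesion volumes) under scratch/ to exercise the file interface.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, study_cohort

from strokelink.synthetic import write_cohort


def main():
    cohort = study_cohort()
    sev = cohort.truth.lesion_severity
    lesion_vox = np.array([l.n_voxels for l in cohort.lesions])
    missing = cohort.behaviour.isna().to_numpy().mean()

    summary = pd.DataFrame([
        ("participants", cohort.n_participants),
        ("parcels", cohort.scheme.n_parcels),
        ("fc_edges", cohort.scheme.n_edges),
        ("behaviour_measures", cohort.behaviour.shape[1]),
        ("atlas_streamlines", cohort.atlas.n_streamlines),
        ("lesion_voxels_median", float(np.median(lesion_vox))),
        ("severity_mean_frac_disrupted", float(sev.mean())),
        ("severity_sd", float(sev.std())),
        ("behaviour_missing_frac", float(missing)),
    ], columns=["quantity", "value"])
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "01_cohort_summary.tsv", sep="\t", index=False)

    out = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
    write_cohort(cohort, out, write_volumes=True)

    print(f"cohort: {cohort.n_participants} participants, "
          f"{cohort.scheme.n_parcels} parcels -> {cohort.scheme.n_edges} FC edges, "
          f"{cohort.atlas.n_streamlines} atlas streamlines")
    print(f"lesions disrupt a mean fraction {sev.mean():.3f} (sd {sev.std():.3f}) "
          f"of atlas streamlines; {100 * missing:.1f}% behaviour cells missing")
    print(f"wrote {RESULTS / '01_cohort_summary.tsv'} and cohort export {out}")


if __name__ == "__main__":
    main()
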