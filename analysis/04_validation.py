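"""Replication and reliability of the FC-behaviour latent component.

Projects a replication cohort (same ground truth, new participants) onto
the trained saliences, compares independently refitted saliences, runs
leave-one-out PLSC generalization, and split-half stability.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, analysis_blocks, replication_cohort, study_cohort

from strokelink.plsc import fit_plsc
from strokelink.validation import (
    loocv_plsc,
    project_cohort,
    salience_similarity,
    split_half,
)


def main():
    cohort = study_cohort()
    X, Y = analysis_blocks(cohort)
    model = fit_plsc(X, Y)

    rep = replication_cohort(cohort)
    X2, Y2 = analysis_blocks(rep)
    proj = project_cohort(model, X2, Y2, n_perm=1000, seed=SEED + 13)
    sim = salience_similarity(model, fit_plsc(X2, Y2))
    loo = loocv_plsc(X, Y, n_perm=200, seed=SEED + 14)
    _, _, half = split_half(X, Y, seed=SEED + 15)

    rows = [
        ("replication_projection_lc1_r", proj.score_correlation[0]),
        ("replication_projection_p", proj.permutation_p),
        ("replication_behaviour_salience_r", sim.y_salience_correlation),
        ("replication_fc_salience_r", sim.x_salience_correlation),
        ("loocv_pooled_r", loo.pooled_correlation),
        ("loocv_permutation_p", loo.permutation_p),
        ("split_half_behaviour_salience_r", half.y_salience_correlation),
        ("split_half_fc_salience_r", half.x_salience_correlation),
    ]
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        RESULTS / "04_validation.tsv", sep="\t", index=False)

    print(f"replication cohort projection: LC1 score r = "
          f"{proj.score_correlation[0]:.3f} (permutation p = {proj.permutation_p:.4g})")
    print(f"refit salience similarity: behaviour r = {sim.y_salience_correlation:.3f}, "
          f"FC r = {sim.x_salience_correlation:.3f}")
    print(f"LOOCV held-out composite correlation = {loo.pooled_correlation:.3f} "
          f"(p = {loo.permutation_p:.4g}); split-half behaviour-salience r = "
          f"{half.y_salience_correlation:.3f}")
    print(f"table at {RESULTS}/04_validation.tsv")


if __name__ == "__main__":
    main()
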