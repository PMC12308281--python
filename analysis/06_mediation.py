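"""Mediation among SDC, FC and behaviour composite scores.

Model 1: does FC disruption mediate the SDC -> behaviour association?
Model 2 (reversed): does SDC mediate FC -> behaviour?  Inference by 10 000
bias-corrected bootstraps; coefficients standardized.  The generative chain
(lesion -> disconnection -> network disruption -> deficits) predicts a
strong mediated effect in model 1 only.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, analysis_blocks, sdc_model_blocks, study_cohort

from strokelink.mediation import dual_mediation
from strokelink.plsc import composite_scores, fit_plsc


def main():
    cohort = study_cohort()
    X, Y = analysis_blocks(cohort)
    scores_fc = composite_scores(fit_plsc(X, Y), X, Y)
    sdc_nz, _ = sdc_model_blocks(cohort)
    scores_sdc = composite_scores(fit_plsc(sdc_nz, Y), sdc_nz, Y)

    med = dual_mediation(scores_sdc.x_scores[:, 0], scores_fc.x_scores[:, 0],
                         scores_fc.y_scores[:, 0], n_boot=10_000,
                         seed=SEED + 16, standardized=True)
    rows = []
    for name, rep in med.items():
        rows.append({"model": name, "a": rep.a, "b": rep.b, "c": rep.c,
                     "c_prime": rep.c_prime, "ab": rep.ab,
                     "ci_low": rep.ci_low, "ci_high": rep.ci_high,
                     "proportion_mediated": rep.proportion_mediated,
                     "significant": rep.significant})
        print(f"{name}: ab = {rep.ab:.3f} [{rep.ci_low:.3f}, {rep.ci_high:.3f}], "
              f"c = {rep.c:.3f}, proportion mediated = "
              f"{100 * rep.proportion_mediated:.1f}%, "
              f"{'significant' if rep.significant else 'not significant'}")
    pd.DataFrame(rows).to_csv(RESULTS / "06_mediation.tsv", sep="\t", index=False)
    print("these are statistical associations, not causal effects "
          "(mediator and outcome measured simultaneously)")
    print(f"table at {RESULTS}/06_mediation.tsv")


if __name__ == "__main__":
    main()
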