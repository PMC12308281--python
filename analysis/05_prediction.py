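"""Ridge prediction of LC1 composite scores from structural lesion features.

Leave-one-out ridge regression with nested alpha selection (2^-10 ... 2^5)
predicts the FC-model behavioural and FC composite scores from (a) SDC edge
features and (b) percent grey-matter damage, reproducing the structural-
disconnection-versus-focal-damage contrast.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, analysis_blocks, structural_features, study_cohort

from strokelink.plsc import composite_scores, fit_plsc
from strokelink.prediction import loocv_predict


def main():
    cohort = study_cohort()
    X, Y = analysis_blocks(cohort)
    scores = composite_scores(fit_plsc(X, Y), X, Y)
    damage, sdc = structural_features(cohort)

    rows = []
    for feat_name, feats in (("sdc", sdc), ("damage", damage)):
        for target_name, target in (("behaviour_composite", scores.y_scores[:, 0]),
                                    ("fc_composite", scores.x_scores[:, 0])):
            rep = loocv_predict(feats, target)
            rows.append({"features": feat_name, "target": target_name,
                         "r": rep.r, "r2": rep.r2, "mae": rep.mae})
            print(f"{feat_name:>6} -> {target_name}: r = {rep.r:.3f}, "
                  f"R2 = {rep.r2:.3f}, MAE = {rep.mae:.3f}")
    pd.DataFrame(rows).to_csv(RESULTS / "05_prediction.tsv", sep="\t", index=False)

    sdc_r = rows[0]["r"]
    dmg_r = rows[2]["r"]
    print(f"structural disconnection out-predicts focal damage for the "
          f"behavioural composite: r = {sdc_r:.3f} vs {dmg_r:.3f}")
    print(f"table at {RESULTS}/05_prediction.tsv")


if __name__ == "__main__":
    main()
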