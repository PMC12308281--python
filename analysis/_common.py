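"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same seed-1 synthetic cohort (deterministic,
~1 s) so each script can be run on its own, in any order.
"""

from pathlib import Path

import numpy as np

from strokelink.features import (
    damage_vector,
    drop_zero_features,
    impute_behaviour,
    sdc_matrix,
    vectorize_upper,
)
from strokelink.synthetic import SyntheticConfig, generate_cohort

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_cohort():
    """Default-condition cohort: 81 participants, 41 measures, 26 parcels."""
    return generate_cohort(SyntheticConfig(seed=SEED))


def replication_cohort(cohort):
    """Fresh participant sample under the training cohort's ground truth."""
    return generate_cohort(cohort.config, truth=cohort.truth,
                           participant_seed=cohort.config.seed + 101)


def analysis_blocks(cohort):
    """(X fc-edges, Y imputed behaviour) numpy blocks for PLSC."""
    Y = impute_behaviour(cohort.behaviour).to_numpy()
    X = np.asarray(cohort.fc_edges)
    return X, Y


def structural_features(cohort):
    """(damage percent matrix, SDC edge matrix) from the lesion masks."""
    damage = np.vstack([damage_vector(l, cohort.scheme) for l in cohort.lesions])
    sdc = np.vstack([vectorize_upper(sdc_matrix(l, cohort.atlas, cohort.scheme)).values
                     for l in cohort.lesions])
    return damage, sdc


def sdc_model_blocks(cohort):
    """Zero-column-free SDC block for the SDC-behaviour PLSC."""
    _, sdc = structural_features(cohort)
    sdc_nz, kept = drop_zero_features(sdc)
    return sdc_nz, kept
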