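"""Shared fixtures: synthetic datasets and (expensively) trained models.

The trained-model fixtures are session-scoped because CNN training on the
NumPy backend is the costly step; every test that needs a fitted
classifier shares the same one.
"""

from __future__ import annotations

import numpy as np
import pytest

import splicevar as sv

# Desk-scale study conditions: full-strength donor motif, 2,000 windows
# per class for training, 500 per class held out, CNN_4 for 5 epochs.
TRAIN_PER_CLASS = 2000
HOLD_PER_CLASS = 500
EPOCHS = 5
SEED = 2024


@pytest.fixture(scope="session")
def donor_motif():
    return sv.default_motif("donor", "DLAI40", strength=1.0)


@pytest.fixture(scope="session")
def donor_data(donor_motif):
    """(train_records, holdout_records, holdout_labels) at strength 1."""
    n = TRAIN_PER_CLASS + HOLD_PER_CLASS
    pos = sv.sample_positive(donor_motif, n, SEED)
    neg = sv.sample_negative(
        sv.GeneratorConfig("donor", "DLAI40", 0, n, seed=SEED + 1))
    train = pos[:TRAIN_PER_CLASS] + neg[:TRAIN_PER_CLASS]
    holdout = pos[TRAIN_PER_CLASS:] + neg[TRAIN_PER_CLASS:]
    y_hold = np.array([1] * HOLD_PER_CLASS + [0] * HOLD_PER_CLASS)
    return train, holdout, y_hold


@pytest.fixture(scope="session")
def trained_cnn4(donor_data):
    """CNN_4 fitted for 5 epochs on the strength-1 donor training set."""
    train, _, _ = donor_data
    clf = sv.SpliceSiteClassifier("CNN_4", epochs=EPOCHS, random_state=0)
    return clf.fit(train, [r.label for r in train])


@pytest.fixture(scope="session")
def shuffled_null(donor_data):
    """No-signal null: labels permuted across the whole dataset.

    Returns (classifier trained on shuffled-label training data,
    shuffled holdout labels); sequence and label are independent
    everywhere, so holdout discrimination can only be chance.
    """
    train, holdout, y_hold = donor_data
    y_train = np.array([1 if r.label is sv.Label.POSITIVE else 0
                        for r in train])
    rng = np.random.default_rng(SEED + 2)
    perm = rng.permutation(np.concatenate([y_train, y_hold]))
    clf = sv.SpliceSiteClassifier("CNN_4", epochs=EPOCHS, random_state=0)
    clf.fit(train, perm[:len(train)])
    return clf, perm[len(train):]


@pytest.fixture(scope="session")
def scored_variant_groups(donor_motif, donor_data, trained_cnn4):
    """Disruptive and neutral variant scores, 200 per class."""
    train, _, _ = donor_data
    positives = [r for r in train if r.label is sv.Label.POSITIVE]
    vset = sv.generate_variants(positives, 200, 200, SEED + 3, donor_motif)
    scores = sv.score_variants(trained_cnn4, vset.records)
    disruptive = [s for s in scores
                  if s.record.clinical_class is sv.ClinicalClass.PATHOGENIC]
    neutral = [s for s in scores
               if s.record.clinical_class is sv.ClinicalClass.BENIGN]
    return disruptive, neutral
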