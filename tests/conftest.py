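"""Shared fixtures: small synthetic cohorts and toy matrices."""

import numpy as np
import pandas as pd
import pytest

from mixsig import PanelConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale panel: fast to generate, full structure."""
    return PanelConfig(n_samples=60, n_mrna=80, n_housekeeping=6,
                       n_mrna_internal_controls=3, n_protein=10,
                       n_informative_mrna=4, n_informative_protein=2,
                       effect_size=1.2, block_size=8, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default panel (59 x 770-plex + 44 x 3 DSP)."""
    return generate_cohort(PanelConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_scores():
    """Separable-ish scores with ties for metric tests."""
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.8, 0.9, 0.2, 0.7])
    labels = np.array([0, 0, 0, 1, 1, 1, 0, 1])
    return scores, labels


def brute_force_auc(scores, labels):
    """Independent pair-counting oracle for the rank-sum AUC."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def pair_counting_auc():
    return brute_force_auc
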