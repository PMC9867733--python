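import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from ssrinet import make_ground_truth, simulate_trial


def no_missing(gt):
    """Overrides removing missingness and trial heterogeneity."""
    return {"missing_rate": {w: 0.0 for w in (0, 1, 2, 3, 4, 6)}, "trial_shift_sd": 0.0}


@pytest.fixture(scope="session")
def paper_gt():
    return make_ground_truth("paper_like")


@pytest.fixture(scope="session")
def clean_paper_gt():
    gt = make_ground_truth("paper_like")
    return make_ground_truth("paper_like", overrides=no_missing(gt))


@pytest.fixture(scope="session")
def null_gt():
    gt = make_ground_truth("null")
    return make_ground_truth("null", overrides=no_missing(gt))


@pytest.fixture(scope="session")
def small_latent_ds(clean_paper_gt):
    """n=2000 latent paper_like dataset at weeks 0/1/6 (shared, read-only)."""
    return simulate_trial(clean_paper_gt, 2000, weeks=(0, 1, 6), seed=11,
                          latent_only=True)


@pytest.fixture(scope="session")
def small_ordinal_ds(paper_gt):
    """n=1500 ordinal paper_like dataset with default missingness."""
    return simulate_trial(paper_gt, 1500, weeks=(0, 1, 6), seed=5)


@pytest.fixture(scope="session")
def recovery_latent_ds(clean_paper_gt):
    """n=5000 latent paper_like dataset at weeks 0/6 (recovery scale)."""
    return simulate_trial(clean_paper_gt, 5000, weeks=(0, 6), seed=11,
                          latent_only=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
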