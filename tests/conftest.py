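from pathlib import Path

import numpy as np
import pytest

from embryoexpress.motifs import read_meme
from embryoexpress.patterns import PatternSpec, ap_stripe
from embryoexpress.simulate import EmbryoGeometry, render_embryo

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_pwms():
    return read_meme(DATA_DIR / "synthetic_motifs.meme")


@pytest.fixture(scope="session")
def default_geometry():
    return EmbryoGeometry(semi_major=300.0, semi_minor=120.0)


@pytest.fixture(scope="session")
def noiseless_stripe_embryo(default_geometry):
    """One zero-noise rendered embryo with a single AP stripe."""
    spec = PatternSpec([ap_stripe(0.35, 0.05, 400.0)], baseline=50.0)
    image, truth = render_embryo(default_geometry, spec, noise=0.0, seed=42)
    return image, truth, spec


def brute_force_word_scores(pwm):
    """All 4^L word log-odds scores and background probabilities, vectorized."""
    lod = pwm.log_odds()
    scores = np.zeros(1)
    probs = np.ones(1)
    for i in range(len(pwm)):
        scores = (scores[:, None] + lod[i][None, :]).ravel()
        probs = (probs[:, None] * pwm.background[None, :]).ravel()
    return scores, probs


def brute_force_pvalue(scores, probs, s, slack=0.0):
    """Background probability of a word scoring >= s - slack."""
    return probs[scores >= s - slack].sum()
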