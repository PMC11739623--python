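import numpy as np
import pytest

from frugijam import io, synth
from frugijam.io import AnalysisConfig, DietMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """60 bats with a 6-plant presence/absence diet and known coefficients."""
    rng = np.random.default_rng(11)
    bats = synth.simulate_bats(60, n_plants=6, rng=rng)
    from frugijam.design import encode_design

    X, kept = encode_design(bats)
    B = np.zeros((X.k, 6))
    B[:3, :] = -0.3
    E = synth.exchangeable_correlation(6, 0.2)
    diet = synth.simulate_diet(X, B, E, io.PRESENCE_ABSENCE, rng)
    for rec, row in zip(bats, diet.values):
        rec.occurrence = row.astype(np.int8)
    return bats, diet, X


@pytest.fixture(scope="session")
def tiny_fc_samples():
    """A small fitted posterior on exact (censor-free) compositional data.

    Shared across tests that need any valid PosteriorSamples object.
    """
    from frugijam import gjam

    rng = np.random.default_rng(5)
    n, P, K = 120, 3, 2
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    raw = rng.random((n, P)) + 0.1
    Y = DietMatrix(raw / raw.sum(axis=1, keepdims=True), io.FRACTIONAL_COMPOSITION,
                   ["pa", "pb", "pc"])
    cfg = AnalysisConfig(mode=io.FRACTIONAL_COMPOSITION, n_iterations=500,
                         n_burnin=100, thin=2, n_chains=2, rng_seed=9)
    return gjam.fit(X, Y, cfg, covariate_labels=["intercept", "x1"]), X, Y, cfg


@pytest.fixture(scope="session")
def paper_shaped_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture") / "paper-shaped"
    synth.make_fixture("paper-shaped", 7, out)
    return out
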