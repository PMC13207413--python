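import numpy as np
import pytest

from screenvalid import synthetic_data as sd


@pytest.fixture
def hdaa_model():
    """4-feature model (one hydrophobe, one donor, two acceptors)."""
    return sd.gen_model("HDAA", seed=11)


@pytest.fixture
def small_pool():
    """2000-record simulated compound pool with drug-like marginals."""
    return sd.gen_compound_pool(sd.PoolSimConfig(n=2000, seed=101))


@pytest.fixture
def small_actives():
    """20 simulated actives drawn from the same marginals."""
    return sd.gen_compound_pool(sd.PoolSimConfig(n=20, active_fraction=1.0, seed=202))


def random_screen(rng: np.random.Generator, n_min: int = 5, n_max: int = 60):
    """A random labeled, scored screen with at least one of each label."""
    from screenvalid import screen_eval as se

    n = int(rng.integers(n_min, n_max))
    a = int(rng.integers(1, n))
    scores = rng.normal(size=n)
    if rng.random() < 0.3:  # exercise tie handling
        scores = np.round(scores, 1)
    labels = ["active"] * a + ["decoy"] * (n - a)
    rng.shuffle(labels)
    entries = [
        se.RankedEntry(id=f"m{i}", score=float(scores[i]), label=labels[i]) for i in range(n)
    ]
    return se.rank_screen(entries)
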