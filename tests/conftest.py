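import numpy as np
import pytest

from dvcorr import (
    ClassPair,
    EmbeddingConfig,
    Representation,
    SDTObserverPair,
    StimulusSet,
    embed_representation,
    simulate_latent_dvs,
)

PAIR_AB = ClassPair("a", "b")


def make_embedded_pair(
    rho: float,
    n_trials_per_class: int = 1000,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_features: int = 64,
    d_prime: float = 2.0,
):
    """Simulate two correlated observers and embed them with independent noise."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    cfg = SDTObserverPair(
        rho=rho, d_prime=d_prime, n_trials_per_class=n_trials_per_class,
        seed=int(seeds[0]),
    )
    dv1, dv2, stim = simulate_latent_dvs(cfg)
    rep1 = embed_representation(
        dv1, EmbeddingConfig(n_features, int(seeds[1]), noise_sd),
        seed=int(seeds[3]), observer_id="observer_1",
    )
    rep2 = embed_representation(
        dv2, EmbeddingConfig(n_features, int(seeds[2]), noise_sd),
        seed=int(seeds[4]), observer_id="observer_2",
    )
    return rep1, rep2, stim, dv1, dv2


def gaussian_two_class(
    n_per_class: int,
    mu_a,
    mu_b,
    cov,
    seed: int = 0,
    observer_id: str = "obs",
):
    """Two Gaussian classes with shared covariance as an observer."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.asarray(cov, float))
    Xa = rng.standard_normal((n_per_class, len(mu_a))) @ L.T + np.asarray(mu_a)
    Xb = rng.standard_normal((n_per_class, len(mu_b))) @ L.T + np.asarray(mu_b)
    X = np.vstack([Xa, Xb])
    labels = np.repeat(["a", "b"], n_per_class)
    ids = [f"s{i:05d}" for i in range(2 * n_per_class)]
    stim = StimulusSet(stimulus_id=np.array(ids), class_label=labels)
    return stim, Representation(observer_id=observer_id, matrix=X)


@pytest.fixture
def tiny_observer(tmp_path):
    """A 6-trial, 4-feature observer written to matrix/label files."""
    rng = np.random.default_rng(42)
    matrix = rng.standard_normal((6, 4))
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    ids = np.array([f"img{i}" for i in range(6)])
    mpath = tmp_path / "matrix.csv"
    lpath = tmp_path / "labels.csv"
    np.savetxt(mpath, matrix, delimiter=",", fmt="%.17g")
    with open(lpath, "w") as fh:
        fh.write("stimulus_id,class_label\n")
        for i, c in zip(ids, labels):
            fh.write(f"{i},{c}\n")
    return mpath, lpath, matrix, ids, labels
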