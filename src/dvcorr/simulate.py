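"""Ground-truth signal-detection simulator for validating the DVC pipeline.

Two observers share a binary classification task. Per trial, class a
contributes a latent decision-variable mean of -d'/2 and class b of +d'/2;
around the class mean the two observers' DVs are bivariate normal with unit
variances and correlation rho — the quantity every estimator downstream is
trying to recover. A shared criterion c turns DVs into biased choices
(choose class b when DV > c) without touching the DVs themselves, which is
what makes DVC criterion-invariant while kappa is not.

Latent DVs are embedded into high-dimensional feature vectors as

    x_t = dv_t * w + sum_j z_tj * u_j + eps_t

with a fixed unit signal axis w, optional task-irrelevant nuisance axes u_j
(orthogonalized against w) carrying standard-normal trial loadings, and
i.i.d. Gaussian feature noise eps. Feature noise is drawn independently per
observer and per feature, so it is independent across feature-split halves
by construction — exactly the noise model under which the split-half
attenuation correction is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import cohens_kappa
from .data import ClassPair, Representation, StimulusSet
from .decoding import ChoiceSeries, DVSeries
from .dvc import split_half_dvc

__all__ = [
    "SDTObserverPair",
    "EmbeddingConfig",
    "simulate_latent_dvs",
    "threshold_choices",
    "embed_representation",
    "bias_sweep_experiment",
]

CLASS_A = "a"
CLASS_B = "b"
PAIR = ClassPair(CLASS_A, CLASS_B)


@dataclass
class SDTObserverPair:
    """Generative ground truth for a pair of signal-detection observers.

    ``d_prime`` may be a scalar (both observers) or a per-observer pair;
    ``criterion`` is the shared decision threshold in DV units (0 is optimal
    for symmetric classes).
    """

    rho: float
    d_prime: float | tuple[float, float] = 2.0
    criterion: float = 0.0
    n_trials_per_class: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.n_trials_per_class < 2:
            raise ValueError("need at least 2 trials per class")

    @property
    def d_primes(self) -> tuple[float, float]:
        if np.isscalar(self.d_prime):
            return (float(self.d_prime), float(self.d_prime))
        d1, d2 = self.d_prime
        return (float(d1), float(d2))


@dataclass
class EmbeddingConfig:
    """How a latent DV series is embedded into a noisy feature space."""

    n_features: int
    signal_axis_seed: int = 0
    noise_sd: float = 1.0
    n_nuisance_dims: int = 0
    nuisance_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_nuisance_dims < 0:
            raise ValueError("n_nuisance_dims must be >= 0")
        if self.n_nuisance_dims >= self.n_features:
            raise ValueError("n_nuisance_dims must be < n_features")


def simulate_latent_dvs(
    config: SDTObserverPair,
) -> tuple[DVSeries, DVSeries, StimulusSet]:
    """Draw correlated latent DVs for the two observers.

    Trials are balanced across the two classes; per trial the observers'
    DVs are bivariate normal with unit variances, correlation ``rho`` and
    class means of minus/plus d'/2. Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials_per_class
    labels = np.repeat([CLASS_A, CLASS_B], n)
    ids = np.array([f"s{i:06d}" for i in range(2 * n)])
    rho = float(config.rho)
    chol = np.array([[1.0, 0.0], [rho, np.sqrt(max(0.0, 1.0 - rho * rho))]])
    z = rng.standard_normal((2 * n, 2)) @ chol.T
    signs = np.where(labels == CLASS_B, 0.5, -0.5)
    d1, d2 = config.d_primes
    stim = StimulusSet(stimulus_id=ids, class_label=labels)
    series = []
    for obs, (col, d) in enumerate([(0, d1), (1, d2)], start=1):
        series.append(
            DVSeries(
                observer_id=f"sim_observer_{obs}",
                class_pair=PAIR,
                stimulus_id=ids,
                dv=z[:, col] + signs * d,
                trial_classes=labels,
                sign_convention=CLASS_B,
            )
        )
    return series[0], series[1], stim


def threshold_choices(dv: DVSeries, criterion: float = 0.0) -> ChoiceSeries:
    """Apply a decision criterion: choose class b when DV exceeds it."""
    choice = np.where(dv.dv > criterion, dv.class_pair.class_b, dv.class_pair.class_a)
    return ChoiceSeries(
        observer_id=dv.observer_id,
        class_pair=dv.class_pair,
        stimulus_id=dv.stimulus_id,
        choice=choice,
        trial_classes=dv.trial_classes,
    )


def _orthonormal_axes(rng: np.random.Generator, n_features: int, n_axes: int):
    """A unit signal axis plus nuisance axes orthogonalized against it."""
    w = rng.standard_normal(n_features)
    w /= np.linalg.norm(w)
    axes = [w]
    for _ in range(n_axes):
        v = rng.standard_normal(n_features)
        for u in axes:
            v -= (v @ u) * u
        v /= np.linalg.norm(v)
        axes.append(v)
    return w, np.array(axes[1:])


def embed_representation(
    dv: DVSeries,
    config: EmbeddingConfig,
    seed: int,
    observer_id: str | None = None,
) -> Representation:
    """Embed a latent DV series into a noisy high-dimensional representation.

    The signal and nuisance axes are drawn from ``config.signal_axis_seed``
    (shared geometry); the per-feature Gaussian noise and the nuisance trial
    loadings are drawn from ``seed``, so two calls with different seeds give
    independent noise — use distinct seeds per observer.
    """
    rng_axes = np.random.default_rng(config.signal_axis_seed)
    w, nuisance = _orthonormal_axes(rng_axes, config.n_features, config.n_nuisance_dims)
    rng_noise = np.random.default_rng(seed)
    n = len(dv)
    X = dv.dv[:, None] * w[None, :]
    if config.n_nuisance_dims:
        loadings = rng_noise.standard_normal((n, config.n_nuisance_dims))
        X = X + (loadings * config.nuisance_sd) @ nuisance
    X = X + rng_noise.standard_normal((n, config.n_features)) * config.noise_sd
    return Representation(
        observer_id=observer_id or dv.observer_id, matrix=X
    )


def bias_sweep_experiment(
    rho: float = 0.5,
    d_prime: float = 2.0,
    criteria: list[float] = (0.0, 0.5, 1.0, 1.5),
    n_trials_per_class: int = 2000,
    seed: int = 0,
    n_features: int = 64,
    noise_sd: float = 0.7,
    n_splits: int = 5,
    k: int | None = None,
) -> pd.DataFrame:
    """Shared-criterion sweep: kappa reacts to decision bias, DVC does not.

    For each criterion c a fresh observer pair is simulated, both observers
    choose class b when their DV exceeds c, kappa is computed from the
    choices, and raw/corrected DVC from independently embedded noisy
    representations. One row per criterion with columns
    (criterion, accuracy, kappa, kappa_degenerate, raw_dvc, corrected_dvc).
    """
    criteria = list(criteria)
    if not criteria:
        raise ValueError("criteria list must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for c in criteria:
        sub = rng.integers(0, 2**31 - 1, size=6)
        cfg = SDTObserverPair(
            rho=rho,
            d_prime=d_prime,
            criterion=float(c),
            n_trials_per_class=n_trials_per_class,
            seed=int(sub[0]),
        )
        dv1, dv2, stim = simulate_latent_dvs(cfg)
        ch1 = threshold_choices(dv1, c)
        ch2 = threshold_choices(dv2, c)
        ag = cohens_kappa(ch1, ch2)
        rep1 = embed_representation(
            dv1,
            EmbeddingConfig(n_features, signal_axis_seed=int(sub[1]), noise_sd=noise_sd),
            seed=int(sub[3]),
            observer_id="observer_1",
        )
        rep2 = embed_representation(
            dv2,
            EmbeddingConfig(n_features, signal_axis_seed=int(sub[2]), noise_sd=noise_sd),
            seed=int(sub[4]),
            observer_id="observer_2",
        )
        pdvc = split_half_dvc(
            rep1, rep2, stim, PAIR, k=k, n_splits=n_splits, seed=int(sub[5])
        )
        rows.append(
            {
                "criterion": float(c),
                "accuracy": (ag.accuracy_1 + ag.accuracy_2) / 2.0,
                "kappa": ag.kappa,
                "kappa_degenerate": ag.degenerate,
                "raw_dvc": pdvc.mean_raw,
                "corrected_dvc": pdvc.mean_corrected,
            }
        )
    return pd.DataFrame(rows)
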