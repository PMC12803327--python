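"""Decision variable correlation (DVC) with split-half attenuation correction.

DVC measures the task-relevant similarity of two observers A and B: for a
given pair of classes, each observer's representation is decoded into a
per-trial decision variable (DV), and the two DV series are Pearson
correlated within each class. Conditioning on class removes the shared
class-separation component, so the statistic reflects trial-by-trial
consistency of the decision strategies rather than mere separability.

Measurement noise attenuates the raw correlation. To correct for it, each
observer's features are split into two halves, yielding four decoded series
DV_A1, DV_A2, DV_B1, DV_B2, and

    rho_corrected = r_cross / r_self

where ``r_cross`` is the geometric mean of the four cross-observer
correlations rho(A1,B1), rho(A1,B2), rho(A2,B1), rho(A2,B2) and ``r_self``
is the geometric mean of the two within-observer split-half reliabilities
rho(A1,A2) and rho(B1,B2). Under independent additive symmetric noise in
the decoded DVs this ratio is an unbiased estimate of the correlation of
the underlying noise-free signals (the classical correction for
attenuation, with the split-half correlations standing in for the unknown
reliabilities).

The primary entry point is the :class:`DecisionVariableCorrelation` model,
whose :meth:`~DecisionVariableCorrelation.fit` returns a
:class:`DVCResults` carrying per-pair, per-class raw and corrected values,
their averages and diagnostics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    ClassPair,
    Representation,
    StimulusSet,
    align_observers,
    load_observer,
    make_feature_split,
    subset_observer,
)
from .decoding import decode_dv, DVSeries

__all__ = [
    "PairDVC",
    "DVCResults",
    "DVCMatrix",
    "DecisionVariableCorrelation",
    "raw_pair_dvc",
    "split_half_dvc",
    "dvc_between",
    "dvc_matrix",
    "correct_attenuation",
    "fisher_mean",
]

#: reliabilities at or below this floor make the corrected ratio explode;
#: the corrected value is reported missing instead of clipped
DEFAULT_RELIABILITY_FLOOR = 0.05

DEFAULT_N_SPLITS = 10

_CLIP = 1.0 - 1e-15


def _derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed from a run seed and a string label (order-free)."""
    rng = np.random.default_rng([int(seed), zlib.crc32(label.encode())])
    return int(rng.integers(0, 2**31 - 1))


def fisher_mean(r: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Fisher-z average of correlations (tanh of the mean arctanh)."""
    z = np.arctanh(np.clip(np.asarray(r, float), -_CLIP, _CLIP))
    return np.tanh(z.mean(axis=axis))


def _pearson(x: np.ndarray, y: np.ndarray, context: str) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError(f"zero variance within {context}; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# raw (uncorrected) DVC


def _check_series_match(dv_1: DVSeries, dv_2: DVSeries) -> None:
    if dv_1.class_pair != dv_2.class_pair:
        raise ValueError("DV series are for different class pairs")
    if dv_1.sign_convention != dv_2.sign_convention:
        raise ValueError("DV series use different sign conventions")
    if not np.array_equal(dv_1.stimulus_id, dv_2.stimulus_id):
        raise ValueError("DV series cover different trials or orders")


def raw_pair_dvc(dv_1: DVSeries, dv_2: DVSeries) -> tuple[float, float]:
    """Per-class Pearson correlations of two observers' DVs.

    Returns one correlation per class of the pair, computed over that
    class's trials only, in canonical class order.
    """
    _check_series_match(dv_1, dv_2)
    out = []
    for cls in dv_1.class_pair.classes:
        m = dv_1.class_mask(cls)
        if m.sum() < 3:
            raise ValueError(f"class {cls!r} has < 3 trials; correlation unreliable")
        out.append(_pearson(dv_1.dv[m], dv_2.dv[m], f"class {cls!r}"))
    return tuple(out)


# ---------------------------------------------------------------------------
# attenuation correction arithmetic


def correct_attenuation(
    cross: np.ndarray,
    rel_1: float,
    rel_2: float,
    reliability_floor: float = DEFAULT_RELIABILITY_FLOOR,
) -> tuple[float, float, float, tuple[str, ...]]:
    """Form the corrected DVC from four cross correlations and two reliabilities.

    Returns ``(r_cross, r_self, corrected, flags)``. The fourth root of the
    cross product is taken on its absolute value with the sign of the
    Fisher-z mean of the four correlations, which reduces to the plain
    geometric mean whenever the signs agree (and flags the estimate when
    they do not). Reliabilities at or below ``reliability_floor`` make the
    corrected value missing (NaN) rather than clipped; corrected magnitudes
    above 1 are reported as computed, with a flag.
    """
    cross = np.asarray(cross, dtype=float)
    if cross.shape != (4,):
        raise ValueError("need exactly four cross-observer correlations")
    flags: list[str] = []
    sign = 1.0 if float(np.arctanh(np.clip(cross, -_CLIP, _CLIP)).mean()) >= 0 else -1.0
    nonzero_signs = set(np.sign(cross[cross != 0]))
    if len(nonzero_signs) > 1:
        flags.append("cross_sign_disagreement")
    r_cross = sign * float(np.abs(np.prod(cross)) ** 0.25)
    if rel_1 <= reliability_floor or rel_2 <= reliability_floor:
        flags.append("low_reliability")
        return r_cross, float("nan"), float("nan"), tuple(flags)
    r_self = float(np.sqrt(rel_1 * rel_2))
    corrected = r_cross / r_self
    if abs(corrected) > 1.0:
        flags.append("exceeds_unity")
    return r_cross, r_self, corrected, tuple(flags)


# ---------------------------------------------------------------------------
# split-half corrected DVC for one class pair


@dataclass
class PairDVC:
    """Raw and noise-corrected DVC values for one class pair.

    Arrays are indexed by ``classes`` (the two classes in canonical order,
    or the single entry ``("pooled",)`` in pooled mode). ``corrected``
    entries are NaN where a reliability fell below the floor.
    """

    class_pair: ClassPair
    classes: tuple[str, ...]
    raw: np.ndarray
    corrected: np.ndarray
    r_cross: np.ndarray
    r_self_1: np.ndarray
    r_self_2: np.ndarray
    n_trials_per_class: dict[str, int]
    flags: dict[str, tuple[str, ...]]
    n_splits: int
    seed: int

    @property
    def mean_raw(self) -> float:
        return float(np.mean(self.raw))

    @property
    def mean_corrected(self) -> float:
        finite = self.corrected[np.isfinite(self.corrected)]
        return float(finite.mean()) if finite.size else float("nan")


def _class_groups(
    dv: DVSeries, mode: str
) -> list[tuple[str, np.ndarray]]:
    if mode == "per_class":
        return [(cls, dv.class_mask(cls)) for cls in dv.class_pair.classes]
    if mode == "pooled":
        return [("pooled", np.ones(len(dv), dtype=bool))]
    raise ValueError(f"unknown mode {mode!r} (expected 'per_class' or 'pooled')")


def split_half_dvc(
    rep_1: Representation,
    rep_2: Representation,
    stim: StimulusSet,
    pair: ClassPair,
    k: int | None = None,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int = 0,
    reliability_floor: float = DEFAULT_RELIABILITY_FLOOR,
    mode: str = "per_class",
) -> PairDVC:
    """Raw and split-half noise-corrected DVC for one class pair.

    For each of ``n_splits`` seeded feature splits of each observer, decodes
    DV_A1, DV_A2, DV_B1, DV_B2 and computes, per class, the four cross
    correlations and the two split-half reliabilities. The six correlations
    are Fisher-z averaged across splits before the corrected ratio is
    formed. Each observer's split seeds derive from (seed, observer_id), so
    swapping the observer arguments returns identical numbers.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    dv_a = decode_dv(rep_1, stim, pair, k=k)
    dv_b = decode_dv(rep_2, stim, pair, k=k)
    groups = _class_groups(dv_a, mode)
    for cls, m in groups:
        if m.sum() < 3:
            raise ValueError(f"class {cls!r} has < 3 trials in pair {pair}")

    raw = np.array(
        [_pearson(dv_a.dv[m], dv_b.dv[m], f"class {cls!r}") for cls, m in groups]
    )

    seeds_1 = np.random.default_rng(
        [_derive_seed(seed, rep_1.observer_id)]
    ).integers(0, 2**31 - 1, size=n_splits)
    seeds_2 = np.random.default_rng(
        [_derive_seed(seed, rep_2.observer_id)]
    ).integers(0, 2**31 - 1, size=n_splits)

    corrs = np.empty((n_splits, len(groups), 6))
    for s in range(n_splits):
        sp1 = make_feature_split(rep_1.n_features, int(seeds_1[s]))
        sp2 = make_feature_split(rep_2.n_features, int(seeds_2[s]))
        a1 = decode_dv(rep_1, stim, pair, k=k, feature_subset=sp1.half_1).dv
        a2 = decode_dv(rep_1, stim, pair, k=k, feature_subset=sp1.half_2).dv
        b1 = decode_dv(rep_2, stim, pair, k=k, feature_subset=sp2.half_1).dv
        b2 = decode_dv(rep_2, stim, pair, k=k, feature_subset=sp2.half_2).dv
        for g, (cls, m) in enumerate(groups):
            ctx = f"class {cls!r}, split {s}"
            corrs[s, g] = [
                _pearson(a1[m], b1[m], ctx),
                _pearson(a1[m], b2[m], ctx),
                _pearson(a2[m], b1[m], ctx),
                _pearson(a2[m], b2[m], ctx),
                _pearson(a1[m], a2[m], ctx),
                _pearson(b1[m], b2[m], ctx),
            ]

    zbar = np.asarray(fisher_mean(corrs, axis=0))  # (n_groups, 6)
    corrected = np.empty(len(groups))
    r_cross = np.empty(len(groups))
    r_self_1 = zbar[:, 4].copy()
    r_self_2 = zbar[:, 5].copy()
    flags: dict[str, tuple[str, ...]] = {}
    for g, (cls, _) in enumerate(groups):
        rc, _, corr_val, fl = correct_attenuation(
            zbar[g, :4], zbar[g, 4], zbar[g, 5], reliability_floor
        )
        r_cross[g] = rc
        corrected[g] = corr_val
        flags[cls] = fl

    return PairDVC(
        class_pair=pair,
        classes=tuple(cls for cls, _ in groups),
        raw=raw,
        corrected=corrected,
        r_cross=r_cross,
        r_self_1=r_self_1,
        r_self_2=r_self_2,
        n_trials_per_class={cls: int(m.sum()) for cls, m in groups},
        flags=flags,
        n_splits=int(n_splits),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# results container (statsmodels-style)


class DVCResults:
    """Estimates, uncertainties and diagnostics of a fitted DVC comparison.

    ``mean_raw`` / ``mean_corrected`` are arithmetic means over all defined
    per-class values (two per class pair); missing corrected values are
    excluded and counted in ``coverage``. Standard errors are the spread of
    the per-class values across pairs and classes, a descriptive dispersion
    rather than a sampling-theory SE.
    """

    def __init__(
        self,
        observer_1: str,
        observer_2: str,
        pair_values: list[PairDVC],
        n_splits: int,
        seed: int,
        mode: str,
        reliability_floor: float,
    ):
        self.observer_1 = observer_1
        self.observer_2 = observer_2
        self.pair_values = pair_values
        self.n_splits = int(n_splits)
        self.split_seed = int(seed)
        self.mode = mode
        self.reliability_floor = float(reliability_floor)

    @property
    def _raw_values(self) -> np.ndarray:
        return np.concatenate([p.raw for p in self.pair_values])

    @property
    def _corrected_values(self) -> np.ndarray:
        return np.concatenate([p.corrected for p in self.pair_values])

    @property
    def n_values(self) -> int:
        return int(self._raw_values.size)

    @property
    def n_corrected_defined(self) -> int:
        return int(np.isfinite(self._corrected_values).sum())

    @property
    def coverage(self) -> float:
        return self.n_corrected_defined / self.n_values

    @property
    def mean_raw(self) -> float:
        return float(self._raw_values.mean())

    @property
    def mean_corrected(self) -> float:
        vals = self._corrected_values
        finite = vals[np.isfinite(vals)]
        return float(finite.mean()) if finite.size else float("nan")

    @property
    def se_raw(self) -> float:
        v = self._raw_values
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")

    @property
    def se_corrected(self) -> float:
        v = self._corrected_values
        v = v[np.isfinite(v)]
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")

    def pair_table(self) -> pd.DataFrame:
        """Tidy table: one row per (class pair, class)."""
        rows = []
        for p in self.pair_values:
            for g, cls in enumerate(p.classes):
                rows.append(
                    {
                        "class_a": p.class_pair.class_a,
                        "class_b": p.class_pair.class_b,
                        "class": cls,
                        "n_trials": p.n_trials_per_class[cls],
                        "raw_dvc": p.raw[g],
                        "corrected_dvc": p.corrected[g],
                        "r_cross": p.r_cross[g],
                        "r_self_1": p.r_self_1[g],
                        "r_self_2": p.r_self_2[g],
                        "flags": ";".join(p.flags[cls]),
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "observer_1": self.observer_1,
                    "observer_2": self.observer_2,
                    "n_class_pairs": len(self.pair_values),
                    "n_values": self.n_values,
                    "mean_raw": self.mean_raw,
                    "se_raw": self.se_raw,
                    "mean_corrected": self.mean_corrected,
                    "se_corrected": self.se_corrected,
                    "coverage": self.coverage,
                    "n_splits": self.n_splits,
                    "seed": self.split_seed,
                    "mode": self.mode,
                }
            ]
        )

    def summary(self) -> str:
        bar = "=" * 58
        rule = "-" * 58
        lines = [
            bar,
            "Decision Variable Correlation".center(58),
            bar,
            f"Observer 1:        {self.observer_1}",
            f"Observer 2:        {self.observer_2}",
            f"Class pairs:       {len(self.pair_values)}"
            f"    Per-class values: {self.n_values}",
            f"Splits per pair:   {self.n_splits}    Mode: {self.mode}",
            rule,
            f"Mean raw DVC:       {self.mean_raw: .4f}   (SE {self.se_raw:.4f})",
            f"Mean corrected DVC: {self.mean_corrected: .4f}   (SE {self.se_corrected:.4f})",
            f"Coverage:           {self.n_corrected_defined}/{self.n_values}"
            " corrected values defined",
            bar,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DVCResults {self.observer_1} vs {self.observer_2}: "
            f"raw={self.mean_raw:.3f} corrected={self.mean_corrected:.3f}>"
        )


def dvc_between(
    rep_1: Representation,
    rep_2: Representation,
    stim: StimulusSet,
    k: int | None = None,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int = 0,
    reliability_floor: float = DEFAULT_RELIABILITY_FLOOR,
    mode: str = "per_class",
) -> DVCResults:
    """Corrected and raw DVC between two observers over all class pairs.

    The reported means average the per-class values of every canonical
    class pair (N(N-1) values for N classes in per-class mode). Per-pair
    seeds derive from the pair label, so the result is independent of
    iteration order and exactly symmetric in the observer arguments.
    """
    rep_1.validate_against(stim)
    rep_2.validate_against(stim)
    pair_values = [
        split_half_dvc(
            rep_1,
            rep_2,
            stim,
            pair,
            k=k,
            n_splits=n_splits,
            seed=_derive_seed(seed, str(pair)),
            reliability_floor=reliability_floor,
            mode=mode,
        )
        for pair in stim.class_pairs()
    ]
    return DVCResults(
        observer_1=rep_1.observer_id,
        observer_2=rep_2.observer_id,
        pair_values=pair_values,
        n_splits=n_splits,
        seed=seed,
        mode=mode,
        reliability_floor=reliability_floor,
    )


# ---------------------------------------------------------------------------
# model class


class DecisionVariableCorrelation:
    """Model object: two observers on a shared stimulus set.

    Parameters
    ----------
    rep_1, rep_2
        Observer representations, rows aligned to ``stimuli``.
    stimuli
        Shared stimulus ids and class labels.
    k
        Reduced dimensionality used for both observers (None = data-limited
        default, min(50, n_pair_trials // 10, rank)).
    n_splits
        Number of random feature splits averaged per class pair.
    reliability_floor
        Split-half reliability below which the corrected value is missing.
    mode
        'per_class' (default) correlates within each class; 'pooled'
        correlates over the pooled two-class trials.

    ``fit(seed)`` runs the split-half procedure for every class pair and
    returns a :class:`DVCResults`.
    """

    def __init__(
        self,
        rep_1: Representation,
        rep_2: Representation,
        stimuli: StimulusSet,
        k: int | None = None,
        n_splits: int = DEFAULT_N_SPLITS,
        reliability_floor: float = DEFAULT_RELIABILITY_FLOOR,
        mode: str = "per_class",
    ):
        rep_1.validate_against(stimuli)
        rep_2.validate_against(stimuli)
        self.rep_1 = rep_1
        self.rep_2 = rep_2
        self.stimuli = stimuli
        self.k = k
        self.n_splits = int(n_splits)
        self.reliability_floor = float(reliability_floor)
        if mode not in ("per_class", "pooled"):
            raise ValueError("mode must be 'per_class' or 'pooled'")
        self.mode = mode

    @classmethod
    def from_files(
        cls,
        matrix_1: str | Path,
        labels_1: str | Path,
        matrix_2: str | Path,
        labels_2: str | Path,
        observer_1: str | None = None,
        observer_2: str | None = None,
        **kwargs,
    ) -> "DecisionVariableCorrelation":
        """Load two observers from matrix/label files and align them by id."""
        stim_1, rep_1 = load_observer(matrix_1, labels_1, observer_id=observer_1)
        stim_2, rep_2 = load_observer(matrix_2, labels_2, observer_id=observer_2)
        aln = align_observers(stim_1, stim_2)
        stim = aln.stimulus_set()
        _, rep_1 = subset_observer(stim_1, rep_1, aln.indices_1)
        _, rep_2 = subset_observer(stim_2, rep_2, aln.indices_2)
        return cls(rep_1, rep_2, stim, **kwargs)

    def fit(self, seed: int = 0) -> DVCResults:
        return dvc_between(
            self.rep_1,
            self.rep_2,
            self.stimuli,
            k=self.k,
            n_splits=self.n_splits,
            seed=seed,
            reliability_floor=self.reliability_floor,
            mode=self.mode,
        )


# ---------------------------------------------------------------------------
# observer-by-observer matrices


@dataclass
class DVCMatrix:
    """Symmetric observer-by-observer DVC matrices (unit diagonal)."""

    raw: pd.DataFrame
    corrected: pd.DataFrame
    results: dict[tuple[str, str], DVCResults] = field(default_factory=dict)

    @property
    def dissimilarity_raw(self) -> pd.DataFrame:
        return 1.0 - self.raw

    @property
    def dissimilarity_corrected(self) -> pd.DataFrame:
        return 1.0 - self.corrected


def dvc_matrix(
    observers: list[Representation],
    stim: StimulusSet,
    k: int | None = None,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int = 0,
    reliability_floor: float = DEFAULT_RELIABILITY_FLOOR,
    mode: str = "per_class",
) -> DVCMatrix:
    """All-pairs mean DVCs between observers aligned to one stimulus set.

    Each unordered observer pair is computed once; the diagonal is 1 by
    convention (an observer's similarity to itself is not estimated).
    """
    if len(observers) < 2:
        raise ValueError("need at least 2 observers for a DVC matrix")
    ids = [r.observer_id for r in observers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate observer_id in observer list")
    n = len(observers)
    raw = np.eye(n)
    corrected = np.eye(n)
    results: dict[tuple[str, str], DVCResults] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = dvc_between(
                observers[i],
                observers[j],
                stim,
                k=k,
                n_splits=n_splits,
                seed=seed,
                reliability_floor=reliability_floor,
                mode=mode,
            )
            raw[i, j] = raw[j, i] = res.mean_raw
            corrected[i, j] = corrected[j, i] = res.mean_corrected
            results[(ids[i], ids[j])] = res
    return DVCMatrix(
        raw=pd.DataFrame(raw, index=ids, columns=ids),
        corrected=pd.DataFrame(corrected, index=ids, columns=ids),
        results=results,
    )
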