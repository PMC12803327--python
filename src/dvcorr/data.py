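"""Containers and text I/O for observer representations on a shared stimulus set.

An *observer* is anything that yields a trials x features activation matrix
for a fixed set of stimuli: a recorded neural population (e.g. macaque V4/IT
units) or a layer of an artificial network. Trials are identified by a
stimulus id string and aligned across observers by id, never by row
position — every downstream comparison is image-by-image and a silent
positional misalignment would corrupt it.

Matrix files are delimited text (comma or tab, auto-detected) with an
optional header row of feature ids and one trial per row, stored at full
double precision. Label files are two-column delimited text
(stimulus_id, class_label) with a header, in the same row order as the
matrix.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClassPair",
    "StimulusSet",
    "Representation",
    "FeatureSplit",
    "Alignment",
    "load_observer",
    "save_observer",
    "save_matrix",
    "save_labels",
    "align_observers",
    "align_many",
    "subset_observer",
    "make_feature_split",
]

#: text format for matrix files; %.17g round-trips IEEE doubles exactly
FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True, order=True)
class ClassPair:
    """An unordered pair of class labels in canonical (lexicographic) order.

    Construction canonicalizes the order, so each unordered pair has exactly
    one representation and ``class_b`` is always the lexicographically later
    label. By convention ``class_b`` is the positive class of the decision
    axis.
    """

    class_a: str
    class_b: str

    def __post_init__(self) -> None:
        a, b = str(self.class_a), str(self.class_b)
        if a == b:
            raise ValueError("a class pair needs two distinct classes")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "class_a", a)
        object.__setattr__(self, "class_b", b)

    def __str__(self) -> str:
        return f"{self.class_a}|{self.class_b}"

    @classmethod
    def from_string(cls, text: str) -> "ClassPair":
        a, _, b = text.partition("|")
        return cls(a, b)

    @property
    def classes(self) -> tuple[str, str]:
        return (self.class_a, self.class_b)


@dataclass
class StimulusSet:
    """The shared trial index: stimulus ids and class labels, one per trial."""

    stimulus_id: np.ndarray
    class_label: np.ndarray

    def __post_init__(self) -> None:
        self.stimulus_id = np.asarray(self.stimulus_id, dtype=str)
        self.class_label = np.asarray(self.class_label, dtype=str)
        if self.stimulus_id.ndim != 1 or self.class_label.ndim != 1:
            raise ValueError("stimulus ids and class labels must be 1-D")
        if self.stimulus_id.size != self.class_label.size:
            raise ValueError(
                "row-count mismatch: "
                f"{self.stimulus_id.size} stimulus ids vs "
                f"{self.class_label.size} class labels"
            )
        uniq, counts = np.unique(self.stimulus_id, return_counts=True)
        if (counts > 1).any():
            dupes = uniq[counts > 1][:5]
            raise ValueError(f"duplicate stimulus_id values: {list(dupes)}")
        classes, ccounts = np.unique(self.class_label, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        small = classes[ccounts < 2]
        if small.size:
            raise ValueError(f"class {str(small[0])!r} has < 2 trials")

    @property
    def n_trials(self) -> int:
        return int(self.stimulus_id.size)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(np.unique(self.class_label)))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_pairs(self) -> list[ClassPair]:
        """All canonical unordered class pairs, lexicographically ordered."""
        return [ClassPair(a, b) for a, b in combinations(self.classes, 2)]

    def pair_mask(self, pair: ClassPair) -> np.ndarray:
        missing = [c for c in pair.classes if c not in self.classes]
        if missing:
            raise ValueError(f"class {missing[0]!r} not present in stimulus set")
        return np.isin(self.class_label, pair.classes)


@dataclass
class Representation:
    """One observer's trials x features activation matrix."""

    observer_id: str
    matrix: np.ndarray
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("representation matrix must be 2-D (trials x features)")
        if self.matrix.shape[1] < 2:
            raise ValueError("representation needs >= 2 features")
        if not np.isfinite(self.matrix).all():
            raise ValueError(
                f"representation {self.observer_id!r} contains missing/non-finite values"
            )
        if self.feature_ids is not None:
            self.feature_ids = [str(f) for f in self.feature_ids]
            if len(self.feature_ids) != self.matrix.shape[1]:
                raise ValueError("feature_ids length does not match feature count")

    @property
    def n_trials(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.matrix.shape[1])

    def validate_against(self, stim: StimulusSet) -> None:
        if self.n_trials != stim.n_trials:
            raise ValueError(
                "row-count mismatch: matrix has "
                f"{self.n_trials} rows but stimulus set has {stim.n_trials} trials"
            )


@dataclass(frozen=True)
class FeatureSplit:
    """A random disjoint halving of an observer's feature indices."""

    half_1: np.ndarray
    half_2: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        h1 = np.sort(np.asarray(self.half_1, dtype=int))
        h2 = np.sort(np.asarray(self.half_2, dtype=int))
        if np.intersect1d(h1, h2).size:
            raise ValueError("feature split halves overlap")
        if abs(h1.size - h2.size) > 1:
            raise ValueError("feature split halves differ in size by more than 1")
        object.__setattr__(self, "half_1", h1)
        object.__setattr__(self, "half_2", h2)


def make_feature_split(n_features: int, seed: int) -> FeatureSplit:
    """Uniformly random disjoint halving of ``range(n_features)``.

    Reproducible from ``seed``; for odd counts the halves differ in size by
    one. This realizes the split of an observer's units into two independent
    halves used by the attenuation correction.
    """
    if n_features < 2:
        raise ValueError("need n_features >= 2 to split features in half")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_features)
    half = n_features // 2
    return FeatureSplit(half_1=perm[:half], half_2=perm[half:], seed=int(seed))


# ---------------------------------------------------------------------------
# file I/O


def _sniff_matrix(path: str | Path) -> tuple[str, bool]:
    """Detect the delimiter and whether a feature-id header row is present."""
    with open(path, "r") as fh:
        first = fh.readline()
    sep = "," if "," in first else ("\t" if "\t" in first else r"\s+")
    tokens = [t for t in first.strip().split(None if sep == r"\s+" else sep) if t != ""]
    if not tokens:
        raise ValueError(f"empty matrix file: {path}")
    has_header = False
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    return sep, has_header


def load_matrix(path: str | Path, observer_id: str | None = None) -> Representation:
    """Read a delimited-text matrix (optional feature-id header row)."""
    sep, has_header = _sniff_matrix(path)
    if sep == r"\s+":
        feature_ids = None
        if has_header:
            with open(path) as fh:
                feature_ids = fh.readline().split()
        matrix = np.loadtxt(path, skiprows=1 if has_header else 0, ndmin=2)
    else:
        # round_trip parsing: the default fast converter can be off by 1 ulp,
        # which split-half correlations are sensitive to
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if has_header else None,
            float_precision="round_trip",
        )
        feature_ids = [str(c) for c in df.columns] if has_header else None
        matrix = df.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise ValueError(f"matrix file {path} contains missing values")
    if observer_id is None:
        observer_id = Path(path).stem
    return Representation(observer_id=observer_id, matrix=matrix, feature_ids=feature_ids)


def load_labels(path: str | Path) -> StimulusSet:
    """Read a two-column (stimulus_id, class_label) label file with header."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (stimulus_id, class_label)")
    if df.iloc[:, :2].isna().any().any():
        raise ValueError(f"label file {path} contains missing values")
    return StimulusSet(
        stimulus_id=df.iloc[:, 0].to_numpy(), class_label=df.iloc[:, 1].to_numpy()
    )


def load_observer(
    matrix_path: str | Path,
    labels_path: str | Path,
    observer_id: str | None = None,
) -> tuple[StimulusSet, Representation]:
    """Load and validate one observer: matrix + labels in shared row order."""
    rep = load_matrix(matrix_path, observer_id=observer_id)
    stim = load_labels(labels_path)
    rep.validate_against(stim)
    return stim, rep


def save_matrix(rep: Representation, path: str | Path) -> None:
    cols = rep.feature_ids or [f"f{i}" for i in range(rep.n_features)]
    pd.DataFrame(rep.matrix, columns=cols).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def save_labels(stim: StimulusSet, path: str | Path) -> None:
    pd.DataFrame(
        {"stimulus_id": stim.stimulus_id, "class_label": stim.class_label}
    ).to_csv(path, index=False)


def save_observer(
    stim: StimulusSet,
    rep: Representation,
    matrix_path: str | Path,
    labels_path: str | Path,
) -> None:
    rep.validate_against(stim)
    save_matrix(rep, matrix_path)
    save_labels(stim, labels_path)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class Alignment:
    """Ordered intersection of two observers' stimuli and their row indices."""

    stimulus_id: np.ndarray
    class_label: np.ndarray
    indices_1: np.ndarray
    indices_2: np.ndarray
    dropped_classes: tuple[str, ...] = ()

    def stimulus_set(self) -> StimulusSet:
        return StimulusSet(stimulus_id=self.stimulus_id, class_label=self.class_label)


def _positions(stim: StimulusSet) -> dict[str, int]:
    return {sid: i for i, sid in enumerate(stim.stimulus_id)}


def align_observers(set_1: StimulusSet, set_2: StimulusSet) -> Alignment:
    """Match trials of two observers by stimulus id.

    Returns the shared stimuli (in ``set_1`` order) with per-observer row
    indices. Classes left with fewer than 2 shared trials are dropped with a
    warning; an empty intersection is an error, as is a label disagreement
    on a shared stimulus.
    """
    pos2 = _positions(set_2)
    shared_mask = np.array([sid in pos2 for sid in set_1.stimulus_id])
    if not shared_mask.any():
        raise ValueError("no shared stimuli between the two observers")
    ids = set_1.stimulus_id[shared_mask]
    labels = set_1.class_label[shared_mask]
    idx2 = np.array([pos2[sid] for sid in ids])
    mismatch = labels != set_2.class_label[idx2]
    if mismatch.any():
        bad = ids[mismatch][0]
        raise ValueError(f"class label disagreement for shared stimulus {bad!r}")

    all_classes = set(set_1.classes) | set(set_2.classes)
    keep_classes, counts = np.unique(labels, return_counts=True)
    retained = set(keep_classes[counts >= 2])
    dropped = tuple(sorted(all_classes - retained))
    if dropped:
        warnings.warn(
            f"classes dropped in alignment (fewer than 2 shared trials): {dropped}",
            stacklevel=2,
        )
    keep = np.isin(labels, sorted(retained))
    idx1 = np.flatnonzero(shared_mask)[keep]
    return Alignment(
        stimulus_id=ids[keep],
        class_label=labels[keep],
        indices_1=idx1,
        indices_2=idx2[keep],
        dropped_classes=dropped,
    )


def subset_observer(
    stim: StimulusSet, rep: Representation, indices: np.ndarray
) -> tuple[StimulusSet, Representation]:
    """Restrict an observer to the given trial rows (e.g. from an Alignment)."""
    indices = np.asarray(indices, dtype=int)
    sub_stim = StimulusSet(
        stimulus_id=stim.stimulus_id[indices], class_label=stim.class_label[indices]
    )
    sub_rep = Representation(
        observer_id=rep.observer_id,
        matrix=rep.matrix[indices],
        feature_ids=rep.feature_ids,
    )
    return sub_stim, sub_rep


def align_many(
    observers: list[tuple[StimulusSet, Representation]],
) -> tuple[StimulusSet, list[Representation]]:
    """Align several observers onto their common stimulus intersection."""
    if len(observers) < 2:
        raise ValueError("need at least 2 observers to align")
    base_stim, base_rep = observers[0]
    stim, reps = base_stim, [base_rep]
    for other_stim, other_rep in observers[1:]:
        aln = align_observers(stim, other_stim)
        stim = aln.stimulus_set()
        reps = [
            Representation(r.observer_id, r.matrix[aln.indices_1], r.feature_ids)
            for r in reps
        ]
        _, sub = subset_observer(other_stim, other_rep, aln.indices_2)
        reps.append(sub)
    return stim, reps
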