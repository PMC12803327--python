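"""Cohen's-kappa error consistency and its accuracy-difference ceiling.

Kappa measures chance-corrected agreement of two observers' binary choices,
kappa = (p_o - p_e) / (1 - p_e), with the expected agreement p_e formed
from each observer's own marginal choice frequencies (Cohen's original
definition, not Scott's pooled pi). Because p_e depends on the marginals,
kappa is bounded above by a function of the two observers' accuracies and
the class balance: observers with very different accuracies cannot agree
perfectly no matter how correlated their decision variables are. The bound
is computed exactly by optimizing over the joint choice distribution
consistent with the fixed marginal accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .data import ClassPair
from .decoding import ChoiceSeries
from .dvc import PairDVC

__all__ = [
    "AgreementResult",
    "cohens_kappa",
    "kappa_from_contingency",
    "kappa_upper_bound",
    "kappa_vs_dvc_table",
]


@dataclass
class AgreementResult:
    """Kappa, agreement rates, accuracies and decision biases for one pair.

    ``contingency`` counts joint choices, rows = observer 1's choice and
    columns = observer 2's, both in canonical class order (class_a first).
    ``bias`` is the signed over-choice of the positive class: the fraction
    of trials on which the observer chose class_b minus the fraction of
    class_b trials. ``degenerate`` marks constant choice series, for which
    kappa is reported as 0 when p_e = 1.
    """

    class_pair: ClassPair
    kappa: float
    p_o: float
    p_e: float
    accuracy_1: float
    accuracy_2: float
    bias_1: float
    bias_2: float
    contingency: np.ndarray
    n_trials: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class_pair": str(self.class_pair),
                    "kappa": self.kappa,
                    "p_o": self.p_o,
                    "p_e": self.p_e,
                    "accuracy_1": self.accuracy_1,
                    "accuracy_2": self.accuracy_2,
                    "bias_1": self.bias_1,
                    "bias_2": self.bias_2,
                    "n_trials": self.n_trials,
                    "degenerate": self.degenerate,
                }
            ]
        )


def kappa_from_contingency(table: np.ndarray) -> tuple[float, float, float, bool]:
    """Kappa, p_o and p_e from a 2x2 joint choice-count table.

    Returns ``(kappa, p_o, p_e, degenerate)``; when p_e = 1 (both observers
    constant and identical) kappa is defined as 0 with the degeneracy flag.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("contingency must be a nonnegative 2x2 count table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p = t / n
    p_o = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        return 0.0, p_o, p_e, True
    return float((p_o - p_e) / (1.0 - p_e)), p_o, p_e, False


def cohens_kappa(choices_1: ChoiceSeries, choices_2: ChoiceSeries) -> AgreementResult:
    """Cohen's kappa between two observers' choices on the same trials."""
    if choices_1.class_pair != choices_2.class_pair:
        raise ValueError("choice series are for different class pairs")
    if not np.array_equal(choices_1.stimulus_id, choices_2.stimulus_id):
        raise ValueError("choice series cover different trials or orders")
    if not np.array_equal(choices_1.trial_classes, choices_2.trial_classes):
        raise ValueError("choice series disagree on true class labels")
    pair = choices_1.class_pair
    c1 = (choices_1.choice == pair.class_b).astype(int)
    c2 = (choices_2.choice == pair.class_b).astype(int)
    table = np.zeros((2, 2))
    np.add.at(table, (c1, c2), 1)
    kappa, p_o, p_e, degen = kappa_from_contingency(table)
    # a constant rater makes kappa formally 0/defined but uninformative
    degen = degen or c1.std() == 0 or c2.std() == 0
    base_rate = float(np.mean(choices_1.trial_classes == pair.class_b))
    return AgreementResult(
        class_pair=pair,
        kappa=kappa,
        p_o=p_o,
        p_e=p_e,
        accuracy_1=choices_1.accuracy,
        accuracy_2=choices_2.accuracy,
        bias_1=float(c1.mean()) - base_rate,
        bias_2=float(c2.mean()) - base_rate,
        contingency=table,
        n_trials=len(choices_1),
        degenerate=degen,
    )


# ---------------------------------------------------------------------------
# accuracy-difference upper bound


def _kappa_at(a1a, a2a, acc1, acc2, beta):
    """Kappa under maximal within-class coupling, given per-class accuracies.

    ``a1a`` / ``a2a`` are the observers' accuracies on class a; class-b
    accuracies follow from the overall accuracies and balance. With the
    per-class accuracies fixed the choice marginals (hence p_e) are fixed
    and kappa is maximized by the maximal-overlap coupling within each
    class, p(agree | class) = 1 - |a1 - a2| there.
    """
    a1a = np.asarray(a1a, dtype=float)
    a2a = np.asarray(a2a, dtype=float)
    a1b = (acc1 - (1.0 - beta) * a1a) / beta
    a2b = (acc2 - (1.0 - beta) * a2a) / beta
    feasible = (a1b >= -1e-12) & (a1b <= 1 + 1e-12) & (a2b >= -1e-12) & (a2b <= 1 + 1e-12)
    a1b = np.clip(a1b, 0.0, 1.0)
    a2b = np.clip(a2b, 0.0, 1.0)
    p1b = (1.0 - beta) * (1.0 - a1a) + beta * a1b
    p2b = (1.0 - beta) * (1.0 - a2a) + beta * a2b
    p_o = (1.0 - beta) * (1.0 - np.abs(a1a - a2a)) + beta * (1.0 - np.abs(a1b - a2b))
    p_e = p1b * p2b + (1.0 - p1b) * (1.0 - p2b)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(
            p_e < 1.0 - 1e-12,
            (p_o - p_e) / (1.0 - p_e),
            np.where(p_o > 1.0 - 1e-12, 1.0, 0.0),
        )
    return np.where(feasible, kappa, -np.inf)


def kappa_upper_bound(
    accuracy_1: float, accuracy_2: float, class_balance: float = 0.5
) -> float:
    """Maximum achievable kappa given the two accuracies and class balance.

    Maximizes kappa over all joint choice distributions whose marginal
    accuracies match ``accuracy_1`` and ``accuracy_2`` at the given fraction
    of class-b trials. Identical accuracies admit perfect agreement (bound
    1) at any balance. Computed by a vectorized grid search over the
    per-class accuracy allocations followed by a simplex polish.
    """
    for name, v in (("accuracy_1", accuracy_1), ("accuracy_2", accuracy_2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must be strictly between 0 and 1")
    beta = float(class_balance)

    def box(acc):
        lo = max(0.0, (acc - beta) / (1.0 - beta))
        hi = min(1.0, acc / (1.0 - beta))
        return lo, hi

    lo1, hi1 = box(accuracy_1)
    lo2, hi2 = box(accuracy_2)
    g1 = np.linspace(lo1, hi1, 401)
    g2 = np.linspace(lo2, hi2, 401)
    K = _kappa_at(g1[:, None], g2[None, :], accuracy_1, accuracy_2, beta)
    i, j = np.unravel_index(np.argmax(K), K.shape)
    best = float(K[i, j])

    def neg(x):
        a1 = min(max(x[0], lo1), hi1)
        a2 = min(max(x[1], lo2), hi2)
        v = float(_kappa_at(a1, a2, accuracy_1, accuracy_2, beta))
        return 1e9 if not np.isfinite(v) else -v

    res = minimize(
        neg,
        x0=[g1[i], g2[j]],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return float(max(best, -res.fun))


# ---------------------------------------------------------------------------
# joint kappa / DVC table


def kappa_vs_dvc_table(
    entries: list[tuple[str, ChoiceSeries, ChoiceSeries, PairDVC]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tabulate kappa against DVC across observer pairs.

    Each entry is ``(pair_label, choices_1, choices_2, pair_dvc)``; one row
    is produced per entry (observer pair x class pair). Also returns the
    Spearman rank correlations of kappa with the raw and corrected DVC
    columns (NaN with fewer than 2 rows).
    """
    rows = []
    for label, c1, c2, pdvc in entries:
        if c1.class_pair != pdvc.class_pair:
            raise ValueError(f"entry {label!r}: choices and DVC class pairs differ")
        ag = cohens_kappa(c1, c2)
        rows.append(
            {
                "observer_pair": label,
                "class_pair": str(ag.class_pair),
                "kappa": ag.kappa,
                "accuracy_1": ag.accuracy_1,
                "accuracy_2": ag.accuracy_2,
                "accuracy_diff": abs(ag.accuracy_1 - ag.accuracy_2),
                "raw_dvc": pdvc.mean_raw,
                "corrected_dvc": pdvc.mean_corrected,
            }
        )
    df = pd.DataFrame(rows)
    stats: dict[str, float] = {
        "spearman_kappa_raw": float("nan"),
        "spearman_kappa_corrected": float("nan"),
    }
    if len(df) >= 2:
        for col, key in (
            ("raw_dvc", "spearman_kappa_raw"),
            ("corrected_dvc", "spearman_kappa_corrected"),
        ):
            ok = np.isfinite(df[col])
            if ok.sum() >= 2:
                rho = spearmanr(df.loc[ok, "kappa"], df.loc[ok, col]).statistic
                stats[key] = float(rho)
    return df, stats
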