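"""Evaluation protocol: chronological cross-validation, AUC, statistics.

Classifiers are trained and tested in a k-fold chronological
cross-validation whose folds are contiguous blocks of whole trials, so a
trial's windows never straddle the train/test boundary and no test trial
precedes training data from the same fold split.  The reduced-data
condition keeps only the first of the three repetitions in each trial
(33 % of the windows).  Window-level performance is the area under the
ROC curve; paired pipeline comparisons use the two-sided Wilcoxon
signed-rank test with Holm-Bonferroni correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .data import EpochSet, EventSchedule
from .decoding import fit_pipeline, predict_window_scores

__all__ = [
    "CVResult",
    "chronological_folds",
    "reduced_data_view",
    "auc",
    "grand_average",
    "compare_pipelines",
    "holm_adjust",
    "run_cv",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    variant: str
    data_fraction: float
    fold_aucs: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def chronological_folds(sched: EventSchedule, k: int = 5) -> dict[int, int]:
    """Assign each trial to one of k contiguous chronological folds."""
    order = (
        sched.frame.groupby("trial")["onset_s"].min().sort_values().index.to_numpy()
    )
    if len(order) < k:
        raise ValueError(f"need at least {k} trials, got {len(order)}")
    assignment: dict[int, int] = {}
    for fold, block in enumerate(np.array_split(order, k)):
        for trial in block:
            assignment[int(trial)] = fold
    return assignment


def reduced_data_view(ep: EpochSet) -> EpochSet:
    """Keep only first-repetition windows (the 33 % data condition)."""
    return ep.subset(ep.schedule.frame["repetition"].to_numpy() == 1)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Window-level AUC: the Mann-Whitney pair statistic.

    Fraction of (target, non-target) pairs where the target window scores
    higher, ties counted one half.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def grand_average(
    ep: EpochSet,
    group_by: tuple[str, ...] = ("object", "position_group", "is_target"),
    include_rejected: bool = True,
) -> dict[tuple, tuple[np.ndarray, int]]:
    """Per-group mean waveforms and window counts.

    By default groups over object x initial/subsequent x class and, as is
    usual for ERP grand averages, includes artifact windows.  Empty
    groups are omitted with a warning.
    """
    frame = ep.schedule.frame
    mask = np.ones(ep.n_epochs, dtype=bool) if include_rejected else ep.retained
    out: dict[tuple, tuple[np.ndarray, int]] = {}
    for key, grp in frame.groupby(list(group_by), sort=True):
        idx = np.asarray(grp.index)
        idx = idx[mask[idx]]
        if idx.size == 0:
            warnings.warn(f"group {key} is empty; omitted", RuntimeWarning, stacklevel=2)
            continue
        out[key if isinstance(key, tuple) else (key,)] = (
            ep.windows[idx].mean(axis=0),
            int(idx.size),
        )
    return out


def compare_pipelines(auc_a: np.ndarray, auc_b: np.ndarray) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-participant AUCs.

    Uses the exact null distribution for n <= 25 when there are no zero
    differences or ties, otherwise the normal approximation with Pratt
    zero handling.  Reports the median paired difference.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise ValueError("paired vectors of length >= 5 required")
    d = a - b
    if np.all(d == 0):
        return {"p_value": 1.0, "median_difference": 0.0, "statistic": np.nan,
                "note": "no difference"}
    abs_d = np.abs(d[d != 0])
    exact_ok = a.size <= 25 and np.all(d != 0) and np.unique(abs_d).size == abs_d.size
    res = scipy.stats.wilcoxon(
        a, b,
        zero_method="pratt",
        alternative="two-sided",
        method="exact" if exact_ok else "approx",
    )
    return {
        "p_value": float(res.pvalue),
        "median_difference": float(np.median(d)),
        "statistic": float(res.statistic),
    }


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values for a comparison family."""
    _, adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="holm")
    return adj


def run_cv(
    ep: EpochSet,
    variant: str,
    k: int = 5,
    subclass_definition: str = "object",
    data_fraction: float = 1.0,
) -> CVResult:
    """Chronological k-fold CV of one pipeline on a preprocessed session.

    Prototypes, xDAWN filters, references and classifiers are all refitted
    per fold on the training trials only.  Rejected windows are excluded
    from fitting and from the test-fold AUC.
    """
    if data_fraction not in (1.0, 0.33):
        raise ValueError("data_fraction must be 1.0 or 0.33")
    if data_fraction == 0.33:
        ep = reduced_data_view(ep)
    folds = chronological_folds(ep.schedule, k)
    fold_of = np.array([folds[t] for t in ep.schedule.trials])
    fold_aucs = []
    for fold in range(k):
        train = ep.subset(fold_of != fold)
        test = ep.subset(fold_of == fold)
        model = fit_pipeline(variant, train, subclass_definition=subclass_definition)
        scores = predict_window_scores(model, test)
        keep = test.retained
        fold_aucs.append(auc(scores[keep], test.schedule.labels[keep]))
        logger.info("fold %d %s: AUC %.3f", fold, variant, fold_aucs[-1])
    return CVResult(
        variant=variant, data_fraction=data_fraction,
        fold_aucs=np.asarray(fold_aucs),
    )


def run_experiment(
    sessions,
    variants=("ts_lda", "sep_ts_lda", "cts_reg_lda"),
    data_fractions=(0.33, 1.0),
    k: int = 5,
    subclass_definition: str = "object",
) -> pd.DataFrame:
    """Full evaluation matrix over preprocessed sessions (participants).

    ``sessions`` is a mapping participant-id -> preprocessed EpochSet.
    Returns one row per participant x variant x data fraction with the
    fold-averaged AUC.
    """
    rows = []
    for pid, ep in sessions.items():
        for fraction in data_fractions:
            for variant in variants:
                res = run_cv(
                    ep, variant, k=k,
                    subclass_definition=subclass_definition,
                    data_fraction=fraction,
                )
                rows.append(
                    {
                        "participant": pid,
                        "variant": variant,
                        "data_fraction": fraction,
                        "mean_auc": res.mean_auc,
                        **{f"fold{i}_auc": v for i, v in enumerate(res.fold_aucs)},
                    }
                )
    return pd.DataFrame(rows)
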