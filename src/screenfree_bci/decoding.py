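"""Tangent-space classification pipelines with subclass handling.

Three pipelines over the same covariance features:

* ``ts_lda`` — one Fréchet mean over the pooled training covariances, one
  LDA in its tangent space (subclass-agnostic baseline).
* ``sep_ts_lda`` — an independent Fréchet mean, tangent space and LDA per
  subclass, each fitted only on that subclass's windows.
* ``cts_reg_lda`` — each subclass is centered by parallel transport of its
  covariances to the identity (equivalently: tangent projection at the
  subclass mean), so all subclasses share one tangent space; per-subclass
  LDA classifiers are then regularized by replacing their class means with
  multi-target-shrunk (MTS) convex combinations of all subclasses' class
  means, with weights from a mean-squared-error-minimizing quadratic
  program.  The within-class scatter is pooled over all centered
  subclasses.

Subclasses are partitions of the stimuli — by highlighted object, by
position in the stimulation sequence, or by initial/subsequent position —
that induce distinct ERP response distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
from sklearn.covariance import ledoit_wolf

from .data import EpochSet, EventSchedule
from .geometry import frechet_mean, spd_sqrt_invsqrt
from .preprocessing import (
    PrototypePair,
    XdawnModel,
    augment_epochs,
    compute_prototypes,
    epoch_covariances,
    fit_xdawn,
)

__all__ = [
    "VARIANTS",
    "TangentDataset",
    "LDAModel",
    "PipelineModel",
    "featurize",
    "fit_lda",
    "mts_weights",
    "mts_shrunk_mean",
    "fit_pipeline",
    "predict_window_scores",
    "select_object",
]

logger = logging.getLogger(__name__)

VARIANTS = ("ts_lda", "sep_ts_lda", "cts_reg_lda")


@dataclass
class TangentDataset:
    """Vectorized tangent-space features aligned with labels."""

    vectors: np.ndarray  # K x n(n+1)/2
    class_labels: np.ndarray  # bool, True = target
    subclass_labels: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=bool)
        self.subclass_labels = np.asarray(self.subclass_labels)


@dataclass
class LDAModel:
    """Binary LDA with shrunk within-class covariance.

    The weight vector solves ``C_lda w = mu_t - mu_nt``; the decision
    value is ``w . x + b`` with b placing 0 at the midpoint of the class
    means (higher = more target-like).
    """

    w: np.ndarray
    b: float
    mu_t: np.ndarray
    mu_nt: np.ndarray
    C_lda: np.ndarray

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w + self.b


@dataclass
class PipelineModel:
    variant: str
    subclass_definition: str
    proto: PrototypePair
    xdawn: XdawnModel
    global_ref: np.ndarray | None = None
    global_lda: LDAModel | None = None
    subclass_refs: dict = field(default_factory=dict)
    subclass_ldas: dict = field(default_factory=dict)
    mts_alpha: dict = field(default_factory=dict)  # (subclass, class) -> (ids, alpha)


def featurize(
    covs: np.ndarray,
    references,
    subclass_labels: np.ndarray | None = None,
    mode: str = "pooled",
) -> np.ndarray:
    """Project window covariances to vectorized tangent-space features.

    ``pooled``: tangent projection of every covariance at the single
    reference.  ``per_subclass_centered``: each covariance is transported
    to the identity using its subclass's reference mean and projected
    there; since transport is a congruence by the inverse square root of
    the reference, this equals the tangent projection at that reference.
    """
    covs = np.asarray(covs)
    if mode == "pooled":
        ref = np.asarray(references)
        return _batch_log_vectors(covs, ref)
    if mode == "per_subclass_centered":
        if subclass_labels is None:
            raise ValueError("centered mode requires subclass labels")
        out = np.empty((covs.shape[0], covs.shape[1] * (covs.shape[1] + 1) // 2))
        for j in np.unique(subclass_labels):
            if j not in references:
                raise ValueError(f"no reference for subclass {j!r}")
            mask = subclass_labels == j
            out[mask] = _batch_log_vectors(covs[mask], references[j])
        return out
    raise ValueError(f"unknown featurize mode: {mode!r}")


def _batch_log_vectors(covs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    _, inv_sqrt = spd_sqrt_invsqrt(ref)
    whitened = np.einsum("ij,kjl,lm->kim", inv_sqrt, covs, inv_sqrt)
    whitened = 0.5 * (whitened + whitened.transpose(0, 2, 1))
    w, Q = np.linalg.eigh(whitened)
    if np.any(w <= 0):
        raise ValueError("covariance not positive definite after whitening")
    logs = np.einsum("kij,kj,klj->kil", Q, np.log(w), Q)
    n = logs.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    diag = logs[:, np.arange(n), np.arange(n)]
    return np.concatenate([diag, np.sqrt(2.0) * logs[:, iu, ju]], axis=1)


def _within_class_cov(
    X: np.ndarray, y: np.ndarray, mu_t: np.ndarray, mu_nt: np.ndarray
) -> np.ndarray:
    resid = X - np.where(y[:, None], mu_t[None, :], mu_nt[None, :])
    cov, _ = ledoit_wolf(resid, assume_centered=True)
    return 0.5 * (cov + cov.T)


def fit_lda(X: np.ndarray, y: np.ndarray) -> LDAModel:
    """Fit binary LDA with analytic (Ledoit-Wolf) shrinkage of the scatter."""
    y = np.asarray(y, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError(
            f"LDA needs >= 2 members per class (targets={int(y.sum())}, "
            f"non-targets={int((~y).sum())})"
        )
    mu_t = X[y].mean(axis=0)
    mu_nt = X[~y].mean(axis=0)
    C = _within_class_cov(X, y, mu_t, mu_nt)
    w = scipy.linalg.solve(C, mu_t - mu_nt, assume_a="pos")
    b = -0.5 * float(w @ (mu_t + mu_nt))
    return LDAModel(w=w, b=b, mu_t=mu_t, mu_nt=mu_nt, C_lda=C)


# ---------------------------------------------------------------------------
# multi-target shrinkage of class means


def _mean_and_variance(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Sample mean and estimated total variance of the mean estimator.

    The variance of the mean is estimated as the summed per-dimension
    sample variance divided by the number of samples.
    """
    mu = X.mean(axis=0)
    v = float(X.var(axis=0, ddof=1).sum() / X.shape[0])
    return mu, v


def _psd_floor(B: np.ndarray) -> np.ndarray:
    B = 0.5 * (B + B.T)
    w, Q = np.linalg.eigh(B)
    return (Q * np.clip(w, 0.0, None)) @ Q.T


def mts_objective(
    alpha: np.ndarray, v_j: float, v_others: np.ndarray, B: np.ndarray
) -> float:
    """Estimated MSE of the multi-target-shrunk mean at weights ``alpha``."""
    s = alpha.sum()
    return float(
        (1.0 - s) ** 2 * v_j
        + (alpha**2 * v_others).sum()
        + alpha @ B @ alpha
    )


def mts_components(
    mu_j: np.ndarray,
    v_j: float,
    mus_other: np.ndarray,
    v_others: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Debiased bias Gram matrix and variance vector for the MTS QP.

    Diagonal entries estimate the squared bias ``||mu_j' - mu_j||^2``
    debiased by both estimator variances; off-diagonal cross terms share
    the subclass-j estimate so only ``v_j`` is subtracted.  The matrix is
    floored to the positive semidefinite cone to keep the QP convex.
    """
    diffs = mus_other - mu_j[None, :]
    G = diffs @ diffs.T
    B = G - v_j
    np.fill_diagonal(B, np.diag(G) - v_j - v_others)
    return _psd_floor(B), np.asarray(v_others, dtype=float)


def mts_weights(
    X: np.ndarray,
    y: np.ndarray,
    subclass_labels: np.ndarray,
    j,
    target_class: bool,
) -> tuple[list, np.ndarray]:
    """MTS weights for the class mean of subclass ``j``.

    Minimizes the estimated mean-squared error of the shrunk mean — a
    convex quadratic in the weights over the constraint set
    ``alpha >= 0, sum(alpha) <= 1`` — and returns the other subclass ids
    together with their weights.  A failed solve falls back to
    ``alpha = 0`` (the pure subclass mean) with a warning.
    """
    y = np.asarray(y, dtype=bool)
    cls_mask = y == target_class
    own = cls_mask & (subclass_labels == j)
    if own.sum() < 2:
        raise ValueError(f"subclass {j!r} has < 2 members of the class")
    mu_j, v_j = _mean_and_variance(X[own])
    others = [s for s in np.unique(subclass_labels) if s != j]
    usable, mus, vs = [], [], []
    for s in others:
        m = cls_mask & (subclass_labels == s)
        if m.sum() < 2:
            continue
        mu, v = _mean_and_variance(X[m])
        usable.append(s)
        mus.append(mu)
        vs.append(v)
    if not usable:
        return [], np.zeros(0)
    mus = np.stack(mus)
    vs = np.asarray(vs)
    B, v_others = mts_components(mu_j, v_j, mus, vs)
    m = len(usable)
    P = v_j * np.ones((m, m)) + np.diag(v_others) + B
    P = 0.5 * (P + P.T)
    q = -v_j * np.ones(m)

    def fun(a):
        return 0.5 * a @ P @ a + q @ a

    def jac(a):
        return P @ a + q

    res = scipy.optimize.minimize(
        fun,
        np.zeros(m),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "ineq", "fun": lambda a: 1.0 - a.sum(),
                      "jac": lambda a: -np.ones_like(a)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success:
        warnings.warn(
            f"MTS QP failed for subclass {j!r} ({res.message}); "
            "falling back to the unshrunk subclass mean",
            RuntimeWarning,
            stacklevel=2,
        )
        return usable, np.zeros(m)
    alpha = np.clip(res.x, 0.0, None)
    total = alpha.sum()
    if total > 1.0:
        alpha = alpha / total
    return usable, alpha


def mts_shrunk_mean(
    mu_j: np.ndarray, mus_other: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Convex combination of the subclass mean with other subclasses' means."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size == 0:
        return np.asarray(mu_j, dtype=float).copy()
    if np.any(alpha < -1e-12) or alpha.sum() > 1.0 + 1e-9:
        raise ValueError("alpha must be nonnegative with sum <= 1")
    return (1.0 - alpha.sum()) * mu_j + alpha @ np.atleast_2d(mus_other)


# ---------------------------------------------------------------------------
# pipelines


def _class_mean(X, y, subclass_labels, j, target_class, pooled_fallback):
    mask = (y == target_class) & (subclass_labels == j)
    if mask.sum() < 2:
        warnings.warn(
            f"subclass {j!r} has < 2 windows of one class; using the pooled "
            "class mean for that cell",
            RuntimeWarning,
            stacklevel=2,
        )
        return pooled_fallback, False
    return X[mask].mean(axis=0), True


def fit_pipeline(
    variant: str,
    epochs: EpochSet,
    subclass_definition: str = "object",
    use_mts: bool = True,
    pooled_scatter: bool = True,
) -> PipelineModel:
    """Fit one of the three pipelines on training epochs.

    Prototypes and xDAWN filters are fitted once on the retained training
    windows and shared by every variant.  ``use_mts`` and
    ``pooled_scatter`` only affect ``cts_reg_lda``; disabling both reduces
    it to per-subclass classifiers in centered tangent spaces, which is
    score-equivalent to ``sep_ts_lda``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    train = epochs.subset(epochs.retained)
    proto = compute_prototypes(train)
    xd = fit_xdawn(train)
    covs = epoch_covariances(augment_epochs(train, proto, xd))
    y = train.schedule.labels
    sub = train.schedule.subclass_labels(subclass_definition)

    model = PipelineModel(
        variant=variant, subclass_definition=subclass_definition,
        proto=proto, xdawn=xd,
    )
    # pooled reference/classifier: the ts_lda model itself, and the
    # fallback for windows of subclasses unseen during training
    model.global_ref = frechet_mean(list(covs))
    pooled_vecs = featurize(covs, model.global_ref, mode="pooled")
    model.global_lda = fit_lda(pooled_vecs, y)
    if variant == "ts_lda":
        return model

    subclasses = list(np.unique(sub))
    for j in subclasses:
        mask = sub == j
        if y[mask].sum() < 2 or (~y[mask]).sum() < 2:
            raise ValueError(
                f"subclass {j!r} lacks two windows of each class; cannot fit "
                f"{variant}"
            )
        model.subclass_refs[j] = frechet_mean(list(covs[mask]))

    if variant == "sep_ts_lda":
        for j in subclasses:
            mask = sub == j
            vecs = featurize(covs[mask], model.subclass_refs[j], mode="pooled")
            model.subclass_ldas[j] = fit_lda(vecs, y[mask])
        return model

    # cts_reg_lda: common tangent space after per-subclass centering
    vecs = featurize(
        covs, model.subclass_refs, subclass_labels=sub,
        mode="per_subclass_centered",
    )
    cell_means = {}
    for j in subclasses:
        for cls in (True, False):
            pooled_mu = vecs[y == cls].mean(axis=0)
            cell_means[(j, cls)], _ = _class_mean(
                vecs, y, sub, j, cls, pooled_mu
            )
    # within-class scatter: residuals against subclass-and-class cell means
    resid = np.stack([
        vecs[i] - cell_means[(sub[i], bool(y[i]))] for i in range(len(vecs))
    ])
    if pooled_scatter:
        pooled_C, _ = ledoit_wolf(resid, assume_centered=True)
        pooled_C = 0.5 * (pooled_C + pooled_C.T)
    for j in subclasses:
        shrunk = {}
        for cls in (True, False):
            if use_mts:
                ids, alpha = mts_weights(vecs, y, sub, j, cls)
            else:
                ids, alpha = [s for s in subclasses if s != j], np.zeros(
                    len(subclasses) - 1
                )
            model.mts_alpha[(j, cls)] = (ids, alpha)
            mus_other = np.stack([cell_means[(s, cls)] for s in ids]) if ids else np.zeros((0, vecs.shape[1]))
            shrunk[cls] = mts_shrunk_mean(cell_means[(j, cls)], mus_other, alpha)
        if pooled_scatter:
            C = pooled_C
        else:
            mask = sub == j
            C, _ = ledoit_wolf(
                np.stack([
                    vecs[i] - cell_means[(j, bool(y[i]))]
                    for i in np.nonzero(mask)[0]
                ]),
                assume_centered=True,
            )
            C = 0.5 * (C + C.T)
        w = scipy.linalg.solve(C, shrunk[True] - shrunk[False], assume_a="pos")
        b = -0.5 * float(w @ (shrunk[True] + shrunk[False]))
        model.subclass_ldas[j] = LDAModel(
            w=w, b=b, mu_t=shrunk[True], mu_nt=shrunk[False], C_lda=C
        )
    return model


def predict_window_scores(model: PipelineModel, epochs: EpochSet) -> np.ndarray:
    """LDA decision values per window (higher = more target-like).

    Each window is routed to its subclass's reference and classifier;
    ``ts_lda`` uses the single global pair.  Windows of subclasses unseen
    at training time fall back to the pooled model with a warning.
    """
    covs = epoch_covariances(augment_epochs(epochs, model.proto, model.xdawn))
    scores = np.empty(epochs.n_epochs)
    if model.variant == "ts_lda":
        vecs = featurize(covs, model.global_ref, mode="pooled")
        return model.global_lda.score(vecs)
    sub = epochs.schedule.subclass_labels(model.subclass_definition)
    for j in np.unique(sub):
        mask = sub == j
        if j not in model.subclass_refs:
            warnings.warn(
                f"subclass {j!r} unseen at training time; scoring with the "
                "pooled classifier",
                RuntimeWarning,
                stacklevel=2,
            )
            vecs = featurize(covs[mask], model.global_ref, mode="pooled")
            scores[mask] = model.global_lda.score(vecs)
            continue
        vecs = featurize(covs[mask], model.subclass_refs[j], mode="pooled")
        scores[mask] = model.subclass_ldas[j].score(vecs)
    return scores


def select_object(
    scores: np.ndarray,
    sched: EventSchedule,
    trial: int,
    retained: np.ndarray | None = None,
) -> int:
    """Pick the trial's decoded object: highest mean window score.

    Candidates with no retained windows are excluded with a warning; ties
    are broken toward the lowest object id.
    """
    scores = np.asarray(scores, dtype=float)
    in_trial = sched.trials == trial
    if retained is not None:
        in_trial = in_trial & np.asarray(retained, dtype=bool)
    candidates = np.unique(sched.objects[sched.trials == trial])
    best_obj, best_score = None, -np.inf
    for obj in sorted(candidates):
        mask = in_trial & (sched.objects == obj)
        if not mask.any():
            warnings.warn(
                f"object {obj} has no scored windows in trial {trial}; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        m = scores[mask].mean()
        if m > best_score:
            best_obj, best_score = int(obj), m
    if best_obj is None:
        raise ValueError(f"trial {trial} has no scored windows")
    return best_obj
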