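"""From continuous EEG to prototype-augmented, covariance-ready epochs.

Pipeline: zero-phase band-pass (0.5-16 Hz) -> anti-aliased downsampling to
100 Hz -> 1 s stimulus-locked windows (101 samples, endpoints inclusive)
with 200 ms pre-stimulus baseline subtraction -> peak-to-peak artifact
rejection at 100 uV -> augmentation of each window with xDAWN-filtered
class-mean prototypes -> Ledoit-Wolf shrunk 8x8 window covariances.

The augmentation stacks, per window X_k,

    (W_t Xbar_t ; W_nt Xbar_nt ; W_t X_k ; W_nt X_k)

where Xbar_i are the class-mean prototypes of the training data and W_i
the two leading xDAWN spatial filters per class, so the covariance of the
stacked 8 x 101 matrix carries both the spatial signal covariance and the
cross-covariance (phase) of the window with the class prototypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.signal
import scipy.linalg
import scipy.sparse
from sklearn.covariance import ledoit_wolf

from .data import ContinuousRecording, EpochSet, EventSchedule

__all__ = [
    "PrototypePair",
    "XdawnModel",
    "bandpass_and_resample",
    "extract_epochs",
    "reject_artifacts",
    "compute_prototypes",
    "fit_xdawn",
    "augment_window",
    "augment_epochs",
    "shrinkage_covariance",
    "epoch_covariances",
    "WINDOW_S",
    "BASELINE_S",
]

logger = logging.getLogger(__name__)

WINDOW_S = 1.0  # [onset, onset + 1 s], endpoints inclusive
BASELINE_S = 0.2  # [onset - 0.2 s, onset)


@dataclass(frozen=True)
class PrototypePair:
    """Euclidean class-mean responses (N_c x N_t, uV)."""

    target_mean: np.ndarray
    nontarget_mean: np.ndarray


@dataclass(frozen=True)
class XdawnModel:
    """Per-class xDAWN spatial filter matrices, two unit-norm rows each.

    ``eigvals_t`` / ``eigvals_nt`` hold the full generalized-eigenvalue
    spectra (descending) for introspection of evoked-to-total power.
    """

    Wt: np.ndarray
    Wnt: np.ndarray
    eigvals_t: np.ndarray | None = None
    eigvals_nt: np.ndarray | None = None


def bandpass_and_resample(
    rec: ContinuousRecording,
    low: float = 0.5,
    high: float = 16.0,
    out_rate: float = 100.0,
) -> ContinuousRecording:
    """Zero-phase band-pass then anti-aliased downsampling.

    The band-pass is a 4th-order Butterworth applied forward-backward
    (``sosfiltfilt``) so ERP latencies are preserved; resampling uses a
    polyphase FIR with its own anti-aliasing low-pass.  Event onsets stay
    in seconds and are unaffected.
    """
    if not 0 < low < high < rec.rate / 2:
        raise ValueError(f"band ({low}, {high}) Hz invalid for rate {rec.rate}")
    if out_rate > rec.rate:
        raise ValueError("out_rate must not exceed the input rate")
    if out_rate / 2 <= high:
        raise ValueError(
            f"out_rate {out_rate} violates Nyquist for the {high} Hz band edge"
        )
    sos = scipy.signal.butter(
        4, [low, high], btype="bandpass", fs=rec.rate, output="sos"
    )
    filtered = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    frac = Fraction(out_rate / rec.rate).limit_denominator(1000)
    if not math.isclose(frac.numerator / frac.denominator * rec.rate, out_rate):
        raise ValueError(f"rate ratio {out_rate}/{rec.rate} is not rational")
    data = scipy.signal.resample_poly(
        filtered, frac.numerator, frac.denominator, axis=1
    )
    return ContinuousRecording(
        data=data, rate=out_rate, channel_names=list(rec.channel_names)
    )


def extract_epochs(rec: ContinuousRecording, sched: EventSchedule) -> EpochSet:
    """Cut 1 s baseline-corrected windows at each highlighting onset.

    The window covers [onset, onset + 1 s] inclusive of both endpoints
    (101 samples at 100 Hz); the per-channel mean over [onset - 0.2 s,
    onset) is subtracted.  Onsets are snapped to the nearest sample.
    Events too close to the recording edges are dropped with a warning.
    """
    n_t = int(round(WINDOW_S * rec.rate)) + 1
    n_base = int(round(BASELINE_S * rec.rate))
    onset_idx = np.round(sched.onsets * rec.rate).astype(int)
    keep = (onset_idx - n_base >= 0) & (onset_idx + n_t <= rec.n_samples)
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning(
            "dropping %d event(s) too close to the recording edge", dropped
        )
    sched = sched.subset(keep)
    onset_idx = onset_idx[keep]
    windows = np.empty((len(onset_idx), rec.n_channels, n_t))
    for i, idx in enumerate(onset_idx):
        win = rec.data[:, idx : idx + n_t]
        baseline = rec.data[:, idx - n_base : idx].mean(axis=1, keepdims=True)
        windows[i] = win - baseline
    return EpochSet(windows=windows, schedule=sched, rate=rec.rate)


def reject_artifacts(ep: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Mark windows whose peak-to-peak amplitude exceeds ``threshold`` uV.

    Rejection is strict: a window is marked only if max - min on some
    channel is strictly greater than the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ptp = ep.windows.max(axis=2) - ep.windows.min(axis=2)
    rejected = (ptp > threshold).any(axis=1)
    logger.info(
        "artifact rejection: %d/%d windows rejected (> %g uV peak-to-peak)",
        int(rejected.sum()),
        ep.n_epochs,
        threshold,
    )
    return EpochSet(
        windows=ep.windows,
        schedule=ep.schedule,
        rate=ep.rate,
        rejected_mask=ep.rejected_mask | rejected,
    )


def compute_prototypes(ep: EpochSet) -> PrototypePair:
    """Euclidean class-mean responses over retained training windows."""
    labels = ep.schedule.labels
    keep = ep.retained
    n_t = int((labels & keep).sum())
    n_nt = int((~labels & keep).sum())
    if n_t == 0 or n_nt == 0:
        raise ValueError(
            f"both classes required to build prototypes (targets={n_t}, "
            f"non-targets={n_nt})"
        )
    return PrototypePair(
        target_mean=ep.windows[labels & keep].mean(axis=0),
        nontarget_mean=ep.windows[~labels & keep].mean(axis=0),
    )


def _overlap_design(
    ep: EpochSet, n_t: int
) -> tuple[scipy.sparse.csr_matrix, np.ndarray]:
    """Stimulus-onset design over the concatenated retained windows.

    Models response overlap: with a 250 ms SOA each 1 s window contains
    the (lagged) responses of up to four highlightings, so the evoked
    response per class is estimated jointly by least squares against a
    Toeplitz-structured 0/1 design with one column per class and lag.
    Rows are the samples of the retained windows (in global sample time);
    columns [0, n_t) are target lags, [n_t, 2 n_t) non-target lags.
    """
    keep = ep.retained
    onset_idx = np.round(ep.schedule.onsets * ep.rate).astype(int)
    labels = ep.schedule.labels
    all_onsets = onset_idx  # all retained-schedule events may overlap a window
    rows, cols = [], []
    data_rows = []
    row0 = 0
    win_idx = np.nonzero(keep)[0]
    for i in win_idx:
        g0 = onset_idx[i]
        data_rows.append(ep.windows[i].T)  # n_t x N_c
        # events whose [onset, onset + n_t) support intersects this window
        near = np.nonzero(
            (all_onsets > g0 - n_t) & (all_onsets < g0 + n_t) & keep
        )[0]
        for e in near:
            lag0 = all_onsets[e] - g0  # may be negative
            t_lo = max(0, lag0)
            t_hi = min(n_t, lag0 + n_t)
            t = np.arange(t_lo, t_hi)
            rows.append(row0 + t)
            base = 0 if labels[e] else n_t
            cols.append(base + (t - lag0))
        row0 += n_t
    X = np.concatenate(data_rows, axis=0)  # total_samples x N_c
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    D = scipy.sparse.csr_matrix(
        (np.ones(rows.shape[0]), (rows, cols)), shape=(row0, 2 * n_t)
    )
    return D, X


def fit_xdawn(
    ep: EpochSet,
    sched: EventSchedule | None = None,
    n_components_per_class: int = 2,
) -> XdawnModel:
    """Fit xDAWN spatial filters maximizing evoked-response SNR.

    Per class, solves the generalized eigenproblem of the covariance of
    the least-squares-estimated evoked component (under an overlap-aware
    stimulus-onset design) against the total signal covariance, and keeps
    the ``n_components_per_class`` leading unit-norm eigenvector rows.
    """
    del sched  # schedule travels inside the EpochSet
    labels = ep.schedule.labels
    keep = ep.retained
    if (labels & keep).sum() < 2 or (~labels & keep).sum() < 2:
        raise ValueError("need at least two retained windows per class")
    n_c = ep.windows.shape[1]
    if n_components_per_class > n_c:
        raise ValueError("more components requested than channels")
    n_t = ep.windows.shape[2]
    D, X = _overlap_design(ep, n_t)
    gram = (D.T @ D).toarray()
    dtx = D.T @ X  # 2 n_t x N_c
    try:
        A = scipy.linalg.solve(gram, dtx, assume_a="pos")
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate design
        raise ValueError(f"overlap design is rank deficient: {err}") from err
    total_cov = (X.T @ X) / X.shape[0]
    cond = np.linalg.cond(total_cov)
    if cond > 1e10:
        raise ValueError(
            f"total covariance is near-singular (cond={cond:.2e}); "
            "apply shrinkage or remove flat channels"
        )
    filters, spectra = [], []
    for cls_slice in (slice(0, n_t), slice(n_t, 2 * n_t)):
        Ai = A[cls_slice]  # n_t x N_c evoked estimate
        evoked_cov = Ai.T @ gram[cls_slice, cls_slice] @ Ai / X.shape[0]
        w, V = scipy.linalg.eigh(evoked_cov, total_cov)
        top = V[:, ::-1][:, :n_components_per_class].T
        top = top / np.linalg.norm(top, axis=1, keepdims=True)
        filters.append(top)
        spectra.append(w[::-1])
    return XdawnModel(
        Wt=filters[0], Wnt=filters[1],
        eigvals_t=spectra[0], eigvals_nt=spectra[1],
    )


def xdawn_pattern(W: np.ndarray, total_cov: np.ndarray) -> np.ndarray:
    """Spatial patterns (forward model) corresponding to filter rows."""
    A = total_cov @ W.T
    return (A / np.linalg.norm(A, axis=0, keepdims=True)).T


def augment_window(
    Xk: np.ndarray, proto: PrototypePair, xd: XdawnModel
) -> np.ndarray:
    """Stack filtered prototypes over the filtered window (8 x N_t)."""
    if Xk.shape != proto.target_mean.shape:
        raise ValueError(
            f"window shape {Xk.shape} does not match prototypes "
            f"{proto.target_mean.shape}"
        )
    return np.vstack(
        [
            xd.Wt @ proto.target_mean,
            xd.Wnt @ proto.nontarget_mean,
            xd.Wt @ Xk,
            xd.Wnt @ Xk,
        ]
    )


def augment_epochs(
    ep: EpochSet, proto: PrototypePair, xd: XdawnModel
) -> np.ndarray:
    """Vectorized :func:`augment_window` over all windows -> (K, 8, N_t)."""
    Wt, Wnt = xd.Wt, xd.Wnt
    proto_rows = np.vstack([Wt @ proto.target_mean, Wnt @ proto.nontarget_mean])
    sig_t = np.einsum("ij,kjt->kit", Wt, ep.windows)
    sig_nt = np.einsum("ij,kjt->kit", Wnt, ep.windows)
    k = ep.n_epochs
    out = np.empty((k, proto_rows.shape[0] + sig_t.shape[1] + sig_nt.shape[1], ep.windows.shape[2]))
    out[:, : proto_rows.shape[0]] = proto_rows
    out[:, proto_rows.shape[0] : proto_rows.shape[0] + sig_t.shape[1]] = sig_t
    out[:, proto_rows.shape[0] + sig_t.shape[1] :] = sig_nt
    return out


def shrinkage_covariance(Xa: np.ndarray, return_shrinkage: bool = False):
    """Ledoit-Wolf shrunk covariance of an augmented window.

    Time samples are the observations and the 8 surrogate channels the
    features; the analytic shrinkage coefficient in [0, 1] guarantees a
    positive-definite output even for rank-deficient windows.
    """
    if Xa.ndim != 2 or Xa.shape[1] < 2:
        raise ValueError("augmented window must be channels x time, N_t > 1")
    cov, shrinkage = ledoit_wolf(Xa.T, assume_centered=False)
    cov = 0.5 * (cov + cov.T)
    if return_shrinkage:
        return cov, float(shrinkage)
    return cov


def epoch_covariances(augmented: np.ndarray) -> np.ndarray:
    """Shrunk covariances for a stack of augmented windows -> (K, 8, 8).

    Batched implementation of the same analytic Ledoit-Wolf shrinkage as
    :func:`shrinkage_covariance` (they agree to machine precision; the
    per-window route just carries per-call overhead).
    """
    X = np.asarray(augmented, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a stack of augmented windows (K, N'_c, N_t)")
    k, p, n = X.shape
    Xc = X - X.mean(axis=2, keepdims=True)
    emp = np.einsum("kpt,kqt->kpq", Xc, Xc) / n
    mu = np.trace(emp, axis1=1, axis2=2) / p
    eye = np.eye(p)
    delta = ((emp - mu[:, None, None] * eye) ** 2).sum(axis=(1, 2)) / p
    X2 = Xc**2
    beta_ = (
        np.einsum("kpt,kqt->kpq", X2, X2) / n - emp**2
    ).sum(axis=(1, 2)) / (n * p)
    beta = np.minimum(beta_, delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(delta > 0, beta / delta, 0.0)
    out = (1.0 - shrink)[:, None, None] * emp + (shrink * mu)[:, None, None] * eye
    return 0.5 * (out + out.transpose(0, 2, 1))
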