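"""Consensus label fusion: multilabel STAPLE EM plus a majority-vote baseline.

The generative model: each voxel has a hidden true label drawn from a
stationary global prior; rater r emits label m at a true-label-l voxel
with probability theta_r[l, m].  The EM algorithm alternates a posterior
(E) step and a confusion-matrix (M) step until the parameters stop
moving.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import GridMismatchError, LabelMap

logger = logging.getLogger(__name__)

__all__ = ["FusionResult", "fuse_staple", "fuse_majority"]

_EPS = 1e-300


@dataclasses.dataclass
class FusionResult:
    """Output of STAPLE fusion.

    Attributes
    ----------
    consensus : LabelMap
        Per-voxel argmax of the posterior (ties -> smallest label).
    rater_performance : ndarray, shape (R, K, K)
        Estimated confusion matrices (row = true label, col = emitted).
    posterior : ndarray, shape (V, K)
        Per-voxel label posterior, rows summing to 1.
    n_iterations : int
    converged : bool
    log_likelihood : list of float
        Observed-data log-likelihood after every E step (non-decreasing).
    """

    consensus: LabelMap
    rater_performance: np.ndarray
    posterior: np.ndarray
    n_iterations: int
    converged: bool
    log_likelihood: list


def _stack_raters(raters: list[LabelMap], n_labels: int) -> np.ndarray:
    if not raters:
        raise ValueError("need at least one rater")
    shapes = {r.shape for r in raters}
    if len(shapes) > 1:
        raise GridMismatchError(f"rater grids differ: {shapes}")
    D = np.stack([r.data.ravel() for r in raters])  # (R, V)
    if D.min() < 0 or D.max() >= n_labels:
        raise ValueError(f"rater labels must lie in 0..{n_labels - 1}")
    return D


def fuse_majority(raters: list[LabelMap]) -> LabelMap:
    """Per-voxel modal label; ties break toward the smallest label index."""
    n_labels = int(max(r.data.max() for r in raters)) + 1
    D = _stack_raters(raters, n_labels)
    counts = np.zeros((D.shape[1], n_labels), dtype=np.int64)
    for r in range(D.shape[0]):
        np.add.at(counts, (np.arange(D.shape[1]), D[r]), 1)
    modal = counts.argmax(axis=1).astype(np.int32)  # argmax -> first max -> smallest label
    ref = raters[0]
    return LabelMap(modal.reshape(ref.shape), voxel_size_mm=ref.voxel_size_mm, labels=ref.labels)


def fuse_staple(
    raters: list[LabelMap],
    n_labels: int,
    prior: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    init_diag: float = 0.99,
    exclude_all_background: bool = False,
) -> FusionResult:
    """Multilabel STAPLE consensus via EM.

    Parameters
    ----------
    raters : list of LabelMap
        Aligned candidate segmentations with labels in 0..n_labels-1.
    n_labels : int
        Number of labels K (>= 2).
    prior : array of K probabilities, optional
        Stationary global label prior; defaults to the raters' pooled
        label frequencies.  Held fixed across iterations.
    max_iter, tol :
        EM stops when every confusion entry changes by less than ``tol``
        or after ``max_iter`` iterations.
    init_diag : float
        Initial confusion diagonal (off-diagonal mass spread uniformly).
    exclude_all_background : bool
        If True, voxels where every rater emits 0 are excluded from the
        M-step parameter updates (they still receive a posterior).

    Returns
    -------
    FusionResult
    """
    if n_labels < 2:
        raise ValueError("need n_labels >= 2")
    D = _stack_raters(raters, n_labels)
    R, V = D.shape
    K = n_labels

    if prior is None:
        freq = np.bincount(D.ravel(), minlength=K).astype(np.float64)
        prior = freq / freq.sum()
    else:
        prior = np.asarray(prior, dtype=np.float64)
        if prior.shape != (K,) or np.any(prior < 0):
            raise ValueError("prior must be K nonnegative probabilities")
        prior = prior / prior.sum()

    theta = np.full((R, K, K), (1.0 - init_diag) / (K - 1))
    for r in range(R):
        np.fill_diagonal(theta[r], init_diag)

    if exclude_all_background:
        m_step_mask = ~(D == 0).all(axis=0)  # (V,)
    else:
        m_step_mask = np.ones(V, dtype=bool)

    log_prior = np.log(np.maximum(prior, _EPS))
    loglik_trace: list[float] = []
    converged = False
    it = 0
    posterior = np.empty((V, K))
    for it in range(1, max_iter + 1):
        # E step: log posterior(v, l) = log prior_l + sum_r log theta_r[l, D[r, v]]
        logp = np.broadcast_to(log_prior, (V, K)).copy()
        log_theta = np.log(np.maximum(theta, _EPS))
        for r in range(R):
            logp += log_theta[r][:, D[r]].T  # (V, K)
        mx = logp.max(axis=1, keepdims=True)
        w = np.exp(logp - mx)
        norm = w.sum(axis=1, keepdims=True)
        posterior = w / norm
        loglik_trace.append(float(np.sum(mx.ravel() + np.log(norm.ravel()))))

        # M step: theta_r[l, m] = sum_v post(v, l) [D[r, v] = m] / sum_v post(v, l)
        post_m = posterior[m_step_mask]
        denom = post_m.sum(axis=0)  # (K,)
        new_theta = np.empty_like(theta)
        for r in range(R):
            num = np.zeros((K, K))
            d = D[r, m_step_mask]
            np.add.at(num.T, d, post_m)  # num[l, m] += post(v, l) where d_v = m
            with np.errstate(divide="ignore", invalid="ignore"):
                new_theta[r] = num / denom[:, None]
            empty = denom == 0
            if empty.any():  # keep previous row when no mass supports label l
                new_theta[r][empty] = theta[r][empty]

        delta = float(np.max(np.abs(new_theta - theta)))
        theta = new_theta
        if delta < tol:
            converged = True
            break

    # final E step so the posterior matches the returned theta
    logp = np.broadcast_to(log_prior, (V, K)).copy()
    log_theta = np.log(np.maximum(theta, _EPS))
    for r in range(R):
        logp += log_theta[r][:, D[r]].T
    mx = logp.max(axis=1, keepdims=True)
    w = np.exp(logp - mx)
    norm = w.sum(axis=1, keepdims=True)
    posterior = w / norm
    loglik_trace.append(float(np.sum(mx.ravel() + np.log(norm.ravel()))))

    if not converged:
        logger.warning("STAPLE did not converge in %d iterations", max_iter)

    consensus = posterior.argmax(axis=1).astype(np.int32)  # ties -> smallest label
    ref = raters[0]
    return FusionResult(
        consensus=LabelMap(
            consensus.reshape(ref.shape), voxel_size_mm=ref.voxel_size_mm, labels=ref.labels
        ),
        rater_performance=theta,
        posterior=posterior,
        n_iterations=it,
        converged=converged,
        log_likelihood=loglik_trace,
    )
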