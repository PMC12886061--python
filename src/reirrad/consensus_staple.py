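"""STAPLE label fusion: a consensus structure from multiple raters.

Simultaneous Truth and Performance Level Estimation treats each rater's
binary mask as a noisy observation of an unknown true segmentation and
runs expectation-maximisation: the E-step computes the per-voxel posterior
probability of foreground given the current rater sensitivities ``p_j`` and
specificities ``q_j``; the M-step re-estimates ``p_j`` and ``q_j`` from the
posterior.  The consensus is the posterior thresholded at 50% agreement
(ties included), matching the benchmark's fusion of the structures
transferred by all centres.

The global foreground prior is spatially uniform and set to the mean
foreground fraction across raters, computed on a bounding box dilated by
10 voxels around the union of the raters; the classic unconstrained prior
over the full volume would be biased by the large empty background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import StructureMask

_EPS = 1e-6


@dataclass
class ConsensusResult:
    """Output of the STAPLE EM run."""

    probability: np.ndarray  # posterior foreground probability, full grid
    mask: StructureMask      # probability >= threshold
    sensitivity: np.ndarray  # p_j per rater
    specificity: np.ndarray  # q_j per rater
    iterations: int
    converged: bool
    degenerate: bool = False


def _common_grid(masks):
    grid = masks[0].grid
    for m in masks[1:]:
        if not m.grid.same_geometry(grid):
            raise ValueError("all rater masks must share one grid")
    return grid


def _union_bbox(stack: np.ndarray, pad: int):
    union = stack.any(axis=0)
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, union.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def staple(masks, threshold: float = 0.5, prior: float | None = None,
           tol: float = 1e-6, max_iter: int = 100) -> ConsensusResult:
    """Fuse ``masks`` (>= 2, common grid) into a consensus structure.

    Parameters
    ----------
    threshold : float
        Posterior agreement threshold; voxels with ``W >= threshold`` are
        foreground in the consensus (default 50%).
    prior : float, optional
        Global foreground prior; defaults to the mean rater foreground
        fraction within the dilated union bounding box.
    tol, max_iter :
        EM stops when every ``|Δp_j|`` and ``|Δq_j|`` falls below ``tol``,
        or after ``max_iter`` iterations.
    """
    if len(masks) < 2:
        raise ValueError("STAPLE requires at least 2 rater masks")
    grid = _common_grid(masks)
    stack_full = np.stack([m.voxels > 0 for m in masks])

    probability = np.zeros(grid.size)
    if not stack_full.any():
        empty = StructureMask(organ=masks[0].organ, grid=grid,
                              voxels=np.zeros(grid.size, dtype=np.uint8),
                              allow_empty=True)
        nan = np.full(len(masks), np.nan)
        return ConsensusResult(probability=probability, mask=empty,
                               sensitivity=nan, specificity=nan,
                               iterations=0, converged=False, degenerate=True)

    box = _union_bbox(stack_full, pad=10)
    d = stack_full[(slice(None), *box)].reshape(len(masks), -1).astype(float)
    n_raters = d.shape[0]

    pi = float(np.mean(d)) if prior is None else float(prior)
    pi = min(max(pi, _EPS), 1.0 - _EPS)

    p = np.full(n_raters, 0.99)
    q = np.full(n_raters, 0.99)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # E-step: voxel posterior of foreground under rater independence
        log_a = np.log(pi) + (d * np.log(p[:, None]) + (1 - d) * np.log1p(-p[:, None])).sum(axis=0)
        log_b = np.log1p(-pi) + ((1 - d) * np.log(q[:, None]) + d * np.log1p(-q[:, None])).sum(axis=0)
        m = np.maximum(log_a, log_b)
        w = np.exp(log_a - m) / (np.exp(log_a - m) + np.exp(log_b - m))
        # M-step: rater performance given the posterior
        sw = w.sum()
        swc = (1.0 - w).sum()
        p_new = np.clip((d * w).sum(axis=1) / max(sw, _EPS), _EPS, 1.0 - _EPS)
        q_new = np.clip(((1 - d) * (1 - w)).sum(axis=1) / max(swc, _EPS), _EPS, 1.0 - _EPS)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    probability[box] = w.reshape(probability[box].shape)
    consensus = StructureMask(organ=masks[0].organ, grid=grid,
                              voxels=(probability >= threshold),
                              allow_empty=True)
    return ConsensusResult(probability=probability, mask=consensus,
                           sensitivity=p, specificity=q,
                           iterations=iterations, converged=converged)


def majority_vote(masks, threshold: float = 0.5) -> StructureMask:
    """Voxel foreground iff the fraction of raters voting foreground >= threshold."""
    if len(masks) < 2:
        raise ValueError("majority vote requires at least 2 rater masks")
    grid = _common_grid(masks)
    frac = np.mean(np.stack([m.voxels > 0 for m in masks]), axis=0)
    return StructureMask(organ=masks[0].organ, grid=grid,
                         voxels=(frac >= threshold), allow_empty=True)
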