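"""Generalized Procrustes analysis of 2-D landmark configurations.

Translation is removed by centring on the centroid, size by scaling to unit
centroid size, and orientation by the SVD-based optimal rotation restricted to
determinant +1 — reflections are never applied, because left/right chirality
is biologically meaningful.  PCA downstream operates on the Procrustes
coordinates directly (no explicit tangent-space projection), a good
approximation at the small shape variation typical of these datasets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, DegenerateInputError, ShapeMismatchError
from .morpho_io import LandmarkConfiguration

ARCHETYPES = ("straight", "incomplete", "complete")


def centroid_size(points: np.ndarray | LandmarkConfiguration) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    pts = points.points if isinstance(points, LandmarkConfiguration) else np.asarray(points, float)
    pts = pts.reshape(-1, 2)
    centred = pts - pts.mean(axis=0)
    size = float(np.sqrt(np.sum(centred**2)))
    if size <= 0:
        raise DegenerateInputError("all landmarks coincide; centroid size is zero")
    return size


def _centre_and_scale(pts: np.ndarray) -> np.ndarray:
    centred = pts - pts.mean(axis=0)
    return centred / centroid_size(centred)


def optimal_rotation(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimising ||target @ R - reference||_F."""
    m = target.T @ reference
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, d])
    return u @ correction @ vt


def align_pair(
    reference: np.ndarray | LandmarkConfiguration,
    target: np.ndarray | LandmarkConfiguration,
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes fit of ``target`` onto ``reference``.

    Both are centred and scaled to unit centroid size; the target is then
    rotated by the optimal proper rotation.  Returns the aligned target and
    the minimised root-sum-of-squares (Procrustes distance).
    """
    ref = reference.points if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    tgt = target.points if isinstance(target, LandmarkConfiguration) else np.asarray(target, float)
    if ref.shape != tgt.shape:
        raise ShapeMismatchError(f"point counts differ: {ref.shape[0]} vs {tgt.shape[0]}")
    ref = _centre_and_scale(ref)
    tgt = _centre_and_scale(tgt)
    rot = optimal_rotation(ref, tgt)
    aligned = tgt @ rot
    return aligned, float(np.sqrt(np.sum((aligned - ref) ** 2)))


def procrustes_distance(a, b) -> float:
    return align_pair(a, b)[1]


@dataclass
class AlignedDataset:
    """Procrustes-superimposed configurations with sizes and consensus."""

    specimen_ids: list[str]
    coords: np.ndarray  # (n, k, 2) aligned configurations
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2)
    trait: str | None = None
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.group_labels is not None:
            unknown = set(self.group_labels) - set(ARCHETYPES)
            if unknown:
                raise ValueError(f"unknown archetype labels: {sorted(unknown)}")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def flattened(self) -> np.ndarray:
        """(n, 2k) matrix of aligned coordinates (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(self.n_specimens, -1)


def gpa(
    configs: list[LandmarkConfiguration] | np.ndarray,
    group_labels: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalized Procrustes analysis.

    All configurations are centred and scaled to unit centroid size, then
    iteratively rotated to the running consensus; the consensus is the
    coordinate-wise mean, renormalised to unit centroid size each round.
    Convergence is measured as root-mean-square change of the consensus.
    """
    if isinstance(configs, np.ndarray):
        ids = [f"specimen_{i + 1}" for i in range(len(configs))]
        arrays = [np.asarray(c, float) for c in configs]
        trait = None
    else:
        ids = [c.specimen_id for c in configs]
        arrays = [c.points for c in configs]
        traits = {c.trait for c in configs}
        if len(traits) > 1:
            raise ShapeMismatchError(f"mixed traits in one dataset: {traits}")
        trait = traits.pop() if traits else None
    if len(arrays) < 2:
        raise DegenerateInputError("GPA needs at least 2 configurations")
    k = arrays[0].shape[0]
    if any(a.shape != (k, 2) for a in arrays):
        raise ShapeMismatchError("all configurations must have the same point count")

    sizes = np.array([centroid_size(a) for a in arrays])
    stack = np.stack([_centre_and_scale(a) for a in arrays])

    # start from the raw mean when the inputs are already roughly co-oriented
    # (this makes GPA a fixed point on its own output); otherwise seed with
    # the first configuration.
    mean0 = stack.mean(axis=0)
    if float(np.sqrt(np.sum(mean0**2))) > 1e-3:
        consensus = mean0 / centroid_size(mean0)
    else:
        consensus = stack[0].copy()

    for _ in range(max_iter):
        for i in range(len(stack)):
            stack[i] = stack[i] @ optimal_rotation(consensus, stack[i])
        new_consensus = stack.mean(axis=0)
        new_consensus = new_consensus / centroid_size(new_consensus)
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise ConvergenceError(f"GPA did not converge; last consensus change {change:g}")

    # final pass so every configuration is aligned to the converged consensus
    for i in range(len(stack)):
        stack[i] = stack[i] @ optimal_rotation(consensus, stack[i])
    consensus = stack.mean(axis=0)

    # the Procrustes solution is unique only up to a global rotation; fix a
    # canonical frame by aligning the consensus with its principal axes
    rot = _canonical_rotation(consensus)
    stack = stack @ rot
    consensus = consensus @ rot

    return AlignedDataset(ids, stack, sizes, consensus, trait=trait, group_labels=group_labels)


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation putting a centred configuration into principal-axes
    orientation with a deterministic 180-degree sign choice."""
    centred = consensus - consensus.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:
        rot[:, 1] *= -1.0
    aligned = centred @ rot
    j = int(np.argmax(np.abs(aligned[:, 0])))
    if aligned[j, 0] < 0:
        rot = -rot  # rotate by 180 degrees (not a reflection)
    return rot
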