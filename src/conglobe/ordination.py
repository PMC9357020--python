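"""Ordination of aligned shapes: PCA, Mahalanobis distances, CVA and
permutation tests of group separation.

Because the landmark dimension (2k) usually exceeds the specimen count, the
pooled within-group covariance is inverted inside the subspace of its leading
eigenvectors.  The retained dimension is the largest one (capped by a
user-settable ``subspace_dim``, default ``min(n - g, 20)``) whose condition
number stays below 1e8; this makes the pseudo-inversion rule explicit and
testable rather than implementation-defined.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import DimensionalityError, InsufficientDataError
from .superimposition import AlignedDataset

DEFAULT_SEED = 20220806
COND_MAX = 1e8


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # (m,) non-negative, descending
    axes: np.ndarray  # (m, p) orthonormal rows
    scores: np.ndarray  # (n, m), column means zero
    mean: np.ndarray  # (p,) flattened mean shape
    n_landmarks: int | None = None

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def mean_shape(self) -> np.ndarray:
        if self.n_landmarks is None:
            raise ValueError("PCA was not run on landmark data")
        return self.mean.reshape(self.n_landmarks, 2)

    def project(self, flat: np.ndarray) -> np.ndarray:
        """Scores of new (flattened) configurations in this PCA space."""
        return (np.atleast_2d(flat) - self.mean) @ self.axes.T


def pca_matrix(x: np.ndarray) -> PCAResult:
    """Eigendecomposition of the covariance of the rows of ``x`` (n, p)."""
    x = np.asarray(x, float)
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError("PCA needs at least 3 specimens")
    mean = x.mean(axis=0)
    centred = x - mean
    # SVD route: numerically stable for p >> n
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > max(eigenvalues[0], 1.0) * 1e-12 if len(s) else slice(0)
    eigenvalues = eigenvalues[keep]
    axes = vt[keep]
    # deterministic sign convention: the largest-magnitude loading is positive
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] *= -1.0
    scores = centred @ axes.T
    return PCAResult(eigenvalues, axes, scores, mean)


def pca(aligned: AlignedDataset) -> PCAResult:
    """PCA of flattened Procrustes coordinates."""
    result = pca_matrix(aligned.flattened())
    result.n_landmarks = aligned.n_landmarks
    return result


def pc_deformation(result: PCAResult, axis: int, score: float) -> np.ndarray:
    """Shape at ``score`` along a PC axis: mean + score * axis (k, 2)."""
    if axis < 0 or axis >= result.n_components:
        raise IndexError(f"axis {axis} out of range (0..{result.n_components - 1})")
    if result.eigenvalues[axis] <= 0:
        raise DimensionalityError(f"axis {axis} has zero variance")
    flat = result.mean + score * result.axes[axis]
    k = result.n_landmarks or len(flat) // 2
    return flat.reshape(k, 2)


# ---------------------------------------------------------------------------
# Mahalanobis machinery
# ---------------------------------------------------------------------------


def _group_indices(labels: np.ndarray) -> dict[str, np.ndarray]:
    return {g: np.flatnonzero(labels == g) for g in sorted(set(labels))}


def pooled_within_covariance(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled within-group covariance (divisor n - g)."""
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    groups = _group_indices(labels)
    n, g = x.shape[0], len(groups)
    if g < 2:
        raise InsufficientDataError("need at least 2 groups")
    if n - g < 1:
        raise InsufficientDataError("need more specimens than groups")
    scatter = np.zeros((x.shape[1], x.shape[1]))
    for idx in groups.values():
        if len(idx) < 2:
            continue
        centred = x[idx] - x[idx].mean(axis=0)
        scatter += centred.T @ centred
    return scatter / (n - g)


@dataclass
class _WithinSubspace:
    """Eigen-truncated pooled within-group covariance."""

    vectors: np.ndarray  # (p, d) retained eigenvectors
    values: np.ndarray  # (d,)

    @property
    def dim(self) -> int:
        return len(self.values)

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        diff = (np.asarray(a, float) - np.asarray(b, float)) @ self.vectors
        return float(np.sqrt(np.sum(diff**2 / self.values)))


def _within_subspace(
    x: np.ndarray, labels: np.ndarray, subspace_dim: int | None
) -> _WithinSubspace:
    cov = pooled_within_covariance(x, labels)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n, g = x.shape[0], len(set(labels.tolist()))
    requested = subspace_dim if subspace_dim is not None else min(n - g, 20)
    requested = min(requested, x.shape[1])
    d = 0
    for i in range(requested):
        if vals[i] <= 0 or vals[0] / vals[i] >= COND_MAX:
            break
        d = i + 1
    if d < 1:
        raise DimensionalityError(
            "pooled within-group covariance is singular in the requested "
            "subspace; try a smaller subspace_dim"
        )
    return _WithinSubspace(vecs[:, :d], vals[:d])


def mahalanobis_matrix(
    x: np.ndarray,
    labels,
    subspace_dim: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Pairwise Mahalanobis distances between group means.

    Distances use the pooled within-group covariance inverted inside the
    leading-eigenvector subspace (see module docstring).  Returns the sorted
    group names and the symmetric distance matrix.
    """
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    groups = _group_indices(labels)
    if any(len(idx) < 2 for idx in groups.values()):
        raise InsufficientDataError("every group needs at least 2 members")
    sub = _within_subspace(x, labels, subspace_dim)
    names = list(groups)
    means = {g: x[idx].mean(axis=0) for g, idx in groups.items()}
    d = np.zeros((len(names), len(names)))
    for i, j in combinations(range(len(names)), 2):
        d[i, j] = d[j, i] = sub.distance(means[names[i]], means[names[j]])
    return names, d


def point_to_group_distances(
    point: np.ndarray,
    x: np.ndarray,
    labels,
    subspace_dim: int | None = None,
) -> dict[str, float]:
    """Mahalanobis distance of a single point to each group mean, using the
    terminal-only pooled within-group covariance (a singleton contributes no
    covariance of its own)."""
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    sub = _within_subspace(x, labels, subspace_dim)
    return {
        g: sub.distance(point, x[idx].mean(axis=0))
        for g, idx in _group_indices(labels).items()
    }


# ---------------------------------------------------------------------------
# permutation test & CVA
# ---------------------------------------------------------------------------


def permutation_test(
    statistic,
    x: np.ndarray,
    labels,
    n_rounds: int = 10000,
    seed: int = DEFAULT_SEED,
    exact: bool = False,
) -> dict[tuple[str, str], float]:
    """One-sided permutation test on pairwise group-distance statistics.

    ``statistic(x, labels)`` must return ``(names, matrix)``.  Labels are
    permuted as a whole (group sizes preserved); the empirical p-value uses
    +1 smoothing with ">=" tie handling:
    ``p = (1 + #{permuted >= observed}) / (n_rounds + 1)``.

    With ``exact=True`` every distinct label arrangement is enumerated
    instead (feasible for small n) and the p-value is the exact exceedance
    fraction ``#{arrangement >= observed} / #arrangements`` — the identity
    arrangement is included, so p is never zero and no smoothing is needed.
    """
    labels = np.asarray(labels)
    names, observed = statistic(x, labels)
    if exact:
        from itertools import permutations as _perms

        arrangements = {tuple(labels[list(p)]) for p in _perms(range(len(labels)))}
        exceed = np.zeros_like(observed)
        for arr in arrangements:
            _, mat = statistic(x, np.asarray(arr))
            exceed += mat >= observed
        denom = len(arrangements)
    else:
        if n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(observed)
        for _ in range(n_rounds):
            perm = rng.permutation(labels)
            _, mat = statistic(x, perm)
            exceed += mat >= observed
        exceed = exceed + 1
        denom = n_rounds + 1
    pairs = {}
    for i, j in combinations(range(len(names)), 2):
        pairs[(names[i], names[j])] = float(exceed[i, j] / denom)
    return pairs


@dataclass
class CVAResult:
    group_names: list[str]
    canonical_axes: np.ndarray  # (n_axes, p), n_axes <= g - 1
    scores: np.ndarray  # (n, n_axes) per-specimen canonical scores
    pairwise_mahalanobis: np.ndarray  # (g, g) symmetric
    permutation_p: dict[tuple[str, str], float]
    n_permutations: int
    seed: int
    subspace_dim: int

    def p_matrix(self) -> np.ndarray:
        g = len(self.group_names)
        out = np.full((g, g), np.nan)
        for (a, b), p in self.permutation_p.items():
            i, j = self.group_names.index(a), self.group_names.index(b)
            out[i, j] = out[j, i] = p
        return out


def cva(
    data: AlignedDataset | np.ndarray,
    labels=None,
    subspace_dim: int | None = None,
    n_permutations: int = 10000,
    seed: int = DEFAULT_SEED,
) -> CVAResult:
    """Canonical variate analysis across archetype groups.

    Canonical axes maximise between-group relative to within-group variance
    inside the truncated within-covariance subspace; at most g - 1 axes are
    returned.  Pairwise Mahalanobis distances between group means are tested
    by permuting group labels over specimens (one-sided: larger distance =
    more separated).
    """
    if isinstance(data, AlignedDataset):
        if labels is None:
            labels = data.group_labels
        x = data.flattened()
    else:
        x = np.asarray(data, float)
    if labels is None:
        raise InsufficientDataError("CVA needs group labels")
    labels = np.asarray(labels)
    groups = _group_indices(labels)
    g = len(groups)

    sub = _within_subspace(x, labels, subspace_dim)
    # whiten within-group variation, then take principal axes of group means
    centred = x - x.mean(axis=0)
    whitened_axes = sub.vectors / np.sqrt(sub.values)  # (p, d)
    means = np.stack([x[idx].mean(axis=0) for idx in groups.values()])
    mw = (means - x.mean(axis=0)) @ whitened_axes
    _, s, vt = np.linalg.svd(mw - mw.mean(axis=0), full_matrices=False)
    n_axes = min(g - 1, int(np.sum(s > s[0] * 1e-9))) if len(s) else 0
    can_axes = (whitened_axes @ vt[:n_axes].T).T  # (n_axes, p)
    scores = centred @ can_axes.T

    names, dist = mahalanobis_matrix(x, labels, subspace_dim)
    if n_permutations > 0:
        # permute in the row space of the data: the truncated within-covariance
        # eigenvectors live there, so distances are unchanged but each round's
        # eigendecomposition shrinks from p x p to at most (n-1) x (n-1)
        reduced = pca_matrix(x).scores if x.shape[1] > x.shape[0] else x
        p = permutation_test(
            lambda xx, ll: mahalanobis_matrix(xx, ll, subspace_dim),
            reduced,
            labels,
            n_rounds=n_permutations,
            seed=seed,
        )
    else:
        p = {}
    return CVAResult(names, can_axes, scores, dist, p, n_permutations, seed, sub.dim)
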