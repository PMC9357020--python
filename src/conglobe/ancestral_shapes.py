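"""Ancestral landmark shapes by squared-change parsimony and the
archetype-similarity trajectory statistic.

Internal-node values minimise the sum over branches of squared coordinate
change divided by branch length (with equal branch lengths this coincides
with the Brownian-motion maximum-likelihood ancestral state).  Each landmark
coordinate is reconstructed independently, keeping ancestral configurations
in the same Procrustes frame as the terminals.

For the trajectory statistic, every ancestral node is treated as an
independent singleton group embedded among the terminals: its Mahalanobis
distances to the three archetype group means (using the terminal-only pooled
within-archetype covariance) are normalised to sum to 1, and similarities are
the reciprocals of the normalised distances.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, MappingError
from .ordination import point_to_group_distances
from .phylogeny import Phylogeny
from .superimposition import ARCHETYPES, AlignedDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# squared-change parsimony
# ---------------------------------------------------------------------------


def squared_change_parsimony(
    tree: Phylogeny, tip_values: Mapping[str, float | np.ndarray]
) -> dict[int, np.ndarray]:
    """Internal-node values minimising sum of (parent - child)^2 / length.

    ``tip_values`` maps taxon label -> scalar or vector; vectors are solved
    column-wise in one linear solve.  Returns values for every node (tips
    echo their data).  Zero-length branches are contracted: both endpoints
    are forced to the same value (with a warning).
    """
    tips = tree.tips()
    missing = [tree.taxon(t) for t in tips if tree.taxon(t) not in tip_values]
    if missing:
        raise MappingError(f"tips without values: {missing}")

    # contract zero-length branches by merging endpoint variables
    rep = {n: n for n in tree.nodes}

    def find(n: int) -> int:
        while rep[n] != n:
            rep[n] = rep[rep[n]]
            n = rep[n]
        return n

    for node in tree.preorder():
        par = tree.parent(node)
        if par is not None and tree.branch_length(node) == 0.0:
            warnings.warn(
                f"zero-length branch above node {node}: endpoint values forced equal",
                stacklevel=2,
            )
            rep[find(node)] = find(par)

    variables = sorted({find(n) for n in tree.nodes})
    var_index = {v: i for i, v in enumerate(variables)}

    first = np.atleast_1d(np.asarray(next(iter(tip_values.values())), float))
    m = first.size
    fixed_value: dict[int, np.ndarray] = {}
    for t in tips:
        v = find(t)
        val = np.atleast_1d(np.asarray(tip_values[tree.taxon(t)], float))
        if v in fixed_value and not np.allclose(fixed_value[v], val):
            raise MappingError("contracted tips carry conflicting values")
        fixed_value[v] = val

    free = [v for v in variables if v not in fixed_value]
    free_index = {v: i for i, v in enumerate(free)}
    nf = len(free)
    if nf == 0:
        return {n: fixed_value[find(n)] for n in tree.nodes}

    lap = np.zeros((nf, nf))
    rhs = np.zeros((nf, m))
    for node in tree.preorder():
        par = tree.parent(node)
        if par is None:
            continue
        length = tree.branch_length(node)
        if length == 0.0:
            continue
        w = 1.0 / length
        a, b = find(node), find(par)
        if a == b:
            continue
        for p, q in ((a, b), (b, a)):
            if p in free_index:
                i = free_index[p]
                lap[i, i] += w
                if q in free_index:
                    lap[i, free_index[q]] -= w
                else:
                    rhs[i] += w * fixed_value[q]
    solution = np.linalg.solve(lap, rhs)

    out: dict[int, np.ndarray] = {}
    for n in tree.nodes:
        v = find(n)
        out[n] = fixed_value[v] if v in fixed_value else solution[free_index[v]]
    return out


def scp_objective(tree: Phylogeny, values: Mapping[int, np.ndarray]) -> float:
    """Sum over branches of squared change / branch length for given values."""
    total = 0.0
    for node in tree.preorder():
        par = tree.parent(node)
        if par is None:
            continue
        length = tree.branch_length(node)
        diff = np.atleast_1d(values[node]) - np.atleast_1d(values[par])
        if length == 0.0:
            continue
        total += float(np.sum(diff**2)) / length
    return total


# ---------------------------------------------------------------------------
# ancestral configurations
# ---------------------------------------------------------------------------


@dataclass
class ContinuousASR:
    """Reconstructed landmark configurations at internal nodes."""

    tree: Phylogeny
    configurations: dict[int, np.ndarray]  # node -> (k, 2), tips included
    objective: float

    def node_configuration(self, node: int) -> np.ndarray:
        if node not in self.configurations:
            raise MappingError(f"node {node} has no reconstruction")
        return self.configurations[node]


def reconstruct_ancestral_configurations(
    aligned: AlignedDataset,
    tree: Phylogeny,
    tip_map: Mapping[str, str] | None = None,
) -> ContinuousASR:
    """Squared-change-parsimony reconstruction of ancestral shapes.

    ``tip_map`` maps taxon label -> specimen_id (identity by default).
    Reconstructed configurations stay in the Procrustes frame of ``aligned``.
    """
    ids = {s: i for i, s in enumerate(aligned.specimen_ids)}
    flat = aligned.flattened()
    tip_values: dict[str, np.ndarray] = {}
    missing = []
    for taxon in tree.taxa():
        spec = tip_map.get(taxon, taxon) if tip_map else taxon
        if spec not in ids:
            missing.append(taxon)
        else:
            tip_values[taxon] = flat[ids[spec]]
    if missing:
        raise MappingError(f"tree tips without aligned specimens: {missing}")
    values = squared_change_parsimony(tree, tip_values)
    k = aligned.n_landmarks
    configs = {n: v.reshape(k, 2) for n, v in values.items()}
    return ContinuousASR(tree, configs, scp_objective(tree, values))


# ---------------------------------------------------------------------------
# archetype similarity trajectories
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTrajectory:
    """Per ancestral node: distances to the three archetypes, their sum-to-1
    normalisation, and reciprocal similarities."""

    node_ids: list[int]
    archetypes: tuple[str, ...]
    raw_distances: np.ndarray  # (n_nodes, 3)
    normalized_distances: np.ndarray  # rows sum to 1
    similarities: np.ndarray  # 1 / normalised distance (inf at zero distance)

    def as_dict(self, node: int) -> dict[str, dict[str, float]]:
        i = self.node_ids.index(node)
        return {
            "raw": dict(zip(self.archetypes, self.raw_distances[i])),
            "normalized": dict(zip(self.archetypes, self.normalized_distances[i])),
            "similarity": dict(zip(self.archetypes, self.similarities[i])),
        }


def normalize_distances(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-1 normalisation and reciprocal similarities.

    A zero raw distance yields similarity +inf (degenerate input surfaced,
    not clamped), with a warning.
    """
    raw = np.asarray(raw, float)
    totals = raw.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise InsufficientDataError("distances sum to zero; cannot normalise")
    norm = raw / totals
    with np.errstate(divide="ignore"):
        sim = 1.0 / norm
    if np.any(norm == 0):
        warnings.warn("zero distance to an archetype: similarity reported as +inf", stacklevel=2)
    return norm, sim


def archetype_similarity(
    asr: ContinuousASR,
    aligned: AlignedDataset,
    node_ids: Sequence[int],
    subspace_dim: int | None = None,
) -> SimilarityTrajectory:
    """Archetype-similarity trajectory for the requested ancestral nodes.

    Each node's reconstructed configuration is measured against the three
    terminal archetype groups by Mahalanobis distance (terminal-only pooled
    within-archetype covariance, eigen-truncated subspace rule of the
    ordination module), normalised to sum 1 per node; similarity is the
    reciprocal of the normalised distance.
    """
    if aligned.group_labels is None:
        raise InsufficientDataError("aligned dataset carries no archetype labels")
    present = set(aligned.group_labels)
    if not set(ARCHETYPES) <= present:
        raise InsufficientDataError(f"need all three archetypes, have {sorted(present)}")
    flat = aligned.flattened()
    labels = np.asarray(aligned.group_labels)
    raw = np.zeros((len(node_ids), len(ARCHETYPES)))
    for i, node in enumerate(node_ids):
        point = asr.node_configuration(node).reshape(-1)
        dists = point_to_group_distances(point, flat, labels, subspace_dim)
        raw[i] = [dists[a] for a in ARCHETYPES]
    norm, sim = normalize_distances(raw)
    return SimilarityTrajectory(list(node_ids), ARCHETYPES, raw, norm, sim)


@dataclass
class TrendSummary:
    archetype: str
    rho: float  # Spearman rank correlation of similarity vs node order
    direction: str  # "increasing" | "decreasing" | "flat"


def trajectory_trend(
    trajectory: SimilarityTrajectory, node_order: Sequence[int] | None = None
) -> list[TrendSummary]:
    """Signed rank-correlation of similarity vs root-to-tip node order.

    ``node_order`` defaults to the trajectory's node list; it must follow an
    ancestor-to-descendant path.  Constant similarity is classified flat.
    """
    order = list(node_order) if node_order is not None else list(trajectory.node_ids)
    if len(order) < 3:
        raise InsufficientDataError("trend needs at least 3 nodes")
    idx = [trajectory.node_ids.index(n) for n in order]
    out = []
    ranks = np.arange(len(order), dtype=float)
    for j, archetype in enumerate(trajectory.archetypes):
        series = trajectory.similarities[idx, j]
        if np.allclose(series, series[0]):
            out.append(TrendSummary(archetype, 0.0, "flat"))
            continue
        finite = np.isfinite(series)
        rho = float(stats.spearmanr(ranks[finite], series[finite]).statistic)
        direction = "increasing" if rho > 0 else "decreasing" if rho < 0 else "flat"
        out.append(TrendSummary(archetype, rho, direction))
    return out
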