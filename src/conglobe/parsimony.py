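"""Equal-weights maximum parsimony for unordered multistate characters.

Tree length and ancestral state sets are computed with exact uniform-cost
dynamic programming (Sankoff recursions with 0/1 costs), which coincides with
Fitch's algorithm on binary trees and remains exact on multifurcations.
Missing (``?``) and inapplicable (``-``) cells are both treated as the full
state set, matching common practice under nonadditive coding.

Heuristic search follows the classic recipe: random-addition starting trees
followed by tree-bisection-reconnection (TBR) hill climbing with
first-improvement acceptance in randomized branch order.  Exhaustive
enumeration is available for small taxon sets and doubles as the oracle for
Bremer (decay) supports.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, MappingError
from .morpho_io import INAPPLICABLE, MISSING, CharacterMatrix
from .phylogeny import Phylogeny, tree_from_splits

logger = logging.getLogger(__name__)

_INF = np.inf

Split = frozenset  # frozenset of two frozensets of taxon labels


# ---------------------------------------------------------------------------
# character encoding
# ---------------------------------------------------------------------------


def _character_states(char: Mapping[str, str]) -> list[str]:
    observed = sorted({s for s in char.values() if s not in (MISSING, INAPPLICABLE)})
    if not observed:
        raise InsufficientDataError("character has no observed state")
    return observed


def _tip_cost_vectors(
    char: Mapping[str, str], states: Sequence[str]
) -> dict[str, np.ndarray]:
    index = {s: i for i, s in enumerate(states)}
    out = {}
    for taxon, symbol in char.items():
        v = np.full(len(states), _INF)
        if symbol in (MISSING, INAPPLICABLE):
            v[:] = 0.0
        else:
            v[index[symbol]] = 0.0
        out[taxon] = v
    return out


def _down_costs(
    tree: Phylogeny, char: Mapping[str, str], states: Sequence[str]
) -> dict[int, np.ndarray]:
    tips = _tip_cost_vectors(char, states)
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            taxon = tree.taxon(node)
            if taxon not in tips:
                raise MappingError(f"taxon {taxon!r} on tree but absent from character")
            down[node] = tips[taxon].copy()
        else:
            acc = np.zeros(len(states))
            for child in tree.children(node):
                c = down[child]
                acc += np.minimum(c, c.min() + 1.0)
            down[node] = acc
    return down


def fitch_length(tree: Phylogeny, char: Mapping[str, str]) -> int:
    """Minimum number of state changes for one unordered character.

    ``char`` maps taxon label -> state symbol (``?``/``-`` = full state set).
    """
    states = _character_states(char)
    down = _down_costs(tree, char, states)
    return int(down[tree.root].min())


# ---------------------------------------------------------------------------
# tree score (length, CI, RI)
# ---------------------------------------------------------------------------


@dataclass
class TreeScore:
    """Tree length with ensemble consistency and retention indices."""

    length: int  # s
    min_steps: int  # m = sum of per-character minima
    max_steps: int  # g = sum of per-character maxima on any tree

    @property
    def ci(self) -> float:
        return self.min_steps / self.length if self.length > 0 else float("nan")

    @property
    def ri(self) -> float:
        if self.max_steps == self.min_steps:
            return float("nan")
        return (self.max_steps - self.length) / (self.max_steps - self.min_steps)

    def rounded(self) -> tuple[float, float]:
        """CI and RI rounded to 2 decimals (round-half-even) for display."""
        return round(self.ci, 2), round(self.ri, 2)


def tree_score(tree: Phylogeny, matrix: CharacterMatrix) -> TreeScore:
    if matrix.n_characters == 0:
        raise InsufficientDataError("empty character matrix")
    s = m = g = 0
    for i in range(matrix.n_characters):
        col = matrix.column(i)
        observed = [v for v in col.values() if v not in (MISSING, INAPPLICABLE)]
        if not observed:
            continue
        s += fitch_length(tree, col)
        distinct = len(set(observed))
        m += distinct - 1
        freq = max(observed.count(x) for x in set(observed))
        g += len(observed) - freq
    return TreeScore(s, m, g)


# ---------------------------------------------------------------------------
# ancestral states (MPR sets + one most-parsimonious resolution)
# ---------------------------------------------------------------------------


@dataclass
class BranchChange:
    """A state change forced on the branch above ``node``."""

    node: int
    parent_states: frozenset[str]
    child_states: frozenset[str]
    unambiguous: bool  # both endpoint MPR sets are disjoint singletons


@dataclass
class AncestralStates:
    """Most-parsimonious state sets, one resolution, and branch changes."""

    states: dict[int, frozenset[str]]  # MPR set per node
    resolution: dict[int, str]  # one most-parsimonious labelling
    changes: list[BranchChange]
    length: int

    def unambiguous_changes(self) -> list[BranchChange]:
        return [c for c in self.changes if c.unambiguous]

    def state_origins(self, state: str) -> list[int]:
        """Nodes whose branch gains ``state`` in the resolution."""
        out = []
        for node, s in self.resolution.items():
            par = self._parents.get(node)
            if s == state and par is not None and self.resolution[par] != state:
                out.append(node)
        return out

    _parents: dict[int, int | None] = field(default_factory=dict, repr=False)


def fitch_asr(tree: Phylogeny, char: Mapping[str, str]) -> AncestralStates:
    """MPR state sets via exact down/up dynamic programming.

    A state belongs to a node's MPR set iff some most-parsimonious labelling
    assigns it there.  One concrete resolution is produced by backtracking
    (ties prefer the parent's state, then the smallest symbol).  A branch
    change is annotated whenever the endpoint MPR sets are disjoint;
    it is *unambiguous* when both sets are singletons.
    """
    states = _character_states(char)
    down = _down_costs(tree, char, states)
    length = int(down[tree.root].min())

    # outside costs: up[v][s] = best cost of the rest of the tree if v has state s
    up: dict[int, np.ndarray] = {tree.root: np.zeros(len(states))}
    for node in tree.preorder():
        if tree.is_tip(node):
            continue
        children = tree.children(node)
        mins = {c: np.minimum(down[c], down[c].min() + 1.0) for c in children}
        total = up[node] + sum(mins.values())
        for c in children:
            a = total - mins[c]
            up[c] = np.minimum(a, a.min() + 1.0)

    mpr: dict[int, frozenset[str]] = {}
    for node in tree.preorder():
        tot = down[node] + up[node]
        best = tot.min()
        mpr[node] = frozenset(states[i] for i in np.flatnonzero(tot <= best + 1e-9))

    # backtrack one most-parsimonious labelling
    resolution: dict[int, str] = {}
    for node in tree.preorder():
        par = tree.parent(node)
        if par is None:
            cand = down[node]
            best = cand.min()
            choices = [states[i] for i in np.flatnonzero(cand <= best + 1e-9)]
        else:
            ps = resolution[par]
            cand = down[node] + np.array([0.0 if s == ps else 1.0 for s in states])
            best = cand.min()
            choices = [states[i] for i in np.flatnonzero(cand <= best + 1e-9)]
            if ps in choices:
                choices = [ps]
        resolution[node] = min(choices)

    changes: list[BranchChange] = []
    parents = {n: tree.parent(n) for n in tree.nodes}
    for node in tree.preorder():
        par = parents[node]
        if par is None:
            continue
        a, b = mpr[par], mpr[node]
        if a.isdisjoint(b):
            changes.append(
                BranchChange(node, a, b, unambiguous=len(a) == 1 and len(b) == 1)
            )
    asr = AncestralStates(mpr, resolution, changes, length)
    asr._parents = parents
    return asr


# ---------------------------------------------------------------------------
# unrooted search machinery (internal representation: adjacency dict)
# ---------------------------------------------------------------------------


def _encode_matrix(matrix: CharacterMatrix) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Taxa, per-leaf bitmask array (n_taxa, n_unique_chars) and column weights.

    Duplicate columns are collapsed with integer weights.  Bit i of a mask is
    state i of that character's observed-state alphabet; ``?``/``-`` get the
    full mask.
    """
    taxa = list(matrix.taxa)
    cols = []
    for i in range(matrix.n_characters):
        observed = sorted(matrix.observed_states(i))
        if not observed:
            continue
        index = {s: 1 << j for j, s in enumerate(observed)}
        full = (1 << len(observed)) - 1
        col = tuple(
            index.get(matrix.cells[t, i], full)
            if matrix.cells[t, i] not in (MISSING, INAPPLICABLE)
            else full
            for t in range(matrix.n_taxa)
        )
        cols.append(col)
    unique: dict[tuple, int] = {}
    for col in cols:
        unique[col] = unique.get(col, 0) + 1
    masks = np.array(list(unique), dtype=np.int64).T if unique else np.zeros((len(taxa), 0), np.int64)
    weights = np.array(list(unique.values()), dtype=np.int64)
    return taxa, masks, weights


def _unrooted_length(adj: dict[int, list[int]], masks: np.ndarray, weights: np.ndarray) -> int:
    """Vectorized Fitch length of an unrooted binary tree.

    ``adj`` maps node -> neighbours; leaves are 0..n-1 indexing rows of
    ``masks``.  The tree is scored rooted along the edge at leaf 0.
    """
    if masks.shape[1] == 0:
        return 0
    n_chars = masks.shape[1]
    cost = np.zeros(n_chars, dtype=np.int64)
    node_mask: dict[int, np.ndarray] = {}
    # iterative postorder rooted along the edge at the smallest leaf present
    anchor = min(k for k in adj if k < masks.shape[0])
    root = adj[anchor][0]
    order: list[tuple[int, int]] = []
    stack = [(root, anchor)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(order):
        nbs = [nb for nb in adj[node] if nb != parent]
        if not nbs:  # leaf
            node_mask[node] = masks[node]
            continue
        m1, m2 = node_mask[nbs[0]], node_mask[nbs[1]]
        inter = m1 & m2
        empty = inter == 0
        cost += empty
        node_mask[node] = np.where(empty, m1 | m2, inter)
    final = node_mask[root] & masks[anchor]
    cost += final == 0
    return int((cost * weights).sum())


def _splits_of(adj: dict[int, list[int]], taxa: Sequence[str]) -> frozenset[Split]:
    """Canonical non-trivial split set of an unrooted adjacency tree."""
    n = len(taxa)
    all_taxa = frozenset(taxa)
    splits: set[Split] = set()

    def side(node: int, parent: int) -> frozenset[str]:
        if node < n:
            return frozenset([taxa[node]])
        acc: set[str] = set()
        for nb in adj[node]:
            if nb != parent:
                acc |= side(nb, node)
        return frozenset(acc)

    seen = set()
    for u in adj:
        for v in adj[u]:
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            a = side(u, v)
            b = all_taxa - a
            if len(a) >= 2 and len(b) >= 2:
                splits.add(frozenset([a, b]))
    return frozenset(splits)


def _add_edge(adj, u, v):
    adj[u].append(v)
    adj[v].append(u)


def _remove_edge(adj, u, v):
    adj[u].remove(v)
    adj[v].remove(u)


def _copy_adj(adj):
    return {k: list(v) for k, v in adj.items()}


def _edges_in(adj, nodes):
    out = []
    for u in nodes:
        for v in adj[u]:
            if v in nodes and u < v:
                out.append((u, v))
    return out


def _component(adj, start, blocked_edge):
    bu, bv = blocked_edge
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if (node, nb) in ((bu, bv), (bv, bu)):
                continue
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _tbr_neighbours(
    adj: dict[int, list[int]], rng: np.random.Generator
) -> Iterator[dict[int, list[int]]]:
    """Yield TBR rearrangements: bisect every branch, reconnect via all
    pairs of reattachment edges, in randomized branch order."""
    fresh = max(adj) + 1
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    rng.shuffle(edges)
    for u, v in edges:
        base = _copy_adj(adj)
        _remove_edge(base, u, v)
        comp_u = _component(base, u, (u, v))
        comp_v = _component(base, v, (u, v))

        def prepare(comp, end):
            """Suppress the degree-2 node left by bisection; return component
            node set and its reattachment edges (or a lone leaf)."""
            work = comp
            if len(base[end]) == 2:
                a, b = base[end]
                _remove_edge(base, end, a)
                _remove_edge(base, end, b)
                _add_edge(base, a, b)
                work = comp - {end}
                return work, _edges_in(base, work), (end, a, b)
            if len(base[end]) == 0:  # lone leaf
                return comp, [], None
            return comp, _edges_in(base, comp), None

        nodes_u, edges_u, undo_u = prepare(comp_u, u)
        nodes_v, edges_v, undo_v = prepare(comp_v, v)

        att_u = edges_u if edges_u else [None]
        att_v = edges_v if edges_v else [None]
        for e1 in att_u:
            for e2 in att_v:
                new = _copy_adj(base)
                nid = fresh
                if e1 is None:
                    p = next(iter(nodes_u))  # lone leaf
                else:
                    a, b = e1
                    _remove_edge(new, a, b)
                    p = nid
                    nid += 1
                    new[p] = []
                    _add_edge(new, p, a)
                    _add_edge(new, p, b)
                if e2 is None:
                    q = next(iter(nodes_v))
                else:
                    a, b = e2
                    _remove_edge(new, a, b)
                    q = nid
                    nid += 1
                    new[q] = []
                    _add_edge(new, q, a)
                    _add_edge(new, q, b)
                _add_edge(new, p, q)
                # drop suppressed node entries
                yield {k: vs for k, vs in new.items() if vs}


def _random_addition_tree(
    order: Sequence[int], masks: np.ndarray, weights: np.ndarray, n_leaves: int
) -> dict[int, list[int]]:
    """Greedy stepwise addition in the given (random) taxon order."""
    a, b, c = order[0], order[1], order[2]
    hub = n_leaves
    adj: dict[int, list[int]] = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    fresh = n_leaves + 1
    for leaf in order[3:]:
        best = None
        best_len = None
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for u, v in edges:
            cand = _copy_adj(adj)
            _remove_edge(cand, u, v)
            cand[fresh] = []
            cand[leaf] = []
            _add_edge(cand, fresh, u)
            _add_edge(cand, fresh, v)
            _add_edge(cand, fresh, leaf)
            ln = _unrooted_length(cand, masks, weights)
            if best_len is None or ln < best_len:
                best, best_len = cand, ln
        adj = best
        fresh += 1
    return adj


def _hill_climb(
    adj: dict[int, list[int]],
    masks: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict[int, list[int]], int]:
    cur = adj
    cur_len = _unrooted_length(cur, masks, weights)
    improved = True
    while improved:
        improved = False
        for nb in _tbr_neighbours(cur, rng):
            ln = _unrooted_length(nb, masks, weights)
            if ln < cur_len:
                cur, cur_len = nb, ln
                improved = True
                break
    return cur, cur_len


def _adj_to_tree(adj: dict[int, list[int]], taxa: Sequence[str]) -> Phylogeny:
    return tree_from_splits(taxa, _splits_of(adj, taxa))


@dataclass
class SearchResult:
    """Outcome of a parsimony tree search."""

    trees: list[Phylogeny]
    best_length: int
    truncated: bool = False
    n_replicates: int = 0

    def strict_consensus(self) -> Phylogeny:
        return strict_consensus(self.trees)


def heuristic_search(
    matrix: CharacterMatrix,
    n_replicates: int = 1000,
    hold_per_rep: int = 1,
    max_trees: int = 10000,
    seed: int | None = None,
) -> SearchResult:
    """Random-addition + TBR hill-climbing search for shortest trees.

    Each replicate builds a random-addition starting tree, then applies TBR
    with first-improvement acceptance until no strictly shorter neighbour
    exists.  All distinct topologies attaining the best length found are
    kept (canonical split-set hashing), capped at ``max_trees``.
    """
    if matrix.n_taxa < 4:
        raise InsufficientDataError("search needs at least 4 taxa")
    taxa, masks, weights = _encode_matrix(matrix)
    n = len(taxa)
    rng = np.random.default_rng(seed)
    best_len: int | None = None
    found: dict[frozenset, dict[int, list[int]]] = {}
    truncated = False
    for _ in range(n_replicates):
        order = rng.permutation(n)
        start = _random_addition_tree(list(order), masks, weights, n)
        opt, opt_len = _hill_climb(start, masks, weights, rng)
        candidates = [(opt, opt_len)]
        if hold_per_rep > 1:
            held = 1
            for nb in _tbr_neighbours(opt, rng):
                if held >= hold_per_rep:
                    break
                if _unrooted_length(nb, masks, weights) == opt_len:
                    candidates.append((nb, opt_len))
                    held += 1
        for cand, ln in candidates:
            if best_len is None or ln < best_len:
                best_len = ln
                found = {}
            if ln == best_len:
                key = _splits_of(cand, taxa)
                if key not in found:
                    if len(found) >= max_trees:
                        truncated = True
                        logger.warning("max_trees=%d reached; truncating", max_trees)
                    else:
                        found[key] = cand
    ordered = sorted(found.items(), key=lambda kv: _topology_key(kv[0]))
    trees = [_adj_to_tree(adj, taxa) for _, adj in ordered]
    return SearchResult(trees, int(best_len), truncated, n_replicates)


def _topology_key(splits: frozenset):
    """Deterministic sort key for a canonical split set."""
    return sorted(sorted(sorted(side) for side in split) for split in splits)


def _all_topologies(n_leaves: int) -> Iterator[dict[int, list[int]]]:
    """All unrooted binary topologies on leaves 0..n-1 by stepwise addition."""
    hub = n_leaves
    base = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}

    def extend(adj: dict[int, list[int]], leaf: int, fresh: int):
        if leaf == n_leaves:
            yield adj
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for u, v in edges:
            cand = _copy_adj(adj)
            _remove_edge(cand, u, v)
            cand[fresh] = []
            cand[leaf] = []
            _add_edge(cand, fresh, u)
            _add_edge(cand, fresh, v)
            _add_edge(cand, fresh, leaf)
            yield from extend(cand, leaf + 1, fresh + 1)

    if n_leaves == 3:
        yield base
    else:
        yield from extend(base, 3, n_leaves + 1)


def exhaustive_search(matrix: CharacterMatrix) -> SearchResult:
    """Exact search by enumerating every unrooted topology (<= 9 taxa)."""
    if matrix.n_taxa > 9:
        raise InsufficientDataError("exhaustive search is limited to 9 taxa")
    if matrix.n_taxa < 3:
        raise InsufficientDataError("need at least 3 taxa")
    taxa, masks, weights = _encode_matrix(matrix)
    best_len: int | None = None
    best: list[dict[int, list[int]]] = []
    for adj in _all_topologies(len(taxa)):
        ln = _unrooted_length(adj, masks, weights)
        if best_len is None or ln < best_len:
            best_len, best = ln, [adj]
        elif ln == best_len:
            best.append(adj)
    trees = [_adj_to_tree(adj, taxa) for adj in best]
    return SearchResult(trees, int(best_len))


# ---------------------------------------------------------------------------
# consensus and Bremer support
# ---------------------------------------------------------------------------


def strict_consensus(trees: Sequence[Phylogeny]) -> Phylogeny:
    """Tree containing exactly the bipartitions present in every input tree."""
    if not trees:
        raise InsufficientDataError("no trees to summarise")
    taxa = set(trees[0].taxa())
    for t in trees[1:]:
        if set(t.taxa()) != taxa:
            raise MappingError("trees have different tip sets")
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common &= t.bipartitions()
    return tree_from_splits(sorted(taxa), common)


@dataclass
class BremerSupport:
    split: Split
    support: int  # decay value (extra steps to lose the split)
    capped: bool  # True means ">= support" (no contradicting tree found)


def _suboptimal_pool(
    matrix: CharacterMatrix,
    mpts_adj: list[dict[int, list[int]]],
    slack: int,
    rng: np.random.Generator,
) -> list[tuple[frozenset, int]]:
    """(splits, length) pool of trees within best+slack.

    Exhaustive for <= 9 taxa; otherwise a one-step TBR sweep around each
    shortest tree (a heuristic: reported supports are then upper bounds).
    """
    taxa, masks, weights = _encode_matrix(matrix)
    pool: dict[frozenset, int] = {}
    if matrix.n_taxa <= 9:
        best = None
        entries = []
        for adj in _all_topologies(len(taxa)):
            ln = _unrooted_length(adj, masks, weights)
            entries.append((adj, ln))
            best = ln if best is None else min(best, ln)
        for adj, ln in entries:
            if ln <= best + slack:
                key = _splits_of(adj, taxa)
                pool[key] = min(pool.get(key, ln), ln)
    else:
        best = min(_unrooted_length(a, masks, weights) for a in mpts_adj)
        for adj in mpts_adj:
            pool[_splits_of(adj, taxa)] = _unrooted_length(adj, masks, weights)
            for nb in _tbr_neighbours(adj, rng):
                ln = _unrooted_length(nb, masks, weights)
                if ln <= best + slack:
                    key = _splits_of(nb, taxa)
                    pool[key] = min(pool.get(key, ln), ln)
    return list(pool.items())


def bremer_supports(
    matrix: CharacterMatrix,
    search: SearchResult,
    max_subopt: int = 10,
    seed: int | None = None,
) -> list[BremerSupport]:
    """Decay values for every non-trivial split of the strict consensus.

    For each split, the support is the smallest extra length d (1..cap) at
    which trees lacking the split appear among trees within best+d; splits
    still uncontradicted at best+cap are reported capped (">= cap").
    """
    rng = np.random.default_rng(seed)
    consensus = strict_consensus(search.trees)
    taxa, masks, weights = _encode_matrix(matrix)
    mpts_adj = []
    for t in search.trees:
        # rebuild the adjacency form of each shortest tree from its splits
        adj = _tree_to_adj(t, taxa)
        mpts_adj.append(adj)
    best = search.best_length
    pool = _suboptimal_pool(matrix, mpts_adj, max_subopt, rng)
    out = []
    for split in sorted(consensus.bipartitions(), key=_split_key):
        contradicting = [ln for splits, ln in pool if split not in splits]
        if contradicting:
            d = min(contradicting) - best
            out.append(BremerSupport(split, int(max(d, 0)), capped=False))
        else:
            out.append(BremerSupport(split, max_subopt, capped=True))
    return out


def _split_key(split: Split):
    return sorted(sorted(side) for side in split)


def _tree_to_adj(tree: Phylogeny, taxa: Sequence[str]) -> dict[int, list[int]]:
    """Unrooted adjacency (leaves = indices into ``taxa``) from a rooted tree,
    suppressing the root if it has degree 2."""
    index = {t: i for i, t in enumerate(taxa)}
    adj: dict[int, list[int]] = {}
    next_id = [len(taxa)]
    node_id: dict[int, int] = {}
    for node in tree.preorder():
        if tree.is_tip(node):
            node_id[node] = index[tree.taxon(node)]
        else:
            node_id[node] = next_id[0]
            next_id[0] += 1
        adj.setdefault(node_id[node], [])
        par = tree.parent(node)
        if par is not None:
            _add_edge(adj, node_id[node], node_id[par])
    rid = node_id[tree.root]
    if len(adj[rid]) == 2:
        a, b = adj[rid]
        _remove_edge(adj, rid, a)
        _remove_edge(adj, rid, b)
        _add_edge(adj, a, b)
        del adj[rid]
    return adj
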