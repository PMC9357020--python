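"""Rooted phylogeny container with stable integer node IDs.

The container is deliberately small: a parent map, children lists, branch
lengths and tip labels.  Node IDs are assigned deterministically in preorder
with the root numbered 1, so that published node numbers can be mapped onto a
reimplementation via a relabelling table.  Newick round-trips are delegated to
dendropy in :mod:`conglobe.morpho_io`.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

from .errors import MappingError


class Phylogeny:
    """A rooted tree with unique integer node IDs and default branch length 1.

    Parameters
    ----------
    parent:
        Mapping child ID -> parent ID.  Exactly one node (the root) is absent
        from the keys or maps to ``None``.
    lengths:
        Mapping node ID -> length of the branch above the node.  Missing
        entries default to 1.0 (the equal-branch-length assumption used for
        ancestral reconstruction).
    tip_labels:
        Mapping tip ID -> taxon label.  IDs absent from ``children`` must all
        be labelled; labels must be unique.
    """

    def __init__(
        self,
        parent: Mapping[int, int | None],
        lengths: Mapping[int, float] | None = None,
        tip_labels: Mapping[int, str] | None = None,
    ) -> None:
        self._parent: dict[int, int | None] = dict(parent)
        self._children: dict[int, list[int]] = {}
        roots = []
        for node, par in self._parent.items():
            self._children.setdefault(node, [])
            if par is None:
                roots.append(node)
            else:
                self._children.setdefault(par, []).append(node)
                if par not in self._parent:
                    self._parent[par] = None
                    roots.append(par)
        if len(roots) != 1:
            raise MappingError(f"tree must have exactly one root, found {roots}")
        self.root: int = roots[0]
        self._length: dict[int, float] = {n: 1.0 for n in self._parent}
        if lengths:
            for n, ln in lengths.items():
                if ln < 0:
                    raise ValueError(f"negative branch length on node {n}")
                self._length[n] = float(ln)
        self._taxon: dict[int, str] = dict(tip_labels or {})
        tips = [n for n, ch in self._children.items() if not ch]
        missing = [n for n in tips if n not in self._taxon]
        if missing:
            raise MappingError(f"unlabelled tips: {missing}")
        labels = list(self._taxon.values())
        if len(set(labels)) != len(labels):
            raise MappingError("tip labels are not unique")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_nested(
        cls, nested, lengths: Mapping[str, float] | None = None
    ) -> "Phylogeny":
        """Build from nested tuples of taxon labels, e.g. ``(("A","B"),("C","D"))``.

        IDs are assigned in preorder, root = 1.  ``lengths`` optionally maps
        taxon labels to terminal branch lengths (internal branches default 1).
        """
        parent: dict[int, int | None] = {}
        tip_labels: dict[int, str] = {}
        lens: dict[int, float] = {}
        counter = [0]

        def walk(sub, par: int | None) -> None:
            counter[0] += 1
            me = counter[0]
            parent[me] = par
            if isinstance(sub, (tuple, list)):
                for child in sub:
                    walk(child, me)
            else:
                tip_labels[me] = str(sub)
                if lengths and str(sub) in lengths:
                    lens[me] = lengths[str(sub)]

        walk(nested, None)
        return cls(parent, lens, tip_labels)

    def relabelled_preorder(self) -> "Phylogeny":
        """Return a copy with IDs renumbered 1..n in preorder (children in
        current order)."""
        mapping: dict[int, int] = {}
        for i, node in enumerate(self.preorder(), start=1):
            mapping[node] = i
        parent = {
            mapping[n]: (None if p is None else mapping[p])
            for n, p in self._parent.items()
        }
        lengths = {mapping[n]: l for n, l in self._length.items()}
        tips = {mapping[n]: t for n, t in self._taxon.items()}
        return Phylogeny(parent, lengths, tips)

    def copy(self) -> "Phylogeny":
        return Phylogeny(dict(self._parent), dict(self._length), dict(self._taxon))

    # -- basic queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self._parent)

    @property
    def nodes(self) -> list[int]:
        return list(self._parent)

    def parent(self, node: int) -> int | None:
        return self._parent[node]

    def children(self, node: int) -> list[int]:
        return list(self._children[node])

    def is_tip(self, node: int) -> bool:
        return not self._children[node]

    def tips(self) -> list[int]:
        return [n for n in self.preorder() if self.is_tip(n)]

    def taxa(self) -> list[str]:
        return [self._taxon[t] for t in self.tips()]

    def taxon(self, tip: int) -> str:
        return self._taxon[tip]

    def tip_of(self, taxon: str) -> int:
        for n, t in self._taxon.items():
            if t == taxon:
                return n
        raise MappingError(f"taxon {taxon!r} not on tree")

    def branch_length(self, node: int) -> float:
        return self._length[node]

    def set_branch_length(self, node: int, length: float) -> None:
        if length < 0:
            raise ValueError("negative branch length")
        self._length[node] = float(length)

    # -- traversals ----------------------------------------------------------

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self._children[node]))

    def postorder(self) -> Iterator[int]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self._children[node])
        return iter(reversed(out))

    def internal_nodes(self) -> list[int]:
        return [n for n in self.preorder() if not self.is_tip(n)]

    # -- set-based views -----------------------------------------------------

    def clusters(self) -> dict[int, frozenset[str]]:
        """Taxon set under each node (tips map to singletons)."""
        out: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if self.is_tip(node):
                out[node] = frozenset([self._taxon[node]])
            else:
                acc: set[str] = set()
                for ch in self._children[node]:
                    acc |= out[ch]
                out[node] = frozenset(acc)
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial unrooted splits of the taxon set."""
        all_taxa = frozenset(self.taxa())
        splits: set[frozenset[frozenset[str]]] = set()
        for node, cluster in self.clusters().items():
            if node == self.root:
                continue
            other = all_taxa - cluster
            if len(cluster) >= 2 and len(other) >= 2:
                splits.add(frozenset([cluster, other]))
        return splits

    # -- serialisation -------------------------------------------------------

    def to_newick(self, include_lengths: bool = True) -> str:
        def fmt(node: int) -> str:
            if self.is_tip(node):
                base = self._taxon[node]
            else:
                base = "(" + ",".join(fmt(c) for c in self._children[node]) + ")"
            if include_lengths and self._parent[node] is not None:
                return f"{base}:{self._length[node]:g}"
            return base

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Phylogeny({len(self.tips())} tips, root={self.root})"


def tree_from_splits(
    taxa: Sequence[str], splits: Iterable[frozenset[frozenset[str]]]
) -> Phylogeny:
    """Build a (possibly polytomous) rooted tree realising exactly ``splits``.

    The tree is rooted on the branch leading to the alphabetically first
    taxon, so node IDs are deterministic.  Splits must be pairwise compatible.
    """
    taxa = sorted(taxa)
    ref = taxa[0]
    # convert each split to the cluster not containing the reference taxon
    clusters = {frozenset(taxa) - frozenset([ref])}
    for split in splits:
        a, b = tuple(split)
        clusters.add(a if ref not in a else b)
    for t in taxa:
        if t != ref:
            clusters.add(frozenset([t]))
    ordered = sorted(clusters, key=lambda c: (-len(c), sorted(c)))
    parent: dict[int, int | None] = {1: None}
    tip_labels: dict[int, str] = {}
    counter = [1]
    # root node 1 has the reference tip and the big cluster as children
    counter[0] += 1
    ref_tip = counter[0]
    parent[ref_tip] = 1
    tip_labels[ref_tip] = ref
    cluster_node: dict[frozenset[str], int] = {}

    for cluster in ordered:
        counter[0] += 1
        me = counter[0]
        # parent: smallest strictly containing cluster, else the root
        par = 1
        best: frozenset[str] | None = None
        for other in ordered:
            if other is not cluster and cluster < other:
                if best is None or len(other) < len(best):
                    best = other
        if best is not None:
            par = cluster_node[best]
        parent[me] = par
        cluster_node[cluster] = me
        if len(cluster) == 1:
            tip_labels[me] = next(iter(cluster))
    return Phylogeny(parent, None, tip_labels).relabelled_preorder()
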