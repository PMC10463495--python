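"""Rooted phylogeny with branch lengths.

Newick parsing, writing and re-rooting are delegated to dendropy; the
class itself keeps a flat array representation (parent pointers, child
lists, postorder) that the pruning engine consumes directly.

Branch lengths are expected numbers of substitutions per site.  The
Newick dialect is strict: unquoted labels, branch lengths mandatory on
every non-root edge, any length on the root edge ignored, polytomies
rejected by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .io import FormatError, ValidationError


@dataclass
class Phylogeny:
    """Rooted binary tree over named leaves.

    Nodes are integers ``0..n_nodes-1``; ``parent[i]`` is ``-1`` for the
    root; ``length[i]`` is the length of the edge above node ``i``
    (``nan`` for the root).  ``name[i]`` is the taxon label for leaves
    and an automatically assigned ``N<k>`` label for unnamed internal
    nodes.
    """

    parent: np.ndarray
    length: np.ndarray
    children: list[list[int]]
    name: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.intp)
        self.length = np.asarray(self.length, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self._root = int(roots[0])
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValidationError("duplicate leaf labels")
        nonroot = np.arange(self.n_nodes) != self._root
        if np.any(~np.isfinite(self.length[nonroot])):
            bad = [self.name[i] for i in np.flatnonzero(nonroot & ~np.isfinite(self.length))]
            raise FormatError(f"missing branch length above node(s): {bad}")
        if np.any(self.length[nonroot] < 0):
            raise ValidationError("negative branch length")
        self._index = {n: i for i, n in enumerate(self.name)}

    # -- basic structure ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.name)

    @property
    def root(self) -> int:
        return self._root

    @property
    def leaves(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if ch]

    @property
    def leaf_names(self) -> list[str]:
        return [self.name[i] for i in self.leaves]

    def node(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no node named {name!r}") from None

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self._root]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self.children[u])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def path_to_root(self, node: int) -> list[int]:
        """Nodes from ``node`` up to and including the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, taxa) -> int:
        """Most recent common ancestor of a set of leaf names."""
        paths = []
        for t in taxa:
            paths.append(set(self.path_to_root(self.node(t))))
        common = set.intersection(*paths)
        # deepest common node = the one whose ancestor chain is longest
        return max(common, key=lambda u: len(self.path_to_root(u)))

    def with_lengths(self, lengths: dict[str, float]) -> "Phylogeny":
        """Copy of the tree with branch lengths replaced (keyed by child node name)."""
        new = self.length.copy()
        for nm, t in lengths.items():
            i = self.node(nm)
            if i == self._root:
                continue
            new[i] = t
        return Phylogeny(self.parent.copy(), new, [list(c) for c in self.children],
                         list(self.name))

    # -- dendropy bridge -------------------------------------------------

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree, allow_polytomies: bool = False
                       ) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.intp)
        length = np.full(len(nodes), np.nan)
        children: list[list[int]] = [[] for _ in nodes]
        names: list[str] = [""] * len(nodes)
        auto = 0
        for i, n in enumerate(nodes):
            kids = n.child_nodes()
            if kids and len(kids) != 2 and not allow_polytomies:
                raise FormatError(
                    f"polytomy (degree {len(kids)}) at node "
                    f"{n.taxon.label if n.taxon else i}; resolve upstream"
                )
            for c in kids:
                j = idx[id(c)]
                parent[j] = i
                children[i].append(j)
            if n.taxon is not None:
                names[i] = n.taxon.label
            elif n.label:
                names[i] = n.label
            if n.parent_node is not None:
                if n.edge.length is None:
                    who = names[i] or f"node #{i}"
                    raise FormatError(f"missing branch length above {who}")
                length[i] = float(n.edge.length)
        used = set(filter(None, names))
        for i, nm in enumerate(names):
            if not nm:
                auto += 1
                while f"N{auto}" in used:
                    auto += 1
                names[i] = f"N{auto}"
        return cls(parent, length, children, names)

    def _to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {self._root: dtree.seed_node}
        for u in self.preorder():
            dn = dnodes[u]
            if not self.children[u]:
                dn.taxon = taxa.new_taxon(self.name[u])
            else:
                dn.label = self.name[u]
            if self.parent[u] >= 0:
                dn.edge.length = float(self.length[u])
            for c in self.children[u]:
                dnodes[c] = dn.new_child()
        return dtree

    @classmethod
    def from_newick(cls, newick: str, allow_polytomies: bool = False) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        return cls._from_dendropy(dtree, allow_polytomies=allow_polytomies)

    def to_newick(self, internal_labels: bool = False) -> str:
        dtree = self._to_dendropy()
        if not internal_labels:
            for n in dtree.preorder_node_iter():
                if n.child_nodes():
                    n.label = None
        return dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
        ).strip()

    def rerooted(self, edge_child: str, fraction: float = 0.5) -> "Phylogeny":
        """New tree rooted on the edge above ``edge_child``.

        ``fraction`` is the portion of that edge assigned below the new
        root (towards the child).  Used for re-rooting invariance checks;
        under a reversible model the likelihood must not change.
        """
        if not 0.0 <= fraction <= 1.0:
            raise ValidationError("fraction must lie in [0, 1]")
        dtree = self._to_dendropy()
        target = None
        for n in dtree.preorder_node_iter():
            nm = n.taxon.label if n.taxon else n.label
            if nm == edge_child and n.parent_node is not None:
                target = n
                break
        if target is None:
            raise KeyError(f"no non-root node named {edge_child!r}")
        t = target.edge.length
        dtree.reroot_at_edge(
            target.edge,
            length1=(1.0 - fraction) * t,  # towards old parent
            length2=fraction * t,          # towards child
            update_bipartitions=False,
        )
        dtree.suppress_unifurcations()  # the old root becomes degree-2
        for n in dtree.preorder_node_iter():  # drop stale internal labels
            if n.child_nodes():
                n.label = None
        return Phylogeny._from_dendropy(dtree)


def read_tree(path: str | Path, allow_polytomies: bool = False) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    return Phylogeny.from_newick(Path(path).read_text(),
                                 allow_polytomies=allow_polytomies)


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
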