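"""Ultrametric phylogeny container used throughout the package.

The comparative machinery needs a rooted, strictly bifurcating tree whose
root-to-tip distances are all equal (branch lengths in relative time, root
depth conventionally rescaled to 1).  Newick parsing and writing are
delegated to :mod:`dendropy`; internally the tree is held as flat arrays in
a canonical preorder so that downstream code (regime painting, covariance
construction, simulation) can index nodes stably and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for structurally invalid input trees."""


@dataclass
class UltrametricTree:
    """Rooted bifurcating ultrametric tree in canonical preorder.

    Node 0 is the root; every node stores its parent index and the length of
    the branch subtending it (the root's is 0).  Children are ordered by the
    lexicographically smallest tip label in their clade, which makes node
    indices, Newick output and every downstream enumeration deterministic.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]]
    labels: list[str | None]
    _times: np.ndarray | None = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------ build
    @classmethod
    def from_dendropy(
        cls,
        tree: dendropy.Tree,
        rescale: bool = False,
        rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    ) -> "UltrametricTree":
        root = tree.seed_node

        def min_tip_label(node) -> str:
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("tree has an unlabeled tip")
                return node.taxon.label
            return min(min_tip_label(c) for c in node.child_nodes())

        parent: list[int] = []
        lengths: list[float] = []
        children: list[list[int]] = []
        labels: list[str | None] = []

        def add(node, parent_idx: int) -> int:
            idx = len(parent)
            parent.append(parent_idx)
            if parent_idx < 0:
                lengths.append(0.0)
            else:
                if node.edge.length is None:
                    raise TreeError("tree has a branch without a length")
                lengths.append(float(node.edge.length))
            children.append([])
            labels.append(
                " ".join(node.taxon.label.split()) if node.is_leaf() else None
            )
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise TreeError(
                    f"tree is not strictly bifurcating: node with {len(kids)} children"
                )
            for child in sorted(kids, key=min_tip_label):
                cidx = add(child, idx)
                children[idx].append(cidx)
            return idx

        add(root, -1)
        out = cls(
            parent=np.asarray(parent, dtype=int),
            edge_length=np.asarray(lengths, dtype=float),
            children=children,
            labels=labels,
        )
        out._validate(rtol=rtol)
        if rescale:
            out = out.rescale_depth(1.0)
        return out

    @classmethod
    def from_newick(
        cls,
        newick: str,
        rescale: bool = False,
        rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    ) -> "UltrametricTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree, rescale=rescale, rtol=rtol)

    def _validate(self, rtol: float) -> None:
        if self.n_tips < 2:
            raise TreeError("tree must have at least 2 tips")
        if np.any(self.edge_length[1:] < 0):
            raise TreeError("negative branch length")
        tips = self.tip_indices
        tip_labels = [self.labels[i] for i in tips]
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeError("duplicate tip labels")
        depths = self.times[tips]
        dev = float(np.max(depths) - np.min(depths))
        if dev > rtol * max(float(np.max(depths)), np.finfo(float).tiny):
            raise TreeError(
                f"tree is not ultrametric: max root-to-tip deviation {dev:.6g} "
                f"exceeds tolerance (relative {rtol:g})"
            )

    # ------------------------------------------------------------- properties
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def is_leaf(self) -> np.ndarray:
        return np.array([len(c) == 0 for c in self.children])

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf)

    @property
    def n_tips(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def times(self) -> np.ndarray:
        """Time of each node measured from the root (root = 0)."""
        if self._times is None:
            t = np.zeros(self.n_nodes)
            for i in range(1, self.n_nodes):  # preorder: parent precedes child
                t[i] = t[self.parent[i]] + self.edge_length[i]
            self._times = t
        return self._times

    @property
    def depth(self) -> float:
        return float(np.max(self.times[self.tip_indices]))

    # ------------------------------------------------------------- operations
    def rescale_depth(self, depth: float = 1.0) -> "UltrametricTree":
        scale = depth / self.depth
        return UltrametricTree(
            parent=self.parent.copy(),
            edge_length=self.edge_length * scale,
            children=[list(c) for c in self.children],
            labels=list(self.labels),
        )

    def relabel_tips(self, labels: dict[str, str] | list[str]) -> "UltrametricTree":
        """Return a copy with tip labels replaced (list: in tip-index order)."""
        new = list(self.labels)
        tips = self.tip_indices
        if isinstance(labels, dict):
            for i in tips:
                new[i] = labels[self.labels[i]]
        else:
            if len(labels) != len(tips):
                raise TreeError("label list length does not match tip count")
            for i, lab in zip(tips, labels):
                new[i] = lab
        return UltrametricTree(
            parent=self.parent.copy(),
            edge_length=self.edge_length.copy(),
            children=[list(c) for c in self.children],
            labels=new,
        )

    def postorder(self) -> list[int]:
        order: list[int] = []

        def walk(i: int) -> None:
            for c in self.children[i]:
                walk(c)
            order.append(i)

        walk(0)
        return order

    def clade_tips(self, node: int) -> np.ndarray:
        """Tip indices (into the tip ordering) descending from ``node``."""
        tips = self.tip_indices
        pos = {int(t): k for k, t in enumerate(tips)}
        out: list[int] = []

        def walk(i: int) -> None:
            if not self.children[i]:
                out.append(pos[i])
            for c in self.children[i]:
                walk(c)

        walk(node)
        return np.asarray(sorted(out), dtype=int)

    def shared_times(self) -> np.ndarray:
        """Tip x tip matrix of time shared from the root (MRCA times).

        Diagonal entries equal the tree depth.  Tips are ordered as in
        :attr:`tip_labels`.
        """
        n = self.n_tips
        S = np.zeros((n, n))
        t = self.times
        for node in range(self.n_nodes):
            kids = self.children[node]
            if len(kids) == 2:
                a = self.clade_tips(kids[0])
                b = self.clade_tips(kids[1])
                S[np.ix_(a, b)] = t[node]
                S[np.ix_(b, a)] = t[node]
        np.fill_diagonal(S, t[self.tip_indices])
        return S

    def tip_lineage(self, tip_node: int) -> list[int]:
        """Non-root nodes on the root-to-tip path, root end first."""
        path = []
        i = tip_node
        while i != 0:
            path.append(i)
            i = int(self.parent[i])
        return path[::-1]

    # --------------------------------------------------------------------- io
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def build(i: int, dnode) -> None:
            for c in self.children[i]:
                child = dnode.new_child(edge_length=float(self.edge_length[c]))
                if not self.children[c]:
                    child.taxon = taxa.new_taxon(self.labels[c])
                build(c, child)

        build(0, tree.seed_node)
        return tree

    def to_newick(self) -> str:
        return (
            self.to_dendropy()
            .as_string(schema="newick", suppress_rooting=True, real_value_format_specifier=".17g")
            .strip()
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")
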