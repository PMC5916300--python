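"""Rooted phylogenetic trees backed by flat arrays.

Trees are parsed with dendropy and converted to a postorder array
representation (parent pointers + edge lengths) that the distance,
signal and simulation code can traverse cheaply.  Tips occupy indices
``0 .. n_tips-1`` in the order their labels appear in ``tip_labels``;
the root is always the last node.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed or inconsistent trees."""


def _normalize_label(label: str) -> str:
    # trim, underscores -> spaces, collapse runs of whitespace
    return " ".join(label.strip().replace("_", " ").split())


class PhyloTree:
    """A rooted tree with branch lengths, in postorder array form.

    Attributes
    ----------
    tip_labels : list of str
        Normalized tip labels, ordered by tip index.
    parent : ndarray of int
        ``parent[i]`` is the index of node *i*'s parent; root has -1.
    edge_len : ndarray of float
        Length of the edge above each node; NaN when absent, 0.0 at root.
    children : list of list of int
        Child indices per node (empty for tips).
    postorder : ndarray of int
        Node indices in postorder (children before parents, root last).
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        labels = []
        for nd in tips:
            if nd.taxon is None or not (nd.taxon.label or "").strip():
                raise TreeError("tree has an unlabeled tip")
            labels.append(_normalize_label(nd.taxon.label))
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise TreeError(f"duplicate tip labels: {dupes}")

        index = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        j = len(tips)
        for nd in nodes:
            if not nd.is_leaf():
                index[id(nd)] = j
                j += 1

        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        edge_len = np.full(n, np.nan)
        children: list[list[int]] = [[] for _ in range(n)]
        has_zero = False
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                bl = nd.edge.length
                if bl is not None:
                    if bl < 0:
                        raise TreeError(f"negative branch length {bl} above node {i}")
                    if bl == 0:
                        has_zero = True
                    edge_len[i] = float(bl)
            else:
                edge_len[i] = 0.0 if nd.edge.length is None else float(nd.edge.length)
        if has_zero:
            warnings.warn("tree contains zero-length branches", stacklevel=2)

        self.tip_labels = labels
        self.parent = parent
        self.edge_len = edge_len
        self.children = children
        self.postorder = np.array([index[id(nd)] for nd in nodes], dtype=np.int64)
        self.root = int(self.postorder[-1])

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def has_branch_lengths(self) -> bool:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return not np.isnan(self.edge_len[mask]).any()

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(_normalize_label(label))

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------------
    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Return a copy restricted to ``labels``, unifurcations collapsed."""
        keep = {_normalize_label(l) for l in labels}
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        clone = self._dtree.clone(depth=1)
        raw = [
            t for t in clone.taxon_namespace
            if _normalize_label(t.label) in keep
        ]
        clone.retain_taxa(raw)
        return PhyloTree(clone)

    # ------------------------------------------------------------------
    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        if not self.has_branch_lengths:
            raise TreeError("tree lacks branch lengths")
        depth = np.zeros(self.n_nodes)
        for i in self.postorder[::-1]:
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.edge_len[i]
        return depth

    def tip_descendants(self) -> list[np.ndarray]:
        """Tip indices beneath each node (tips include themselves)."""
        desc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.postorder:
            if not self.children[i]:
                desc[i] = [i]
            else:
                acc: list[int] = []
                for c in self.children[i]:
                    acc.extend(desc[c])
                desc[i] = acc
        return [np.array(d, dtype=np.int64) for d in desc]

    def vcv(self) -> np.ndarray:
        """Shared-path (Brownian) covariance matrix among tips.

        ``C[i, j]`` is the root-to-MRCA depth of tips i and j;
        ``C[i, i]`` the root-to-tip depth.
        """
        depth = self.node_depths()
        desc = self.tip_descendants()
        n = self.n_tips
        C = np.zeros((n, n))
        for i in self.postorder:
            kids = self.children[i]
            if not kids:
                continue
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ta, tb = desc[kids[a]], desc[kids[b]]
                    C[np.ix_(ta, tb)] = depth[i]
                    C[np.ix_(tb, ta)] = depth[i]
        C[np.diag_indices(n)] = depth[:n]
        return C

    def patristic(self) -> np.ndarray:
        """Tip-to-tip path-length matrix."""
        depth = self.node_depths()
        C = self.vcv()
        d = depth[: self.n_tips]
        return d[:, None] + d[None, :] - 2.0 * C
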