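"""Time-calibrated HSC phylogenies with per-branch mutation bookkeeping.

The container is deliberately small: branch lengths are in years, every tip
ends at the individual's age (ultrametric), and each somatic mutation is
assigned to exactly one branch (the branch above a node carries the mutations
acquired between the parent split and the node's end).  Newick import/export
goes through dendropy.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import dendropy
import numpy as np

__all__ = ["TreeNode", "PhylogenyTree"]


class TreeNode:
    """Node of a rooted, time-calibrated tree.

    ``t_start``/``t_end`` are absolute times in years; the edge above the
    node spans ``[t_start, t_end]`` and ``mutations`` lists the variant ids
    placed on that edge.
    """

    __slots__ = ("parent", "children", "t_start", "t_end", "mutations", "label")

    def __init__(
        self,
        t_start: float,
        t_end: float,
        label: str | None = None,
        parent: "TreeNode | None" = None,
    ) -> None:
        self.parent = parent
        self.children: list[TreeNode] = []
        self.t_start = t_start
        self.t_end = t_end
        self.mutations: list[str] = []
        self.label = label

    @property
    def length(self) -> float:
        return self.t_end - self.t_start

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class PhylogenyTree:
    """Rooted ultrametric HSC phylogeny.

    The root's edge starts at time 0, so truncal mutations (carried by every
    sampled lineage) live on the root edge.
    """

    def __init__(self, root: TreeNode, age: float) -> None:
        self.root = root
        self.age = age

    # -- traversal ---------------------------------------------------------

    def nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal (every node owns the edge above it)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes() if n.is_tip)

    def tip_counts(self) -> dict[TreeNode, int]:
        """Number of descendant tips per node (tips count themselves)."""
        counts: dict[TreeNode, int] = {}
        order = list(self.nodes())
        for node in reversed(order):  # children precede parents in reversed preorder
            counts[node] = 1 if node.is_tip else sum(counts[c] for c in node.children)
        return counts

    def tip_labels_under(self, node: TreeNode) -> list[str]:
        stack, labels = [node], []
        while stack:
            n = stack.pop()
            if n.is_tip:
                labels.append(n.label)
            else:
                stack.extend(n.children)
        return labels

    def split_times(self) -> np.ndarray:
        """Sorted times at which a lineage bifurcates."""
        return np.sort([n.t_end for n in self.nodes() if not n.is_tip])

    def lineages_at(self, time: float) -> list[TreeNode]:
        """Branches extant at ``time`` (edge spans t_start <= time < t_end)."""
        return [n for n in self.nodes() if n.t_start <= time < n.t_end]

    def n_mutations(self) -> int:
        return sum(len(n.mutations) for n in self.nodes())

    def validate_ultrametric(self, tol: float = 1e-9) -> None:
        for tip in self.tips():
            if abs(tip.t_end - self.age) > tol:
                raise ValueError(
                    f"tip {tip.label!r} ends at {tip.t_end}, expected {self.age}"
                )

    # -- newick ------------------------------------------------------------

    def _newick_node(self, node: TreeNode) -> str:
        if node.is_tip:
            return f"{node.label}:{node.length:.10g}"
        inner = ",".join(self._newick_node(c) for c in node.children)
        return f"({inner}):{node.length:.10g}"

    def to_newick(self, path: str | Path | None = None) -> str:
        newick = self._newick_node(self.root) + ";"
        if path is not None:
            Path(path).write_text(newick + "\n", encoding="utf-8")
        return newick

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhylogenyTree":
        """Load a time-calibrated tree (branch lengths in years) via dendropy.

        Mutation lists are empty; node times are reconstructed from root
        distances and the individual's age is taken as the maximum tip time.
        """
        if isinstance(source, Path):
            text = source.read_text()
        else:
            s = str(source)
            text = s if ("(" in s or ";" in s) else Path(s).read_text()
        dtree = dendropy.Tree.get(data=text, schema="newick")
        droot = dtree.seed_node
        root_len = droot.edge.length or 0.0
        root = TreeNode(0.0, root_len, label=None)
        mapping = {droot: root}
        for dnode in dtree.preorder_node_iter():
            if dnode is droot:
                continue
            parent = mapping[dnode.parent_node]
            length = dnode.edge.length or 0.0
            node = TreeNode(
                parent.t_end,
                parent.t_end + length,
                label=dnode.taxon.label if dnode.taxon else None,
            )
            parent.add_child(node)
            mapping[dnode] = node
        tree = cls(root, age=root.t_end)
        tree.age = max(tip.t_end for tip in tree.tips())
        return tree
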