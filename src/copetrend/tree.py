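"""Rooted-tree containers used throughout the pipeline.

Two conventions coexist in the fossil-calibration literature and both are
used here, with conversions centralized on :class:`CalibratedTree`:

* **age** — millions of years (Ma) before present; parents are *older*
  (larger age) than their children.
* **depth** — Ma measured forward from the root node (root depth 0);
  parents are *shallower* than their children.

``age = root_age - depth`` everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ValidationError


class Node:
    """One vertex of a rooted tree; the branch *above* a node belongs to it."""

    __slots__ = ("parent", "children", "label", "length", "id")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.label = label
        self.length = length  # duration (Ma) of the branch above this node
        self.id: int = -1  # preorder index, assigned by Tree.reindex()

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree over labelled tips; polytomies permitted, lengths optional.

    Serves as the cladogram container (no branch lengths) and as the base of
    :class:`CalibratedTree`.
    """

    def __init__(self, root: Node):
        self.root = root
        self.reindex()
        labels = [t.label for t in self.tips()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        if any(lbl is None for lbl in labels):
            raise ValidationError("every tip must carry a label")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def reindex(self) -> None:
        """Assign stable preorder ids; call after any topology edit."""
        for i, node in enumerate(self.preorder()):
            node.id = i

    # -- editing -----------------------------------------------------------
    def copy(self) -> "Tree":
        return type(self)._copy_into(self)

    @staticmethod
    def _clone_subtree(node: Node) -> Node:
        new = Node(node.label, node.length)
        for c in node.children:
            new.add_child(Tree._clone_subtree(c))
        return new

    @classmethod
    def _copy_into(cls, tree: "Tree"):
        new_root = Tree._clone_subtree(tree.root)
        if isinstance(tree, CalibratedTree):
            return CalibratedTree(new_root, root_age=tree.root_age)
        return Tree(new_root)

    def prune_to(self, keep_labels: Sequence[str]) -> "Tree":
        """Return a copy restricted to ``keep_labels``, suppressing
        unifurcations (their branch durations are summed)."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels())
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")

        def build(node: Node) -> Optional[Node]:
            if node.is_tip:
                if node.label in keep:
                    return Node(node.label, node.length)
                return None
            kids = [build(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if node.length is not None and child.length is not None:
                    child.length += node.length
                elif node.length is not None:
                    child.length = node.length
                return child
            new = Node(node.label, node.length)
            for k in kids:
                new.add_child(k)
            return new

        new_root = build(self.root)
        if new_root is None or new_root.is_tip:
            raise ValidationError("pruning left fewer than 2 tips")
        new_root.length = None
        if isinstance(self, CalibratedTree):
            return CalibratedTree(new_root, root_age=self.root_age)
        return Tree(new_root)

    # -- MRCA --------------------------------------------------------------
    def mrca(self, labels: Sequence[str]) -> Node:
        want = set(labels)
        missing = want - set(self.tip_labels())
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")
        best = None
        for node in self.postorder():
            below = {t.label for t in _subtree_tips(node)}
            if want <= below:
                best = node
                break  # postorder: first container is the most exclusive
        return best

    # -- serialization -----------------------------------------------------
    def newick(self, lengths: bool = True, precision: int = 12) -> str:
        def fmt(node: Node) -> str:
            lbl = _quote_label(node.label) if node.label else ""
            if node.is_tip:
                s = lbl
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + lbl
            if lengths and node.length is not None:
                s += f":{node.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"


def _subtree_tips(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ():;,[]'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


class CalibratedTree(Tree):
    """Binary rooted tree with branch durations in Ma and an absolute root age.

    ``root_age`` is the age of the root node in Ma before present; depths of
    all other nodes follow from the branch durations. This is the substrate
    of every likelihood computation: it exposes root-to-tip times ``T_i``,
    shared root-to-MRCA times ``s_ij`` and tip ages.
    """

    def __init__(self, root: Node, root_age: float):
        self.root_age = float(root_age)
        super().__init__(root)
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None or node.length < 0:
                raise ValidationError(
                    f"calibrated tree requires nonnegative durations (node {node.label or node.id})"
                )

    # -- geometry ----------------------------------------------------------
    def depths(self) -> dict[int, float]:
        """Node id -> depth from root (Ma)."""
        out = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node.id] = out[node.parent.id] + node.length
        return out

    def tip_depths(self) -> dict[str, float]:
        d = self.depths()
        return {t.label: d[t.id] for t in self.tips()}

    def tip_ages(self) -> dict[str, float]:
        return {lbl: self.root_age - dep for lbl, dep in self.tip_depths().items()}

    def max_depth(self) -> float:
        return max(self.tip_depths().values())

    def shared_times(self, tip_order: Sequence[str]) -> np.ndarray:
        """Matrix ``s_ij`` of root-to-MRCA path times; diagonal = tip depth ``T_i``.

        This is the Brownian-motion phylogenetic covariance matrix at unit
        rate, valid for non-ultrametric trees.
        """
        depths = self.depths()
        tips = {t.label: t for t in self.tips()}
        order = list(tip_order)
        idx = {lbl: i for i, lbl in enumerate(order)}
        n = len(order)
        S = np.zeros((n, n))
        for lbl in order:
            S[idx[lbl], idx[lbl]] = depths[tips[lbl].id]
        # postorder: record, per node, the tips below each child; pairs across
        # children have their MRCA at this node
        below: dict[int, list[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[node.id] = [node.label] if node.label in idx else []
                continue
            groups = [below[c.id] for c in node.children]
            d = depths[node.id]
            for g1, g2 in itertools.combinations(groups, 2):
                for a in g1:
                    for b in g2:
                        S[idx[a], idx[b]] = d
                        S[idx[b], idx[a]] = d
            below[node.id] = [x for g in groups for x in g]
        return S

    def mrca_depth(self, label_a: str, label_b: str) -> float:
        S = self.shared_times([label_a, label_b])
        return S[0, 1]


@dataclass
class RegimeMap:
    """Painting of regime labels onto branch segments of one CalibratedTree.

    ``segments[node_id]`` tiles the branch above that node, ordered from the
    parent (shallow) end to the node (deep) end, as
    ``(start_depth, end_depth, label)`` triples. Maps are bound to the tree
    instance whose node ids they reference.
    """

    regimes: list[str]
    segments: dict[int, list[tuple[float, float, str]]]
    root_regime: str
    tree: "CalibratedTree" = field(repr=False, default=None)

    def validate(self) -> None:
        tree = self.tree
        depths = tree.depths()
        tol = 1e-9 * max(1.0, tree.max_depth())
        for node in tree.preorder():
            if node is tree.root:
                continue
            segs = self.segments.get(node.id)
            if not segs:
                raise ValidationError(f"branch above node {node.id} is unpainted")
            top, bottom = depths[node.parent.id], depths[node.id]
            if abs(segs[0][0] - top) > tol or abs(segs[-1][1] - bottom) > tol:
                raise ValidationError(f"segments do not span branch {node.id}")
            for (s0, e0, lab), (s1, e1, _) in zip(segs, segs[1:]):
                if abs(e0 - s1) > tol:
                    raise ValidationError(f"gap/overlap in painting of branch {node.id}")
            for s0, e0, lab in segs:
                if e0 < s0 - tol:
                    raise ValidationError(f"negative segment on branch {node.id}")
                if lab not in self.regimes:
                    raise ValidationError(f"unknown regime label {lab!r}")

    def total_duration(self) -> dict[str, float]:
        """Painted duration per regime (Ma); sums to total tree duration."""
        out = {r: 0.0 for r in self.regimes}
        for segs in self.segments.values():
            for s0, e0, lab in segs:
                out[lab] += e0 - s0
        return out


def single_regime_map(tree: CalibratedTree, label: str = "all") -> RegimeMap:
    depths = tree.depths()
    segs = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        segs[node.id] = [(depths[node.parent.id], depths[node.id], label)]
    return RegimeMap(regimes=[label], segments=segs, root_regime=label, tree=tree)
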