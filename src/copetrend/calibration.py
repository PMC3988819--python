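"""Time-calibration of fossil cladograms and regime painting.

A cladogram plus per-taxon stratigraphic age ranges becomes a replicate set
of time-calibrated binary trees: polytomies are resolved at random, tip ages
are drawn uniformly within each taxon's stratigraphic range, minimum node
ages are computed, and zero-length branches are removed either by imposing a
minimum branch duration (``mbl``) or by redistributing duration from the
nearest basal positive branch (``equal``).

Regimes (clade paintings or era paintings with branches split exactly at
time boundaries) are attached as :class:`~copetrend.tree.RegimeMap` objects.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seeding import rng_for
from .tree import CalibratedTree, Node, RegimeMap, Tree

_TOL = 1e-9


# ---------------------------------------------------------------------------
# Polytomy resolution
# ---------------------------------------------------------------------------

def resolve_polytomies(cladogram: Tree, seed: int) -> Tree:
    """Randomly resolve every polytomy into a bifurcating tree.

    Each polytomy is resolved by sequential random attachment: child
    subtrees are inserted one at a time onto a uniformly chosen edge
    (including the edge above the local root) of the growing local tree.
    This samples uniformly among the (2k-3)!! rooted binary arrangements of
    a k-way polytomy. Deterministic under a fixed seed.
    """
    rng = rng_for(seed, "resolve_polytomies")
    tree = cladogram.copy()
    for node in list(tree.preorder()):
        while len(node.children) > 2:
            _resolve_one(node, rng)
    tree.reindex()
    return tree


def _resolve_one(node: Node, rng: np.random.Generator) -> None:
    kids = list(node.children)
    for k in kids:
        k.parent = None
    node.children = []
    # local binary tree over the child subtrees; start from the first two
    local_root = Node()
    local_root.add_child(kids[0])
    local_root.add_child(kids[1])
    for extra in kids[2:]:
        # edges: one above each non-root local node, plus the local root edge
        local_nodes = _local_subtree_nodes(local_root)
        attach_points = [n for n in local_nodes if n is not local_root]
        choice = rng.integers(0, len(attach_points) + 1)
        if choice == len(attach_points):  # root edge
            new_root = Node()
            new_root.add_child(local_root)
            new_root.add_child(extra)
            local_root = new_root
        else:
            target = attach_points[choice]
            parent = target.parent
            joint = Node()
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            target.parent = None
            joint.add_child(target)
            joint.add_child(extra)
    for c in local_root.children:
        node.add_child(c)


def _local_subtree_nodes(local_root: Node) -> list[Node]:
    """Nodes of the local resolution scaffold, stopping at original subtrees."""
    out, stack = [], [local_root]
    while stack:
        n = stack.pop()
        out.append(n)
        if n.label is None and not _is_original(n):
            stack.extend(reversed(n.children))
    return out


def _is_original(node: Node) -> bool:
    # scaffold nodes are freshly created with id == -1; original subtree
    # roots were indexed by the source tree
    return node.id != -1


# ---------------------------------------------------------------------------
# Tip ages
# ---------------------------------------------------------------------------

def sample_tip_ages(ages: pd.DataFrame, seed: int) -> dict[str, float]:
    """Draw each taxon's tip age uniformly within [age_min, age_max] (Ma)."""
    rng = rng_for(seed, "sample_tip_ages")
    out = {}
    for _, row in ages.iterrows():
        lo, hi = float(row["age_min"]), float(row["age_max"])
        if hi < lo:
            raise ValidationError(f"age_max < age_min for {row['taxon']}")
        out[str(row["taxon"])] = lo if hi == lo else float(rng.uniform(lo, hi))
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _min_node_ages(tree: Tree, tip_ages: Mapping[str, float]) -> dict[int, float]:
    """Minimum node ages: each internal node as old as its oldest descendant tip."""
    ages: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in tip_ages:
                raise ValidationError(f"no age for tip {node.label!r}")
            ages[node.id] = float(tip_ages[node.label])
        else:
            ages[node.id] = max(ages[c.id] for c in node.children)
    return ages


def _tree_from_ages(tree: Tree, ages: Mapping[int, float]) -> CalibratedTree:
    new = tree.copy()  # copies preserve preorder ids
    for node in new.preorder():
        if node.parent is None:
            node.length = None
        else:
            node.length = ages[node.parent.id] - ages[node.id]
            if node.length < -_TOL:
                raise ValidationError("parent younger than child after calibration")
            node.length = max(node.length, 0.0)
    return CalibratedTree(new.root, root_age=ages[tree.root.id])


def calibrate_mbl(
    cladogram: Tree,
    tip_ages: Mapping[str, float],
    min_bl: float = 2.0,
    node_ages: Optional[Mapping[int, float]] = None,
) -> CalibratedTree:
    """Minimum-branch-length time-scaling.

    Node ages start at their stratigraphic minima (oldest descendant tip
    age, or ``node_ages`` if supplied) and a tips-to-root pass enforces
    ``parent_age >= max(child ages) + min_bl``, so every branch duration is
    at least ``min_bl`` Ma. Tip ages are never moved.
    """
    if min_bl <= 0:
        raise ValidationError("min_bl must be positive")
    if not cladogram.is_binary():
        raise ValidationError("calibrate_mbl requires a binary tree; resolve polytomies first")
    ages = dict(node_ages) if node_ages is not None else _min_node_ages(cladogram, tip_ages)
    for t in cladogram.tips():
        ages[t.id] = float(tip_ages[t.label])
    for node in cladogram.postorder():
        if node.is_tip:
            continue
        ages[node.id] = max(ages[node.id], max(ages[c.id] for c in node.children) + min_bl)
    return _tree_from_ages(cladogram, ages)


def calibrate_equal(
    cladogram: Tree,
    tip_ages: Mapping[str, float],
    root_buffer: float = 2.0,
) -> CalibratedTree:
    """'equal' time-scaling: zero-duration branches borrow from basal branches.

    Starting from minimum node ages, each maximal connected run of
    zero-duration branches, together with the first positive-duration branch
    above it (the donor), has the donor's duration redistributed so that the
    branches along every root-to-tip path through the run have equal
    duration. Tip ages are unchanged. If zero branches reach the root, the
    root age is first raised by ``root_buffer`` Ma to create a donor.
    """
    if not cladogram.is_binary():
        raise ValidationError("calibrate_equal requires a binary tree; resolve polytomies first")
    ages = _min_node_ages(cladogram, tip_ages)
    root = cladogram.root
    if any(ages[c.id] >= ages[root.id] - _TOL for c in root.children):
        if root_buffer <= 0:
            raise ValidationError(
                "zero-duration branch at the root and no root_buffer to extend it"
            )
        ages[root.id] += root_buffer

    # zero branches, identified by their child node
    zero_children = {
        n.id
        for n in cladogram.preorder()
        if n.parent is not None and ages[n.parent.id] - ages[n.id] <= _TOL
    }
    by_id = {n.id: n for n in cladogram.preorder()}

    # "moved" nodes are parents of zero branches; group them into connected
    # components (runs)
    moved = sorted({by_id[z].parent.id for z in zero_children})
    visited: set[int] = set()
    for m in moved:
        if m in visited:
            continue
        comp = _zero_component(by_id[m], zero_children, visited)
        top = _component_top(comp, zero_children, by_id)
        donor_parent = by_id[top].parent
        if donor_parent is None:
            raise ValidationError(
                f"no positive-duration ancestor branch available above node {top}"
            )
        d = ages[donor_parent.id] - ages[top]
        if d <= _TOL:
            path = f"{donor_parent.id}->{top}"
            raise ValidationError(f"zero total available duration on path {path}")
        _redistribute(by_id[top], donor_parent, d, ages, zero_children, comp)

    out = _tree_from_ages(cladogram, ages)
    for node in out.preorder():
        if node.parent is not None and node.length <= 0:
            raise ValidationError("equal calibration left a non-positive branch")
    return out


def _zero_component(start: Node, zero_children: set[int], visited: set[int]) -> set[int]:
    """Connected set of *moved* nodes (parents of zero branches) containing start."""
    comp, stack = set(), [start]
    while stack:
        node = stack.pop()
        if node.id in comp:
            continue
        comp.add(node.id)
        visited.add(node.id)
        # connected downward through zero branches
        for c in node.children:
            if c.id in zero_children and c.children and _parents_zero(c, zero_children):
                stack.append(c)
        # connected upward if this node's own branch is zero
        if node.id in zero_children and node.parent is not None and _parents_zero(
            node.parent, zero_children
        ):
            stack.append(node.parent)
    return comp


def _parents_zero(node: Node, zero_children: set[int]) -> bool:
    return any(c.id in zero_children for c in node.children)


def _component_top(comp: set[int], zero_children: set[int], by_id) -> int:
    # the unique component member whose own incoming branch is positive
    tops = [m for m in comp if m not in zero_children]
    if len(tops) != 1:
        # the top moved node's incoming branch may itself be zero only if its
        # parent is outside the component, which cannot happen for connected
        # runs; fall back to the shallowest member
        depth = {}
        for m in comp:
            d, n = 0, by_id[m]
            while n.parent is not None:
                d += 1
                n = n.parent
            depth[m] = d
        return min(comp, key=lambda m: depth[m])
    return tops[0]


def _redistribute(top, donor_parent, d, ages, zero_children, comp) -> None:
    """Assign new ages inside one run: along every path from the donor's top
    node to the run's bottom, branch durations are equal."""
    a_top = ages[donor_parent.id]

    def zero_depth_below(node) -> int:
        best = 0
        for c in node.children:
            if c.id in zero_children:
                extra = 1
                if c.id in comp:  # c is itself a moved node
                    extra += zero_depth_below(c)
                best = max(best, extra)
        return best

    def assign(node, i):
        L = i + zero_depth_below(node)
        ages[node.id] = a_top - d * i / L
        for c in node.children:
            if c.id in zero_children and c.id in comp:
                assign(c, i + 1)

    assign(top, 1)


# ---------------------------------------------------------------------------
# Regime painting
# ---------------------------------------------------------------------------

def paint_clades(
    tree: CalibratedTree,
    clade_definitions: Mapping[str, Sequence[str]],
    basal_label: str = "basal",
    stem: bool = True,
) -> RegimeMap:
    """Paint clade regimes: each branch belongs wholly to the most exclusive
    clade containing it; a clade's stem branch belongs to the clade (set
    ``stem=False`` for crown-only painting); residual branches get the basal
    label."""
    tipsets = {lab: set(tips) for lab, tips in clade_definitions.items()}
    labs = list(tipsets)
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            inter = tipsets[a] & tipsets[b]
            if inter and not (tipsets[a] <= tipsets[b] or tipsets[b] <= tipsets[a]):
                raise ValidationError(f"clades {a!r} and {b!r} overlap without nesting")

    mrcas = {lab: tree.mrca(tips) for lab, tips in tipsets.items()}
    # branch -> innermost clade; innermost = smallest tip set containing it
    order = sorted(labs, key=lambda L: len(tipsets[L]))  # most exclusive first
    assignment: dict[int, str] = {}

    def paint_subtree(node, label):
        stack = [node]
        while stack:
            n = stack.pop()
            assignment.setdefault(n.id, label)
            stack.extend(n.children)

    for lab in order:
        node = mrcas[lab]
        paint_subtree(node, lab)
        if stem and node.parent is not None:
            assignment.setdefault(node.id, lab)  # already set by paint_subtree
        if not stem and node.parent is not None:
            # crown-only: the MRCA's own branch reverts to the surrounding label
            assignment.pop(node.id, None)

    depths = tree.depths()
    segments = {}
    used = set()
    for node in tree.preorder():
        if node is tree.root:
            continue
        lab = assignment.get(node.id, basal_label)
        used.add(lab)
        segments[node.id] = [(depths[node.parent.id], depths[node.id], lab)]

    regimes = [basal_label] if basal_label in used else []
    regimes += [lab for lab in labs if lab in used]
    root_labels = {assignment.get(c.id, basal_label) for c in tree.root.children}
    if basal_label in root_labels or basal_label in used:
        root_regime = basal_label if basal_label in used else sorted(root_labels)[0]
    else:
        root_regime = sorted(root_labels)[0]
    rm = RegimeMap(regimes=regimes, segments=segments, root_regime=root_regime, tree=tree)
    rm.validate()
    return rm


def paint_eras(
    tree: CalibratedTree,
    boundary_ages: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> RegimeMap:
    """Paint time-slice regimes: branches are split exactly at each boundary
    age (Ma before present) they cross; segments are labelled by the era
    containing them, oldest era first. Boundaries older than the root are
    ignored with a warning."""
    bounds = sorted(set(float(b) for b in boundary_ages), reverse=True)  # old -> young
    kept = []
    for b in bounds:
        if b >= tree.root_age:
            warnings.warn(f"era boundary {b} Ma is older than the root; ignored", stacklevel=2)
        else:
            kept.append(b)
    if labels is not None and len(labels) != len(kept) + 1:
        raise ValidationError("need one era label per interval (n_boundaries + 1)")
    era_labels = list(labels) if labels is not None else [f"era{i}" for i in range(len(kept) + 1)]
    # boundary depths from the root, ascending
    bdepths = [tree.root_age - b for b in kept]

    def era_of(depth: float) -> str:
        i = int(np.searchsorted(bdepths, depth, side="right"))
        return era_labels[i]

    depths = tree.depths()
    segments = {}
    used = set()
    for node in tree.preorder():
        if node is tree.root:
            continue
        top, bottom = depths[node.parent.id], depths[node.id]
        cuts = [top] + [bd for bd in bdepths if top < bd < bottom] + [bottom]
        segs = []
        for s0, e0 in zip(cuts, cuts[1:]):
            segs.append((s0, e0, era_of(0.5 * (s0 + e0))))
            used.add(segs[-1][2])
        segments[node.id] = segs
    regimes = [lab for lab in era_labels if lab in used]
    rm = RegimeMap(regimes=regimes, segments=segments, root_regime=regimes[0], tree=tree)
    rm.validate()
    return rm


# ---------------------------------------------------------------------------
# Replicate generation
# ---------------------------------------------------------------------------

def replicate_trees(
    cladogram: Tree,
    ages: pd.DataFrame,
    n_trees: int,
    seed: int,
    method: str = "mbl",
    min_bl: float = 2.0,
    root_buffer: float = 2.0,
) -> list[CalibratedTree]:
    """Generate replicate calibrated trees, each from its own derived seed
    (independent polytomy resolutions and tip-age draws)."""
    out = []
    for i in range(n_trees):
        s = rng_for(seed, "replicate", i).integers(0, 2**31 - 1)
        binary = resolve_polytomies(cladogram, seed=s)
        tip_ages = sample_tip_ages(ages, seed=s)
        if method == "mbl":
            out.append(calibrate_mbl(binary, tip_ages, min_bl=min_bl))
        elif method == "equal":
            out.append(calibrate_equal(binary, tip_ages, root_buffer=root_buffer))
        else:
            raise ValidationError(f"unknown calibration method {method!r}")
    return out
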