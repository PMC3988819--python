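"""Synthetic fossil data with the statistical structure the pipeline assumes.

The generator emulates the study conditions of a pterosaur-like wingspan
data set: a non-ultrametric tree of ~70-110 fossil tips spanning ~160 Ma,
stage-level stratigraphic age uncertainty (2-10 Ma windows), log10-scale
trait evolution under a constrained basal regime followed by a
trending/attracted derived regime, per-tip standard errors of the order of
the wingspan-regression estimate errors (~0.04-0.09 log10 m), and heavy
block-missingness of distal wing elements. Every downstream stage is
therefore testable without access to the original specimen data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .calibration import paint_clades, paint_eras
from .errors import ValidationError
from .io_core import ELEMENTS, MeasurementTable, TraitVector
from .seeding import rng_for
from .tree import CalibratedTree, Node, RegimeMap, single_regime_map


@dataclass
class OUParams:
    """Per-regime Ornstein-Uhlenbeck parameters.

    alpha: attraction strength (1/Ma), 0 gives the Brownian-motion limit;
    beta: Brownian variance (log10(m)^2 per Ma);
    theta: trait optimum (log10 m).
    """

    alpha: float
    beta: float
    theta: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValidationError("beta must be > 0")


def _default_regimes() -> dict[str, OUParams]:
    # basal: strong attraction to a ~1 m optimum (constrained, stasis-like);
    # derived: weaker attraction to an optimum above the observed range,
    # i.e. a sustained upward trend after the era boundary
    return {
        "basal": OUParams(alpha=0.03, beta=0.0008, theta=0.0),
        "derived": OUParams(alpha=0.015, beta=0.0008, theta=0.9),
    }


def _default_missingness() -> dict[str, float]:
    # block-missingness concentrated in distal wing elements, leaving only a
    # minority of taxa with complete forelimbs
    return {
        "skull": 0.35,
        "mandible": 0.25,
        "rostrum": 0.45,
        "humerus": 0.15,
        "ulna": 0.25,
        "radius": 0.30,
        "mcIV": 0.30,
        "phIV1": 0.45,
        "phIV2": 0.50,
        "phIV3": 0.35,
        "phIV4": 0.55,
    }


@dataclass
class SimScenario:
    """Generative settings for one synthetic study.

    Defaults describe the emulated study conditions: ~90 tips over a 160 Ma
    span rooted at 228 Ma before present, a two-era regime shift at 150 Ma
    (constrained basal regime, then an attracted/trending derived regime on
    the log10-metre scale), observation error 0.05 log10 m, and block
    missingness of skeletal elements.
    """

    n_tips: int = 90
    span_ma: float = 160.0
    root_age: float = 228.0
    regime_scheme: str = "era_shift"  # single | clade_shift | era_shift
    boundary_age: float = 150.0
    #: tip fraction of the derived clade under clade_shift; the emulated
    #: study's basal/derived split is 19 vs 53 analysed taxa (~0.74)
    clade_fraction: float = 0.74
    regimes: dict[str, OUParams] = field(default_factory=_default_regimes)
    z0: float = 0.0
    se_scale: float = 0.05
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    #: fraction of taxa preserved as complete specimens (block structure:
    #: real missingness is concentrated in partial skeletons, so element
    #: losses are correlated within taxa rather than independent)
    complete_fraction: float = 0.25
    age_window_ma: tuple[float, float] = (2.0, 10.0)
    juvenile_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValidationError("n_tips must be >= 2")
        if self.span_ma <= 0:
            raise ValidationError("span_ma must be > 0")
        for f in self.missingness.values():
            if not 0 <= f <= 1:
                raise ValidationError("missingness fractions must lie in [0, 1]")
        if self.regime_scheme not in ("single", "clade_shift", "era_shift"):
            raise ValidationError(f"unknown regime scheme {self.regime_scheme!r}")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    span_ma: float,
    seed: int,
    root_age: Optional[float] = None,
    birth: float = 0.09,
    death: float = 0.07,
) -> CalibratedTree:
    """Simulate a non-ultrametric fossil tree by a forward birth-death walk.

    Extinct lineages are retained as tips of heterogeneous depth; surviving
    lineages are cut at the final sampling time. Branch durations are
    rescaled so the root-to-youngest-tip span equals ``span_ma``.
    Deterministic under a fixed seed.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    if span_ma <= 0:
        raise ValidationError("span_ma must be > 0")
    for attempt in range(1000):
        rng = rng_for(seed, "simulate_tree", attempt)
        result = _bd_attempt(n_tips, rng, birth, death)
        if result is not None:
            root, t_end = result
            break
    else:  # pragma: no cover - astronomically unlikely
        raise ValidationError("birth-death simulation failed to reach n_tips")

    scale = span_ma / t_end
    i = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.length is not None:
            node.length *= scale
        if not node.children:
            i += 1
            node.label = f"t{i}"
        stack.extend(reversed(node.children))
    return CalibratedTree(root, root_age=root_age if root_age is not None else span_ma)


def _bd_attempt(n_tips, rng, birth, death):
    root = Node()
    t = 0.0
    active: list[tuple[Node, float]] = [(root, 0.0), (root, 0.0)]
    total = 2
    done: list[Node] = []
    while active and total < n_tips:
        rate = len(active) * (birth + death)
        t += rng.exponential(1.0 / rate)
        i = int(rng.integers(0, len(active)))
        parent, t0 = active.pop(i)
        node = Node(length=t - t0)
        parent.add_child(node)
        if rng.random() < birth / (birth + death):
            active.append((node, t))
            active.append((node, t))
            total += 1
        else:
            node.label = "x"
            done.append(node)
    if total < n_tips or not active:
        return None
    # close surviving lineages a little beyond the last event
    t_end = t + rng.exponential(1.0 / (len(active) * (birth + death)))
    for parent, t0 in active:
        tip = Node(label="x", length=t_end - t0)
        parent.add_child(tip)
    # the youngest tips are the survivors, so the tree spans exactly t_end
    _suppress_unifurcations(root)
    return root, t_end


def _suppress_unifurcations(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        while len(node.children) == 1:
            child = node.children[0]
            node.label = child.label
            node.length = (node.length or 0.0) + (child.length or 0.0)
            node.children = child.children
            for c in node.children:
                c.parent = node
        stack.extend(node.children)


def make_ultrametric(tree: CalibratedTree) -> CalibratedTree:
    """Extend every pendant branch so all tips reach the maximum tip depth
    (a contemporaneous sample, e.g. for Pagel's-lambda simulations)."""
    new = tree.copy()
    depths = new.depths()
    target = max(depths[t.id] for t in new.tips())
    for t in new.tips():
        t.length += target - depths[t.id]
    return CalibratedTree(new.root, root_age=new.root_age)


# ---------------------------------------------------------------------------
# Regime maps for scenarios
# ---------------------------------------------------------------------------

def scenario_regime_map(tree: CalibratedTree, scenario: SimScenario) -> RegimeMap:
    """Build the regime painting a scenario prescribes for a given tree."""
    labels = list(scenario.regimes)
    if scenario.regime_scheme == "single":
        return single_regime_map(tree, label=labels[0])
    if scenario.regime_scheme == "era_shift":
        return paint_eras(tree, [scenario.boundary_age], labels=labels[:2])
    # clade_shift: the internal clade whose size is closest to
    # clade_fraction * n_tips becomes the derived regime
    target = scenario.clade_fraction * tree.n_tips
    best, best_diff = None, np.inf
    for node in tree.internal_nodes():
        if node is tree.root:
            continue
        k = sum(1 for t in tree.tips() if _has_ancestor(t, node))
        if 2 <= k < tree.n_tips and abs(k - target) < best_diff:
            best, best_diff = node, abs(k - target)
    clade_tips = [t.label for t in tree.tips() if _has_ancestor(t, best)]
    return paint_clades(tree, {labels[1]: clade_tips}, basal_label=labels[0])


def _has_ancestor(node: Node, anc: Node) -> bool:
    while node is not None:
        if node is anc:
            return True
        node = node.parent
    return False


# ---------------------------------------------------------------------------
# Trait simulation: exact OU transitions
# ---------------------------------------------------------------------------

def _segment_moments(x_mean, alpha, beta, theta, dt):
    """Exact OU transition over one branch segment (BM limit at alpha == 0)."""
    if alpha > 0:
        decay = np.exp(-alpha * dt)
        mean = theta + (x_mean - theta) * decay
        var = -beta / (2.0 * alpha) * np.expm1(-2.0 * alpha * dt)
    else:
        mean = x_mean
        var = beta * dt
    return mean, var


def simulate_trait(
    tree: CalibratedTree,
    regime_map: RegimeMap,
    params: Mapping[str, OUParams],
    z0: float,
    seed: int,
    se_scale: float = 0.0,
) -> TraitVector:
    """Simulate one trait realization by exact per-segment OU transitions.

    Each branch segment draws X(end) ~ Normal(theta + (X(start) - theta)
    e^(-alpha t), (beta/2 alpha)(1 - e^(-2 alpha t))); alpha = 0 uses the
    Brownian limit (mean X(start), variance beta t). Independent
    Normal(0, se_scale^2) observation noise is added to tips when
    ``se_scale > 0``.
    """
    X = simulate_trait_replicates(tree, regime_map, params, z0, n_rep=1, seed=seed)[0]
    rng = rng_for(seed, "obs_noise")
    tips = tree.tips()
    values, se, prov = {}, {}, {}
    for i, tip in enumerate(tips):
        v = X[i]
        if se_scale > 0:
            v += rng.normal(0.0, se_scale)
        values[tip.label] = float(v)
        se[tip.label] = float(se_scale)
        prov[tip.label] = "simulated"
    return TraitVector(values=values, se=se, provenance=prov)


def simulate_trait_replicates(
    tree: CalibratedTree,
    regime_map: RegimeMap,
    params: Mapping[str, OUParams],
    z0: float,
    n_rep: int,
    seed: int,
) -> np.ndarray:
    """Vectorized exact-transition simulation: (n_rep, n_tips) array of tip
    values in tip order (no observation noise)."""
    for lab in regime_map.regimes:
        if lab not in params:
            raise ValidationError(f"no parameters for regime {lab!r}")
    rng = rng_for(seed, "simulate_trait")
    state: dict[int, np.ndarray] = {tree.root.id: np.full(n_rep, float(z0))}
    tip_vals: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        x = state[node.parent.id]
        segs = regime_map.segments.get(node.id)
        if segs is None:
            raise ValidationError(f"branch above node {node.id} is unpainted")
        for s0, e0, lab in segs:
            p = params[lab]
            mean, var = _segment_moments(x, p.alpha, p.beta, p.theta, e0 - s0)
            x = mean + np.sqrt(var) * rng.standard_normal(n_rep)
        if node.is_tip:
            tip_vals[node.label] = x
        else:
            state[node.id] = x
    return np.column_stack([tip_vals[t.label] for t in tree.tips()])


# ---------------------------------------------------------------------------
# Measurement tables and missingness
# ---------------------------------------------------------------------------

#: Nominal fraction of the one-wing skeletal span contributed by each wing
#: element, and allometric fractions for the cranial elements.
_WING_PROPORTIONS = {
    "humerus": 0.11,
    "ulna": 0.16,
    "mcIV": 0.13,
    "phIV1": 0.22,
    "phIV2": 0.17,
    "phIV3": 0.13,
    "phIV4": 0.08,
}
_CRANIAL_PROPORTIONS = {"skull": 0.28, "mandible": 0.24, "rostrum": 0.14}


def simulate_measurements(
    tree: CalibratedTree,
    traits: TraitVector,
    scenario: SimScenario,
    element_noise_sd: float = 0.0,
) -> MeasurementTable:
    """Emit a complete measurement table consistent with the simulated traits.

    Wing-element lengths follow fixed anatomical proportions of the summed
    wing skeleton (so recomputing the wingspan recovers the trait exactly
    when ``element_noise_sd == 0``); cranial elements scale allometrically
    with independent lognormal noise. Stratigraphic ranges are windows of
    width U(age_window) around the true tip age.
    """
    rng = rng_for(scenario.seed, "measurements")
    tip_ages = tree.tip_ages()
    rows = []
    lo_w, hi_w = scenario.age_window_ma
    for taxon in traits.taxa:
        span_mm = 10.0 ** traits.values[taxon] * 1000.0
        row = {"taxon": taxon}
        for el, frac in _WING_PROPORTIONS.items():
            noise = np.exp(rng.normal(0.0, element_noise_sd)) if element_noise_sd else 1.0
            row[el] = frac * span_mm * noise
        for el, frac in _CRANIAL_PROPORTIONS.items():
            row[el] = frac * span_mm * np.exp(rng.normal(0.0, 0.08))
        row["radius"] = row["ulna"] * 0.97 * np.exp(rng.normal(0.0, 0.01))
        w = rng.uniform(lo_w, hi_w)
        age = tip_ages[taxon]
        row["age_min"] = max(0.0, age - w / 2.0)
        row["age_max"] = age + w / 2.0
        row["status"] = (
            "juvenile" if rng.random() < scenario.juvenile_fraction else "adult"
        )
        row["rescale_factor"] = 1.0
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["taxon"] + ELEMENTS + ["status", "rescale_factor", "age_max", "age_min"]
    return MeasurementTable(df[cols])


def apply_missingness(
    table: MeasurementTable, fractions: Mapping[str, float], seed: int
) -> MeasurementTable:
    """Delete element measurements by independent Bernoulli draws per element."""
    for el, f in fractions.items():
        if not 0 <= f <= 1:
            raise ValidationError(f"missingness fraction for {el} outside [0, 1]")
    rng = rng_for(seed, "missingness")
    df = table.data.copy()
    for el in ELEMENTS:
        f = fractions.get(el, 0.0)
        if f <= 0:
            continue
        drop = rng.random(len(df)) < f
        df.loc[drop, el] = np.nan
    return MeasurementTable(df)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def generate_dataset(scenario: SimScenario):
    """Generate one full synthetic study: tree, regime painting, true traits,
    age table and a measurement table with missingness applied.

    Returns ``(tree, regime_map, traits, cladogram, ages, measurements)``
    where ``cladogram`` is the topology stripped of durations (what the
    calibration stage would receive) and ``ages`` is the stratigraphic table.
    """
    tree = simulate_tree(
        scenario.n_tips, scenario.span_ma, seed=scenario.seed, root_age=scenario.root_age
    )
    rmap = scenario_regime_map(tree, scenario)
    traits = simulate_trait(
        tree, rmap, scenario.regimes, scenario.z0,
        seed=scenario.seed, se_scale=scenario.se_scale,
    )
    full = simulate_measurements(tree, traits, scenario)
    # block-structured missingness: a complete-specimen fraction keeps every
    # element; the remainder loses elements independently at rates scaled so
    # the marginal per-element missingness matches the scenario fractions
    rng = rng_for(scenario.seed, "complete_taxa")
    c = scenario.complete_fraction
    is_complete = rng.random(len(full.data)) < c
    scale = 1.0 / max(1.0 - c, 1e-9)
    scaled = {el: min(f * scale, 1.0) for el, f in scenario.missingness.items()}
    holed = apply_missingness(full, scaled, seed=scenario.seed)
    df = holed.data.copy()
    df.loc[is_complete] = full.data.loc[is_complete]
    meas = MeasurementTable(df)
    ages = meas.data[["taxon", "age_max", "age_min"]].copy()
    cladogram = tree.copy()
    for node in cladogram.preorder():
        node.length = None
    from .tree import Tree

    cladogram = Tree(cladogram.root)
    return tree, rmap, traits, cladogram, ages, meas
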