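"""Orchestration: replicate calibrated trees -> trait assembly -> model
fitting -> AICc weights -> aggregate summary tables.

The stochastic steps (polytomy resolution, tip-age draws, optimizer starts)
take derived seeds per replicate, so runs are reproducible end to end from
one master seed and any single replicate can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import CASCADE_ORDER, estimate_wingspan_cascade, filter_adults
from .calibration import paint_clades, paint_eras, replicate_trees
from .errors import ValidationError
from .io_core import (
    MeasurementTable,
    TraitVector,
    read_ages,
    read_measurements,
    read_newick,
    write_json,
    write_newick,
)
from .ou import FitResult, ModelSpec, akaike_weights, fit_model
from .seeding import child_seed
from .tree import CalibratedTree, Tree
from .trends import era_split_trends

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one full analysis needs; serializable to/from YAML."""

    tree_path: Optional[str] = None
    measurements_path: Optional[str] = None
    ages_path: Optional[str] = None  # defaults to ages in the measurement table
    n_replicate_trees: int = 25
    calibration_method: str = "mbl"
    min_bl: float = 2.0
    root_buffer: float = 2.0
    # regime schemes: list of {"name", "type": "clades"|"eras",
    #   "definitions": {label: [tips]}} or {"boundaries": [Ma], "labels": [...]}
    regime_schemes: list[dict] = field(default_factory=list)
    model_families: list[str] = field(default_factory=lambda: ["BM1", "OU1", "OUM"])
    root_modes: list[str] = field(default_factory=lambda: ["root_equals_basal_theta"])
    mserr: bool = True
    cascade_order: list[str] = field(default_factory=lambda: list(CASCADE_ORDER))
    exclude: list[str] = field(default_factory=lambda: ["Jeholopterus"])
    adults_only: bool = True
    trend_boundary_ma: Optional[float] = 145.0
    trend_age_source: str = "midpoint"  # or "sampled"
    seed: int = 0
    output_dir: Optional[str] = None
    n_starts: int = 8

    def __post_init__(self):
        if self.n_replicate_trees < 1:
            raise ValidationError("n_replicate_trees must be >= 1")
        if not self.model_families:
            raise ValidationError("at least one model family is required")
        multi = [f for f in self.model_families if f not in ("BM1", "OU1")]
        if multi and not self.regime_schemes:
            raise ValidationError(
                f"multi-regime families {multi} require at least one regime scheme"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReplicateResult:
    index: int
    seed: int
    n_taxa: int
    fits: list[FitResult]
    weights: dict[str, float]
    ok: bool  # every candidate model optimized successfully


def _build_regime_maps(tree: CalibratedTree, schemes: Sequence[dict]) -> dict:
    maps = {}
    for scheme in schemes:
        name = scheme["name"]
        if scheme["type"] == "clades":
            defs = {
                lab: [t for t in tips if t in set(tree.tip_labels())]
                for lab, tips in scheme["definitions"].items()
            }
            defs = {lab: tips for lab, tips in defs.items() if len(tips) >= 2}
            if not defs:
                log.warning("scheme %s: no clade survives pruning; skipped", name)
                continue
            maps[name] = paint_clades(
                tree, defs, basal_label=scheme.get("basal_label", "basal")
            )
        elif scheme["type"] == "eras":
            rm = paint_eras(tree, scheme["boundaries"], labels=scheme.get("labels"))
            if len(rm.regimes) < 2:
                log.warning("scheme %s: single era on this tree; skipped", name)
                continue
            maps[name] = rm
        else:
            raise ValidationError(f"unknown regime scheme type {scheme['type']!r}")
    return maps


def _model_specs(config: PipelineConfig, regime_maps: dict) -> list[ModelSpec]:
    specs = []
    for fam in config.model_families:
        if fam == "BM1":
            specs.append(ModelSpec("BM1", mserr=config.mserr, name="BM1"))
        elif fam == "OU1":
            for rm_mode in config.root_modes:
                specs.append(
                    ModelSpec(
                        "OU1", root_mode=rm_mode, mserr=config.mserr,
                        name="OU1" + ("_root" if rm_mode == "separate_Z0" else ""),
                    )
                )
        else:
            for name, rmap in regime_maps.items():
                for rm_mode in config.root_modes:
                    tag = f"{fam}_{name}" + ("_root" if rm_mode == "separate_Z0" else "")
                    specs.append(
                        ModelSpec(fam, regime_map=rmap, root_mode=rm_mode,
                                  mserr=config.mserr, name=tag)
                    )
    return specs


def run_pipeline(
    config: PipelineConfig,
    cladogram: Optional[Tree] = None,
    measurements: Optional[MeasurementTable] = None,
    ages: Optional[pd.DataFrame] = None,
) -> dict:
    """Run the full analysis; returns the result bundle (and writes it to
    ``config.output_dir`` when set)."""
    if cladogram is None:
        cladogram = read_newick(config.tree_path)
    if measurements is None:
        measurements = read_measurements(config.measurements_path)
    if ages is None:
        ages = (
            read_ages(config.ages_path)
            if config.ages_path
            else measurements.data[["taxon", "age_max", "age_min"]].copy()
        )

    table = filter_adults(measurements) if config.adults_only else measurements
    tree_taxa = set(cladogram.tip_labels())
    table_taxa = set(table.taxa)
    orphans = sorted(tree_taxa - table_taxa)
    if orphans:
        log.warning("%d tree taxa lack measurements and are pruned: %s ...",
                    len(orphans), orphans[:5])
        if len(tree_taxa - set(orphans)) < 3:
            raise ValidationError("fewer than 3 usable taxa after pruning")
        cladogram = cladogram.prune_to(sorted(tree_taxa & table_taxa))
    ages = ages[ages["taxon"].isin(cladogram.tip_labels())]

    trees = replicate_trees(
        cladogram, ages, config.n_replicate_trees, seed=config.seed,
        method=config.calibration_method, min_bl=config.min_bl,
        root_buffer=config.root_buffer,
    )

    replicates: list[ReplicateResult] = []
    traits_by_rep: list[TraitVector] = []
    for i, tree in enumerate(trees):
        rep_seed = child_seed(config.seed, "replicate", i)
        traits = estimate_wingspan_cascade(
            table, tree, order=config.cascade_order, exclude=config.exclude
        )
        usable = [t for t in tree.tip_labels() if t in traits.values]
        if len(usable) < 3:
            raise ValidationError("fewer than 3 taxa with usable wingspans")
        fit_tree = tree.prune_to(usable) if len(usable) < tree.n_tips else tree
        regime_maps = _build_regime_maps(fit_tree, config.regime_schemes)
        specs = _model_specs(config, regime_maps)
        if not specs:
            raise ValidationError("model set is empty")
        fits = [
            fit_model(s, fit_tree, traits, seed=rep_seed, n_starts=config.n_starts)
            for s in specs
        ]
        ok = all(f.converged for f in fits)
        if not ok:
            bad = [f.name for f in fits if not f.converged]
            log.warning("replicate %d: optimization failed for %s; excluded", i, bad)
        converged = [f for f in fits if f.converged]
        w = akaike_weights([f.aicc for f in converged])
        weights = {f.name: float(wi) for f, wi in zip(converged, w)}
        replicates.append(
            ReplicateResult(index=i, seed=rep_seed, n_taxa=len(usable),
                            fits=fits, weights=weights, ok=ok)
        )
        traits_by_rep.append(traits)

    summary = aggregate(replicates)

    trend = None
    if config.trend_boundary_ma is not None:
        traits0 = traits_by_rep[0]
        if config.trend_age_source == "sampled":
            age_map = trees[0].tip_ages()
        else:
            mid = table.data.set_index("taxon")[["age_max", "age_min"]].mean(axis=1)
            age_map = mid.to_dict()
        taxa = [t for t in traits0.taxa if t in age_map]
        try:
            trend = era_split_trends(
                [age_map[t] for t in taxa],
                [traits0.values[t] for t in taxa],
                config.trend_boundary_ma,
                seed=child_seed(config.seed, "trend"),
            )
        except ValidationError as exc:
            log.warning("era-split trend regression skipped: %s", exc)
            trend = None

    bundle = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "version": __version__,
        "n_replicates": len(replicates),
        "n_successful": sum(r.ok for r in replicates),
        "replicates": [
            {
                "index": r.index,
                "seed": r.seed,
                "n_taxa": r.n_taxa,
                "ok": r.ok,
                "weights": r.weights,
                "fits": [f.to_dict() for f in r.fits],
            }
            for r in replicates
        ],
        "summary": summary,
        "trend": _trend_dict(trend),
        "_objects": {
            "trees": trees,
            "traits": traits_by_rep,
            "replicates": replicates,
        },
    }
    if config.output_dir:
        _write_bundle(bundle, config.output_dir)
    return bundle


def _trend_dict(trend) -> Optional[dict]:
    if trend is None:
        return None
    out = {}
    for interval, fits in trend.items():
        out[interval] = {
            m: {
                "n": f.n,
                "slope": f.slope,
                "slope_ci": list(f.slope_ci),
                "intercept": f.intercept,
                "intercept_m": f.intercept_m,
                "p_value": f.p_value,
            }
            for m, f in fits.items()
        }
    return out


def aggregate(replicates: Sequence[ReplicateResult]) -> dict:
    """Median and absolute range of each parameter per model across the
    successful replicates; median and IQR of AICc weights; models filtered
    to those with at least half the best median weight."""
    ok = [r for r in replicates if r.ok]
    if not ok:
        log.warning("no fully successful replicates; summary is empty")
        return {"models": [], "weights": [], "included_models": []}

    names = [f.name for f in ok[0].fits]
    weight_rows = []
    for name in names:
        w = np.array([r.weights[name] for r in ok])
        weight_rows.append(
            {
                "model": name,
                "weight_median": float(np.median(w)),
                "weight_q1": float(np.percentile(w, 25)),
                "weight_q3": float(np.percentile(w, 75)),
                "weight_min": float(w.min()),
                "weight_max": float(w.max()),
            }
        )
    best = max(r["weight_median"] for r in weight_rows)
    included = [r["model"] for r in weight_rows if r["weight_median"] >= 0.5 * best]

    model_rows = []
    for j, name in enumerate(names):
        fits = [r.fits[j] for r in ok]
        f0 = fits[0]
        regimes = f0.regimes or (["all"] if f0.family == "BM1" else [])
        for lab in (f0.regimes or []):
            alphas = np.array([f.alpha[lab] for f in fits])
            betas = np.array([f.beta[lab] for f in fits])
            thetas = np.array([f.theta[lab] for f in fits])
            ses = np.array([f.theta_se[lab] for f in fits])
            med_alpha = float(np.median(alphas))
            model_rows.append(
                {
                    "model": name,
                    "regime": lab,
                    "alpha_median": med_alpha,
                    "alpha_range": [float(alphas.min()), float(alphas.max())],
                    # both aggregation orders for the half-life
                    "half_life_of_median_alpha": (
                        float(np.log(2) / med_alpha) if med_alpha > 0 else np.inf
                    ),
                    "median_half_life": float(np.median(np.log(2) / alphas)),
                    "beta_median": float(np.median(betas)),
                    "beta_range": [float(betas.min()), float(betas.max())],
                    "theta_median": float(np.median(thetas)),
                    "theta_range": [float(thetas.min()), float(thetas.max())],
                    "theta_se_median": float(np.median(ses)),
                    "theta_m_median": float(10.0 ** np.median(thetas)),
                }
            )
        if f0.family == "BM1":
            betas = np.array([f.beta["all"] for f in fits])
            z0s = np.array([f.z0 for f in fits])
            model_rows.append(
                {
                    "model": name,
                    "regime": "all",
                    "beta_median": float(np.median(betas)),
                    "beta_range": [float(betas.min()), float(betas.max())],
                    "Z0_median": float(np.median(z0s)),
                    "Z0_range": [float(z0s.min()), float(z0s.max())],
                }
            )
    return {"models": model_rows, "weights": weight_rows, "included_models": included}


def _write_bundle(bundle: dict, output_dir) -> None:
    out = Path(output_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    objects = bundle.pop("_objects")
    write_json(bundle, out / "results.json")
    pd.DataFrame(bundle["summary"]["weights"]).to_csv(
        out / "fig2_weights.tsv", sep="\t", index=False
    )
    pd.DataFrame(bundle["summary"]["models"]).to_csv(
        out / "table1.tsv", sep="\t", index=False
    )
    if bundle["trend"] is not None:
        rows = []
        for interval, fits in bundle["trend"].items():
            for method, f in fits.items():
                rows.append({"interval": interval, "method": method, **f})
        pd.DataFrame(rows).to_csv(out / "trend_fits.tsv", sep="\t", index=False)
    for i, tree in enumerate(objects["trees"]):
        write_newick(tree, out / "trees" / f"tree_{i:03d}.nwk")
    objects["traits"][0].to_frame().to_csv(out / "traits.csv", index=False)
    bundle["_objects"] = objects
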