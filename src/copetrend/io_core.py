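"""Readers/writers for the formats the pipeline touches, and the shared
tabular data model.

Formats: Newick (trees, via dendropy so quoted labels and ``[...]`` comments
common in museum-taxon names are handled), CSV (skeletal measurements,
stratigraphic ages, trait vectors), JSON (fit results).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .tree import CalibratedTree, Node, Tree

log = logging.getLogger(__name__)

#: Skeletal elements measured per taxon (lengths in mm). ``mcIV`` is wing
#: metacarpal IV; ``phIV1..phIV4`` are the four wing-finger (digit IV)
#: phalanges, proximal to distal.
ELEMENTS = [
    "skull",
    "mandible",
    "rostrum",
    "humerus",
    "ulna",
    "radius",
    "mcIV",
    "phIV1",
    "phIV2",
    "phIV3",
    "phIV4",
]

#: Elements whose summed length defines the osteological wingspan of one
#: wing pair. The radius is excluded as anatomically parallel to the ulna;
#: override via the ``elements`` argument of the assembly functions.
WINGSPAN_ELEMENTS = ["humerus", "ulna", "mcIV", "phIV1", "phIV2", "phIV3", "phIV4"]

STATUSES = ("adult", "subadult", "juvenile")

_MEAS_COLUMNS = ["taxon"] + ELEMENTS + ["status", "rescale_factor", "age_max", "age_min"]


@dataclass
class MeasurementTable:
    """Per-taxon skeletal element lengths (mm), ontogenetic status, adult
    rescaling factor and stratigraphic age range (Ma)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        for col in _MEAS_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"measurement table missing column {col!r}")
        self.data = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df["taxon"].duplicated().any():
            dupes = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
            raise ValidationError(f"duplicate taxa in measurement table: {dupes}")
        for col in ELEMENTS:
            vals = df[col]
            if (vals.dropna() <= 0).any():
                bad = df.loc[vals.notna() & (vals <= 0), "taxon"].tolist()
                raise ValidationError(f"non-positive {col} length for {bad}")
        if (df["rescale_factor"] < 1).any():
            bad = df.loc[df["rescale_factor"] < 1, "taxon"].tolist()
            raise ValidationError(f"rescale_factor < 1 for {bad}")
        bad_status = set(df["status"]) - set(STATUSES)
        if bad_status:
            raise ValidationError(f"unknown ontogenetic status values: {sorted(bad_status)}")
        age_ok = (df["age_max"] >= df["age_min"]) & (df["age_min"] >= 0)
        if not age_ok.all():
            bad = df.loc[~age_ok, "taxon"].tolist()
            raise ValidationError(f"age_max >= age_min >= 0 violated for {bad}")

    @property
    def taxa(self) -> list[str]:
        return self.data["taxon"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def row(self, taxon: str) -> pd.Series:
        hit = self.data[self.data["taxon"] == taxon]
        if hit.empty:
            raise KeyError(taxon)
        return hit.iloc[0]

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(self.data.copy())


@dataclass
class TraitVector:
    """Per-taxon log10 wingspan (log10 metres) with standard error and
    provenance (``measured`` or ``estimated:<predictor>``)."""

    values: dict[str, float]
    se: dict[str, float]
    provenance: dict[str, str]

    def __post_init__(self):
        for t, v in self.values.items():
            if not np.isfinite(v):
                raise ValidationError(f"non-finite trait value for {t}")
            if self.se.get(t, 0.0) < 0:
                raise ValidationError(f"negative se for {t}")

    @property
    def taxa(self) -> list[str]:
        return list(self.values)

    def arrays(self, order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        y = np.array([self.values[t] for t in order], dtype=float)
        s = np.array([self.se.get(t, 0.0) for t in order], dtype=float)
        return y, s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxa,
                "log10_wingspan_m": [self.values[t] for t in self.taxa],
                "se": [self.se.get(t, 0.0) for t in self.taxa],
                "provenance": [self.provenance.get(t, "") for t in self.taxa],
            }
        )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path) -> Tree:
    """Read a (possibly polytomous) cladogram from a Newick file.

    Branch lengths present in the file are ignored (with a warning): the
    cladogram is a topology; durations come from time calibration.
    """
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "duplicate" in str(exc).lower():
            raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
        raise FormatError(f"Newick parse failure in {path}: {exc}") from exc
    tree = _from_dendropy(dtree)
    if any(n.length is not None for n in tree.preorder()):
        warnings.warn("branch lengths in input Newick are ignored", stacklevel=2)
        for n in tree.preorder():
            n.length = None
    if tree.n_tips < 2:
        raise ValidationError("cladogram must have at least 2 tips")
    return tree


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (convenience wrapper around :func:`read_newick`)."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"Newick parse failure: {exc}") from exc
    tree = _from_dendropy(dtree)
    for n in tree.preorder():
        n.length = None
    return tree


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label if not dnode.child_nodes() else None,
                    length=dnode.edge.length)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return Tree(root)


def write_newick(tree: Tree, path, lengths: bool = True) -> None:
    Path(path).write_text(tree.newick(lengths=lengths) + "\n")


def read_calibrated_newick(path, root_age: float) -> CalibratedTree:
    """Read a Newick file whose branch lengths are durations in Ma."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"Newick parse failure in {path}: {exc}") from exc
    tree = _from_dendropy(dtree)
    return CalibratedTree(tree.root, root_age=root_age)


# ---------------------------------------------------------------------------
# Measurements / ages CSV
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA"}


def _parse_cell(raw: str, col: str, rownum: int) -> float:
    raw = raw.strip()
    if raw in _MISSING_TOKENS:
        return np.nan
    try:
        return float(raw)
    except ValueError:
        # fail loud: anything non-numeric other than ''/'NA' is an error,
        # not a missing value
        raise FormatError(
            f"row {rownum}: cannot parse {col}={raw!r} (use '' or 'NA' for missing)"
        ) from None


def read_measurements(path) -> MeasurementTable:
    """Read a per-taxon measurement CSV.

    Required columns: ``taxon`` plus any subset of the element/age columns;
    missing cells are empty or ``NA``. ``status`` defaults to ``adult`` (with
    a warning) if the column is absent; ``rescale_factor`` defaults to 1;
    absent age columns default to a degenerate 0 Ma range.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "taxon" not in raw.columns:
        raise FormatError("measurement CSV must have a 'taxon' column")
    n_in = len(raw)
    records = {}
    records["taxon"] = raw["taxon"].str.strip()
    for col in ELEMENTS + ["rescale_factor", "age_max", "age_min"]:
        if col in raw.columns:
            records[col] = [
                _parse_cell(v, col, i + 2) for i, v in enumerate(raw[col])
            ]
        else:
            records[col] = [np.nan] * n_in
    if "status" in raw.columns:
        records["status"] = [s.strip().lower() or "adult" for s in raw["status"]]
    else:
        warnings.warn("no 'status' column; assuming all taxa adult", stacklevel=2)
        records["status"] = ["adult"] * n_in
    df = pd.DataFrame(records)
    df["rescale_factor"] = df["rescale_factor"].fillna(1.0)
    df["age_max"] = df["age_max"].fillna(0.0)
    df["age_min"] = df["age_min"].fillna(0.0)
    table = MeasurementTable(df[_MEAS_COLUMNS])
    log.info("read %d measurement records from %s (0 rejected)", len(table), path)
    return table


def write_measurements(table: MeasurementTable, path) -> None:
    df = table.data.copy()
    df.to_csv(path, index=False, na_rep="NA")


def read_ages(path) -> pd.DataFrame:
    """Read a stratigraphic-age CSV with columns taxon, age_max, age_min (Ma)."""
    df = pd.read_csv(path)
    for col in ("taxon", "age_max", "age_min"):
        if col not in df.columns:
            raise FormatError(f"age table missing column {col!r}")
    bad = df[(df["age_max"] < df["age_min"]) | (df["age_min"] < 0)]
    if not bad.empty:
        raise ValidationError(f"bad age range for {bad['taxon'].tolist()}")
    return df[["taxon", "age_max", "age_min"]]


def read_trait_vector(path) -> TraitVector:
    df = pd.read_csv(path)
    return TraitVector(
        values=dict(zip(df["taxon"], df["log10_wingspan_m"])),
        se=dict(zip(df["taxon"], df["se"])),
        provenance=dict(zip(df["taxon"], df["provenance"].fillna(""))),
    )


def write_trait_vector(traits: TraitVector, path) -> None:
    traits.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON fit results
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
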