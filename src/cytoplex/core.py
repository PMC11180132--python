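"""Core domain containers.

Conventions used throughout the package:

* coordinates are micron-valued, origin at the top-left of the image,
  ``y`` increasing downward (raster convention);
* mask pixel ``(r, c)`` covers the half-open square
  ``[c*s, (c+1)*s) x [r*s, (r+1)*s)`` microns, where ``s`` is the
  microns-per-pixel scale — this makes the cell-to-pixel lookup unambiguous;
* marker intensities are mean pixel intensities per cell and are consumed
  as provided (no transformation); marker names are case-sensitive exact
  strings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MaskError, SchemaError, ValidationError

logger = logging.getLogger("cytoplex")

REQUIRED_COLUMNS = ("cell_id", "image_id", "x", "y")

Pattern = Mapping[str, str]  # marker -> "+" or "-"; unnamed markers are unconstrained


# ---------------------------------------------------------------------------
# CellTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTable:
    """A per-cell table: spatial centroid plus one intensity column per marker.

    ``df`` holds columns ``cell_id``, ``image_id``, ``x``, ``y`` (microns),
    optionally ``area`` (square microns) and one non-negative column per
    marker in ``markers``.  ``(image_id, cell_id)`` is unique; row order is
    preserved as read.
    """

    df: pd.DataFrame
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        for col in REQUIRED_COLUMNS:
            if col not in self.df.columns:
                raise SchemaError(f"cell table is missing required column {col!r}")
        for m in self.markers:
            if m not in self.df.columns:
                raise SchemaError(f"cell table is missing marker column {m!r}")
        dup = self.df.duplicated(subset=["image_id", "cell_id"])
        if dup.any():
            raise ValidationError(
                f"(image_id, cell_id) not unique; first duplicate at row "
                f"{int(np.flatnonzero(dup.to_numpy())[0])}"
            )
        xy = self.df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise ValidationError(f"non-finite coordinate at row {bad}")
        if self.markers:
            inten = self.df[list(self.markers)].to_numpy(dtype=float)
            finite = np.isfinite(inten)
            if not finite.all():
                bad = int(np.flatnonzero(~finite.all(axis=1))[0])
                raise ValidationError(f"non-finite intensity at row {bad}")
            if (inten < 0).any():
                bad = int(np.flatnonzero((inten < 0).any(axis=1))[0])
                raise ValidationError(f"negative intensity at row {bad}")

    # -- accessors ----------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def images(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.df["image_id"]))

    def intensities(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Intensity matrix (cells x markers), float64, row order preserved."""
        cols = list(self.markers if markers is None else markers)
        return self.df[cols].to_numpy(dtype=float)

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(self.df.loc[mask].reset_index(drop=True), self.markers)

    def drop_markers(self, to_drop: Sequence[str]) -> "CellTable":
        keep = tuple(m for m in self.markers if m not in set(to_drop))
        return CellTable(self.df.drop(columns=[m for m in to_drop if m in self.df]), keep)


# ---------------------------------------------------------------------------
# TypingSchema
# ---------------------------------------------------------------------------

DEFAULT_REFERENCE_MARKERS = ("CD3", "CD4", "CD8a")

#: Default reference-population criteria over the default reference markers.
#: ``dominant`` combinations are the expected-frequent T-cell phenotypes in
#: peripheral non-lymphoid tissue; ``rare`` combinations are biologically
#: implausible there (lone CD8a without CD3, and CD4/CD8a double positives).
DEFAULT_POPULATION_CRITERIA: dict[str, tuple[Pattern, ...]] = {
    "dominant": (
        {"CD3": "+", "CD4": "+", "CD8a": "-"},
        {"CD3": "+", "CD4": "-", "CD8a": "+"},
    ),
    "rare": (
        {"CD3": "-", "CD4": "-", "CD8a": "+"},
        {"CD4": "+", "CD8a": "+"},
    ),
    "low_frequency": ({"CD3": "+"},),
    "variable": ({"CD4": "+"},),
}


@dataclass(frozen=True)
class Lineage:
    name: str
    markers: tuple[str, ...]


@dataclass(frozen=True)
class Subtype:
    name: str
    parent: str
    markers: tuple[str, ...]
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class Perturbation:
    """Which lineage to exclude when building the perturbed model, and which
    marker columns to drop from the input so that no remaining marker can
    identify it.  The drop set must cover the lineage's uniquely defining
    markers and intersect its defining set; dropping the whole defining set
    (the exemplar for a lineage defined by a single shared marker) is the
    strongest choice."""

    lineage: str
    markers: tuple[str, ...]


def _patterns_disjoint(a: Pattern, b: Pattern) -> bool:
    return any(a.get(m) == "+" and b.get(m) == "-" or a.get(m) == "-" and b.get(m) == "+"
               for m in set(a) | set(b))


@dataclass(frozen=True)
class TypingSchema:
    """Hierarchical typing configuration: markers, major lineages, subtypes,
    reference markers for cutoff optimisation and reference-population
    criteria.  The lineage hierarchy is inferred from shared defining
    markers: lineage A is an ancestor of lineage B when A's defining set is
    a strict subset of B's."""

    markers: tuple[str, ...]
    lineages: tuple[Lineage, ...]
    subtypes: tuple[Subtype, ...] = ()
    reference_markers: tuple[str, ...] = DEFAULT_REFERENCE_MARKERS
    population_criteria: Mapping[str, tuple[Pattern, ...]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_CRITERIA))
    perturbation: Perturbation | None = None

    def __post_init__(self) -> None:
        marker_set = set(self.markers)
        if len(marker_set) != len(self.markers):
            raise SchemaError("duplicate marker names in panel")
        if not self.lineages:
            raise SchemaError("schema defines no lineages")
        names = [l.name for l in self.lineages]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate lineage names")
        for lin in self.lineages:
            if not lin.markers:
                raise SchemaError(f"lineage {lin.name!r} has no defining marker")
            for m in lin.markers:
                if m not in marker_set:
                    raise SchemaError(
                        f"defining marker {m!r} of lineage {lin.name!r} "
                        f"is not in the marker panel")
        for sub in self.subtypes:
            if sub.parent not in set(names):
                raise SchemaError(
                    f"subtype {sub.name!r} references unknown parent lineage "
                    f"{sub.parent!r}")
            for m in sub.markers + sub.excluded:
                if m not in marker_set:
                    raise SchemaError(
                        f"marker {m!r} of subtype {sub.name!r} is not in the panel")
        ref = set(self.reference_markers)
        for label in ("rare", "dominant"):
            for pat in self.population_criteria.get(label, ()):
                for m, sign in pat.items():
                    if m not in ref:
                        raise SchemaError(
                            f"{label} population pattern uses marker {m!r} outside "
                            f"the reference markers {self.reference_markers}")
                    if sign not in ("+", "-"):
                        raise SchemaError(f"pattern sign must be '+' or '-', got {sign!r}")
        for r in self.population_criteria.get("rare", ()):
            for d in self.population_criteria.get("dominant", ()):
                if not _patterns_disjoint(r, d):
                    raise SchemaError(
                        f"rare pattern {dict(r)} overlaps dominant pattern {dict(d)}")
        if self.perturbation is not None:
            if self.perturbation.lineage not in set(names):
                raise SchemaError(
                    f"perturbation lineage {self.perturbation.lineage!r} unknown")
            unique = set(self.lineage_unique_markers()[self.perturbation.lineage])
            drop = set(self.perturbation.markers)
            defining = set(self.lineage(self.perturbation.lineage).markers)
            if not unique <= drop:
                raise SchemaError(
                    "perturbation drop markers must cover the excluded lineage's "
                    f"uniquely defining markers {sorted(unique)}; otherwise a "
                    "remaining marker could still identify it (vacuous perturbation)")
            if not drop <= set(self.markers):
                raise SchemaError("perturbation drop markers must be panel markers")
            if not (drop & defining):
                raise SchemaError(
                    f"perturbation of {self.perturbation.lineage!r} drops none of "
                    f"its defining markers {sorted(defining)} (vacuous perturbation)")

    # -- hierarchy ----------------------------------------------------------

    def lineage(self, name: str) -> Lineage:
        for lin in self.lineages:
            if lin.name == name:
                return lin
        raise SchemaError(f"unknown lineage {name!r}")

    def ancestors(self, name: str) -> tuple[str, ...]:
        """Lineages whose defining set is a strict subset of ``name``'s."""
        own = set(self.lineage(name).markers)
        return tuple(l.name for l in self.lineages
                     if l.name != name and set(l.markers) < own)

    def lineage_unique_markers(self) -> dict[str, tuple[str, ...]]:
        """Markers used by exactly one lineage definition, keyed by lineage."""
        usage: dict[str, list[str]] = {}
        for lin in self.lineages:
            for m in lin.markers:
                usage.setdefault(m, []).append(lin.name)
        out: dict[str, tuple[str, ...]] = {l.name: () for l in self.lineages}
        for m, users in usage.items():
            if len(users) == 1:
                out[users[0]] = out[users[0]] + (m,)
        return out

    def assignable(self) -> tuple[Subtype, ...]:
        """Units a cell can be annotated with: declared subtypes plus every
        lineage acting as its own trivial subtype."""
        as_subtypes = tuple(Subtype(l.name, l.name, l.markers) for l in self.lineages)
        return as_subtypes + tuple(self.subtypes)

    def indicator(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Binary lineage-by-marker matrix over ``markers`` (panel order)."""
        cols = list(self.markers if markers is None else markers)
        ind = np.zeros((len(self.lineages), len(cols)))
        for i, lin in enumerate(self.lineages):
            for m in lin.markers:
                if m in cols:
                    ind[i, cols.index(m)] = 1.0
        return ind

    # -- (de)serialisation --------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "TypingSchema":
        lineages = tuple(Lineage(x["name"], tuple(x["markers"]))
                         for x in d.get("lineages", ()))
        subtypes = tuple(Subtype(x["name"], x["parent"], tuple(x["markers"]),
                                 tuple(x.get("excluded", ())))
                         for x in d.get("subtypes", ()))
        crit = d.get("population_criteria")
        if crit is not None:
            crit = {k: tuple(dict(p) for p in v) for k, v in crit.items()}
        pert = d.get("perturbation")
        if pert is not None:
            pert = Perturbation(pert["lineage"], tuple(pert["markers"]))
        kwargs = {}
        if crit is not None:
            kwargs["population_criteria"] = crit
        if "reference_markers" in d:
            kwargs["reference_markers"] = tuple(d["reference_markers"])
        return cls(markers=tuple(d["markers"]), lineages=lineages,
                   subtypes=subtypes, perturbation=pert, **kwargs)

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "lineages": [{"name": l.name, "markers": list(l.markers)}
                         for l in self.lineages],
            "subtypes": [{"name": s.name, "parent": s.parent,
                          "markers": list(s.markers), "excluded": list(s.excluded)}
                         for s in self.subtypes],
            "reference_markers": list(self.reference_markers),
            "population_criteria": {k: [dict(p) for p in v]
                                    for k, v in self.population_criteria.items()},
            "perturbation": (None if self.perturbation is None else
                             {"lineage": self.perturbation.lineage,
                              "markers": list(self.perturbation.markers)}),
        }


# ---------------------------------------------------------------------------
# CompartmentMaskSet
# ---------------------------------------------------------------------------

@dataclass
class CompartmentMaskSet:
    """Binary tissue-compartment rasters per image, all sharing one
    microns-per-pixel scale.  Pixel values are strictly {0, 1}."""

    masks: dict[str, dict[str, np.ndarray]]  # image_id -> compartment -> raster
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0) or not math.isfinite(self.microns_per_pixel):
            raise MaskError(f"microns_per_pixel must be > 0, got {self.microns_per_pixel}")
        for image_id, comps in self.masks.items():
            shapes = {name: arr.shape for name, arr in comps.items()}
            if len(set(shapes.values())) > 1:
                raise MaskError(
                    f"compartment masks for image {image_id!r} have mismatched "
                    f"shapes: {shapes}")
            for name, arr in comps.items():
                if arr.ndim != 2:
                    raise MaskError(
                        f"mask {name!r} of image {image_id!r} is not single-channel")
                vals = np.unique(arr)
                if not np.isin(vals, (0, 1)).all():
                    raise MaskError(
                        f"mask {name!r} of image {image_id!r} has values outside "
                        "{0, 1}; binarise on read")

    def compartments(self, image_id: str) -> tuple[str, ...]:
        return tuple(self.masks[image_id])

    def shape(self, image_id: str) -> tuple[int, int]:
        comps = self.masks[image_id]
        return next(iter(comps.values())).shape

    def label_points(self, image_id: str, x: np.ndarray, y: np.ndarray,
                     priority: Sequence[str] | None = None) -> np.ndarray:
        """Compartment label of the pixel containing each micron centroid.

        Overlaps are resolved in ``priority`` order; points outside every
        compartment, or outside the raster extent, are labelled
        ``"background"``.  Pixel lookup follows the half-open 0-based rule.
        """
        comps = self.masks[image_id]
        order = [c for c in (priority or ()) if c in comps]
        order += [c for c in comps if c not in order]
        s = self.microns_per_pixel
        rows = np.floor(np.asarray(y, dtype=float) / s).astype(int)
        cols = np.floor(np.asarray(x, dtype=float) / s).astype(int)
        h, w = self.shape(image_id)
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        n_out = int((~inside).sum())
        if n_out:
            logger.warning("%d cell centroid(s) outside the raster extent of image %s "
                           "labelled 'background'", n_out, image_id)
        labels = np.full(len(rows), "background", dtype=object)
        unset = labels == "background"
        for name in order:
            arr = comps[name]
            hit = inside & unset & (arr[np.clip(rows, 0, h - 1),
                                        np.clip(cols, 0, w - 1)] > 0)
            labels[hit] = name
            unset &= ~hit
        return labels

    def areas_mm2(self, image_id: str, include_background: bool = True) -> dict[str, float]:
        """Compartment areas in square millimetres (pixel count x scale^2).

        Overlapping pixels are attributed per mask independently; the
        ``background`` area is the complement of the union."""
        s2 = self.microns_per_pixel ** 2 / 1e6
        comps = self.masks[image_id]
        out = {name: float(arr.sum()) * s2 for name, arr in comps.items()}
        if include_background:
            union = np.zeros(self.shape(image_id), dtype=bool)
            for arr in comps.values():
                union |= arr > 0
            out["background"] = float((~union).sum()) * s2
        return out


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable settings for a full run; the seed is recorded in every output.

    Lineage-model settings mirror the published defaults (learning_rate,
    shrinkage, batch correction via a batch identifier column); clustering
    uses a kNN graph with modularity community detection (k = 30 by default);
    the cutoff grid step defaults to 1e-4 over [0, 1]; spatial eps and the
    alpha radius have **no defaults** — an appropriate value must be chosen
    per dataset by the user.
    """

    # lineage model
    learning_rate: float = 0.01
    shrinkage: bool = True
    batch_key: str | None = None
    em_max_iter: int = 200
    em_tol: float = 1e-6
    em_damping: float = 1.0
    # stratum clustering
    k: int = 30
    cluster_method: str = "leiden"
    jaccard: bool = False
    # positivity
    grid_step: float = 1e-4
    dscore_mode: str = "area"         # "area" (integrated CDF gap) or "max"
    background: str = "pooled"        # "pooled" | "pooled-marker" | "uniform"
    # annotation
    compartment_priority: tuple[str, ...] = ("tumour", "stroma")
    compartment_lineages: dict[str, str] = field(default_factory=dict)
    # spatial clustering
    eps: float | None = None
    min_samples: int = 5
    alpha_radius: float | None = None
    raster_scale: float = 1.0         # microns per pixel for cluster masks
    # barrier scoring
    graph_method: str = "delaunay"    # or "knn"
    max_edge_length: float = 50.0
    knn_k: int = 10
    mutual_knn: bool = False
    min_target_cluster_size: int | None = None
    max_paths: int = 1000
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.grid_step < 1):
            raise ConfigError(f"grid_step must be in (0, 1), got {self.grid_step}")
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if self.eps is not None and not self.eps > 0:
            raise ConfigError(f"eps must be > 0, got {self.eps}")
        if self.alpha_radius is not None and not self.alpha_radius > 0:
            raise ConfigError(f"alpha_radius must be > 0, got {self.alpha_radius}")
        if self.cluster_method == "flowsom":
            raise ConfigError(
                "cluster_method 'flowsom' is not implemented in this package; "
                "use 'leiden' (kNN-graph modularity communities)")
        if self.cluster_method != "leiden":
            raise ConfigError(f"unknown cluster_method {self.cluster_method!r}")
        if self.dscore_mode not in ("max", "area"):
            raise ConfigError(f"dscore_mode must be 'max' or 'area', got {self.dscore_mode!r}")
        if self.background not in ("pooled", "pooled-marker", "uniform"):
            raise ConfigError(
                "background must be 'pooled', 'pooled-marker' or 'uniform'")
        if self.graph_method not in ("delaunay", "knn"):
            raise ConfigError(f"graph_method must be 'delaunay' or 'knn'")
        if not (0 < self.em_damping <= 1):
            raise ConfigError("em_damping must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("compartment_priority",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["compartment_priority"] = list(self.compartment_priority)
        return d

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
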