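"""Seeded synthetic-tissue generator.

Emulates the inputs of a multiplexed-imaging run: a cell-by-marker intensity
table with planted lineages and marker positivity, spatial niches (discs of
one subtype), an optional barrier annulus between a niche and the
surrounding scatter, and binary tumour/stroma compartment masks.

Intensity model: a positive marker draws from a log-normal signal
distribution, everything else from a log-normal background — multiplexed
mean-intensity data is heavy-tailed and strictly positive, which the
log-normal captures with two parameters.  Planted low-confidence cells have
their positive markers multiplied by an attenuation factor in (0, 1], so
"weak, low signal-to-noise" cells are controlled by a single knob.
Spillover mixes marker pairs convexly: ``i' = (1-f)*i + f*i_other``.

Counts are prescribed, not sampled: realised per-subtype counts equal the
spec exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CellTable, CompartmentMaskSet
from .errors import ValidationError

__all__ = ["PopulationSpec", "Blob", "Annulus", "SceneSpec", "GroundTruth",
           "generate_scene", "generate_masks"]


@dataclass(frozen=True)
class PopulationSpec:
    """One planted subtype: its size, positive markers and intensity model.

    ``signal_mu``/``signal_sigma`` are the log-scale location/scale of the
    positive-marker distribution; defaults give a median of ~12 against a
    background median of ~1 (high separation).  ``lowconf_fraction`` of the
    cells have their positive markers attenuated by ``attenuation``.
    """

    name: str
    count: int
    positive_markers: tuple[str, ...]
    signal_mu: float = 2.5
    signal_sigma: float = 0.35
    lowconf_fraction: float = 0.0
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"population {self.name!r}: count must be >= 0")
        if not (0 < self.attenuation <= 1):
            raise ValidationError(f"population {self.name!r}: attenuation must be in (0, 1]")
        if not (0 <= self.lowconf_fraction <= 1):
            raise ValidationError(f"population {self.name!r}: lowconf_fraction in [0, 1]")


@dataclass(frozen=True)
class Blob:
    """A disc-shaped niche of ``count`` cells of one subtype."""
    centre: tuple[float, float]
    radius: float
    subtype: str
    count: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("blob radius must be > 0")


@dataclass(frozen=True)
class Annulus:
    """A ring of ``count`` cells of one subtype (a planted barrier)."""
    centre: tuple[float, float]
    inner_radius: float
    outer_radius: float
    subtype: str
    count: int

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValidationError("annulus radii must satisfy 0 < inner < outer")


@dataclass(frozen=True)
class SceneSpec:
    markers: tuple[str, ...]
    populations: tuple[PopulationSpec, ...]
    image_size: tuple[float, float] = (1000.0, 1000.0)  # (width, height) microns
    image_id: str = "scene_01"
    blobs: tuple[Blob, ...] = ()
    annulus: Annulus | None = None
    background_mu: float = 0.0
    background_sigma: float = 0.4
    spillover: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate population names")
        for p in self.populations:
            for m in p.positive_markers:
                if m not in self.markers:
                    raise ValidationError(
                        f"population {p.name!r}: marker {m!r} not in scene markers")
        w, h = self.image_size
        if self.blobs:
            from shapely.geometry import Point, box
            image = box(0, 0, w, h)
            demand = sum(Point(b.centre).buffer(b.radius, quad_segs=64)
                         .intersection(image).area for b in self.blobs)
            if demand > w * h + 1e-9:
                raise ValidationError(
                    f"planted blobs demand {demand:.0f} µm² inside a "
                    f"{w * h:.0f} µm² image")
        counts = {p.name: p.count for p in self.populations}
        planted: dict[str, int] = {}
        for b in self.blobs:
            planted[b.subtype] = planted.get(b.subtype, 0) + b.count
        if self.annulus is not None:
            planted[self.annulus.subtype] = planted.get(self.annulus.subtype, 0) \
                + self.annulus.count
        for name, n in planted.items():
            if name not in counts:
                raise ValidationError(f"layout references unknown subtype {name!r}")
            if n > counts[name]:
                raise ValidationError(
                    f"layout demands {n} cells of {name!r} but the population "
                    f"count is {counts[name]}")

    @classmethod
    def from_dict(cls, d) -> "SceneSpec":
        pops = tuple(PopulationSpec(**p) if not isinstance(p, PopulationSpec) else p
                     for p in ({**q, "positive_markers": tuple(q["positive_markers"])}
                               for q in d.get("populations", ())))
        blobs = tuple(Blob(tuple(b["centre"]), b["radius"], b["subtype"], b["count"])
                      for b in d.get("blobs", ()))
        ann = d.get("annulus")
        annulus = None if ann is None else Annulus(
            tuple(ann["centre"]), ann["inner_radius"], ann["outer_radius"],
            ann["subtype"], ann["count"])
        spill = {tuple(k.split("<-")): v for k, v in d.get("spillover", {}).items()} \
            if isinstance(d.get("spillover"), dict) else {}
        kwargs = {k: d[k] for k in ("background_mu", "background_sigma", "seed",
                                    "image_id") if k in d}
        if "image_size" in d:
            kwargs["image_size"] = tuple(d["image_size"])
        return cls(markers=tuple(d["markers"]), populations=pops, blobs=blobs,
                   annulus=annulus, spillover=spill, **kwargs)


@dataclass
class GroundTruth:
    """Planted per-cell truth: subtype, per-marker positivity, confidence
    flag and spatial-blob label; plus scene-level layout parameters."""

    df: pd.DataFrame           # cell_id, image_id, subtype, blob, lowconf, pos_<marker>...
    blob_counts: dict[str, int]
    spec: SceneSpec

    def positivity(self, markers: Sequence[str]) -> np.ndarray:
        return self.df[[f"pos_{m}" for m in markers]].to_numpy(dtype=bool)


def _disc_points(rng: np.random.Generator, centre, radius, n) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)])


def _annulus_points(rng: np.random.Generator, centre, r_in, r_out, n) -> np.ndarray:
    r = np.sqrt(rng.uniform(r_in ** 2, r_out ** 2, size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)])


def generate_scene(spec: SceneSpec) -> tuple[CellTable, GroundTruth]:
    """Generate one scene; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    rows_xy, rows_subtype, rows_blob = [], [], []

    for pop in spec.populations:
        remaining = pop.count
        for bi, blob in enumerate(spec.blobs):
            if blob.subtype != pop.name:
                continue
            rows_xy.append(_disc_points(rng, blob.centre, blob.radius, blob.count))
            rows_subtype += [pop.name] * blob.count
            rows_blob += [bi] * blob.count
            remaining -= blob.count
        if spec.annulus is not None and spec.annulus.subtype == pop.name:
            a = spec.annulus
            rows_xy.append(_annulus_points(rng, a.centre, a.inner_radius,
                                           a.outer_radius, a.count))
            rows_subtype += [pop.name] * a.count
            rows_blob += [-2] * a.count          # -2 marks the annulus
            remaining -= a.count
        if remaining:
            rows_xy.append(np.column_stack([rng.uniform(0, w, remaining),
                                            rng.uniform(0, h, remaining)]))
            rows_subtype += [pop.name] * remaining
            rows_blob += [-1] * remaining        # -1 marks uniform scatter

    xy = np.vstack(rows_xy) if rows_xy else np.empty((0, 2))
    n = len(xy)
    subtype = np.array(rows_subtype, dtype=object)
    blob_label = np.array(rows_blob, dtype=int)

    by_name = {p.name: p for p in spec.populations}
    pos = np.zeros((n, len(spec.markers)), dtype=bool)
    for name, pop in by_name.items():
        sel = subtype == name
        for m in pop.positive_markers:
            pos[sel, spec.markers.index(m)] = True

    lowconf = np.zeros(n, dtype=bool)
    for name, pop in by_name.items():
        idx = np.flatnonzero(subtype == name)
        n_low = int(round(pop.lowconf_fraction * len(idx)))
        if n_low:
            lowconf[rng.choice(idx, size=n_low, replace=False)] = True

    inten = np.exp(rng.normal(spec.background_mu, spec.background_sigma,
                              size=(n, len(spec.markers))))
    for name, pop in by_name.items():
        sel = subtype == name
        for m in pop.positive_markers:
            j = spec.markers.index(m)
            inten[sel, j] = np.exp(rng.normal(pop.signal_mu, pop.signal_sigma,
                                              size=int(sel.sum())))
            att = sel & lowconf
            inten[att, j] *= pop.attenuation

    if spec.spillover:
        mixed = inten.copy()
        for (m_to, m_from), f in spec.spillover.items():
            i, j = spec.markers.index(m_to), spec.markers.index(m_from)
            mixed[:, i] = (1 - f) * inten[:, i] + f * inten[:, j]
        inten = mixed

    cell_ids = np.array([f"c{i:05d}" for i in range(n)], dtype=object)
    df = pd.DataFrame({"cell_id": cell_ids, "image_id": spec.image_id,
                       "x": xy[:, 0], "y": xy[:, 1]})
    for j, m in enumerate(spec.markers):
        df[m] = inten[:, j]
    table = CellTable(df, spec.markers)

    tdf = pd.DataFrame({"cell_id": cell_ids, "image_id": spec.image_id,
                        "subtype": subtype, "blob": blob_label, "lowconf": lowconf})
    for j, m in enumerate(spec.markers):
        tdf[f"pos_{m}"] = pos[:, j]
    blob_counts: dict[str, int] = {}
    for b in spec.blobs:
        blob_counts[b.subtype] = blob_counts.get(b.subtype, 0) + 1
    return table, GroundTruth(tdf, blob_counts, spec)


def generate_masks(spec: SceneSpec, microns_per_pixel: float,
                   tumour_subtypes: Sequence[str] | None = None) -> CompartmentMaskSet:
    """Rasterise the tumour blobs of a scene as the ``tumour`` compartment;
    the complement is ``stroma``.

    ``tumour_subtypes`` selects which blobs count as tumour (default: all
    blobs).  Discs are rasterised with a one-pixel margin so every planted
    blob-member centroid falls inside the tumour compartment.
    """
    if not (microns_per_pixel > 0):
        raise ValidationError(f"scale must be > 0, got {microns_per_pixel}")
    w, h = spec.image_size
    s = microns_per_pixel
    nrow, ncol = int(np.ceil(h / s)), int(np.ceil(w / s))
    cx = (np.arange(ncol) + 0.5) * s
    cy = (np.arange(nrow) + 0.5) * s
    gx, gy = np.meshgrid(cx, cy)
    tumour = np.zeros((nrow, ncol), dtype=np.uint8)
    selected = set(tumour_subtypes) if tumour_subtypes is not None \
        else {b.subtype for b in spec.blobs}
    for b in spec.blobs:
        if b.subtype not in selected:
            continue
        d2 = (gx - b.centre[0]) ** 2 + (gy - b.centre[1]) ** 2
        tumour[d2 <= (b.radius + s) ** 2] = 1       # one-pixel margin
    stroma = (1 - tumour).astype(np.uint8)
    return CompartmentMaskSet({spec.image_id: {"tumour": tumour, "stroma": stroma}}, s)
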