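"""End-to-end orchestration: typing (stratify → positivity → annotate →
densities) and spatial (niches → distances → masks/Dice → barrier), with
CSV outputs and a run manifest.

Every run is deterministic under a fixed seed; rerunning with the same
inputs and seed produces byte-identical CSVs.  The manifest (JSON sidecar)
lists the command, config hash, seed, inputs, outputs, per-stage timings
and warnings, and is written even on partial failure, noting the failed
stage.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import barrier as _barrier
from . import positivity as _positivity
from . import spatial as _spatial
from . import stratify as _stratify
from .core import CellTable, CompartmentMaskSet, RunConfig, TypingSchema
from .errors import SchemaError
from .io import write_run_metadata

logger = logging.getLogger("cytoplex")


class _ManifestWriter:
    def __init__(self, out_dir: Path | None, command: str, config: RunConfig,
                 inputs: dict[str, str]):
        self.out_dir = out_dir
        self.command = command
        self.config = config
        self.inputs = inputs
        self.outputs: list[str] = []
        self.timings: dict[str, float] = {}
        self.warnings: list[str] = []

    def stage(self, name: str):
        writer = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                writer.timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    writer.warnings.append(f"stage {name!r} failed: {exc}")
                    writer.write()
        return _Timer()

    def save(self, df: pd.DataFrame, name: str):
        if self.out_dir is not None:
            path = self.out_dir / name
            df.to_csv(path, index=False)
            self.outputs.append(str(path))

    def write(self):
        if self.out_dir is not None:
            write_run_metadata(self.out_dir / "manifest.json",
                               command=self.command, config=self.config,
                               inputs=self.inputs, outputs=self.outputs,
                               timings=self.timings, warnings=self.warnings)


def _preflight(cells: CellTable, schema: TypingSchema) -> None:
    missing = [m for m in schema.markers if m not in cells.markers]
    if missing:
        raise SchemaError(f"cell table lacks schema marker(s) {missing}")
    missing_ref = [m for m in schema.reference_markers if m not in cells.markers]
    if missing_ref:
        raise SchemaError(f"cell table lacks reference marker(s) {missing_ref}")


def run_typing(cells: CellTable, schema: TypingSchema, config: RunConfig,
               masks: CompartmentMaskSet | None = None,
               out_dir: str | Path | None = None) -> dict:
    """Full typing pipeline.

    Returns a dict with ``strata``, ``dscores``, ``cutoffs`` (trace frame),
    ``cell_objects`` (final annotations), ``positivity``, ``densities``
    (when masks are given) and ``summary``.  All tables are also written to
    ``out_dir`` as CSV with a manifest when a directory is supplied.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    man = _ManifestWriter(out_dir, "typing", config,
                          {"n_cells": str(cells.n_cells)})
    _preflight(cells, schema)

    with man.stage("stratify"):
        strata, model = _stratify.stratify_cells(cells, schema, config)
        man.save(strata, "strata.csv")

    with man.stage("positivity"):
        dscores, cluster_pos, cutoff_results, _profiles = \
            _positivity.positivity_pipeline(cells, strata, schema, config)
        cell_pos = _positivity.cell_positivity(strata, cluster_pos)
        man.save(dscores.reset_index(), "dscores.csv")
        trace = pd.concat([r.trace_frame() for r in cutoff_results.values()
                           if len(r.cutoffs) and len(r.population_counts)],
                          ignore_index=True)
        man.save(trace, "cutoff_trace.csv")
        pos_out = pd.concat([cells.df[["cell_id", "image_id"]], cell_pos], axis=1)
        man.save(pos_out, "positivity.csv")

    with man.stage("annotate"):
        annotations = _annotate.assign_subtypes(cells, strata, cell_pos, schema,
                                                masks=masks, config=config)
        man.save(annotations, "cell_objects.csv")

    dens = None
    if masks is not None:
        with man.stage("densities"):
            dens = _annotate.densities(annotations, masks)
            man.save(dens, "densities.csv")

    labels = annotations["label"]
    frac_unresolved = float(labels.isin([_annotate.AMBIGUOUS,
                                         _annotate.UNASSIGNED]).mean())
    summary = {
        "n_cells": cells.n_cells,
        "n_images": len(cells.images),
        "label_counts": labels.value_counts().to_dict(),
        "ambiguous_unassigned_fraction": frac_unresolved,
        "per_image_counts": {img: int(n) for img, n in
                             annotations.groupby("image_id")["label"].count().items()},
        "selected_cutoffs": {c: r.selected for c, r in cutoff_results.items()},
        "seed": config.seed,
    }
    man.write()
    return {"strata": strata, "model": model, "dscores": dscores,
            "cluster_positivity": cluster_pos, "positivity": cell_pos,
            "cutoffs": cutoff_results, "cell_objects": annotations,
            "densities": dens, "summary": summary}


def run_spatial(cell_objects: pd.DataFrame, config: RunConfig,
                cell_types: list[str] | None = None,
                dice_pairs: list[tuple[str, str]] | None = None,
                triplet: tuple[str, str, str] | None = None,
                out_dir: str | Path | None = None) -> dict:
    """Spatial pipeline on an annotated cell table (needs columns image_id,
    cell_id, label, x, y).

    Spatial clustering always runs (per image, per phenotype, or the
    ``cell_types`` subset); barrier scoring only when a (source, barrier,
    target) ``triplet`` is given.  Empty inputs produce empty outputs and
    succeed.
    """
    for col in ("image_id", "cell_id", "label", "x", "y"):
        if col not in cell_objects.columns:
            raise SchemaError(f"cell objects table lacks column {col!r}")
    if config.eps is None or config.alpha_radius is None:
        raise SchemaError("spatial clustering requires explicit eps and "
                          "alpha_radius (no defaults)")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    man = _ManifestWriter(out_dir, "spatial", config,
                          {"n_cells": str(len(cell_objects))})

    cluster_sets: dict[tuple[str, str], _spatial.SpatialClusterSet] = {}
    assign_rows, comp_rows, dist_rows, dice_rows = [], [], [], []
    with man.stage("spatial_clusters"):
        for image_id, img_df in cell_objects.groupby("image_id", sort=True):
            types = cell_types or sorted(img_df["label"].unique())
            extent = (int(np.ceil(img_df["y"].max() / config.raster_scale)) + 1,
                      int(np.ceil(img_df["x"].max() / config.raster_scale)) + 1) \
                if len(img_df) else (1, 1)
            for ct in types:
                sub = img_df[img_df["label"] == ct]
                if sub.empty:
                    continue
                cs = _spatial.build_cluster_set(
                    image_id, ct, sub["cell_id"].to_numpy(),
                    sub[["x", "y"]].to_numpy(dtype=float),
                    config.eps, config.min_samples, config.alpha_radius)
                cluster_sets[(image_id, ct)] = cs
                assign_rows.append(cs.assignments_frame())
                comp_rows.append(_spatial.composition(cs, cell_objects))
                d = _spatial.signed_distances(
                    cs, img_df[["x", "y"]].to_numpy(dtype=float))
                dist_rows.append(pd.DataFrame({
                    "image_id": image_id, "cluster_type": ct,
                    "cell_id": img_df["cell_id"].to_numpy(),
                    "signed_distance_um": d}))
            for pair in dice_pairs or []:
                a, b = (image_id, pair[0]), (image_id, pair[1])
                if a in cluster_sets and b in cluster_sets:
                    _, _, sc = _spatial.cluster_masks_and_dice(
                        cluster_sets[a], cluster_sets[b],
                        config.raster_scale, extent)
                    dice_rows.append((image_id, pair[0], pair[1], sc))
        empty_assign = pd.DataFrame(columns=["image_id", "cell_type", "cell_id",
                                             "cluster"])
        assignments = pd.concat(assign_rows, ignore_index=True) if assign_rows \
            else empty_assign
        man.save(assignments, "spatial_clusters.csv")
        comp_rows = [c for c in comp_rows if len(c)]
        compositions = pd.concat(comp_rows, ignore_index=True) if comp_rows \
            else pd.DataFrame()
        man.save(compositions, "cluster_summary.csv")
        distances = pd.concat(dist_rows, ignore_index=True) if dist_rows \
            else pd.DataFrame()
        man.save(distances, "distances.csv")
        dice_df = pd.DataFrame(dice_rows, columns=["image_id", "type_a",
                                                   "type_b", "dice"])
        if dice_pairs:
            man.save(dice_df, "dice.csv")

    records = summaries = None
    if triplet is not None:
        source, barr, target = triplet
        with man.stage("barrier"):
            rec_rows, sum_rows = [], []
            for image_id, img_df in cell_objects.groupby("image_id", sort=True):
                if len(img_df) < 2:
                    continue
                graph = _barrier.build_graph(
                    img_df, config.graph_method, config.max_edge_length,
                    config.knn_k, config.mutual_knn)
                allowed = None
                if config.min_target_cluster_size is not None:
                    cs = cluster_sets.get((image_id, target))
                    allowed = []
                    if cs is not None:
                        for lab in cs.cluster_labels:
                            mem = cs.members(lab)
                            if len(mem) > config.min_target_cluster_size:
                                allowed.extend(mem)
                rec = _barrier.score_barrier(graph, source, barr, target,
                                             config.max_paths, allowed)
                rec.insert(0, "image_id", image_id)
                rec_rows.append(rec)
                sum_rows.append(_barrier.summarise(rec, image_id))
            records = pd.concat(rec_rows, ignore_index=True) if rec_rows \
                else pd.DataFrame()
            summaries = pd.concat(sum_rows, ignore_index=True) if sum_rows \
                else pd.DataFrame()
            man.save(records, "barrier_cells.csv")
            man.save(summaries, "barrier_summary.csv")

    man.write()
    return {"cluster_sets": cluster_sets, "assignments": assignments,
            "compositions": compositions, "distances": distances,
            "dice": dice_df, "barrier_records": records,
            "barrier_summary": summaries}
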