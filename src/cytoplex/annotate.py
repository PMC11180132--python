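"""Cell subtype annotation, fallback resolution, compartment labelling and
density quantification.

Specificity score
-----------------
For an assignable subtype ``s`` with defining set ``D_s`` and ancestral
lineage markers ``L_s`` (markers of its parent lineage and of every
ancestor of that lineage), the score of a positive-marker set ``P`` is::

    score(s) = |P ∩ (D_s ∪ L_s)| / |D_s ∪ L_s|
               − λ · |P ∩ (U_other ∪ X_s)|,      λ = 1 / |panel|

where ``U_other`` are markers uniquely defining a lineage outside ``s``'s
own lineage chain and ``X_s`` are ``s``'s explicitly excluded markers.  The
penalty encodes the hierarchy-aware intent: a positive marker that uniquely
contradicts the subtype reduces its specificity by one panel-normalised
unit.  This is a documented in-house instantiation of a "highest
specificity wins" rule, isolated in one operation for easy replacement.

Resolution order: unique positive maximum → direct label; all scores ≤ 0 →
Unassigned; tied maximum → Ambiguous.  Unassigned/Ambiguous cells of high
stratification confidence take the lineage-model label (lineage-fallback);
remaining Ambiguous conflicts are resolved by tissue compartment when masks
and a compartment→lineage mapping are supplied (mask-fallback).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CellTable, CompartmentMaskSet, RunConfig, TypingSchema
from .errors import ValidationError

logger = logging.getLogger("cytoplex")

AMBIGUOUS = "Ambiguous"
UNASSIGNED = "Unassigned"


def _base_sets(schema: TypingSchema):
    uniques = schema.lineage_unique_markers()
    entries = []
    for sub in schema.assignable():
        chain = {sub.parent, *schema.ancestors(sub.parent)}
        base = set(sub.markers) | set(schema.lineage(sub.parent).markers)
        for anc in schema.ancestors(sub.parent):
            base |= set(schema.lineage(anc).markers)
        contra = set()
        for lin_name, um in uniques.items():
            if lin_name not in chain:
                contra |= set(um)
        contra |= set(sub.excluded)
        contra -= base
        entries.append((sub.name, base, contra))
    return entries


def specificity_scores(positive: Sequence[str], schema: TypingSchema
                       ) -> dict[str, float]:
    """Specificity score of one positive-marker set for every assignable
    subtype.  The empty set scores 0 everywhere."""
    p = set(positive)
    lam = 1.0 / len(schema.markers)
    return {name: len(p & base) / len(base) - lam * len(p & contra)
            for name, base, contra in _base_sets(schema)}


def score_matrix(cluster_pos: pd.DataFrame, schema: TypingSchema) -> pd.DataFrame:
    """Specificity scores per cluster (rows) x assignable subtype (columns)."""
    rows = {}
    for cid, row in cluster_pos.iterrows():
        positive = [m for m in cluster_pos.columns if row[m]]
        rows[cid] = specificity_scores(positive, schema)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("cluster_id")


def label_compartments(cells: CellTable, masks: CompartmentMaskSet,
                       priority: Sequence[str] = ("tumour", "stroma")) -> pd.Series:
    """Per-cell compartment from the pixel containing the centroid
    (half-open rule); overlaps resolved by ``priority``; outside → background."""
    labels = np.full(cells.n_cells, "background", dtype=object)
    for image_id in cells.images:
        if image_id not in masks.masks:
            logger.warning("no masks for image %s; its cells get 'background'",
                           image_id)
            continue
        sel = (cells.df["image_id"] == image_id).to_numpy()
        labels[sel] = masks.label_points(
            image_id, cells.df.loc[sel, "x"].to_numpy(),
            cells.df.loc[sel, "y"].to_numpy(), priority)
    return pd.Series(labels, index=cells.df.index, name="compartment")


def assign_subtypes(cells: CellTable, strata: pd.DataFrame,
                    cell_pos: pd.DataFrame, schema: TypingSchema,
                    masks: CompartmentMaskSet | None = None,
                    config: RunConfig | None = None) -> pd.DataFrame:
    """Assign a final label to every cell.

    Returns per-cell annotations: ``label``, winning ``score``,
    ``positive_markers`` (semicolon-joined), ``compartment`` (when masks are
    given), and ``provenance`` in {direct, lineage-fallback, mask-fallback,
    none}; exactly one final label per cell.
    """
    config = config or RunConfig()
    entries = _base_sets(schema)
    names = [e[0] for e in entries]
    marker_cols = [m for m in schema.markers if m in cell_pos.columns]

    # score per unique positivity pattern (cells inherit cluster vectors, so
    # patterns are few)
    pats, inverse = np.unique(cell_pos[marker_cols].to_numpy(dtype=bool),
                              axis=0, return_inverse=True)
    pat_scores = np.empty((len(pats), len(names)))
    for i, pat in enumerate(pats):
        positive = [m for m, flag in zip(marker_cols, pat) if flag]
        sc = specificity_scores(positive, schema)
        pat_scores[i] = [sc[n] for n in names]

    scores = pat_scores[inverse]                        # (N, S)
    best = scores.max(axis=1)
    is_best = np.isclose(scores, best[:, None], rtol=0, atol=1e-12)
    n_best = is_best.sum(axis=1)

    label = np.empty(len(scores), dtype=object)
    provenance = np.full(len(scores), "direct", dtype=object)
    unassigned = best <= 0
    ambiguous = (~unassigned) & (n_best > 1)
    direct = (~unassigned) & (n_best == 1)
    label[unassigned] = UNASSIGNED
    label[ambiguous] = AMBIGUOUS
    label[direct] = np.asarray(names, dtype=object)[scores[direct].argmax(axis=1)]
    provenance[~direct] = "none"

    # lineage-fallback: unresolved cells of high confidence take the
    # lineage-model label
    unresolved = ~direct
    high = (strata["confidence"].to_numpy() == "high")
    take = unresolved & high
    label[take] = strata["lineage"].to_numpy()[take]
    provenance[take] = "lineage-fallback"
    unresolved &= ~take

    compartment = None
    if masks is not None:
        compartment = label_compartments(cells, masks, config.compartment_priority)
        # mask-fallback: an Ambiguous tie whose candidates include the lineage
        # mapped to the cell's compartment resolves to that candidate
        if config.compartment_lineages:
            parent_of = {sub.name: sub.parent for sub in schema.assignable()}
            comp_arr = compartment.to_numpy()
            amb_idx = np.flatnonzero(unresolved & (label == AMBIGUOUS))
            for i in amb_idx:
                want = config.compartment_lineages.get(comp_arr[i])
                if want is None:
                    continue
                cands = [names[j] for j in np.flatnonzero(is_best[i])]
                hits = [c for c in cands if parent_of[c] == want or c == want]
                if len(hits) == 1:
                    label[i] = hits[0]
                    provenance[i] = "mask-fallback"

    pos_join = [";".join(m for m, flag in zip(marker_cols, pats[k]) if flag)
                for k in inverse]
    out = pd.DataFrame({
        "cell_id": cells.df["cell_id"], "image_id": cells.df["image_id"],
        "x": cells.df["x"], "y": cells.df["y"],
        "label": label, "score": best, "positive_markers": pos_join,
        "lineage": strata["lineage"].to_numpy(),
        "confidence": strata["confidence"].to_numpy(),
        "provenance": provenance,
    })
    if compartment is not None:
        out["compartment"] = compartment.to_numpy()
    return out


def densities(annotations: pd.DataFrame, masks: CompartmentMaskSet) -> pd.DataFrame:
    """Cell densities per image x compartment x label.

    ``density_mm2 = count / area_mm2``; each (image, compartment) gets a
    ``Total`` row.  A zero-area compartment holding cells is inconsistent
    input and raises :class:`ValidationError`.
    """
    if "compartment" not in annotations.columns:
        raise ValidationError("annotations lack a 'compartment' column; "
                              "run with masks to quantify densities")
    rows = []
    for image_id, img_df in annotations.groupby("image_id", sort=True):
        areas = masks.areas_mm2(image_id)
        for comp, comp_df in img_df.groupby("compartment", sort=True):
            area = areas.get(comp, 0.0)
            if area == 0 and len(comp_df):
                raise ValidationError(
                    f"compartment {comp!r} of image {image_id} has zero area "
                    f"but {len(comp_df)} cells")
            for lab, lab_df in comp_df.groupby("label", sort=True):
                rows.append((image_id, comp, lab, len(lab_df), area,
                             len(lab_df) / area))
            rows.append((image_id, comp, "Total", len(comp_df), area,
                         len(comp_df) / area))
        # compartments with no cells still get a zero row
        for comp, area in areas.items():
            if comp not in set(img_df["compartment"]):
                rows.append((image_id, comp, "Total", 0, area,
                             0.0 if area > 0 else np.nan))
    return pd.DataFrame(rows, columns=["image_id", "compartment", "label",
                                       "count", "area_mm2", "density_mm2"])
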