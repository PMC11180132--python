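"""Shared fixtures: bundled study scenes run once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cytoplex as cx
from cytoplex import scenes


@pytest.fixture(scope="session")
def demo_run():
    """Full typing run on the eight-lineage demo scene (seed 1), with
    masks and ground truth."""
    spec, schema = scenes.demo_scene(seed=1)
    cells, truth = cx.generate_scene(spec)
    masks = cx.generate_masks(spec, microns_per_pixel=1.0)
    config = cx.RunConfig(seed=1,
                          compartment_lineages={"tumour": "Epithelial cells"})
    result = cx.run_typing(cells, schema, config, masks=masks)
    return {"spec": spec, "schema": schema, "cells": cells, "truth": truth,
            "masks": masks, "config": config, "result": result}


@pytest.fixture(scope="session")
def tcell_run():
    """Typing run on the T-cell cutoff-optimisation scene (seed 1)."""
    spec, schema = scenes.tcell_scene(seed=1)
    cells, truth = cx.generate_scene(spec)
    config = cx.RunConfig(seed=1)
    result = cx.run_typing(cells, schema, config)
    return {"spec": spec, "schema": schema, "cells": cells, "truth": truth,
            "config": config, "result": result}


@pytest.fixture(scope="session")
def barrier_scenes():
    """The paired annulus / annulus-free barrier scenes (seed 3) as
    annotated cell tables."""
    out = {}
    for with_annulus in (True, False):
        spec = scenes.barrier_scene(seed=3, with_annulus=with_annulus)
        cells, truth = cx.generate_scene(spec)
        df = cells.df.assign(label=truth.df["subtype"])
        out[with_annulus] = df
    return out


def majority_subtype_per_cluster(truth, strata) -> pd.Series:
    """Planted subtype of each stratum cluster (majority vote)."""
    return (truth.df.assign(cluster=strata["cluster_id"].to_numpy())
            .groupby("cluster")["subtype"].agg(lambda s: s.mode()[0]))


def planted_positive_markers(spec) -> dict[str, set]:
    return {p.name: set(p.positive_markers) for p in spec.populations}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
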