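"""Lineage EM model, perturbed-model confidence flags, logistic confidence
classification and stratum clustering."""

import numpy as np
import pandas as pd
import pytest

import cytoplex as cx
from cytoplex import scenes
from cytoplex import stratify as strat


def two_lineage_scene(seed=0, **kw):
    pops = (cx.PopulationSpec("T cells", 300, ("CD3",), **kw),
            cx.PopulationSpec("Epithelial", 400, ("panCK",), **kw))
    spec = cx.SceneSpec(markers=("CD3", "panCK"), populations=pops, seed=seed)
    schema = cx.TypingSchema(
        markers=("CD3", "panCK"),
        lineages=(cx.Lineage("T cells", ("CD3",)),
                  cx.Lineage("Epithelial", ("panCK",))),
        reference_markers=("CD3",),
        population_criteria={"dominant": ({"CD3": "+"},)})
    return spec, schema


class TestLineageModel:
    def test_single_lineage_posterior_one(self):
        spec, _ = two_lineage_scene()
        cells, _ = cx.generate_scene(spec)
        schema = cx.TypingSchema(
            markers=("CD3", "panCK"),
            lineages=(cx.Lineage("Everything", ("CD3",)),),
            reference_markers=("CD3",),
            population_criteria={"dominant": ({"CD3": "+"},)})
        _, post = strat.fit_lineage_model(cells, schema, cx.RunConfig())
        assert (post["lineage"] == "Everything").all()
        np.testing.assert_allclose(post["posterior"], 1.0)

    def test_two_lineage_high_separation_recovery(self):
        spec, schema = two_lineage_scene(seed=4)
        cells, truth = cx.generate_scene(spec)
        _, post = strat.fit_lineage_model(cells, schema, cx.RunConfig())
        acc = (post["lineage"].to_numpy() == truth.df["subtype"].to_numpy()).mean()
        assert acc >= 0.99

    def test_row_shuffle_invariance(self):
        spec, schema = two_lineage_scene(seed=4)
        cells, _ = cx.generate_scene(spec)
        _, post = strat.fit_lineage_model(cells, schema, cx.RunConfig())
        rng = np.random.default_rng(0)
        perm = rng.permutation(cells.n_cells)
        shuffled = cx.CellTable(cells.df.iloc[perm].reset_index(drop=True),
                                cells.markers)
        _, post2 = strat.fit_lineage_model(shuffled, schema, cx.RunConfig())
        np.testing.assert_allclose(
            post2[list(schema.markers[:0]) + ["posterior"]].to_numpy(),
            post.iloc[perm][["posterior"]].to_numpy(), atol=1e-9)
        assert (post2["lineage"].to_numpy()
                == post["lineage"].iloc[perm].to_numpy()).all()

    def test_loglik_monotone_and_posteriors_normalised(self, demo_run):
        cells, schema = demo_run["cells"], demo_run["schema"]
        model, post = strat.fit_lineage_model(cells, schema, cx.RunConfig(seed=1))
        ll = np.array(model.loglik_trace)
        assert (np.diff(ll) >= -1e-8 * (np.abs(ll[:-1]) + 1)).all()
        probs = post[[l.name for l in schema.lineages]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_shrinkage_keeps_shifts_nonnegative(self, demo_run):
        model, _ = strat.fit_lineage_model(demo_run["cells"], demo_run["schema"],
                                           cx.RunConfig(seed=1))
        assert (model.shift >= 0).all()

    def test_zero_variance_marker_dropped_not_fatal(self):
        spec, schema = two_lineage_scene()
        cells, _ = cx.generate_scene(spec)
        df = cells.df.copy()
        df["dead"] = 1.0
        cells2 = cx.CellTable(df, cells.markers + ("dead",))
        schema2 = cx.TypingSchema(
            markers=("CD3", "panCK", "dead"),
            lineages=(cx.Lineage("T cells", ("CD3",)),
                      cx.Lineage("Epithelial", ("panCK", "dead"))),
            reference_markers=("CD3",),
            population_criteria={"dominant": ({"CD3": "+"},)})
        model, _ = strat.fit_lineage_model(cells2, schema2, cx.RunConfig())
        assert model.dropped_markers == ("dead",)

    def test_batch_offsets_absorb_shift(self):
        """A constant multiplicative offset on one batch must not change the
        assignments when the batch key is supplied."""
        spec, schema = two_lineage_scene(seed=9)
        cells, truth = cx.generate_scene(spec)
        df = cells.df.copy()
        half = np.arange(len(df)) % 2 == 0
        df["tma"] = np.where(half, "A", "B")
        df.loc[~half, ["CD3", "panCK"]] *= 3.0
        cells2 = cx.CellTable(df, cells.markers)
        _, post = strat.fit_lineage_model(cells2, schema,
                                          cx.RunConfig(batch_key="tma"))
        acc = (post["lineage"].to_numpy() == truth.df["subtype"].to_numpy()).mean()
        assert acc >= 0.98


class TestPerturbation:
    def test_vacuous_perturbation_all_stable(self):
        spec, schema = two_lineage_scene()
        cells, _ = cx.generate_scene(spec)
        out = strat.build_perturbed_labels(cells, schema, cx.RunConfig(),
                                           lineage=None, drop_markers=())
        assert out["stable"].all()

    def test_excluded_lineage_cells_all_variable(self):
        spec, schema = scenes.confidence_scene(seed=1, lowconf_fraction=0.0)
        cells, truth = cx.generate_scene(spec)
        cfg = cx.RunConfig(seed=1)
        _, post = strat.fit_lineage_model(cells, schema, cfg)
        pert = strat.build_perturbed_labels(cells, schema, cfg,
                                            complete_labels=post["lineage"])
        planted_vim = (truth.df["subtype"] == "Vimentin+ cells").to_numpy()
        called_vim = (post["lineage"] == "Vimentin+ cells").to_numpy()
        # cells the complete model called the excluded lineage must change label
        assert (~pert["stable"].to_numpy()[called_vim]).all()
        assert planted_vim.sum() > 0

    def test_attenuated_cells_enriched_among_variable(self):
        spec, schema = scenes.confidence_scene(seed=1)
        cells, truth = cx.generate_scene(spec)
        cfg = cx.RunConfig(seed=1)
        _, post = strat.fit_lineage_model(cells, schema, cfg)
        pert = strat.build_perturbed_labels(cells, schema, cfg,
                                            complete_labels=post["lineage"])
        low = truth.df["lowconf"].to_numpy()
        variable = ~pert["stable"].to_numpy()
        enrichment = low[variable].mean() / low.mean()
        assert enrichment >= 3.0

    def test_insufficient_drop_set_rejected(self):
        _, schema = scenes.tcell_scene()
        cells, _ = cx.generate_scene(scenes.tcell_scene()[0])
        with pytest.raises(cx.SchemaError, match="vacuous"):
            strat.build_perturbed_labels(cells, schema, cx.RunConfig(),
                                         lineage="CD4 T cells",
                                         drop_markers=("CD45",))


class TestConfidence:
    def test_separable_flags_training_accuracy_one(self):
        spec, schema = two_lineage_scene(seed=2)
        cells, _ = cx.generate_scene(spec)
        cfg = cx.RunConfig()
        _, post = strat.fit_lineage_model(cells, schema, cfg)
        # synthetic, perfectly separable flags: stable iff posterior > median
        flags = pd.Series(post["posterior"] > post["posterior"].median(),
                          index=post.index)
        conf, model = strat.classify_confidence(cells, schema, post["lineage"],
                                                post["posterior"], flags)
        pred_high = (conf == "high").to_numpy()
        assert (pred_high == flags.to_numpy()).mean() == 1.0

    def test_attenuated_cells_classified_low(self):
        spec, schema = scenes.confidence_scene(seed=2)
        cells, truth = cx.generate_scene(spec)
        cfg = cx.RunConfig(seed=2)
        _, post = strat.fit_lineage_model(cells, schema, cfg)
        pert = strat.build_perturbed_labels(cells, schema, cfg,
                                            complete_labels=post["lineage"])
        conf, _ = strat.classify_confidence(cells, schema, post["lineage"],
                                            post["posterior"], pert["stable"])
        low = truth.df["lowconf"].to_numpy()
        sensitivity = (conf.to_numpy()[low] == "low").mean()
        assert sensitivity >= 0.8

    def test_posterior_coefficient_nonnegative(self):
        """Raising a cell's posterior (all else fixed) must never flip it
        high→low: the fitted coefficient on the posterior is positive."""
        spec, schema = scenes.confidence_scene(seed=1)
        cells, _ = cx.generate_scene(spec)
        cfg = cx.RunConfig(seed=1)
        _, post = strat.fit_lineage_model(cells, schema, cfg)
        pert = strat.build_perturbed_labels(cells, schema, cfg,
                                            complete_labels=post["lineage"])
        _, model = strat.classify_confidence(cells, schema, post["lineage"],
                                             post["posterior"], pert["stable"])
        assert model is not None
        assert model.coef_[0][0] >= -1e-9

    def test_single_class_flags_warn_and_assign(self):
        spec, schema = two_lineage_scene()
        cells, _ = cx.generate_scene(spec)
        _, post = strat.fit_lineage_model(cells, schema, cx.RunConfig())
        flags = pd.Series(True, index=post.index)
        conf, model = strat.classify_confidence(cells, schema, post["lineage"],
                                                post["posterior"], flags)
        assert model is None and (conf == "high").all()


class TestClusterStrata:
    def test_small_group_single_cluster(self):
        spec, schema = two_lineage_scene()
        cells, _ = cx.generate_scene(spec)
        sub = cells.subset(np.arange(cells.n_cells) < 5)
        strata = pd.DataFrame({"lineage": "T cells", "confidence": "high"},
                              index=sub.df.index)
        ids = strat.cluster_strata(sub, strata, cx.RunConfig(k=30))
        assert ids.nunique() == 1

    def test_two_blob_group_recovered(self):
        """Two well-separated intensity modes in one stratum come out as the
        planted split (adjusted Rand >= 0.95)."""
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(0)
        n = 50  # near-clique kNN graphs at k=30, so modularity keeps each mode whole
        inten = np.concatenate([rng.lognormal(0.0, 0.2, size=n),
                                rng.lognormal(3.0, 0.2, size=n)])
        df = pd.DataFrame({"cell_id": [f"c{i}" for i in range(2 * n)],
                           "image_id": "img", "x": 0.0, "y": 0.0, "m": inten})
        cells = cx.CellTable(df, ("m",))
        strata = pd.DataFrame({"lineage": "L", "confidence": "high"},
                              index=df.index)
        ids = strat.cluster_strata(cells, strata, cx.RunConfig(k=30, seed=0))
        planted = np.repeat([0, 1], n)
        assert adjusted_rand_score(planted, ids.to_numpy()) >= 0.95

    def test_same_seed_identical_partition(self, demo_run):
        cells = demo_run["cells"]
        strata = demo_run["result"]["strata"][["lineage", "confidence"]]
        a = strat.cluster_strata(cells, strata, cx.RunConfig(seed=7))
        b = strat.cluster_strata(cells, strata, cx.RunConfig(seed=7))
        assert a.equals(b)

    def test_stratification_is_partition(self, demo_run):
        strata = demo_run["result"]["strata"]
        cells = demo_run["cells"]
        counts = strata.groupby(["lineage", "confidence", "cluster_id"]).size()
        assert counts.sum() == cells.n_cells
        assert (strata["cluster_id"] >= 0).all()
        # cluster ids unique across groups
        owners = strata.groupby("cluster_id")[["lineage", "confidence"]].nunique()
        assert (owners <= 1).all().all()
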