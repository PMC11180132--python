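"""Cell stratification: probabilistic major-lineage assignment, confidence
splitting via a perturbed model, and graph clustering within each
(lineage x confidence) group.

Lineage model
-------------
A self-contained two-component log-intensity mixture fitted by EM.  Each
marker ``m`` has a background location ``mu_m``, a shared variance
``sigma2_m`` and a non-negative over-expression shift ``d_m``; a lineage's
defining markers are expected at ``mu_m + d_m``, everything else at
``mu_m``.  Optional additive per-batch offsets absorb acquisition effects
(keyed by a batch identifier column, e.g. a TMA id).  Intensities enter as
``log1p(x)``; the cell-specific size factor is one.  The non-negativity
constraint on the shifts realises the shrinkage setting; EM M-steps may be
damped (``em_damping``; 1.0 = plain EM).  Every cell is assigned its
maximum-posterior lineage, however low the probability.

Confidence
----------
A second ("perturbed") model is fitted with one lineage removed from the
definitions and a drop-marker set removed from the input, chosen so no
remaining marker can identify the excluded lineage.  Cells keeping their
label across the complete and perturbed models are *stable* training
examples, cells changing are *variable*.  A binomial logistic regression on
(assigned-lineage posterior, mean defining-marker intensity) is trained on
these flags and applied to all cells: predicted probability >= 0.5 of being
stable means *high* confidence.

Clustering
----------
Within each (lineage x confidence) group, a k-nearest-neighbour graph on
raw intensities (Euclidean) is partitioned by Leiden modularity
optimisation, seed-controlled; optional Jaccard edge weights.  Groups
smaller than k + 1 collapse to one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import CellTable, RunConfig, TypingSchema
from .errors import SchemaError, ValidationError

logger = logging.getLogger("cytoplex")

_VAR_FLOOR = 1e-8


@dataclass
class LineageModel:
    lineages: tuple[str, ...]
    markers: tuple[str, ...]             # markers contributing likelihood terms
    mu: np.ndarray                       # (M,) background locations
    shift: np.ndarray                    # (M,) over-expression shifts, >= 0 under shrinkage
    sigma2: np.ndarray                   # (M,) variances
    pi: np.ndarray                       # (K,) mixing weights
    batches: tuple[str, ...]             # batch levels ("" = single batch)
    batch_offsets: np.ndarray            # (B, M) additive offsets, first row 0
    indicator: np.ndarray                # (K, M) lineage-defines-marker
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    dropped_markers: tuple[str, ...] = ()

    def log_likelihoods(self, y: np.ndarray, batch_idx: np.ndarray) -> np.ndarray:
        """Per-cell per-lineage log-likelihood, (N, K)."""
        z = y - self.mu - self.batch_offsets[batch_idx]          # (N, M)
        inv = 1.0 / self.sigma2
        base = -0.5 * (np.log(2 * np.pi * self.sigma2).sum()
                       + (z ** 2 * inv).sum(axis=1))             # (N,)
        # (z - d*a)^2 = z^2 - 2 z d a + d^2 a  (a binary)
        cross = ((-2 * z * self.shift + self.shift ** 2) * inv) @ self.indicator.T
        return base[:, None] - 0.5 * cross

    def posterior(self, y: np.ndarray, batch_idx: np.ndarray) -> np.ndarray:
        ll = self.log_likelihoods(y, batch_idx) + np.log(self.pi)
        return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))


def _prepare(cells: CellTable, schema: TypingSchema, config: RunConfig):
    markers = [m for m in schema.markers if m in cells.markers]
    missing = set(schema.markers) - set(cells.markers)
    if missing:
        raise SchemaError(f"cell table lacks schema markers {sorted(missing)}")
    y = np.log1p(cells.intensities(markers))
    keep = [i for i in range(len(markers)) if y[:, i].std() > 1e-12]
    dropped = tuple(markers[i] for i in range(len(markers)) if i not in keep)
    if dropped:
        logger.warning("marker(s) %s have zero variance and contribute no "
                       "likelihood term", list(dropped))
    markers = [markers[i] for i in keep]
    y = y[:, keep]
    if config.batch_key is not None:
        if config.batch_key not in cells.df.columns:
            raise SchemaError(f"batch_key column {config.batch_key!r} not in cell table")
        levels = pd.unique(cells.df[config.batch_key].astype(str))
        batch_idx = pd.Categorical(cells.df[config.batch_key].astype(str),
                                   categories=levels).codes.astype(int)
        batches = tuple(levels)
    else:
        batch_idx = np.zeros(cells.n_cells, dtype=int)
        batches = ("",)
    return markers, y, batches, np.asarray(batch_idx), dropped


def fit_lineage_model(cells: CellTable, schema: TypingSchema, config: RunConfig
                      ) -> tuple[LineageModel, pd.DataFrame]:
    """Fit the lineage mixture by EM and return per-cell posteriors.

    Returns a DataFrame with one probability column per lineage plus the
    maximum-posterior ``lineage`` label and its ``posterior``.  The EM
    log-likelihood trace is non-decreasing (within tolerance); on
    non-convergence the best iterate is kept and a warning logged.
    """
    markers, y, batches, batch_idx, dropped = _prepare(cells, schema, config)
    K = len(schema.lineages)
    N, M = y.shape
    if M == 0:
        raise ValidationError("no informative markers left to fit the lineage model")
    ind = schema.indicator(markers)                      # (K, M)

    mu = np.median(y, axis=0)
    shift = np.maximum(np.quantile(y, 0.95, axis=0) - mu, 0.1)
    sigma2 = np.maximum(y.var(axis=0) / 2.0, _VAR_FLOOR)
    pi = np.full(K, 1.0 / K)
    offsets = np.zeros((len(batches), M))

    model = LineageModel(tuple(l.name for l in schema.lineages), tuple(markers),
                         mu, shift, sigma2, pi, batches, offsets, ind,
                         dropped_markers=dropped)
    damp = config.em_damping
    prev_ll = -np.inf
    model.converged = False
    for it in range(config.em_max_iter):
        ll_nk = model.log_likelihoods(y, batch_idx) + np.log(model.pi)
        ll = float(logsumexp(ll_nk, axis=1).sum())
        model.loglik_trace.append(ll)
        if ll - prev_ll < config.em_tol * (abs(ll) + 1) and it > 0:
            model.converged = True
            break
        prev_ll = ll
        r = np.exp(ll_nk - logsumexp(ll_nk, axis=1, keepdims=True))  # (N, K)

        e = r @ ind                                     # (N, M) expected indicator
        # coordinate M-step sweeps (each sweep improves the EM Q-function)
        mu_new, d_new, off_new = model.mu.copy(), model.shift.copy(), model.batch_offsets.copy()
        for _ in range(3):
            o = off_new[batch_idx]
            denom = e.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                d_prop = (e * (y - mu_new - o)).sum(axis=0) / denom
            d_new = np.where(denom > 1e-12, d_prop, d_new)
            if config.shrinkage:
                d_new = np.maximum(d_new, 0.0)
            mu_new = (y - d_new * e - o).mean(axis=0)
            if len(batches) > 1:
                resid = y - mu_new - d_new * e
                for b in range(len(batches)):
                    sel = batch_idx == b
                    off_new[b] = resid[sel].mean(axis=0)
                off_new -= off_new[0]                   # identifiability: first batch 0
        o = off_new[batch_idx]
        z = y - mu_new - o
        s2_new = np.maximum((z ** 2 - 2 * d_new * z * e + d_new ** 2 * e).mean(axis=0),
                            _VAR_FLOOR)
        pi_new = np.maximum(r.mean(axis=0), 1e-12)
        pi_new /= pi_new.sum()

        model.mu += damp * (mu_new - model.mu)
        model.shift += damp * (d_new - model.shift)
        model.sigma2 += damp * (s2_new - model.sigma2)
        model.batch_offsets += damp * (off_new - model.batch_offsets)
        model.pi += damp * (pi_new - model.pi)
    if not model.converged:
        logger.warning("EM did not converge in %d iterations; keeping best iterate",
                       config.em_max_iter)

    post = model.posterior(y, batch_idx)
    out = pd.DataFrame(post, columns=list(model.lineages))
    amax = post.argmax(axis=1)
    out["lineage"] = np.asarray(model.lineages, dtype=object)[amax]
    out["posterior"] = post[np.arange(N), amax]
    out.index = cells.df.index
    return model, out


# ---------------------------------------------------------------------------
# Perturbation and confidence
# ---------------------------------------------------------------------------

def default_perturbation(schema: TypingSchema):
    """Pick the most identifiable lineage (largest unique-marker count) and
    drop its full defining set.  Ties break alphabetically."""
    uniques = schema.lineage_unique_markers()
    best = max(schema.lineages, key=lambda l: (len(uniques[l.name]), l.name))
    if not uniques[best.name]:
        # No lineage has a unique marker; fall back to the lineage with the
        # smallest defining set (its removal perturbs the least input) and
        # drop that whole set, the only way to de-identify it.
        best = min(schema.lineages, key=lambda l: (len(l.markers), l.name))
        return best.name, tuple(best.markers)
    return best.name, tuple(uniques[best.name])


def build_perturbed_labels(cells: CellTable, schema: TypingSchema, config: RunConfig,
                           complete_labels: pd.Series | None = None,
                           lineage: str | None = None,
                           drop_markers: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Fit the perturbed model and flag each cell stable/variable.

    The perturbation removes ``lineage`` from the definitions and drops
    ``drop_markers`` from the input; cells of the excluded lineage must
    change label, so they (and any genuinely uncertain cell) are flagged
    ``variable``.  With no lineage and an empty drop set the models are
    identical and every cell is stable (vacuous perturbation; allowed but
    logged).

    Returns a DataFrame with columns ``perturbed_lineage`` and ``stable``.
    """
    if complete_labels is None:
        _, post = fit_lineage_model(cells, schema, config)
        complete_labels = post["lineage"]
    if lineage is None and drop_markers is None:
        if schema.perturbation is not None:
            lineage = schema.perturbation.lineage
            drop_markers = schema.perturbation.markers
        else:
            lineage, drop_markers = default_perturbation(schema)
            logger.warning("no perturbation configured; excluding lineage %r and "
                           "dropping markers %s", lineage, list(drop_markers))
    drop_markers = tuple(drop_markers or ())
    if lineage is None and not drop_markers:
        logger.warning("vacuous perturbation (no lineage excluded, no markers "
                       "dropped): all cells will be flagged stable")
    if lineage is not None:
        unique = set(schema.lineage_unique_markers()[lineage])
        defining = set(schema.lineage(lineage).markers)
        if not unique <= set(drop_markers) or not (set(drop_markers) & defining):
            raise SchemaError(
                f"perturbation of lineage {lineage!r} must drop its uniquely "
                f"defining markers {sorted(unique) or sorted(defining)}; got "
                f"{sorted(drop_markers)} — a remaining marker could still "
                "identify it (vacuous perturbation)")

    kept_lineages = []
    for lin in schema.lineages:
        if lin.name == lineage:
            continue
        reduced = tuple(m for m in lin.markers if m not in drop_markers)
        if not reduced:
            logger.warning("lineage %r loses every defining marker under the "
                           "perturbation and is removed too", lin.name)
            continue
        kept_lineages.append(type(lin)(lin.name, reduced))
    if not kept_lineages:
        raise SchemaError("perturbation removes every lineage")

    reduced_markers = tuple(m for m in schema.markers if m not in drop_markers)
    reduced_schema = TypingSchema(
        markers=reduced_markers, lineages=tuple(kept_lineages),
        reference_markers=tuple(m for m in schema.reference_markers
                                if m in reduced_markers) or reduced_markers[:1],
        population_criteria={})
    reduced_cells = cells.drop_markers(list(drop_markers))
    _, post = fit_lineage_model(reduced_cells, reduced_schema, config)
    out = pd.DataFrame({"perturbed_lineage": post["lineage"],
                        "stable": (post["lineage"].to_numpy()
                                   == complete_labels.to_numpy())})
    out.index = cells.df.index
    return out


def confidence_features(cells: CellTable, schema: TypingSchema,
                        labels: pd.Series, posterior: pd.Series) -> np.ndarray:
    """(posterior of the assigned lineage, mean log1p intensity of its
    defining markers) per cell."""
    y = np.log1p(cells.intensities(schema.markers))
    cols = {m: j for j, m in enumerate(schema.markers)}
    mean_int = np.empty(cells.n_cells)
    lab = labels.to_numpy()
    for lin in schema.lineages:
        sel = lab == lin.name
        if sel.any():
            idx = [cols[m] for m in lin.markers]
            mean_int[sel] = y[np.ix_(sel, idx)].mean(axis=1)
    return np.column_stack([posterior.to_numpy(dtype=float), mean_int])


def classify_confidence(cells: CellTable, schema: TypingSchema,
                        labels: pd.Series, posterior: pd.Series,
                        stable: pd.Series):
    """Fit the stable-vs-variable logistic model and predict confidence.

    Returns ``(confidence, model)`` where confidence is a Series of
    ``"high"``/``"low"`` (prediction >= 0.5 of stable, ties high) and
    ``model`` is the fitted scikit-learn classifier (None when the training
    flags are single-class, in which case every cell gets that class)."""
    flags = stable.to_numpy(dtype=bool)
    X = confidence_features(cells, schema, labels, posterior)
    if flags.all() or not flags.any():
        only = "high" if flags.all() else "low"
        logger.warning("confidence training flags are single-class; all cells "
                       "assigned %r confidence", only)
        return pd.Series(only, index=cells.df.index, name="confidence"), None
    from sklearn.linear_model import LogisticRegression
    model = LogisticRegression(max_iter=1000)
    model.fit(X, flags.astype(int))
    if model.coef_[0][0] < 0:
        # Confidence must be monotone in the posterior (raising a cell's
        # posterior can never flip it high→low).  Forced label changes of the
        # excluded lineage can carry high posteriors and drag the coefficient
        # negative; in that case the posterior term is dropped and the model
        # refitted on the intensity feature alone.
        logger.warning("posterior coefficient came out negative (%.3g); "
                       "refitting the confidence model without the posterior "
                       "term to preserve monotonicity", model.coef_[0][0])
        X = X.copy()
        X[:, 0] = 0.0
        model = LogisticRegression(max_iter=1000)
        model.fit(X, flags.astype(int))
    p_stable = model.predict_proba(X)[:, list(model.classes_).index(1)]
    conf = np.where(p_stable >= 0.5, "high", "low")
    return pd.Series(conf, index=cells.df.index, name="confidence"), model


# ---------------------------------------------------------------------------
# Graph clustering within strata
# ---------------------------------------------------------------------------

def _leiden_labels(X: np.ndarray, k: int, seed: int, jaccard: bool) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors
    n = len(X)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    ind = nn.kneighbors(return_distance=False)          # excludes self
    edges = set()
    for i in range(n):
        for j in ind[i]:
            if i != j:
                edges.add((min(i, int(j)), max(i, int(j))))
    edges = sorted(edges)
    g = igraph.Graph(n=n, edges=edges)
    weights = None
    if jaccard:
        neigh = [set(ind[i]) | {i} for i in range(n)]
        weights = [len(neigh[a] & neigh[b]) / len(neigh[a] | neigh[b])
                   for a, b in edges]
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights=weights,
        seed=seed, n_iterations=2)
    return np.asarray(part.membership, dtype=int)


def cluster_strata(cells: CellTable, strata: pd.DataFrame, config: RunConfig
                   ) -> pd.Series:
    """Cluster each (lineage x confidence) group on all marker intensities.

    Cluster ids are integers unique across groups; a group smaller than
    ``k + 1`` becomes a single cluster (logged).  Deterministic given the
    configured seed.
    """
    X = cells.intensities()
    cluster_id = np.full(cells.n_cells, -1, dtype=int)
    next_id = 0
    groups = strata.groupby(["lineage", "confidence"], sort=True).indices
    for (lineage, conf), idx in sorted(groups.items()):
        idx = np.sort(np.asarray(idx))
        if len(idx) <= config.k:
            logger.info("stratum (%s, %s) has %d <= k cells; single cluster",
                        lineage, conf, len(idx))
            cluster_id[idx] = next_id
            next_id += 1
            continue
        labels = _leiden_labels(X[idx], config.k, config.seed, config.jaccard)
        cluster_id[idx] = labels + next_id
        next_id += int(labels.max()) + 1
    return pd.Series(cluster_id, index=cells.df.index, name="cluster_id")


def stratify_cells(cells: CellTable, schema: TypingSchema, config: RunConfig
             ) -> tuple[pd.DataFrame, LineageModel]:
    """Run the full three-tier stratification.

    Returns a per-cell DataFrame (cell_id, image_id, lineage, posterior,
    confidence, cluster_id, stable) and the fitted lineage model.  The
    result is a partition: every cell carries exactly one
    (lineage, confidence, cluster) triple.
    """
    model, post = fit_lineage_model(cells, schema, config)
    pert = build_perturbed_labels(cells, schema, config,
                                  complete_labels=post["lineage"])
    conf, _ = classify_confidence(cells, schema, post["lineage"],
                                  post["posterior"], pert["stable"])
    strata = pd.DataFrame({
        "cell_id": cells.df["cell_id"], "image_id": cells.df["image_id"],
        "lineage": post["lineage"], "posterior": post["posterior"],
        "confidence": conf, "stable": pert["stable"],
    })
    strata["cluster_id"] = cluster_strata(cells, strata, config)
    return strata, model
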