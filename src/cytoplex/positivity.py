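"""Marker positivity via rank statistics.

For each confidence group, every cluster is compared pairwise with every
other cluster: the *win probability* ``p(A, B, m)`` is the probability that
a random cell of cluster A has a higher intensity of marker ``m`` than a
random cell of cluster B (the scaled Mann-Whitney U statistic; ties count
half).  A cluster's per-marker win-probability multiset is summarised by a
*D-score*: the deviation of its empirical CDF from a background
distribution.

Two D-score modes are provided:

* ``"max"`` (default): the maximum positive distance from the background
  CDF to the cluster's CDF, evaluated on the union of observed values;
* ``"area"``: the integral of the positive part of the CDF difference over
  [0, 1] (win probabilities live on [0, 1], so the integral is already in
  [0, 1]).

Both clamp at zero, so anti-expressed clusters score 0 and D is in [0, 1].
The background is, by default, the pooled win probabilities over all
ordered cluster pairs of the group for the same marker — under
exchangeability the cluster and background distributions coincide and
D = 0 exactly.  ``background="uniform"`` substitutes the uniform CDF.

Positivity is called per cluster per marker by strict comparison
``D > cutoff``; the cutoff itself is optimised on a grid over [0, 1] so
that configured *rare* reference-marker populations are minimised and
*dominant* ones maximised (minimum of the rare/dominant cell-count ratio,
excluding cutoffs where any dominant population is empty; ties resolve to
the smallest cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import CellTable, Pattern, TypingSchema
from .errors import CutoffError, SchemaError, ValidationError

logger = logging.getLogger("cytoplex")


def win_probability(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """P(random a > random b), ties counting one half.

    Computed from rank sums in O((|A|+|B|) log) — equal to exhaustive pair
    enumeration ``(#(a>b) + 0.5 #(a==b)) / (|A| |B|)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("win_probability requires non-empty intensity multisets")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


@dataclass
class GroupProfiles:
    """Per-confidence-group cluster profiles: sizes and per-marker pairwise
    win-probability matrices (K x K, antisymmetric around 0.5, diagonal NaN)."""

    confidence: str
    cluster_ids: np.ndarray              # (K,) global cluster ids
    sizes: np.ndarray                    # (K,) member counts
    win: dict[str, np.ndarray]           # marker -> (K, K)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


def build_profiles(cells: CellTable, strata: pd.DataFrame,
                   markers: Sequence[str] | None = None) -> dict[str, GroupProfiles]:
    """Compute pairwise win-probability matrices per confidence group.

    Win probabilities for all pairs of one marker are derived from a single
    ranking of that marker's intensities (rank sums per cluster pair)."""
    markers = list(markers if markers is not None else cells.markers)
    out: dict[str, GroupProfiles] = {}
    for conf in sorted(strata["confidence"].unique()):
        sel = (strata["confidence"] == conf).to_numpy()
        ids = np.sort(np.unique(strata.loc[sel, "cluster_id"].to_numpy()))
        members = [np.flatnonzero(sel & (strata["cluster_id"] == cid).to_numpy())
                   for cid in ids]
        sizes = np.array([len(m) for m in members])
        K = len(ids)
        win: dict[str, np.ndarray] = {}
        X = cells.intensities(markers)
        for j, m in enumerate(markers):
            W = np.full((K, K), np.nan)
            for a in range(K):
                for b in range(a + 1, K):
                    p = win_probability(X[members[a], j], X[members[b], j])
                    W[a, b] = p
                    W[b, a] = 1.0 - p
            win[m] = W
        out[conf] = GroupProfiles(conf, ids, sizes, win)
    return out


def _positive_cdf_gap(p: np.ndarray, background: np.ndarray, mode: str) -> float:
    """Positive deviation of the background CDF above the CDF of ``p``."""
    support = np.unique(np.concatenate([p, background]))
    f_p = np.searchsorted(np.sort(p), support, side="right") / p.size
    f_b = np.searchsorted(np.sort(background), support, side="right") / background.size
    gap = np.clip(f_b - f_p, 0.0, None)
    if mode == "max":
        return float(gap.max(initial=0.0))
    # area: CDFs are right-continuous step functions on [0, 1]; integrate the
    # positive gap between consecutive support points (and up to 1, where the
    # gap is zero because both CDFs reach 1).
    edges = np.concatenate([support, [1.0]])
    widths = np.diff(edges)
    return float((gap[: len(widths)] * widths).sum())


def dscore(p: Sequence[float], background: Sequence[float] | None,
           mode: str = "max") -> float:
    """D-score of a win-probability multiset against a background multiset.

    ``background=None`` uses the uniform CDF on [0, 1] (approximated on a
    fine grid for the max mode; exact linear CDF for the area mode)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("dscore requires at least one win probability")
    if background is None:
        grid = np.linspace(0.0, 1.0, 2001)
        return _positive_cdf_gap(p, grid, mode)
    b = np.asarray(background, dtype=float)
    if b.size == 0:
        raise ValidationError("dscore requires a non-empty background")
    return _positive_cdf_gap(p, b, mode)


def dscore_table(group: GroupProfiles, mode: str = "area",
                 background: str = "pooled") -> pd.DataFrame:
    """D-score per cluster per marker for one confidence group.

    ``background`` choices: ``"pooled"`` pools the ordered-pair win
    probabilities of *all* markers of the group (the win-probability null
    distribution is marker-independent under exchangeability, and pooling
    across markers keeps the background representative even for markers
    expressed by many clusters); ``"pooled-marker"`` pools only the same
    marker's pairs; ``"uniform"`` uses the uniform CDF on [0, 1].

    With a single cluster the D-score is undefined: a NaN row is returned
    and downstream positivity falls back to the annotation module (logged).
    """
    K = group.n_clusters
    markers = list(group.win)
    table = pd.DataFrame(np.nan, index=pd.Index(group.cluster_ids, name="cluster_id"),
                         columns=markers)
    if K < 2:
        logger.warning("confidence group %r has a single cluster; D-scores are "
                       "undefined and no positivity will be called from them",
                       group.confidence)
        return table
    mask = ~np.eye(K, dtype=bool)
    pooled_all = np.concatenate([group.win[m][mask] for m in markers])
    for m in markers:
        W = group.win[m]
        if background == "pooled":
            bg = pooled_all
        elif background == "pooled-marker":
            bg = W[mask]
        else:
            bg = None
        for a in range(K):
            p = np.delete(W[a], a)
            table.loc[group.cluster_ids[a], m] = dscore(p, bg, mode)
    return table


# ---------------------------------------------------------------------------
# Cutoff optimisation
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """Trace and selection of the D-score cutoff for one confidence group."""

    confidence: str
    grid_step: float
    cutoffs: np.ndarray                  # the full grid over [0, 1]
    population_counts: dict[str, np.ndarray]   # label -> per-pattern x grid counts
    excluded: np.ndarray                 # True where a dominant population is empty
    ratio: np.ndarray                    # sum(rare) / sum(dominant); NaN where excluded
    selected: float

    def trace_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cutoff": self.cutoffs, "excluded": self.excluded,
                           "ratio": self.ratio})
        for label, counts in self.population_counts.items():
            for i in range(counts.shape[0]):
                df[f"{label}_{i}"] = counts[i]
        df["confidence"] = self.confidence
        return df


def _pattern_matches(pos: np.ndarray, ref_markers: Sequence[str],
                     pattern: Pattern) -> np.ndarray:
    """Boolean (K, T): cluster matches the sign pattern at each cutoff."""
    K, _, T = pos.shape
    out = np.ones((K, T), dtype=bool)
    for m, sign in pattern.items():
        j = list(ref_markers).index(m)
        want = sign == "+"
        out &= pos[:, j, :] == want
    return out


def optimise_cutoff(dtable: pd.DataFrame, sizes: Mapping[int, int],
                    schema: TypingSchema, grid_step: float = 1e-4,
                    confidence: str = "") -> CutoffResult:
    """Select the D-score cutoff minimising the rare/dominant cell ratio.

    ``dtable`` is a cluster x marker D-score table (any confidence group);
    ``sizes`` maps cluster id to member cell count — populations are counted
    in cells, so large clusters dominate.  Cutoffs at which any dominant
    population has zero cells are excluded from selection.  Raises
    :class:`CutoffError` when every cutoff is excluded.
    """
    ref = list(schema.reference_markers)
    missing = [m for m in ref if m not in dtable.columns]
    if missing:
        raise SchemaError(f"reference marker(s) {missing} missing from D-score table")
    criteria = schema.population_criteria
    if not criteria.get("dominant"):
        raise SchemaError("no dominant populations configured; cannot optimise cutoff")

    n_steps = int(round(1.0 / grid_step))
    cutoffs = np.linspace(0.0, 1.0, n_steps + 1)
    D = dtable[ref].to_numpy(dtype=float)                     # (K, R)
    D = np.nan_to_num(D, nan=-1.0)                            # undefined D: never positive
    pos = D[:, :, None] > cutoffs[None, None, :]              # (K, R, T) strict
    weights = np.array([sizes[cid] for cid in dtable.index], dtype=float)

    counts: dict[str, np.ndarray] = {}
    for label, patterns in criteria.items():
        rows = [weights @ _pattern_matches(pos, ref, pat) for pat in patterns]
        counts[label] = np.vstack(rows) if rows else np.zeros((0, len(cutoffs)))

    dominant = counts["dominant"]
    excluded = (dominant == 0).any(axis=0)
    rare_sum = counts.get("rare", np.zeros((0, len(cutoffs)))).sum(axis=0)
    dom_sum = dominant.sum(axis=0)
    ratio = np.full(len(cutoffs), np.nan)
    ok = ~excluded
    ratio[ok] = rare_sum[ok] / dom_sum[ok]
    if not ok.any():
        raise CutoffError(
            "every candidate cutoff leaves a dominant population empty; revise "
            "the population criteria or reference markers for this panel")
    # The minimal ratio is typically attained on a plateau whose two edges are
    # the documented failure directions (too low: spurious double positives;
    # too high: spurious single positives).  Select the centre of the widest
    # minimal-ratio run for maximal margin to both.
    min_ratio = np.nanmin(ratio[ok])
    at_min = ok & (ratio == min_ratio)
    best = _centre_of_widest_run(at_min)
    return CutoffResult(confidence, grid_step, cutoffs, counts, excluded, ratio,
                        float(cutoffs[best]))


def _centre_of_widest_run(mask: np.ndarray) -> int:
    """Index of the middle of the longest contiguous True run (first on ties)."""
    best_start = best_len = -1
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_start, best_len = i, j - i + 1
            i = j + 1
        else:
            i += 1
    return best_start + best_len // 2


def call_positivity(dtable: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Cluster x marker positivity: strictly ``D > cutoff`` (NaN D is negative)."""
    return dtable.gt(cutoff).fillna(False).astype(bool) if dtable.isna().any().any() \
        else dtable.gt(cutoff)


def cell_positivity(strata: pd.DataFrame,
                    cluster_pos: pd.DataFrame) -> pd.DataFrame:
    """Every member cell inherits its cluster's positivity vector."""
    idx = cluster_pos.index.get_indexer(strata["cluster_id"].to_numpy())
    arr = np.zeros((len(strata), cluster_pos.shape[1]), dtype=bool)
    found = idx >= 0
    arr[found] = cluster_pos.to_numpy()[idx[found]]
    out = pd.DataFrame(arr, columns=cluster_pos.columns, index=strata.index)
    return out


def positivity_pipeline(cells: CellTable, strata: pd.DataFrame,
                        schema: TypingSchema, config) -> tuple[
                            pd.DataFrame, pd.DataFrame, dict[str, CutoffResult],
                            dict[str, GroupProfiles]]:
    """Full positivity stage: profiles, D-scores, per-confidence-group cutoff
    optimisation and per-cell positivity calls.

    If cutoff optimisation fails for one confidence group (e.g. a tiny,
    homogeneous group with no dominant-population cells at any cutoff) the
    cutoff selected for the other group is reused with a warning; the run
    aborts only if no group admits a cutoff.
    """
    profiles = build_profiles(cells, strata)
    dtables: dict[str, pd.DataFrame] = {}
    results: dict[str, CutoffResult] = {}
    failures: list[str] = []
    for conf, group in profiles.items():
        dtables[conf] = dscore_table(group, config.dscore_mode, config.background)
        sizes = dict(zip(group.cluster_ids, group.sizes))
        try:
            results[conf] = optimise_cutoff(dtables[conf], sizes, schema,
                                            config.grid_step, conf)
        except CutoffError:
            failures.append(conf)
    if failures and not results:
        raise CutoffError("cutoff optimisation failed for every confidence group")
    for conf in failures:
        donor = sorted(results)[0]
        logger.warning("cutoff optimisation failed for confidence group %r; "
                       "reusing the %r-group cutoff %.4f", conf, donor,
                       results[donor].selected)
        results[conf] = CutoffResult(conf, config.grid_step,
                                     results[donor].cutoffs,
                                     {}, np.zeros(0, dtype=bool), np.zeros(0),
                                     results[donor].selected)
    cluster_pos_frames = []
    for conf, dtable in dtables.items():
        cluster_pos_frames.append(call_positivity(dtable, results[conf].selected))
    cluster_pos = pd.concat(cluster_pos_frames).sort_index()
    dscores = pd.concat(dtables, names=["confidence", "cluster_id"])
    return dscores, cluster_pos, results, profiles
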