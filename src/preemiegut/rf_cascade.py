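"""Random-forest feature-selection cascade for HCG-trajectory prediction.

Stage 1 screens taxa per taxonomic rank: patient-level feature tables
(median in-window percent abundance, and patient presence) are scored by
response-permutation importance, and taxa with significant importance
(p < .05), presence in >= 3 patients and a defined name at the rank are
kept.  Stage 2 pools the screened features across ranks, adds clinical
variables, fits the multi-rank classifier, and removes redundant
descriptors of the same lineage, keeping the best-ranked.  Accuracy is
reported as 100 minus the out-of-bag error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, RepeatedStratifiedKFold

from .data_model import CountMatrix, HcgGroup, RANKS, SampleRecord, TaxonLineage, window_slice

__all__ = [
    "FeatureTable",
    "RfReport",
    "build_feature_table",
    "fit_rf",
    "permutation_importance",
    "screen_rank_features",
    "reduce_redundant",
]


@dataclass
class FeatureTable:
    """Patient x feature matrix with descriptor metadata.

    Feature columns are named ``<taxon>|<statistic>|<rank>`` (or
    ``<name>|clinical``); ``lineages`` maps taxon names to their lineage
    for the redundancy-reduction stage.
    """

    data: pd.DataFrame
    window: str
    lineages: dict[str, TaxonLineage] = field(default_factory=dict)


@dataclass
class RfReport:
    oob_accuracy: float  # percent, = 100 - OOB error
    max_features: int
    importance: pd.DataFrame | None = None  # feature, observed, count, p, rank
    selected: list[str] = field(default_factory=list)


def build_feature_table(
    cm: CountMatrix,
    samples: Sequence[SampleRecord],
    window: str,
    statistic: str = "median",
) -> FeatureTable:
    """Patient-level features from a rank-aggregated count matrix.

    ``median``: per-patient median percent abundance over in-window
    samples.  ``presence``: 1 if any in-window sample has >0 counts.
    Patients with no in-window sample are excluded.
    """
    if statistic not in ("median", "presence"):
        raise ValueError("statistic must be 'median' or 'presence'")
    sub = [s for s in window_slice(samples, window) if s.sample_id in cm.samples]
    frame = cm.to_frame().astype(float)
    pct = 100.0 * frame / frame.sum(axis=0)
    by_patient: dict[str, list[str]] = {}
    for s in sub:
        by_patient.setdefault(s.patient_id, []).append(s.sample_id)
    rank = _table_rank(cm)
    rows = {}
    for p, sids in by_patient.items():
        if statistic == "median":
            rows[p] = pct[sids].median(axis=1)
        else:
            rows[p] = (frame[sids] > 0).any(axis=1).astype(float)
    data = pd.DataFrame(rows).T
    data.columns = [f"{t}|{statistic}|{rank}" for t in cm.features]
    data.index.name = "patient_id"
    return FeatureTable(data=data, window=window, lineages=dict(cm.lineage))


def _table_rank(cm: CountMatrix) -> str:
    """Deepest rank named across the table's lineages."""
    depth = -1
    for lin in cm.lineage.values():
        for i, r in enumerate(RANKS):
            if lin.name_at(r) is not None:
                depth = max(depth, i)
    return RANKS[depth] if depth >= 0 else "unranked"


def _rf(seed: int, n_trees: int, max_features) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )


def fit_rf(
    table: FeatureTable | pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    n_trees: int = 500,
    cv_folds: int = 10,
    cv_repeats: int = 3,
    n_tune: int = 10,
    seed: int = 0,
    tune: bool = True,
) -> RfReport:
    """Tune the per-split candidate count by randomized repeated-CV search,
    refit on all data and report out-of-bag accuracy (percent)."""
    X = table.data if isinstance(table, FeatureTable) else table
    y = pd.Series(labels).loc[X.index].to_numpy().astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need >= 2 patients per class")
    n_features = X.shape[1]
    best_mtry = max(1, int(np.sqrt(n_features)))
    if tune and n_features > 1:
        rng = np.random.default_rng(seed)
        grid = sorted(set(rng.integers(1, n_features + 1, size=n_tune).tolist()))
        folds = min(cv_folds, int(counts.min()))
        cv = RepeatedStratifiedKFold(n_splits=max(folds, 2), n_repeats=cv_repeats, random_state=seed)
        search = RandomizedSearchCV(
            _rf(seed, n_trees, "sqrt"),
            {"max_features": grid},
            n_iter=min(n_tune, len(grid)),
            cv=cv,
            random_state=seed,
            scoring="accuracy",
            n_jobs=1,
        )
        search.fit(X.to_numpy(), y)
        best_mtry = int(search.best_params_["max_features"])
    model = _rf(seed, n_trees, best_mtry)
    model.fit(X.to_numpy(), y)
    return RfReport(oob_accuracy=100.0 * float(model.oob_score_), max_features=best_mtry)


def permutation_importance(
    table: FeatureTable | pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    n_perm: int = 1001,
    n_trees: int = 500,
    max_features: int | str = "sqrt",
    seed: int = 0,
) -> pd.DataFrame:
    """Response-permutation significance of mean-impurity-decrease importance.

    The response vector is permuted ``n_perm`` times; for each feature,
    ``count`` is the number of permutations whose importance fell below
    the observed one and ``p = 1 - count/(n_perm+1)``.  Features are ranked
    by count, descending (rank 1 = most important).
    """
    import warnings

    X = table.data if isinstance(table, FeatureTable) else table
    Xv = X.to_numpy()
    y = pd.Series(labels).loc[X.index].to_numpy().astype(int)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    observed = _rf(seed, n_trees, max_features).fit(Xv, y).feature_importances_
    rng = np.random.default_rng(seed)
    counts = np.zeros(X.shape[1], dtype=int)
    for b in range(n_perm):
        yp = rng.permutation(y)
        imp = _rf(seed + 1 + b, n_trees, max_features).fit(Xv, yp).feature_importances_
        counts += imp < observed
    p = 1.0 - counts / (n_perm + 1.0)
    out = pd.DataFrame(
        {"feature": X.columns, "observed": observed, "count": counts, "p": p}
    )
    out["rank"] = out["count"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def screen_rank_features(
    importance: pd.DataFrame,
    presence_counts: Mapping[str, int],
    rank: str,
    lineages: Mapping[str, TaxonLineage],
    p_threshold: float = 0.05,
    min_patients: int = 3,
) -> list[str]:
    """Keep features significant at ``p < .05`` whose taxon is present in
    >= 3 patients and is actually classified at the examined rank."""
    kept = []
    for row in importance.itertuples():
        taxon = str(row.feature).split("|")[0]
        if row.p >= p_threshold:
            continue
        if presence_counts.get(taxon, 0) < min_patients:
            continue
        lin = lineages.get(taxon)
        if lin is None or lin.name_at(rank) is None:
            continue
        kept.append(str(row.feature))
    return kept


def _lineage_chain(lin: TaxonLineage) -> tuple[str, ...]:
    return tuple(n for n in (lin.phylum, lin.family, lin.genus, lin.species) if n is not None)


def reduce_redundant(
    ranked: pd.DataFrame | Sequence[str],
    lineages: Mapping[str, TaxonLineage],
) -> list[str]:
    """Keep the best-ranked descriptor per underlying lineage.

    Two descriptors are redundant when their taxa lie on the same lineage
    chain (equal, or ancestor and descendant), regardless of statistic;
    the better-ranked one is retained and on rank ties the more specific
    (deeper) rank wins.  Clinical features (no lineage entry) are never
    merged.  ``ranked`` is either an importance frame with ``feature`` and
    ``count`` columns or a best-first sequence of feature names.
    """
    if isinstance(ranked, pd.DataFrame):
        order = list(zip(ranked["feature"], -ranked["count"].to_numpy()))
    else:
        order = [(f, i) for i, f in enumerate(ranked)]

    def depth(item):
        taxon = str(item[0]).split("|")[0]
        lin = lineages.get(taxon)
        return -len(_lineage_chain(lin)) if lin is not None else 0

    # sort by rank score, then deeper lineage first so rank-ties resolve
    # to the more specific descriptor
    order.sort(key=lambda it: (it[1], depth(it)))
    kept: list[str] = []
    kept_chains: list[tuple[str, ...]] = []
    for f, _ in order:
        taxon = str(f).split("|")[0]
        lin = lineages.get(taxon)
        if lin is None:
            kept.append(str(f))  # clinical: never merged
            continue
        chain = _lineage_chain(lin)
        redundant = any(
            chain[: len(c)] == c or c[: len(chain)] == chain for c in kept_chains
        )
        if not redundant:
            kept.append(str(f))
            kept_chains.append(chain)
    return kept
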