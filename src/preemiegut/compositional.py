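"""Quality filtering, rank aggregation, percent/CLR transforms, alpha diversity.

The fixed preprocessing order is: sample QC (drop totals < 1000), rare-taxon
culling (< 0.1% mean percent abundance), then per-rank aggregation.  The
centered log-ratio transform is applied per rank *after* aggregation, with
zeros replaced by the multiplicative-simple rule (delta = 0.65 x the
sample's minimum nonzero proportion, nonzero parts rescaled to keep unit
sum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountMatrix, TaxonLineage, RANKS, ValidationError

__all__ = [
    "ClrMatrix",
    "qc_filter_samples",
    "cull_rare_taxa",
    "aggregate_to_rank",
    "percent_abundance",
    "clr_transform",
    "alpha_diversity",
    "preprocess",
]

#: Multiplicative-simple zero replacement: fraction of the per-sample
#: minimum nonzero proportion used as the imputed value.
DEFAULT_DELTA_FRACTION = 0.65


@dataclass
class ClrMatrix:
    """Centered log-ratios (features x samples) plus the imputation record."""

    values: pd.DataFrame
    imputed: pd.DataFrame  # boolean mask, True where a zero was replaced
    delta: pd.Series  # per-sample replacement value used (NaN if none)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def qc_filter_samples(cm: CountMatrix, min_total: int = 1000) -> CountMatrix:
    """Drop samples with total sequence counts below ``min_total``.

    The boundary is right-closed: a sample with exactly ``min_total`` counts
    is retained (the filter removes "<1000").
    """
    totals = cm.sample_totals()
    keep = [s for s in cm.samples if totals[s] >= min_total]
    if not keep:
        raise ValidationError("QC filter removed every sample")
    if len(keep) == len(cm.samples):
        return cm
    return cm.select_samples(keep)


def percent_abundance(cm: CountMatrix) -> pd.DataFrame:
    """Features x samples percent abundances (columns sum to 100)."""
    df = cm.to_frame().astype(float)
    totals = df.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValidationError(f"samples with zero total counts: {bad[:5]}")
    return 100.0 * df / totals


def cull_rare_taxa(cm: CountMatrix, min_mean_pct: float = 0.1) -> CountMatrix:
    """Remove features whose mean percent abundance is below the threshold.

    Means are computed once, across all currently retained samples; the
    boundary is right-closed (a feature at exactly the threshold stays).
    """
    mean_pct = percent_abundance(cm).mean(axis=1)
    keep = [f for f in cm.features if mean_pct[f] >= min_mean_pct]
    if len(keep) == len(cm.features):
        return cm
    return cm.select_features(keep)


def aggregate_to_rank(cm: CountMatrix, rank: str) -> CountMatrix:
    """Sum counts over features sharing a name at ``rank``.

    Features unclassified at that rank are pooled into a single
    ``unclassified@<rank>`` feature, so per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    unclassified = f"unclassified@{rank}"
    rank_idx = RANKS.index(rank)
    name_of = {}
    lineage_of: dict[str, TaxonLineage] = {}
    for f in cm.features:
        lin = cm.lineage[f]
        name = lin.name_at(rank)
        if name is None:
            name = unclassified
            lineage_of.setdefault(name, TaxonLineage())
        else:
            # truncate the lineage at the aggregation rank
            kw = {r: lin.name_at(r) for r in RANKS[: rank_idx + 1]}
            lineage_of.setdefault(name, TaxonLineage(**kw))
        name_of[f] = name
    names = list(dict.fromkeys(name_of[f] for f in cm.features))
    out = np.zeros((len(names), len(cm.samples)), dtype=np.int64)
    pos = {n: i for i, n in enumerate(names)}
    for i, f in enumerate(cm.features):
        out[pos[name_of[f]]] += cm.counts[i]
    return CountMatrix(features=names, samples=list(cm.samples), counts=out, lineage=lineage_of)


def _impute_zeros(props: np.ndarray, delta_fraction: float) -> tuple[np.ndarray, float]:
    """Multiplicative-simple replacement on one composition (sums to 1)."""
    zero = props == 0
    if not zero.any():
        return props, float("nan")
    delta = delta_fraction * props[~zero].min()
    out = props.copy()
    out[zero] = delta
    # rescale nonzero parts multiplicatively to preserve the unit sum
    out[~zero] *= 1.0 - delta * zero.sum()
    return out, float(delta)


def clr_transform(
    cm: CountMatrix, delta_fraction: float = DEFAULT_DELTA_FRACTION
) -> ClrMatrix:
    """Centered log-ratio transform with multiplicative-simple zero imputation.

    Per sample: proportions are formed, zeros replaced by
    ``delta = delta_fraction x min nonzero proportion`` with the nonzero
    proportions rescaled to keep the unit sum, then
    ``clr(x)_i = ln x_i - mean_j ln x_j``.
    """
    if len(cm.features) < 2:
        raise ValidationError("CLR needs at least 2 features")
    df = cm.to_frame().astype(float)
    totals = df.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValidationError(f"all-zero samples: {bad[:5]}")
    values = np.empty(df.shape)
    imputed = df.to_numpy() == 0
    deltas = []
    for j, s in enumerate(df.columns):
        props = df[s].to_numpy() / totals[s]
        filled, delta = _impute_zeros(props, delta_fraction)
        logs = np.log(filled)
        values[:, j] = logs - logs.mean()
        deltas.append(delta)
    return ClrMatrix(
        values=pd.DataFrame(values, index=df.index, columns=df.columns),
        imputed=pd.DataFrame(imputed, index=df.index, columns=df.columns),
        delta=pd.Series(deltas, index=df.columns),
    )


def alpha_diversity(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample richness (features with count > 0) and Shannon index
    (natural log, over nonzero proportions)."""
    df = cm.to_frame().astype(float)
    totals = df.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("alpha diversity undefined for all-zero samples")
    props = df / totals
    richness = (df > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    shannon = -plogp.sum(axis=0)
    return pd.DataFrame({"richness": richness.astype(int), "shannon": shannon})


def preprocess(
    cm: CountMatrix,
    rank: str,
    min_total: int = 1000,
    min_mean_pct: float = 0.1,
    delta_fraction: float = DEFAULT_DELTA_FRACTION,
) -> tuple[CountMatrix, pd.DataFrame, ClrMatrix]:
    """QC -> cull -> aggregate to ``rank``; returns the rank-level count
    matrix, its percent abundances, and its CLR transform."""
    cm = qc_filter_samples(cm, min_total=min_total)
    cm = cull_rare_taxa(cm, min_mean_pct=min_mean_pct)
    ranked = aggregate_to_rank(cm, rank)
    return ranked, percent_abundance(ranked), clr_transform(ranked, delta_fraction)
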