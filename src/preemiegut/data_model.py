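"""Domain types and on-disk formats shared by every analysis stage.

The analytical substrate is a feature-by-sample table of 16S amplicon
sequence counts, annotated with a phylum-to-species lineage per feature,
per-sample metadata (patient, completed postmenstrual-age week) and a
per-patient clinical table.  Head-circumference-growth (HCG) trajectory
groups are assigned from the loss in Fenton head-circumference z-score
between birth and 36 weeks PMA.

On-disk dialect is TSV throughout: counts as features x samples with a
header row of sample IDs, taxonomy as ``feature<TAB>p__..;f__..;g__..;s__..``,
metadata and clinical tables as tidy TSVs keyed by sample / patient ID.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonLineage",
    "CountMatrix",
    "SampleRecord",
    "ClinicalRecord",
    "HcgGroup",
    "AnalysisWindow",
    "WINDOWS",
    "RANKS",
    "MORBIDITIES",
    "ValidationError",
    "assign_hcg_group",
    "window_slice",
    "read_count_table",
    "write_count_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_clinical_table",
    "write_clinical_table",
    "fenton_z_score",
]

RANKS = ("phylum", "family", "genus", "species")

MORBIDITIES = (
    "BPD",
    "NEC",
    "severe brain injury",
    "seizures",
    "sepsis",
    "severe ROP",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class TaxonLineage:
    """Phylum-to-species lineage; lower ranks may be unclassified (None).

    A rank may only be named if every rank above it is named, so a lineage
    is always a prefix of (phylum, family, genus, species).
    """

    phylum: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        seen_gap = False
        for rank in RANKS:
            name = getattr(self, rank)
            if name is not None and not str(name).strip():
                raise ValidationError(f"empty name at rank {rank!r}")
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValidationError(
                    f"rank {rank!r} named but a higher rank is unclassified: {self}"
                )

    def name_at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def to_string(self) -> str:
        parts = []
        for prefix, rank in zip("pfgs", RANKS):
            name = getattr(self, rank)
            parts.append(f"{prefix}__{name if name is not None else ''}")
        return ";".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "TaxonLineage":
        fields: dict[str, str | None] = {}
        parts = [p.strip() for p in text.split(";")]
        if len(parts) != 4:
            raise ValidationError(f"lineage string needs 4 ranks: {text!r}")
        for part, prefix, rank in zip(parts, "pfgs", RANKS):
            if not part.startswith(f"{prefix}__"):
                raise ValidationError(f"bad lineage field {part!r} in {text!r}")
            name = part[3:]
            fields[rank] = name if name else None
        return cls(**fields)


@dataclass
class CountMatrix:
    """Integer feature x sample sequence counts plus feature lineages."""

    features: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_features, n_samples) nonnegative integers
    lineage: dict[str, TaxonLineage]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(set(self.features)) != len(self.features):
            raise ValidationError("duplicate feature IDs")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = self.features[int(np.argwhere(self.counts < 0)[0][0])]
            raise ValidationError(f"negative count in feature {bad!r}")
        missing = [f for f in self.features if f not in self.lineage]
        if missing:
            raise ValidationError(f"features without lineage: {missing[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.features, columns=self.samples)

    def sample_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.samples)

    def select_samples(self, keep: Sequence[str]) -> "CountMatrix":
        keep = list(keep)
        idx = [self.samples.index(s) for s in keep]
        return CountMatrix(
            features=list(self.features),
            samples=keep,
            counts=self.counts[:, idx].copy(),
            lineage={f: self.lineage[f] for f in self.features},
        )

    def select_features(self, keep: Sequence[str]) -> "CountMatrix":
        keep = list(keep)
        idx = [self.features.index(f) for f in keep]
        return CountMatrix(
            features=keep,
            samples=list(self.samples),
            counts=self.counts[idx, :].copy(),
            lineage={f: self.lineage[f] for f in keep},
        )


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample annotation: owning patient and completed PMA week."""

    sample_id: str
    patient_id: str
    pma_week: int
    total_counts: int = 0

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError(f"sample {self.sample_id!r} lacks a patient ID")
        if not 20 <= self.pma_week <= 44:
            raise ValidationError(
                f"sample {self.sample_id!r}: pma_week {self.pma_week} outside 20..44"
            )


class HcgGroup(enum.IntEnum):
    """Ordered head-circumference-growth trajectory groups.

    Ordering runs from appropriate growth to severely suboptimal growth;
    the integer codes encode that ordering for ordinal models.
    """

    AHCGT = 0
    MILD_SHCGT = 1
    MODERATE_SHCGT = 2
    SEVERE_SHCGT = 3

    @property
    def label(self) -> str:
        return _GROUP_LABELS[self]


_GROUP_LABELS = {
    HcgGroup.AHCGT: "AHCGT",
    HcgGroup.MILD_SHCGT: "mildly SHCGT",
    HcgGroup.MODERATE_SHCGT: "moderately SHCGT",
    HcgGroup.SEVERE_SHCGT: "severely SHCGT",
}

#: Right-closed upper edges of the z-score-loss bins for each group, in
#: severity order.  A loss of exactly 0.5 is still appropriate growth and a
#: loss of exactly 1.0 is still mild, matching the ">=0.5" / "<0.5-1"
#: stratification convention.
DEFAULT_LOSS_BINS: tuple[float, float, float] = (0.5, 1.0, 1.5)


def assign_hcg_group(
    hc_z_birth: float,
    hc_z_36w: float,
    bins: tuple[float, float, float] = DEFAULT_LOSS_BINS,
) -> HcgGroup:
    """Stratify an infant by the loss in head-circumference z-score.

    The loss is ``hc_z_birth - hc_z_36w``; bins are right-closed at
    0.5-unit intervals: loss <= 0.5 is appropriate growth (AHCGT), then
    mildly (<=1), moderately (<=1.5) and severely (>1.5) suboptimal.
    """
    if not (math.isfinite(hc_z_birth) and math.isfinite(hc_z_36w)):
        raise ValueError("z-scores must be finite")
    loss = hc_z_birth - hc_z_36w
    if loss <= bins[0]:
        return HcgGroup.AHCGT
    if loss <= bins[1]:
        return HcgGroup.MILD_SHCGT
    if loss <= bins[2]:
        return HcgGroup.MODERATE_SHCGT
    return HcgGroup.SEVERE_SHCGT


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and HCG outcome."""

    patient_id: str
    delivery_mode: str  # "vaginal" | "cesarean"
    gestational_age_weeks: float
    sex: str  # "male" | "female"
    birth_weight_kg: float
    birth_hc_cm: float
    hc_z_birth: float
    hc_z_36w: float
    antibiotic_total_days: float = 0.0
    antibiotic_max_consecutive_days: float = 0.0
    enteral_total_ml_per_kg: float = 0.0
    human_milk_ml_per_kg: float = 0.0
    formula_ml_per_kg: float = 0.0
    tpn_days: float = 0.0
    day_full_feeds: float = 0.0
    morbidity_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.delivery_mode not in ("vaginal", "cesarean"):
            raise ValidationError(
                f"patient {self.patient_id!r}: bad delivery_mode {self.delivery_mode!r}"
            )
        for name in (
            "antibiotic_total_days",
            "antibiotic_max_consecutive_days",
            "enteral_total_ml_per_kg",
            "human_milk_ml_per_kg",
            "formula_ml_per_kg",
            "tpn_days",
            "day_full_feeds",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"patient {self.patient_id!r}: negative {name}")
        if not (math.isfinite(self.hc_z_birth) and math.isfinite(self.hc_z_36w)):
            raise ValidationError(f"patient {self.patient_id!r}: non-finite z-score")
        unknown = set(self.morbidity_flags) - set(MORBIDITIES)
        if unknown:
            raise ValidationError(
                f"patient {self.patient_id!r}: unknown morbidity flags {sorted(unknown)}"
            )
        self.morbidity_flags = frozenset(self.morbidity_flags)

    @property
    def hcg_group(self) -> HcgGroup:
        return assign_hcg_group(self.hc_z_birth, self.hc_z_36w)

    @property
    def n_morbidities(self) -> int:
        return len(self.morbidity_flags)


@dataclass(frozen=True)
class AnalysisWindow:
    """Inclusive PMA-week window: overall, early (24-30) or late (31-36)."""

    label: str
    start: int
    end: int

    def contains(self, pma_week: int) -> bool:
        return self.start <= pma_week <= self.end


WINDOWS: dict[str, AnalysisWindow] = {
    "overall": AnalysisWindow("overall", 24, 36),
    "early": AnalysisWindow("early", 24, 30),
    "late": AnalysisWindow("late", 31, 36),
}


def window_slice(
    samples: Iterable[SampleRecord], window: str | AnalysisWindow
) -> list[SampleRecord]:
    """Samples whose completed PMA week falls inside the window (inclusive).

    ``overall`` applies no week filtering at all, so samples outside 24-36
    (if any exist) are retained there.
    """
    win = WINDOWS[window] if isinstance(window, str) else window
    if win.label == "overall":
        return list(samples)
    return [s for s in samples if win.contains(s.pma_week)]


# --------------------------------------------------------------------------
# Fenton z-score hook
# --------------------------------------------------------------------------

#: Head-circumference z-scores are consumed as inputs; converting a raw
#: measurement requires the Fenton 2013 LMS reference tables, which are
#: external data.  Install a callable (hc_cm, pma_week, sex) -> z here to
#: enable conversion.
fenton_z_score: Callable[[float, int, str], float] | None = None


# --------------------------------------------------------------------------
# TSV I/O
# --------------------------------------------------------------------------


def write_count_table(cm: CountMatrix, counts_path: str | Path, taxonomy_path: str | Path) -> None:
    df = cm.to_frame()
    df.index.name = "feature"
    df.to_csv(counts_path, sep="\t")
    tax = pd.DataFrame(
        {"feature": cm.features, "lineage": [cm.lineage[f].to_string() for f in cm.features]}
    )
    tax.to_csv(taxonomy_path, sep="\t", index=False)


def read_count_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
) -> CountMatrix:
    """Read a features-x-samples count TSV plus its companion taxonomy TSV.

    Counts: first column is the feature ID, remaining header cells are the
    sample IDs.  Taxonomy: columns ``feature`` and semicolon-delimited
    ``lineage``.  Malformed counts or missing lineages raise
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.columns.size == 0:
        raise ValidationError(f"{counts_path}: no sample columns in header")
    for feat, row in df.iterrows():
        vals = pd.to_numeric(row, errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"{counts_path}: non-numeric count in feature {feat!r}")
        if (vals < 0).any():
            raise ValidationError(f"{counts_path}: negative count in feature {feat!r}")
        if not np.all(np.equal(np.mod(vals.to_numpy(dtype=float), 1), 0)):
            raise ValidationError(f"{counts_path}: non-integer count in feature {feat!r}")
    tax = pd.read_csv(taxonomy_path, sep="\t")
    if not {"feature", "lineage"} <= set(tax.columns):
        raise ValidationError(f"{taxonomy_path}: needs 'feature' and 'lineage' columns")
    lineage = {
        str(r.feature): TaxonLineage.from_string(str(r.lineage)) for r in tax.itertuples()
    }
    missing = [f for f in df.index if f not in lineage]
    if missing:
        raise ValidationError(f"{counts_path}: features without lineage: {missing[:5]}")
    return CountMatrix(
        features=[str(f) for f in df.index],
        samples=[str(s) for s in df.columns],
        counts=df.to_numpy(dtype=np.int64),
        lineage=lineage,
    )


def write_sample_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "pma_week": [r.pma_week for r in records],
            "total_counts": [r.total_counts for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleRecord(
            sample_id=str(r.sample_id),
            patient_id=str(r.patient_id),
            pma_week=int(r.pma_week),
            total_counts=int(getattr(r, "total_counts", 0)),
        )
        for r in df.itertuples()
    ]


_CLINICAL_NUMERIC = (
    "gestational_age_weeks",
    "birth_weight_kg",
    "birth_hc_cm",
    "hc_z_birth",
    "hc_z_36w",
    "antibiotic_total_days",
    "antibiotic_max_consecutive_days",
    "enteral_total_ml_per_kg",
    "human_milk_ml_per_kg",
    "formula_ml_per_kg",
    "tpn_days",
    "day_full_feeds",
)


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "delivery_mode": r.delivery_mode,
            "sex": r.sex,
        }
        for name in _CLINICAL_NUMERIC:
            row[name] = getattr(r, name)
        row["morbidity_flags"] = "|".join(sorted(r.morbidity_flags))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for r in df.itertuples():
        flags = frozenset(x for x in str(r.morbidity_flags).split("|") if x)
        kwargs = {name: float(getattr(r, name)) for name in _CLINICAL_NUMERIC}
        records.append(
            ClinicalRecord(
                patient_id=str(r.patient_id),
                delivery_mode=str(r.delivery_mode),
                sex=str(r.sex),
                morbidity_flags=flags,
                **kwargs,
            )
        )
    return records


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Tidy per-patient DataFrame (one row per patient) for model fitting."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "delivery_mode": r.delivery_mode,
            "sex": r.sex,
            "hcg_group": int(r.hcg_group),
            "n_morbidities": r.n_morbidities,
        }
        for name in _CLINICAL_NUMERIC:
            row[name] = getattr(r, name)
        for m in MORBIDITIES:
            row[f"morb_{m.replace(' ', '_')}"] = int(m in r.morbidity_flags)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
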