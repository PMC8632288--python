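"""Seeded synthetic preterm-infant cohorts with plantable succession structure.

The generator emulates the statistical skeleton of a NICU 16S study: four
head-circumference-growth (HCG) groups of sizes 28/16/8/6, weekly stool
samples over postmenstrual-age (PMA) weeks 24-36 with entry at the week of
birth and geometric dropout, Dirichlet-multinomial counts over a small mock
taxonomy (4 phyla / 8 families / 16 genera / 24 species-like leaves),
group-specific step changes in mean log-abundance planted at a configurable
week (default 30), clinical covariates drawn at the cohort's published group
rates, and head-circumference z-score trajectories that diverge by group
after the planted week.

Everything is a deterministic function of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ClinicalRecord,
    CountMatrix,
    HcgGroup,
    SampleRecord,
    TaxonLineage,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "default_taxonomy",
    "simulate_cohort",
    "simulate_null_cohort",
]


def default_taxonomy() -> dict[str, TaxonLineage]:
    """Mock taxonomy: 24 species-like leaves under 16 genera / 8 families /
    4 phyla, with a few leaves unclassified at species rank."""

    def L(p, f, g, s=None):
        return TaxonLineage(phylum=p, family=f, genus=g, species=s)

    entries = [
        # Bacteroidota
        L("Bacteroidota", "Bacteroidaceae", "Bacteroides", "fragilis"),
        L("Bacteroidota", "Bacteroidaceae", "Bacteroides", "vulgatus"),
        L("Bacteroidota", "Bacteroidaceae", "Phocaeicola", "dorei"),
        L("Bacteroidota", "Tannerellaceae", "Parabacteroides", "distasonis"),
        L("Bacteroidota", "Tannerellaceae", "Parabacteroides", "merdae"),
        L("Bacteroidota", "Tannerellaceae", "Tannerella", None),
        # Firmicutes
        L("Firmicutes", "Lachnospiraceae", "Blautia", "wexlerae"),
        L("Firmicutes", "Lachnospiraceae", "Blautia", None),
        L("Firmicutes", "Lachnospiraceae", "Coprococcus", "comes"),
        L("Firmicutes", "Lachnospiraceae", "Coprococcus", None),
        L("Firmicutes", "Ruminococcaceae", "Faecalibacterium", "prausnitzii"),
        L("Firmicutes", "Ruminococcaceae", "Faecalibacterium", "duncaniae"),
        L("Firmicutes", "Ruminococcaceae", "Ruminococcus", "bromii"),
        # Actinobacteriota
        L("Actinobacteriota", "Bifidobacteriaceae", "Bifidobacterium", "longum"),
        L("Actinobacteriota", "Bifidobacteriaceae", "Bifidobacterium", "breve"),
        L("Actinobacteriota", "Bifidobacteriaceae", "Gardnerella", "vaginalis"),
        L("Actinobacteriota", "Corynebacteriaceae", "Corynebacterium", "amycolatum"),
        L("Actinobacteriota", "Corynebacteriaceae", "Lawsonella", "clevelandensis"),
        # Proteobacteria
        L("Proteobacteria", "Enterobacteriaceae", "Escherichia", "coli"),
        L("Proteobacteria", "Enterobacteriaceae", "Escherichia", "fergusonii"),
        L("Proteobacteria", "Enterobacteriaceae", "Klebsiella", "pneumoniae"),
        L("Proteobacteria", "Enterobacteriaceae", "Klebsiella", None),
        L("Proteobacteria", "Moraxellaceae", "Acinetobacter", "baumannii"),
        L("Proteobacteria", "Moraxellaceae", "Moraxella", "catarrhalis"),
    ]
    return {f"sp{i + 1:02d}": lin for i, lin in enumerate(entries)}


#: Baseline mean log-abundances (softmax logits) per leaf of the default
#: taxonomy, reflecting a Proteobacteria/Firmicutes-dominated preterm gut
#: with moderate Bacteroidota and Lachnospiraceae and low Actinobacteriota.
DEFAULT_BASELINE = (
    1.0, 0.5, 0.2, 0.0, -0.4, -0.6,          # Bacteroidota
    0.8, 0.3, 0.5, 0.0, 0.3, -0.3, -0.1,     # Firmicutes
    0.2, -0.2, -0.8, -0.6, -1.2,             # Actinobacteriota
    1.8, 0.6, 2.0, 0.9, 0.1, -0.5,           # Proteobacteria
)

#: Table-2-style per-group clinical rates (AHCGT, mild, moderate, severe).
DEFAULT_CLINICAL_RATES: dict[str, tuple[float, float, float, float]] = {
    "vaginal": (0.429, 0.125, 0.125, 0.167),
    "male": (0.464, 0.563, 0.250, 0.667),
    "BPD": (0.536, 0.563, 0.625, 0.833),
    "NEC": (0.0, 0.0, 0.0, 0.50),
    "severe brain injury": (0.071, 0.0, 0.125, 0.50),
    "seizures": (0.071, 0.125, 0.125, 0.167),
    "sepsis": (0.0, 0.0, 0.25, 0.0),
    "severe ROP": (0.036, 0.125, 0.25, 0.167),
}

DEFAULT_GA = {"mean": (28.3, 27.1, 27.0, 26.2), "sd": (2.6, 2.2, 3.4, 3.1)}
DEFAULT_BW = {"mean": (1.02, 0.98, 1.07, 0.96), "sd": (0.38, 0.33, 0.55, 0.53)}
DEFAULT_HC = {"mean": (24.9, 24.7, 24.6, 24.3), "sd": (2.9, 2.8, 4.1, 3.8)}

#: Target z-score-loss bands per group, kept 0.05 inside the 0.5-unit
#: stratification bins so the generated records always map back to their
#: generative group.
LOSS_BANDS = ((-0.2, 0.45), (0.55, 0.95), (1.05, 1.45), (1.55, 2.40))


@dataclass
class CohortSpec:
    """Tunable description of a synthetic cohort.

    Defaults reproduce the study conditions the analysis is designed for;
    ``effects`` maps a taxon name at any rank (or a leaf feature ID) to a
    per-group post-change log-scale shift applied from ``change_week`` on.
    """

    n_patients_per_group: tuple[int, int, int, int] = (28, 16, 8, 6)
    week_start: int = 24
    week_end: int = 36
    taxonomy: dict[str, TaxonLineage] = field(default_factory=default_taxonomy)
    baseline_log_abundance: tuple[float, ...] = DEFAULT_BASELINE
    change_week: int = 30
    effects: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "Bacteroidota": (0.0, -2.0, -2.0, -2.0),
            "Lachnospiraceae": (0.0, -2.0, -2.0, -2.0),
        }
    )
    concentration: float = 50.0
    depth_log_mean: float = 9.2
    depth_log_sd: float = 0.5
    dropout_hazard: float = 0.15
    patient_effect_sd: float = 0.5
    clinical_rates: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_RATES)
    )
    loss_bands: tuple[tuple[float, float], ...] = LOSS_BANDS
    z_path_noise_sd: float = 0.05
    morbidity_microbiome_coupling: float = 0.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_patients_per_group):
            raise ValueError("each group needs at least one patient")
        if not self.week_start <= self.change_week <= self.week_end:
            raise ValueError("change_week must lie inside the week range")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0.0 <= self.dropout_hazard < 1.0:
            raise ValueError("dropout_hazard must be in [0, 1)")
        if len(self.baseline_log_abundance) != len(self.taxonomy):
            raise ValueError("baseline vector length must match taxonomy size")
        for key, probs in self.clinical_rates.items():
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"clinical rate for {key!r} outside [0,1]")


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth it was built from."""

    count_matrix: CountMatrix
    sample_records: list[SampleRecord]
    clinical_records: list[ClinicalRecord]
    z_trajectories: pd.DataFrame  # patients x weeks, hc z-score by PMA week
    ground_truth: dict

    @property
    def groups(self) -> dict[str, HcgGroup]:
        """Generative group label per patient (authoritative for analyses)."""
        return {p: HcgGroup(g) for p, g in self.ground_truth["group"].items()}


def _effect_matrix(spec: CohortSpec) -> np.ndarray:
    """Resolve the taxon-keyed effect map to a (n_leaves, 4) shift matrix."""
    leaves = list(spec.taxonomy)
    shifts = np.zeros((len(leaves), 4))
    for key, per_group in spec.effects.items():
        per_group = np.asarray(per_group, dtype=float)
        if per_group.shape != (4,):
            raise ValueError(f"effect for {key!r} must give one shift per group")
        hit = False
        for i, leaf in enumerate(leaves):
            lin = spec.taxonomy[leaf]
            names = {leaf, lin.phylum, lin.family, lin.genus, lin.species}
            if key in names:
                shifts[i] += per_group
                hit = True
        if not hit:
            raise ValueError(f"effect key {key!r} matches no taxon or feature")
    return shifts


def _truncated_normal(rng, mean, sd, low, high):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x
    return float(np.clip(mean, low, high))


def simulate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``spec``; bit-reproducible per seed.

    Per retained (patient, week) sample, composition is
    ``Dirichlet(concentration * softmax(baseline + patient effect + shift))``
    with the group-specific shift active from ``change_week`` onward, and
    counts are ``Multinomial(depth, composition)`` with lognormal depth.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    leaves = list(spec.taxonomy)
    n_leaves = len(leaves)
    baseline = np.asarray(spec.baseline_log_abundance, dtype=float)
    shifts = _effect_matrix(spec)
    weeks = np.arange(spec.week_start, spec.week_end + 1)

    # -- patients and clinical covariates ---------------------------------
    patient_ids: list[str] = []
    groups: dict[str, int] = {}
    k = 0
    for g, n in enumerate(spec.n_patients_per_group):
        for _ in range(n):
            k += 1
            pid = f"P{k:02d}"
            patient_ids.append(pid)
            groups[pid] = g

    clinical: list[ClinicalRecord] = []
    z_rows = {}
    loss_by_patient: dict[str, float] = {}
    for pid in patient_ids:
        g = groups[pid]
        ga = _truncated_normal(rng, DEFAULT_GA["mean"][g], DEFAULT_GA["sd"][g], 23.0, 33.9)
        bw = _truncated_normal(rng, DEFAULT_BW["mean"][g], DEFAULT_BW["sd"][g], 0.3, 2.5)
        hc = _truncated_normal(rng, DEFAULT_HC["mean"][g], DEFAULT_HC["sd"][g], 18.0, 34.0)
        delivery = "vaginal" if rng.random() < spec.clinical_rates["vaginal"][g] else "cesarean"
        sex = "male" if rng.random() < spec.clinical_rates["male"][g] else "female"
        flags = frozenset(
            m
            for m in ("BPD", "NEC", "severe brain injury", "seizures", "sepsis", "severe ROP")
            if rng.random() < spec.clinical_rates[m][g]
        )
        abx_total = float(np.round(rng.gamma(2.0, 4.0)))
        abx_consec = float(min(abx_total, np.round(2 + rng.gamma(1.5, 2.0))))
        enteral = max(0.0, rng.normal(120.0, 25.0))
        milk_frac = rng.beta(2.0, 1.0)
        tpn = float(np.round(rng.gamma(3.0, 4.0)))
        full_feeds = max(5.0, np.round(rng.normal(14.0, 5.0)))

        # z trajectory: flat until change_week, then linear decline to the
        # group's target loss at week_end; endpoints noise-free so the
        # stored record maps back to its generative group exactly.
        z_birth = rng.normal(0.0, 0.8)
        lo, hi = spec.loss_bands[g]
        loss = rng.uniform(lo, hi)
        loss_by_patient[pid] = loss
        z = np.full(weeks.size, z_birth, dtype=float)
        post = weeks > spec.change_week
        if post.any():
            frac = (weeks[post] - spec.change_week) / (spec.week_end - spec.change_week)
            z[post] = z_birth - loss * frac
            interior = post & (weeks < spec.week_end)
            z[interior] += rng.normal(0.0, spec.z_path_noise_sd, interior.sum())
        z_rows[pid] = z
        clinical.append(
            ClinicalRecord(
                patient_id=pid,
                delivery_mode=delivery,
                gestational_age_weeks=round(ga, 1),
                sex=sex,
                birth_weight_kg=round(bw, 2),
                birth_hc_cm=round(hc, 1),
                hc_z_birth=z_birth,
                hc_z_36w=z_birth - loss,
                antibiotic_total_days=abx_total,
                antibiotic_max_consecutive_days=abx_consec,
                enteral_total_ml_per_kg=enteral,
                human_milk_ml_per_kg=enteral * milk_frac,
                formula_ml_per_kg=enteral * (1 - milk_frac),
                tpn_days=tpn,
                day_full_feeds=full_feeds,
                morbidity_flags=flags,
            )
        )

    # -- sampling schedule: entry at week of birth, geometric dropout ------
    schedule: dict[str, list[int]] = {}
    for pid, rec in zip(patient_ids, clinical):
        entry = max(spec.week_start, int(np.floor(rec.gestational_age_weeks)))
        entry = min(entry, spec.week_end)
        kept = [entry]  # the first week is never dropped
        for w in range(entry + 1, spec.week_end + 1):
            if rng.random() < spec.dropout_hazard:
                break
            kept.append(w)
        schedule[pid] = kept

    # -- counts ------------------------------------------------------------
    patient_effects = {
        pid: rng.normal(0.0, spec.patient_effect_sd, n_leaves) for pid in patient_ids
    }
    sample_ids: list[str] = []
    sample_records: list[SampleRecord] = []
    columns: list[np.ndarray] = []
    for pid in patient_ids:
        g = groups[pid]
        rec = next(c for c in clinical if c.patient_id == pid)
        coupling = spec.morbidity_microbiome_coupling * rec.n_morbidities
        for w in schedule[pid]:
            logits = baseline + patient_effects[pid]
            if w >= spec.change_week:
                logits = logits + shifts[:, g]
            if coupling:
                logits = logits + coupling * (shifts[:, 1:] != 0).any(axis=1)
            p = np.exp(logits - logits.max())
            p /= p.sum()
            comp = rng.dirichlet(spec.concentration * p)
            depth = int(np.round(np.exp(rng.normal(spec.depth_log_mean, spec.depth_log_sd))))
            counts = rng.multinomial(max(depth, 1), comp)
            sid = f"{pid}_w{w}"
            sample_ids.append(sid)
            columns.append(counts)
            sample_records.append(
                SampleRecord(sample_id=sid, patient_id=pid, pma_week=w, total_counts=int(counts.sum()))
            )

    cm = CountMatrix(
        features=leaves,
        samples=sample_ids,
        counts=np.column_stack(columns).astype(np.int64),
        lineage=dict(spec.taxonomy),
    )
    z_df = pd.DataFrame(z_rows, index=weeks).T
    z_df.index.name = "patient_id"
    ground_truth = {
        "change_week": spec.change_week,
        "effects": {k: tuple(v) for k, v in spec.effects.items()},
        "group": dict(groups),
        "loss": loss_by_patient,
    }
    return SyntheticCohort(cm, sample_records, clinical, z_df, ground_truth)


def expected_clr_shift(spec: CohortSpec, rank: str, group: int) -> pd.Series:
    """Analytic CLR-scale group contrast implied by the planted effects.

    For the mean-logit composition, a per-leaf logit shift ``d_i`` changes a
    rank-level feature's log abundance by ``log(sum_i p_i e^{d_i}) -
    log(sum_i p_i)`` over its leaves, and the CLR contrast additionally
    subtracts the mean of those changes across the rank's features (the
    softmax normalizer cancels).  This is the value the mixed-model LS-mean
    difference estimates in the post-change window, up to count noise.
    """
    from .data_model import RANKS

    baseline = np.asarray(spec.baseline_log_abundance, dtype=float)
    p = np.exp(baseline - baseline.max())
    p /= p.sum()
    shifts = _effect_matrix(spec)[:, group]
    leaves = list(spec.taxonomy)
    names = []
    for leaf in leaves:
        nm = spec.taxonomy[leaf].name_at(rank)
        names.append(nm if nm is not None else f"unclassified@{rank}")
    feats = list(dict.fromkeys(names))
    a = np.empty(len(feats))
    b = np.empty(len(feats))
    for j, f in enumerate(feats):
        idx = [i for i, nm in enumerate(names) if nm == f]
        a[j] = np.log(np.sum(p[idx] * np.exp(shifts[idx])))
        b[j] = np.log(np.sum(p[idx]))
    delta = (a - a.mean()) - (b - b.mean())
    return pd.Series(delta, index=feats)


def simulate_null_cohort(spec: CohortSpec | None = None, seed: int = 0) -> SyntheticCohort:
    """As :func:`simulate_cohort` with all planted effects and z-score
    decrements forced to zero: group labels (in ``ground_truth``) carry no
    signal, so downstream group tests are calibrated against it."""
    spec = spec or CohortSpec()
    null_spec = replace(
        spec,
        effects={},
        loss_bands=tuple((0.0, 0.0) for _ in range(4)),
        z_path_noise_sd=0.0,
        morbidity_microbiome_coupling=0.0,
        clinical_rates={
            k: (v[0],) * 4 for k, v in spec.clinical_rates.items()
        },
    )
    return simulate_cohort(null_spec, seed)
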