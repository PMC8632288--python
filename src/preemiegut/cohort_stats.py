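"""Group-difference statistics for the cohort.

Covers the per-taxon mixed-effect abundance models (random patient
intercept, LS-mean contrasts, Nakagawa marginal R^2), patient-level
prevalence with Fisher / Freeman-Halton exact tests, Welch ANOVA and
Games-Howell post hoc from raw data or printed summary statistics,
unequal-variance Cohen's D, Benjamini-Hochberg multiplicity control, and a
constrained-ordination (RDA) screen with block-restricted permutations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .compositional import ClrMatrix
from .data_model import CountMatrix, HcgGroup, SampleRecord, WINDOWS, window_slice

__all__ = [
    "LmmResult",
    "ContingencyResult",
    "WelchResult",
    "BhFlags",
    "RdaResult",
    "fit_abundance_lmm",
    "prevalence",
    "fisher_exact",
    "welch_anova",
    "games_howell",
    "cohen_d_welch",
    "bh_adjust",
    "rda_blocked",
    "any_shcgt_indicator",
]


# --------------------------------------------------------------------------
# Mixed-effect abundance models
# --------------------------------------------------------------------------


@dataclass
class LmmResult:
    """One taxon's mixed-model contrast in one analysis window."""

    taxon: str
    window: str
    ls_mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    p_pma: float | None
    marginal_r2: float
    n_obs: int
    n_patients: int
    converged: bool
    p_method: str = "wald_z"


def any_shcgt_indicator(groups: Mapping[str, HcgGroup | int]) -> dict[str, float]:
    """Patient -> 1.0 for any suboptimal-growth group, 0.0 for appropriate."""
    return {p: float(int(g) > 0) for p, g in groups.items()}


def fit_abundance_lmm(
    values: Mapping[str, float] | pd.Series,
    samples: Sequence[SampleRecord],
    indicator: Mapping[str, float],
    window: str = "overall",
    include_pma: bool | None = None,
    taxon: str = "",
) -> LmmResult:
    """REML random-intercept model of one taxon's CLR abundance.

    ``indicator`` maps patient -> contrast coding (e.g. any-SHCGT = 1 vs
    AHCGT = 0, or vaginal = 1 vs cesarean = 0); its coefficient is the
    LS-mean difference between the contrasted groups after adjusting for
    (standardized) PMA and the patient random intercept.  PMA enters as a
    fixed effect for the overall window only, unless overridden.

    The group-effect p-value is a Wald z test on the coefficient (recorded
    in ``p_method``); ``marginal_r2`` is the Nakagawa fixed-effect variance
    fraction.
    """
    vals = pd.Series(values)
    sub = [s for s in window_slice(samples, window) if s.sample_id in vals.index]
    if include_pma is None:
        include_pma = window == "overall"
    rows = [
        (s.sample_id, s.patient_id, s.pma_week, indicator[s.patient_id])
        for s in sub
        if s.patient_id in indicator
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "pma_week", "grp"])
    df["y"] = vals.loc[df["sample_id"]].to_numpy()
    n_patients = df["patient_id"].nunique()
    if len(df) < 3 or df["grp"].nunique() < 2 or n_patients < 4:
        raise ValueError("need >=3 observations and both contrast levels")

    exog = pd.DataFrame({"const": 1.0, "grp": df["grp"].to_numpy()})
    if include_pma:
        pma = df["pma_week"].to_numpy(dtype=float)
        sd = pma.std(ddof=1)
        exog["pma_std"] = (pma - pma.mean()) / sd if sd > 0 else 0.0
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(df["y"].to_numpy(), exog.to_numpy(), groups=df["patient_id"])
            fit = model.fit(reml=True)
            converged = bool(fit.converged)
        except Exception:
            # singular fit: fall back to OLS, flagged as non-converged
            fit = sm.OLS(df["y"].to_numpy(), exog.to_numpy()).fit()
            converged = False

    names = list(exog.columns)
    i_grp = names.index("grp")
    coef = float(fit.params[i_grp])
    se = float(fit.bse[i_grp])
    p = float(2 * stats.norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    ci = (coef - 1.959963984540054 * se, coef + 1.959963984540054 * se)
    p_pma = None
    if include_pma:
        i_pma = names.index("pma_std")
        se_p = float(fit.bse[i_pma])
        p_pma = float(2 * stats.norm.sf(abs(float(fit.params[i_pma])) / se_p)) if se_p > 0 else 1.0

    # Nakagawa marginal R^2: fixed-effect variance share
    fixed_pred = exog.to_numpy() @ np.asarray(fit.params[: len(names)], dtype=float)
    var_fixed = float(np.var(fixed_pred))
    if hasattr(fit, "cov_re"):
        var_re = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
    else:
        var_re = 0.0
        var_resid = float(fit.mse_resid)
    denom = var_fixed + var_re + var_resid
    r2 = var_fixed / denom if denom > 0 else float("nan")

    return LmmResult(
        taxon=taxon,
        window=window,
        ls_mean_diff=coef,
        ci_low=ci[0],
        ci_high=ci[1],
        p_value=p,
        p_pma=p_pma,
        marginal_r2=r2,
        n_obs=len(df),
        n_patients=n_patients,
        converged=converged,
    )


# --------------------------------------------------------------------------
# Prevalence and exact tests
# --------------------------------------------------------------------------


def prevalence(
    cm: CountMatrix,
    samples: Sequence[SampleRecord],
    groups: Mapping[str, HcgGroup | int],
    window: str = "overall",
) -> pd.DataFrame:
    """Patient-level presence counts per taxon and group in a window.

    A taxon is present in a patient if any in-window sample of that patient
    has >0 counts; denominators are the patients with >=1 in-window sample.
    Returns a tidy frame with columns taxon, group, n_present, n_patients.
    """
    sub = window_slice(samples, window)
    by_patient: dict[str, list[str]] = {}
    for s in sub:
        if s.sample_id in cm.samples and s.patient_id in groups:
            by_patient.setdefault(s.patient_id, []).append(s.sample_id)
    frame = cm.to_frame()
    rows = []
    group_levels = sorted({int(g) for g in groups.values()})
    denom = {
        g: sum(1 for p in by_patient if int(groups[p]) == g) for g in group_levels
    }
    for taxon in cm.features:
        present = {g: 0 for g in group_levels}
        for p, sids in by_patient.items():
            if (frame.loc[taxon, sids] > 0).any():
                present[int(groups[p])] += 1
        for g in group_levels:
            rows.append((taxon, g, present[g], denom[g]))
    return pd.DataFrame(rows, columns=["taxon", "group", "n_present", "n_patients"])


@dataclass
class ContingencyResult:
    table: np.ndarray
    p_value: float
    prevalence_pct: np.ndarray  # per column, first-row share in percent
    method: str
    mc_se: float | None = None


def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    return log_const - gammaln(table + 1.0).sum()


def _enumerate_tables(row_sums: Sequence[int], col_sums: Sequence[int]):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(i: int, remaining_cols: tuple[int, ...], rows_acc: list[tuple[int, ...]]):
        if i == r - 1:
            if all(x >= 0 for x in remaining_cols) and sum(remaining_cols) == row_sums[-1]:
                yield rows_acc + [remaining_cols]
            return
        target = row_sums[i]

        def fill(j: int, left: int, row_acc: list[int]):
            if j == c - 1:
                if 0 <= left <= remaining_cols[-1]:
                    yield row_acc + [left]
                return
            for v in range(0, min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - v, row_acc + [v])

        for row in fill(0, target, []):
            new_cols = tuple(rc - rv for rc, rv in zip(remaining_cols, row))
            yield from rec(i + 1, new_cols, rows_acc + [tuple(row)])

    yield from rec(0, tuple(col_sums), [])


def fisher_exact(
    table: np.ndarray | Sequence[Sequence[int]],
    max_exact_total: int = 200,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> ContingencyResult:
    """Two-sided Fisher exact test, generalized to r x c (Freeman-Halton).

    2x2 tables use the standard two-sided test.  Larger tables sum the
    hypergeometric probabilities of all margin-preserving tables whose
    point probability is <= the observed one (ties within 1e-12 relative
    included); enumeration is exact up to ``max_exact_total`` total counts,
    beyond which a Monte-Carlo estimate with reported standard error is
    returned.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("zero margin in contingency table")
    col_tot = t.sum(axis=0).astype(float)
    prev = 100.0 * t[0] / col_tot

    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return ContingencyResult(t, float(min(p, 1.0)), prev, "fisher_2x2")

    n = int(t.sum())
    log_const = gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum() - gammaln(n + 1.0)
    log_p_obs = _log_table_prob(t, log_const)
    cut = log_p_obs + 1e-12 + 1e-12 * abs(log_p_obs)

    if n <= max_exact_total:
        total = 0.0
        for rows in _enumerate_tables(row_sums.tolist(), col_sums.tolist()):
            cand = np.asarray(rows, dtype=np.int64)
            lp = _log_table_prob(cand, log_const)
            if lp <= cut:
                total += math.exp(lp)
        return ContingencyResult(t, float(min(total, 1.0)), prev, "freeman_halton_exact")

    # Monte-Carlo: sample margin-fixed tables via random bipartite assignment
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(t.shape[0]), row_sums)
    col_labels = np.repeat(np.arange(t.shape[1]), col_sums)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        cand = np.zeros_like(t)
        np.add.at(cand, (row_labels, perm), 1)
        if _log_table_prob(cand, log_const) <= cut:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return ContingencyResult(t, float(p), prev, "freeman_halton_mc", mc_se=se)


# --------------------------------------------------------------------------
# Welch ANOVA family
# --------------------------------------------------------------------------


@dataclass
class WelchResult:
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float
    group_stats: list[tuple[int, float, float]]  # (n, mean, sd)
    posthoc: pd.DataFrame | None = None  # Games-Howell pairwise p + Cohen's D


def welch_anova(
    groups: Sequence[Sequence[float]] | None = None,
    summary: Sequence[tuple[int, float, float]] | None = None,
) -> WelchResult:
    """Welch's heteroscedastic ANOVA from raw observations or (n, mean, sd).

    With two groups the p-value equals the two-sided Welch t-test.  Raw
    data and its sufficient statistics give identical results.
    """
    if (groups is None) == (summary is None):
        raise ValueError("pass exactly one of groups= or summary=")
    if groups is not None:
        stats_list = []
        for g in groups:
            arr = np.asarray(g, dtype=float)
            if arr.size < 2:
                raise ValueError("each group needs n >= 2")
            stats_list.append((int(arr.size), float(arr.mean()), float(arr.std(ddof=1))))
    else:
        stats_list = [(int(n), float(m), float(s)) for n, m, s in summary]
        if any(n < 2 for n, _, _ in stats_list):
            raise ValueError("each group needs n >= 2")
    k = len(stats_list)
    if k < 2:
        raise ValueError("need at least two groups")
    if all(s == 0 for _, _, s in stats_list):
        raise ValueError("degenerate: zero variance in every group")
    n = np.array([g[0] for g in stats_list], dtype=float)
    m = np.array([g[1] for g in stats_list], dtype=float)
    s2 = np.array([g[2] for g in stats_list], dtype=float) ** 2
    w = n / np.where(s2 > 0, s2, np.finfo(float).tiny)
    W = w.sum()
    mw = (w * m).sum() / W
    a = ((w * (m - mw) ** 2).sum()) / (k - 1)
    h = (((1 - w / W) ** 2) / (n - 1)).sum()
    b = 1 + (2 * (k - 2) / (k**2 - 1)) * h
    F = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * h)
    p = float(stats.f.sf(F, df1, df2))
    return WelchResult(float(F), float(df1), float(df2), p, stats_list)


def games_howell(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (studentized range, Welch df).

    Returns a frame with columns i, j, mean_diff, p_value, cohen_d.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >=2 groups with n >= 2 each")
    k = len(arrs)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        x, y = arrs[i], arrs[j]
        vi, vj = x.var(ddof=1), y.var(ddof=1)
        ni, nj = x.size, y.size
        se2 = vi / ni + vj / nj
        diff = x.mean() - y.mean()
        if se2 == 0:
            p = 1.0
            d = 0.0
        else:
            df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
            q = abs(diff) / math.sqrt(se2 / 2.0)
            p = float(stats.studentized_range.sf(q, k, df))
            d = cohen_d_welch(x, y)
        rows.append((i, j, float(diff), min(p, 1.0), d))
    return pd.DataFrame(rows, columns=["i", "j", "mean_diff", "p_value", "cohen_d"])


def cohen_d_welch(x: Sequence[float], y: Sequence[float]) -> float:
    """Unequal-variance Cohen's D: (mean_x - mean_y) / sqrt((var_x+var_y)/2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in each sample")
    pooled = (x.var(ddof=1) + y.var(ddof=1)) / 2.0
    if pooled == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float((x.mean() - y.mean()) / math.sqrt(pooled))


# --------------------------------------------------------------------------
# Multiplicity
# --------------------------------------------------------------------------


@dataclass
class BhFlags:
    p_values: np.ndarray
    q_values: np.ndarray
    flags: np.ndarray
    fdr: float


def bh_adjust(p_values: Sequence[float], fdr: float = 0.01) -> BhFlags:
    """Benjamini-Hochberg step-up q-values with flags at ``q < fdr``."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return BhFlags(p, p.copy(), np.zeros(0, dtype=bool), fdr)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return BhFlags(p, q, q < fdr, fdr)


# --------------------------------------------------------------------------
# Redundancy analysis with block-restricted permutations
# --------------------------------------------------------------------------


@dataclass
class RdaResult:
    model_f: float
    model_p: float
    term_stats: pd.DataFrame  # term, marginal_r2, sequential_r2, f, p
    n_perm: int


def _rda_ss(Y: np.ndarray, X: np.ndarray) -> float:
    """Sum of squares of Y explained by least-squares projection on X."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    return float((fitted**2).sum())


def rda_blocked(
    clr: ClrMatrix | pd.DataFrame,
    terms: pd.DataFrame,
    blocks: Mapping[str, str] | pd.Series,
    n_perm: int = 199,
    seed: int = 0,
) -> RdaResult:
    """Constrained ordination of a CLR table on design terms with
    permutation p-values restricted within patient blocks.

    ``terms`` is a samples x terms numeric design (e.g. group dummies and
    standardized PMA); ``blocks`` maps sample -> patient.  Pseudo-F per
    term uses the marginal (added-last) sum of squares; the permutation
    scheme shuffles response rows within each block, so it is informative
    for within-patient terms such as PMA and conservative for terms that
    are constant within a patient.
    """
    values = clr.values if isinstance(clr, ClrMatrix) else clr
    samples = list(terms.index)
    Y = values[samples].to_numpy().T  # samples x features
    Y = Y - Y.mean(axis=0)
    X_terms = terms.to_numpy(dtype=float)
    n, q = X_terms.shape
    if n <= q + 1:
        raise ValueError("need more samples than terms")
    # collinearity check
    ones = np.ones((n, 1))
    Xc = np.column_stack([ones, X_terms])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(f"collinear terms among {list(terms.columns)}")
    total_ss = float((Y**2).sum())

    def model_stats(Yp: np.ndarray) -> tuple[float, np.ndarray]:
        ss_full = _rda_ss(Yp, Xc)
        resid = total_ss - ss_full
        f_model = (ss_full / q) / (resid / (n - q - 1))
        f_terms = np.empty(q)
        for t in range(q):
            X_red = np.delete(Xc, t + 1, axis=1)
            ss_red = _rda_ss(Yp, X_red)
            f_terms[t] = (ss_full - ss_red) / (resid / (n - q - 1))
        return f_model, f_terms

    f_model_obs, f_terms_obs = model_stats(Y)

    # marginal and sequential variance fractions
    marg = np.empty(q)
    seq = np.empty(q)
    prev_ss = 0.0
    for t in range(q):
        marg[t] = _rda_ss(Y, np.column_stack([ones, X_terms[:, [t]]])) / total_ss
        ss_t = _rda_ss(Y, np.column_stack([ones, X_terms[:, : t + 1]]))
        seq[t] = (ss_t - prev_ss) / total_ss
        prev_ss = ss_t

    blocks = pd.Series(blocks)
    block_idx: list[np.ndarray] = [
        np.flatnonzero(blocks.loc[samples].to_numpy() == b)
        for b in pd.unique(blocks.loc[samples])
    ]
    rng = np.random.default_rng(seed)
    ge_model = 0
    ge_terms = np.zeros(q, dtype=int)
    for _ in range(n_perm):
        perm = np.arange(n)
        for idx in block_idx:
            perm[idx] = idx[rng.permutation(idx.size)]
        f_m, f_t = model_stats(Y[perm])
        ge_model += f_m >= f_model_obs
        ge_terms += f_t >= f_terms_obs
    p_model = (1 + ge_model) / (n_perm + 1)
    p_terms = (1 + ge_terms) / (n_perm + 1)
    term_stats = pd.DataFrame(
        {
            "term": list(terms.columns),
            "marginal_r2": marg,
            "sequential_r2": seq,
            "f": f_terms_obs,
            "p": p_terms,
        }
    )
    return RdaResult(float(f_model_obs), float(p_model), term_stats, n_perm)
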