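"""Ordinal moderation analysis of delivery-mode effects on HCG trajectory.

The model is a proportional-odds (cumulative logit) regression of the
4-level ordered HCG trajectory with a per-patient normal random intercept,
fitted by maximum likelihood with the random effect integrated out by
adaptive Gauss-Hermite quadrature.  Fixed effects are standardized PMA,
delivery mode, a moderator (a taxon's CLR abundance or a clinical factor)
and the delivery x moderator interaction.

Orientation: the linear predictor points toward *less severe* outcomes, so
a positive interaction coefficient means the moderator strengthens the
vaginal-delivery benefit (the expected change on the log-odds scale as HCG
severity decreases, per the reporting convention).

Binary predictors are coded +/-0.5 (vaginal = +0.5); continuous predictors
are centered and scaled by their overall mean/sd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats

from .cohort_stats import cohen_d_welch
from .data_model import ClinicalRecord, HcgGroup, SampleRecord

__all__ = [
    "ModerationResult",
    "CLMM_FACTORS",
    "OrdinalMixedModel",
    "fit_ordinal_moderation",
    "mcfadden_r2",
    "consistency_screen",
    "clinical_moderation_panel",
]

#: Clinical factors examined by the moderation panel.
CLMM_FACTORS = (
    "gestational_age_weeks",
    "birth_weight_kg",
    "birth_hc_cm",
    "sex",
    "antibiotic_total_days",
    "antibiotic_max_consecutive_days",
    "enteral_total_ml_per_kg",
    "tpn_days",
    "day_full_feeds",
    "human_milk_ml_per_kg",
    "formula_ml_per_kg",
    "n_morbidities",
)


@dataclass
class ModerationResult:
    moderator: str
    coefficient: float
    ci_low: float
    ci_high: float
    wald_p: float
    mcfadden_r2: float
    ll_model: float
    ll_null: float
    converged: bool
    n_obs: int
    sigma: float
    cohens_d: dict[str, float] = field(default_factory=dict)
    consistent: bool | None = None
    flags: list[str] = field(default_factory=list)


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    ex = np.exp(u[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class OrdinalMixedModel:
    """Proportional-odds model with a cluster random intercept (AGQ).

    ``y`` are ordinal codes 0..C-1 per observation, ``X`` the fixed-effect
    design, ``cluster`` integer cluster codes.  The cumulative logit is
    ``logit P(y <= c) = theta_c + x beta + b`` with ``b ~ N(0, sigma^2)``,
    so positive coefficients push toward *lower* categories.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, cluster: np.ndarray, nodes: int = 9):
        self.y = np.asarray(y, dtype=int)
        self.X = np.asarray(X, dtype=float)
        self.C = int(self.y.max()) + 1
        if self.C < 3:
            raise ValueError("need >= 3 observed outcome levels")
        codes, idx = np.unique(np.asarray(cluster), return_inverse=True)
        self.inv = idx
        self.n_clusters = codes.size
        self.k = self.X.shape[1]
        z, w = hermgauss(nodes)
        self.z, self.logw = z, np.log(w)
        self.nodes = nodes
        # masks for the boundary categories (open-ended intervals)
        self.has_hi = self.y < self.C - 1
        self.has_lo = self.y > 0
        self.i_hi = np.minimum(self.y, self.C - 2)
        self.i_lo = np.maximum(self.y - 1, 0)

    # -- parameter packing: thresholds via increasing transform ------------
    def _thresholds(self, t: np.ndarray) -> np.ndarray:
        th = np.empty(self.C - 1)
        th[0] = t[0]
        if self.C > 2:
            th[1:] = t[0] + np.cumsum(np.exp(t[1:]))
        return th

    def _obs_logp(self, theta, eta, b_obs):
        """Per-observation log P(y | b); ``b_obs`` aligned to observations."""
        u_hi = theta[self.i_hi] + eta + b_obs
        u_lo = theta[self.i_lo] + eta + b_obs
        s_hi = np.where(self.has_hi, _sigmoid(u_hi), 1.0)
        s_lo = np.where(self.has_lo, _sigmoid(u_lo), 0.0)
        return np.log(np.clip(s_hi - s_lo, 1e-300, None))

    def _obs_derivs(self, theta, eta, b_obs):
        """Per-observation (dlogp/db, d2logp/db2)."""
        u_hi = theta[self.i_hi] + eta + b_obs
        u_lo = theta[self.i_lo] + eta + b_obs
        s_hi = np.where(self.has_hi, _sigmoid(u_hi), 1.0)
        s_lo = np.where(self.has_lo, _sigmoid(u_lo), 0.0)
        p = np.clip(s_hi - s_lo, 1e-300, None)
        d_hi = np.where(self.has_hi, s_hi * (1 - s_hi), 0.0)
        d_lo = np.where(self.has_lo, s_lo * (1 - s_lo), 0.0)
        dd_hi = d_hi * (1 - 2 * s_hi)
        dd_lo = d_lo * (1 - 2 * s_lo)
        r = (d_hi - d_lo) / p
        return r, (dd_hi - dd_lo) / p - r**2

    def cluster_logliks(self, params: np.ndarray) -> np.ndarray:
        """Per-cluster marginal log-likelihood terms (AGQ-integrated).

        The per-cluster mode is found by a vectorized Newton search (all
        clusters at once), the curvature there rescales the Gauss-Hermite
        nodes, and a log-sum-exp over nodes gives each cluster's term.
        """
        theta = self._thresholds(params[: self.C - 1])
        beta = params[self.C - 1 : self.C - 1 + self.k]
        sigma = math.exp(params[-1])
        eta = self.X @ beta
        inv = self.inv
        nc = self.n_clusters
        b = np.zeros(nc)
        for _ in range(30):
            g1o, g2o = self._obs_derivs(theta, eta, b[inv])
            grad = np.bincount(inv, weights=g1o, minlength=nc) - b / sigma**2
            hess = np.bincount(inv, weights=g2o, minlength=nc) - 1.0 / sigma**2
            step = np.clip(-grad / hess, -3.0, 3.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-9:
                break
        _, g2o = self._obs_derivs(theta, eta, b[inv])
        h = -(np.bincount(inv, weights=g2o, minlength=nc) - 1.0 / sigma**2)
        h = np.where(np.isfinite(h) & (h > 0), h, 1.0 / sigma**2)
        sh = np.sqrt(2.0 / h)
        const = -0.5 * math.log(2 * math.pi) - math.log(sigma)
        expo = np.empty((self.nodes, nc))
        for k in range(self.nodes):
            bk = b + sh * self.z[k]
            lp = np.bincount(inv, weights=self._obs_logp(theta, eta, bk[inv]), minlength=nc)
            expo[k] = self.logw[k] + self.z[k] ** 2 + lp - 0.5 * bk**2 / sigma**2 + const
        m = expo.max(axis=0)
        return m + np.log(np.exp(expo - m).sum(axis=0)) + np.log(sh)

    def loglik(self, params: np.ndarray) -> float:
        return float(self.cluster_logliks(params).sum())

    def _fit_params(self, x0: np.ndarray, free_beta: bool) -> tuple[np.ndarray, float, bool]:
        if free_beta:
            def nll(p):
                return -self.loglik(p)
            x_init = x0
        else:
            beta_fixed = np.zeros(self.k)

            def nll(p):
                full = np.concatenate([p[: self.C - 1], beta_fixed, p[-1:]])
                return -self.loglik(full)

            x_init = np.concatenate([x0[: self.C - 1], x0[-1:]])
        # the random-intercept scale is bounded (sigma <= ~7.4): with a
        # cluster-constant outcome the variance can drift to infinity
        # (quasi-separation), which degenerates the quadrature
        bounds = [(None, None)] * (x_init.size - 1) + [(-4.6, 2.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                nll, x_init, method="L-BFGS-B", bounds=bounds, options={"maxiter": 300}
            )
        if free_beta:
            return res.x, -res.fun, bool(res.success or res.fun < np.inf)
        full = np.concatenate([res.x[: self.C - 1], np.zeros(self.k), res.x[-1:]])
        return full, -res.fun, bool(res.success)

    def fit(self):
        """Fit full and null (thresholds + random intercept) models.

        Returns (params, ll_model, ll_null, cov, converged); ``cov`` is the
        cluster-robust (sandwich) covariance over the full parameter
        vector.  The robust form is essential here: the outcome is
        typically constant within a patient, so the model-based
        information overstates the effective replication and its Wald
        intervals are badly miscalibrated.
        """
        # empirical cumulative-logit start for thresholds
        freq = np.bincount(self.y, minlength=self.C) / self.y.size
        cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
        th0 = np.log(cum / (1 - cum))
        t0 = np.empty(self.C - 1)
        t0[0] = th0[0]
        if self.C > 2:
            t0[1:] = np.log(np.clip(np.diff(th0), 1e-3, None))
        x0 = np.concatenate([t0, np.zeros(self.k), [math.log(0.5)]])
        params, ll_model, ok = self._fit_params(x0, free_beta=True)
        _, ll_null, _ = self._fit_params(params, free_beta=False)
        cov = self._sandwich_cov(params)
        return params, ll_model, ll_null, cov, ok

    def _cluster_scores(self, params: np.ndarray) -> np.ndarray:
        """Per-cluster score vectors by central differences."""
        n = params.size
        S = np.empty((self.n_clusters, n))
        h = 1e-5 * np.maximum(1.0, np.abs(params))
        for i in range(n):
            e = np.zeros(n)
            e[i] = h[i]
            S[:, i] = (self.cluster_logliks(params + e) - self.cluster_logliks(params - e)) / (
                2 * h[i]
            )
        return S

    def _sandwich_cov(self, params: np.ndarray) -> np.ndarray:
        """Cluster-robust covariance A^-1 B A^-1 with a G/(G-1) correction."""
        A_inv = self._cov(params)
        if not np.all(np.isfinite(A_inv)):
            return A_inv
        S = self._cluster_scores(params)
        S = S - S.mean(axis=0)
        G = self.n_clusters
        B = S.T @ S * (G / max(G - 1, 1))
        return A_inv @ B @ A_inv

    def _cov(self, params: np.ndarray) -> np.ndarray:
        n = params.size
        h = 1e-4 * np.maximum(1.0, np.abs(params))
        H = np.empty((n, n))
        f0 = self.loglik(params)
        fp = np.empty(n)
        fm = np.empty(n)
        for i in range(n):
            e = np.zeros(n)
            e[i] = h[i]
            fp[i] = self.loglik(params + e)
            fm[i] = self.loglik(params - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(n):
            for j in range(i + 1, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                fpp = self.loglik(params + ei + ej)
                fmm = self.loglik(params - ei - ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                    2 * h[i] * h[j]
                )
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.full((n, n), np.nan)


def _standardize(x: np.ndarray) -> np.ndarray:
    vals = np.unique(x)
    if vals.size <= 1:
        raise ValueError("constant predictor")
    if vals.size == 2:
        out = np.where(x == vals.max(), 0.5, -0.5)
        return out.astype(float)
    return (x - x.mean()) / x.std(ddof=1)


def fit_ordinal_moderation(
    moderator: Mapping[str, float] | pd.Series,
    samples: Sequence[SampleRecord],
    outcome: Mapping[str, HcgGroup | int],
    delivery: Mapping[str, str],
    name: str = "",
    nodes: int = 9,
) -> ModerationResult:
    """Wald test of the delivery x moderator interaction on HCG severity.

    ``moderator`` is keyed by sample ID (e.g. per-sample CLR abundance) or
    by patient ID (clinical factor); ``outcome`` maps patient to the
    ordered 4-level group; ``delivery`` maps patient to vaginal/cesarean.
    """
    mod = pd.Series(moderator)
    per_sample = any(s.sample_id in mod.index for s in samples)
    rows = []
    for s in samples:
        key = s.sample_id if per_sample else s.patient_id
        if key not in mod.index or s.patient_id not in outcome:
            continue
        rows.append(
            (
                s.patient_id,
                s.pma_week,
                1.0 if delivery[s.patient_id] == "vaginal" else 0.0,
                float(mod[key]),
                int(outcome[s.patient_id]),
            )
        )
    df = pd.DataFrame(rows, columns=["patient", "pma", "vaginal", "mod", "y"])
    if df["mod"].nunique() <= 1:
        raise ValueError(f"moderator {name!r} has no variance")
    pma = _standardize(df["pma"].to_numpy(dtype=float))
    vag = np.where(df["vaginal"].to_numpy() > 0, 0.5, -0.5)
    m = _standardize(df["mod"].to_numpy(dtype=float))
    X = np.column_stack([pma, vag, m, vag * m])
    # re-code the outcome to consecutive observed levels
    levels = np.unique(df["y"].to_numpy())
    y = np.searchsorted(levels, df["y"].to_numpy())
    model = OrdinalMixedModel(y, X, df["patient"].to_numpy(), nodes=nodes)
    params, ll_model, ll_null, cov, ok = model.fit()
    C = model.C
    i_int = C - 1 + 3  # interaction column
    coef = float(params[i_int])
    var = float(cov[i_int, i_int])
    flags = []
    if not ok:
        flags.append("non_convergence")
    if not np.isfinite(var) or var <= 0:
        flags.append("singular_hessian")
        se = float("nan")
    else:
        se = math.sqrt(var)
    p = float(2 * stats.norm.sf(abs(coef) / se)) if se and np.isfinite(se) else float("nan")
    ci = (coef - 1.959963984540054 * se, coef + 1.959963984540054 * se)
    return ModerationResult(
        moderator=name,
        coefficient=coef,
        ci_low=ci[0],
        ci_high=ci[1],
        wald_p=p,
        mcfadden_r2=mcfadden_r2(ll_model, ll_null),
        ll_model=ll_model,
        ll_null=ll_null,
        converged=ok and np.isfinite(se),
        n_obs=len(df),
        sigma=float(math.exp(params[-1])),
        flags=flags,
    )


def mcfadden_r2(ll_model: float, ll_null: float) -> float:
    """1 - ll_model / ll_null for a model nested above the null."""
    if ll_null == 0:
        raise ValueError("null log-likelihood of zero")
    return 1.0 - ll_model / ll_null


def consistency_screen(
    moderator: Mapping[str, float],
    clinical: Sequence[ClinicalRecord],
    outcome: Mapping[str, HcgGroup | int],
    min_n: int = 2,
) -> tuple[dict[str, float], bool | None, list[str]]:
    """Cohen's D of the moderator, within vaginally delivered infants,
    between AHCGT and each SHCGT severity; consistent iff all three share
    a sign.  Cells with < 2 patients are flagged and skipped.
    """
    mod = pd.Series(moderator)
    vag = [c.patient_id for c in clinical if c.delivery_mode == "vaginal" and c.patient_id in mod.index]
    by_level: dict[int, list[float]] = {}
    for p in vag:
        if p in outcome:
            by_level.setdefault(int(outcome[p]), []).append(float(mod[p]))
    ds: dict[str, float] = {}
    flags: list[str] = []
    ref = by_level.get(0, [])
    for level, label in ((1, "mild"), (2, "moderate"), (3, "severe")):
        grp = by_level.get(level, [])
        if len(ref) < min_n or len(grp) < min_n:
            flags.append(f"insufficient_n_{label}")
            continue
        ds[label] = cohen_d_welch(grp, ref)
    if len(ds) < 3:
        return ds, None, flags
    signs = {math.copysign(1, d) for d in ds.values()}
    small = [k for k, d in ds.items() if abs(d) < 0.1]
    if small:
        flags.append("small_effect:" + ",".join(small))
    return ds, len(signs) == 1, flags


def clinical_moderation_panel(
    clinical: Sequence[ClinicalRecord],
    samples: Sequence[SampleRecord],
    outcome: Mapping[str, HcgGroup | int],
    factors: Sequence[str] = CLMM_FACTORS,
    nodes: int = 9,
) -> list[ModerationResult]:
    """Run the ordinal moderation model for each clinical factor and attach
    per-delivery-mode Cohen's D (AHCGT vs any SHCGT)."""
    delivery = {c.patient_id: c.delivery_mode for c in clinical}
    results = []
    for factor in factors:
        vals = {}
        for c in clinical:
            if factor == "sex":
                vals[c.patient_id] = 1.0 if c.sex == "male" else 0.0
            elif factor == "n_morbidities":
                vals[c.patient_id] = float(c.n_morbidities)
            else:
                vals[c.patient_id] = float(getattr(c, factor))
        if len(set(vals.values())) <= 1:
            results.append(
                ModerationResult(
                    moderator=factor, coefficient=float("nan"), ci_low=float("nan"),
                    ci_high=float("nan"), wald_p=float("nan"), mcfadden_r2=float("nan"),
                    ll_model=float("nan"), ll_null=float("nan"), converged=False,
                    n_obs=0, sigma=float("nan"), flags=["constant_factor"],
                )
            )
            continue
        res = fit_ordinal_moderation(vals, samples, outcome, delivery, name=factor, nodes=nodes)
        for mode in ("vaginal", "cesarean"):
            ref, alt = [], []
            for c in clinical:
                if c.delivery_mode != mode or c.patient_id not in outcome:
                    continue
                (ref if int(outcome[c.patient_id]) == 0 else alt).append(vals[c.patient_id])
            if len(ref) >= 2 and len(alt) >= 2:
                try:
                    res.cohens_d[mode] = cohen_d_welch(alt, ref)
                except ValueError:
                    res.flags.append(f"zero_variance_{mode}")
        results.append(res)
    return results
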