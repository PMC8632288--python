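import math

import numpy as np
import pandas as pd
import pytest

from preemiegut.data_model import SampleRecord
from preemiegut.moderation import (
    CLMM_FACTORS,
    OrdinalMixedModel,
    clinical_moderation_panel,
    consistency_screen,
    fit_ordinal_moderation,
    mcfadden_r2,
)


def _ordinal_sample(rng, X, thresholds, beta, n):
    eta = X @ beta
    p_le = 1 / (1 + np.exp(-(thresholds[None, :] + eta[:, None])))
    return (rng.random(n)[:, None] > p_le).sum(axis=1)


class TestOrdinalMixedModel:
    def test_reduces_to_fixed_effect_proportional_odds(self):
        """With singleton clusters (sigma -> 0) the fit matches a plain
        proportional-odds model from statsmodels."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(3)
        n = 250
        X = np.column_stack(
            [rng.normal(size=n), np.where(rng.random(n) < 0.5, 0.5, -0.5)]
        )
        X = np.column_stack([X, X[:, 0] * X[:, 1]])
        y = _ordinal_sample(rng, X, np.array([-1.0, 0.3, 1.2]), np.array([0.8, -0.5, 0.6]), n)
        m = OrdinalMixedModel(y, X, np.arange(n), nodes=9)
        params, llm, lln, cov, ok = m.fit()
        oracle = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        # orientation: our betas point toward less-severe outcomes
        assert np.allclose(params[3:6], -oracle.params[:3], atol=1e-4)
        assert llm == pytest.approx(oracle.llf, abs=1e-4)

    def test_quadrature_node_doubling_stable(self):
        rng = np.random.default_rng(5)
        rows = []
        for p in range(40):
            b = rng.normal(0, 1.0)
            for _ in range(5):
                rows.append((p, rng.normal(), b))
        arr = np.array(rows)
        X = arr[:, 1:2]
        y = _ordinal_sample(
            rng, X, np.array([-1.0, 0.5, 1.5]), np.array([0.5]), len(arr)
        )
        # inject the cluster effect through the latent scale
        eta = X[:, 0] * 0.5 + arr[:, 2]
        p_le = 1 / (1 + np.exp(-(np.array([-1.0, 0.5, 1.5])[None, :] + eta[:, None])))
        y = (rng.random(len(arr))[:, None] > p_le).sum(axis=1)
        m9 = OrdinalMixedModel(y, X, arr[:, 0].astype(int), nodes=9)
        m18 = OrdinalMixedModel(y, X, arr[:, 0].astype(int), nodes=18)
        p9, *_ = m9.fit()
        p18, *_ = m18.fit()
        assert np.max(np.abs(p9[:4] - p18[:4])) < 1e-3

    def test_likelihood_nesting(self):
        rng = np.random.default_rng(7)
        n = 150
        X = rng.normal(size=(n, 2))
        y = _ordinal_sample(rng, X, np.array([-1.0, 1.0]), np.array([1.0, 0.0]), n)
        y[:3] = [0, 1, 2]  # ensure 3 levels
        m = OrdinalMixedModel(y, X, np.arange(n) % 30, nodes=9)
        _, llm, lln, _, _ = m.fit()
        assert llm >= lln - 1e-6

    def test_two_level_outcome_rejected(self):
        with pytest.raises(ValueError):
            OrdinalMixedModel(np.array([0, 1, 0, 1]), np.zeros((4, 1)), np.arange(4))


class TestMcFadden:
    def test_null_equals_model_gives_zero(self):
        assert mcfadden_r2(-100.0, -100.0) == 0.0

    def test_direct_formula(self):
        assert mcfadden_r2(-50.0, -100.0) == pytest.approx(0.5)

    def test_zero_null_rejected(self):
        with pytest.raises(ValueError):
            mcfadden_r2(-1.0, 0.0)


class TestModerationFit:
    def test_planted_interaction_sign(self, default_cohort):
        rng = np.random.default_rng(0)
        delivery = {r.patient_id: r.delivery_mode for r in default_cohort.clinical_records}
        outcome = {p: int(g) for p, g in default_cohort.groups.items()}
        mod = {}
        for p, g in outcome.items():
            if delivery[p] == "vaginal":
                mod[p] = -1.0 * g + rng.normal(0, 0.5)
            else:
                mod[p] = rng.normal(0, 1.5)
        res = fit_ordinal_moderation(
            mod, default_cohort.sample_records, outcome, delivery, name="planted"
        )
        assert res.coefficient > 0  # depletion with severity strengthens
        assert res.ci_low <= res.coefficient <= res.ci_high
        assert 0.0 <= res.mcfadden_r2 < 1.0

    def test_constant_moderator_rejected(self, default_cohort):
        delivery = {r.patient_id: r.delivery_mode for r in default_cohort.clinical_records}
        outcome = {p: int(g) for p, g in default_cohort.groups.items()}
        with pytest.raises(ValueError):
            fit_ordinal_moderation(
                {p: 1.0 for p in outcome},
                default_cohort.sample_records,
                outcome,
                delivery,
            )


class TestConsistencyScreen:
    def _clinical(self, default_cohort):
        return default_cohort.clinical_records

    def test_uniform_depletion_consistent(self, default_cohort):
        rng = np.random.default_rng(1)
        outcome = {p: int(g) for p, g in default_cohort.groups.items()}
        mod = {p: (2.0 if g == 0 else -2.0) + rng.normal(0, 0.2) for p, g in outcome.items()}
        ds, consistent, flags = consistency_screen(
            mod, self._clinical(default_cohort), outcome
        )
        if consistent is not None:
            assert consistent
            assert all(d < 0 for d in ds.values())

    def test_noise_consistency_rate_matches_orthant_probability(self):
        """Under a noise moderator the three effect sizes share the AHCGT
        reference mean, so their signs are equicorrelated (rho = 1/2 for
        equal group sizes) rather than independent: the chance all three
        agree is 2 x (1/8 + (3/4pi) arcsin 1/2) = 1/2, not 2/8."""
        from preemiegut.data_model import ClinicalRecord

        rng = np.random.default_rng(2)
        clin, outcome = [], {}
        for g in range(4):
            for i in range(8):
                pid = f"G{g}P{i}"
                outcome[pid] = g
                clin.append(
                    ClinicalRecord(
                        patient_id=pid, delivery_mode="vaginal",
                        gestational_age_weeks=28.0, sex="female",
                        birth_weight_kg=1.0, birth_hc_cm=25.0,
                        hc_z_birth=0.0, hc_z_36w=-0.6 * g,
                    )
                )
        verdicts = []
        for _ in range(300):
            mod = {p: rng.normal() for p in outcome}
            _, consistent, _ = consistency_screen(mod, clin, outcome)
            if consistent is not None:
                verdicts.append(consistent)
        frac = np.mean(verdicts)
        assert 0.40 <= frac <= 0.62  # 0.5 +/- binomial and small-n error

    def test_small_effects_flagged(self, default_cohort):
        outcome = {p: int(g) for p, g in default_cohort.groups.items()}
        rng = np.random.default_rng(3)
        mod = {p: rng.normal(0, 1e-3) for p in outcome}
        ds, consistent, flags = consistency_screen(
            mod, self._clinical(default_cohort), outcome
        )
        if ds and all(abs(d) < 0.1 for d in ds.values()):
            assert any(f.startswith("small_effect") for f in flags)


class TestClinicalPanel:
    def test_one_row_per_factor(self, default_cohort):
        outcome = {p: int(g) for p, g in default_cohort.groups.items()}
        factors = ("gestational_age_weeks", "sex", "n_morbidities")
        results = clinical_moderation_panel(
            default_cohort.clinical_records,
            default_cohort.sample_records,
            outcome,
            factors=factors,
        )
        assert [r.moderator for r in results] == list(factors)
        for r in results:
            if r.converged:
                assert np.isfinite(r.coefficient)
                assert "vaginal" in r.cohens_d or "cesarean" in r.cohens_d
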