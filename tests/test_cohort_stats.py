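import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from preemiegut.cohort_stats import (
    any_shcgt_indicator,
    bh_adjust,
    cohen_d_welch,
    fisher_exact,
    fit_abundance_lmm,
    games_howell,
    prevalence,
    rda_blocked,
    welch_anova,
)
from preemiegut.compositional import preprocess
from preemiegut.data_model import SampleRecord


# --------------------------------------------------------------------------
# independent Freeman-Halton oracle: exact rational arithmetic, stars-and-
# bars enumeration with post-hoc margin filtering (no shared code path)
# --------------------------------------------------------------------------


def _compositions(total, parts):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def exact_fisher_oracle(table):
    table = np.asarray(table)
    r, c = table.shape
    row_sums = table.sum(axis=1)
    col_sums = tuple(table.sum(axis=0))
    n = int(table.sum())

    def prob(t):
        num = Fraction(1)
        for rs in row_sums:
            num *= math.factorial(int(rs))
        for cs in col_sums:
            num *= math.factorial(int(cs))
        den = Fraction(math.factorial(n))
        for x in np.ravel(t):
            den *= math.factorial(int(x))
        return num / den

    p_obs = prob(table)
    total = Fraction(0)
    for rows in itertools.product(
        *[list(_compositions(int(rs), c)) for rs in row_sums]
    ):
        cand = np.array(rows)
        if tuple(cand.sum(axis=0)) != col_sums:
            continue
        p = prob(cand)
        if p <= p_obs:
            total += p
    return float(total)


class TestFisherExact:
    def test_2x2_matches_scipy(self):
        t = [[3, 9], [7, 2]]
        res = fisher_exact(np.array(t))
        _, p = stats.fisher_exact(t)
        assert res.p_value == pytest.approx(p)

    def test_identical_rows_give_p_one(self):
        res = fisher_exact(np.array([[4, 4, 4], [4, 4, 4]]))
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(np.array([[0, 0], [1, 2]]))

    def test_rxc_matches_rational_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            r, c = rng.choice([(2, 3), (2, 4), (3, 3)])
            while True:
                t = rng.integers(0, 4, size=(r, c))
                if t.sum() <= 15 and (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
                    break
            res = fisher_exact(t)
            assert res.p_value == pytest.approx(exact_fisher_oracle(t), abs=1e-10)

    def test_monte_carlo_agrees_with_exact(self):
        t = np.array([[0, 0, 0, 3], [28, 16, 8, 3]])
        exact = fisher_exact(t)
        mc = fisher_exact(t, max_exact_total=10, n_mc=40_000, seed=0)
        assert mc.method == "freeman_halton_mc"
        assert mc.p_value == pytest.approx(exact.p_value, abs=4 * (mc.mc_se or 1))


class TestWelch:
    def test_raw_equals_summary(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, s, n) for s, n in ((1, 8), (2, 12), (0.5, 6))]
        a = welch_anova(groups=groups)
        summary = [(len(g), float(np.mean(g)), float(np.std(g, ddof=1))) for g in groups]
        b = welch_anova(summary=summary)
        assert a.f_statistic == pytest.approx(b.f_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_equal_means_f_zero(self):
        res = welch_anova(summary=[(5, 1.0, 0.5), (7, 1.0, 1.5), (4, 1.0, 1.0)])
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equals_welch_t(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        res = welch_anova(groups=[x, y])
        t = stats.ttest_ind(x, y, equal_var=False)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-10)
        assert res.f_statistic == pytest.approx(t.statistic**2, abs=1e-10)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_anova(groups=[[1.0, 1.0], [2.0, 2.0]])


class TestGamesHowell:
    def test_identical_groups_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        out = games_howell([g, g, g])
        assert (out["p_value"] > 0.999).all()

    def test_k3_matches_hand_computation(self):
        groups = [[2.0, 3.0, 4.0, 5.0], [5.0, 6.0, 8.0, 9.0], [1.0, 2.0, 2.0, 3.0]]
        out = games_howell(groups)
        x, y = np.array(groups[0]), np.array(groups[1])
        se2 = x.var(ddof=1) / 4 + y.var(ddof=1) / 4
        df = se2**2 / (
            (x.var(ddof=1) / 4) ** 2 / 3 + (y.var(ddof=1) / 4) ** 2 / 3
        )
        q = abs(x.mean() - y.mean()) / math.sqrt(se2 / 2)
        expect = stats.studentized_range.sf(q, 3, df)
        row = out[(out.i == 0) & (out.j == 1)].iloc[0]
        assert row.p_value == pytest.approx(expect)

    def test_two_group_rejections_track_welch_t(self):
        rng = np.random.default_rng(3)
        agree = 0
        for _ in range(100):
            x = rng.normal(0, 1, 12)
            y = rng.normal(rng.choice([0.0, 1.5]), 2, 9)
            gh = games_howell([x, y])["p_value"].iloc[0]
            wt = stats.ttest_ind(x, y, equal_var=False).pvalue
            agree += (gh < 0.05) == (wt < 0.05)
        assert agree >= 90


class TestCohenD:
    def test_identical_samples_zero(self):
        assert cohen_d_welch([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_difference_unit_variance(self):
        y = [-1.0, 0.0, 1.0]  # sample variance exactly 1
        x = [0.0, 1.0, 2.0]  # mean 1, variance 1
        assert cohen_d_welch(x, y) == pytest.approx(1.0)

    def test_hand_formula(self):
        x, y = [1.0, 4.0, 4.0], [0.0, 1.0, 2.0]
        expect = (np.mean(x) - np.mean(y)) / math.sqrt(
            (np.var(x, ddof=1) + np.var(y, ddof=1)) / 2
        )
        assert cohen_d_welch(x, y) == pytest.approx(expect)


class TestBhAdjust:
    def test_single_small_p_flagged(self):
        out = bh_adjust([0.001], fdr=0.01)
        assert out.flags.tolist() == [True]

    def test_step_up_hand_case(self):
        # classic step-up: all four pass at fdr 0.05 because p4 = 0.04 < 0.05
        out = bh_adjust([0.01, 0.02, 0.03, 0.04], fdr=0.05)
        assert out.flags.all()

    def test_q_at_least_p_and_flags_monotone_in_fdr(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        out_strict = bh_adjust(p, fdr=0.01)
        out_loose = bh_adjust(p, fdr=0.10)
        assert (out_strict.q_values >= out_strict.p_values - 1e-15).all()
        assert not (out_strict.flags & ~out_loose.flags).any()


class TestPrevalence:
    def test_single_positive_sample_counts_as_present(self, tiny_matrix):
        samples = [
            SampleRecord("s1", "P1", 30),
            SampleRecord("s2", "P2", 28),
        ]
        groups = {"P1": 0, "P2": 1}
        out = prevalence(tiny_matrix, samples, groups, "early")
        f3 = out[(out.taxon == "f3") & (out.group == 1)].iloc[0]
        assert f3.n_present == 1 and f3.n_patients == 1
        # f3 zero in s1 -> absent for P1
        f3a = out[(out.taxon == "f3") & (out.group == 0)].iloc[0]
        assert f3a.n_present == 0

    def test_matches_hand_count(self, default_cohort):
        cm = default_cohort.count_matrix
        groups = {p: int(g) for p, g in default_cohort.ground_truth["group"].items()}
        out = prevalence(cm, default_cohort.sample_records, groups, "late")
        taxon = cm.features[0]
        frame = cm.to_frame()
        by_pat = {}
        for s in default_cohort.sample_records:
            if 31 <= s.pma_week <= 36:
                by_pat.setdefault(s.patient_id, []).append(s.sample_id)
        for g in range(4):
            hand = sum(
                1
                for p, sids in by_pat.items()
                if groups[p] == g and (frame.loc[taxon, sids] > 0).any()
            )
            row = out[(out.taxon == taxon) & (out.group == g)].iloc[0]
            assert row.n_present == hand


class TestAbundanceLmm:
    def test_reduces_to_ols_with_one_sample_per_patient(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        samples, vals, ind = [], {}, {}
        for i in range(30):
            pid = f"P{i}"
            sid = f"{pid}_w30"
            samples.append(SampleRecord(sid, pid, 30))
            ind[pid] = float(i < 15)
            vals[sid] = ind[pid] * 0.8 + rng.normal()
        res = fit_abundance_lmm(pd.Series(vals), samples, ind, window="overall", include_pma=False)
        X = np.column_stack([np.ones(30), [ind[f"P{i}"] for i in range(30)]])
        ols = sm.OLS([vals[f"P{i}_w30"] for i in range(30)], X).fit()
        assert res.ls_mean_diff == pytest.approx(ols.params[1], abs=1e-6)

    def test_planted_shift_estimated_in_late_window(self, default_cohort):
        _, _, clr = preprocess(default_cohort.count_matrix, "genus")
        ind = any_shcgt_indicator(default_cohort.groups)
        res = fit_abundance_lmm(
            clr.values.loc["Bacteroides"],
            default_cohort.sample_records,
            ind,
            window="late",
            taxon="Bacteroides",
        )
        assert res.ls_mean_diff < -0.5  # depletion has the planted sign
        assert res.ci_low < res.ls_mean_diff < res.ci_high
        assert 0.0 <= res.marginal_r2 <= 1.0


class TestRdaBlocked:
    def _design(self, n_pat=12, per=4, seed=0):
        rng = np.random.default_rng(seed)
        sids, blocks, pma = [], {}, []
        for p in range(n_pat):
            for w in range(per):
                sid = f"P{p}_w{w}"
                sids.append(sid)
                blocks[sid] = f"P{p}"
                pma.append(w)
        terms = pd.DataFrame({"pma": np.asarray(pma, dtype=float)}, index=sids)
        terms["pma"] = (terms["pma"] - terms["pma"].mean()) / terms["pma"].std()
        return sids, blocks, terms, rng

    def test_exact_linear_response_min_p(self):
        sids, blocks, terms, rng = self._design()
        Y = pd.DataFrame(
            np.outer(np.ones(5), terms["pma"].to_numpy()),
            index=[f"t{i}" for i in range(5)],
            columns=sids,
        )
        Y += rng.normal(0, 1e-6, Y.shape)
        res = rda_blocked(Y, terms, pd.Series(blocks), n_perm=99, seed=1)
        assert res.term_stats["p"].iloc[0] == pytest.approx(1 / 100)

    def test_variance_explained_bounded(self):
        sids, blocks, terms, rng = self._design(seed=2)
        Y = pd.DataFrame(
            rng.normal(size=(6, len(sids))),
            index=[f"t{i}" for i in range(6)],
            columns=sids,
        )
        res = rda_blocked(Y, terms, pd.Series(blocks), n_perm=49, seed=0)
        assert 0.0 <= res.term_stats["marginal_r2"].iloc[0] <= 1.0

    def test_null_p_not_degenerate(self):
        hits = 0
        for seed in range(20):
            sids, blocks, terms, rng = self._design(seed=100 + seed)
            Y = pd.DataFrame(
                rng.normal(size=(4, len(sids))),
                index=[f"t{i}" for i in range(4)],
                columns=sids,
            )
            res = rda_blocked(Y, terms, pd.Series(blocks), n_perm=49, seed=seed)
            hits += res.term_stats["p"].iloc[0] <= 0.1
        assert hits <= 8  # roughly uniform: expect ~2 of 20

    def test_collinear_terms_named(self):
        sids, blocks, terms, rng = self._design(seed=3)
        terms["dup"] = terms["pma"]
        Y = pd.DataFrame(
            rng.normal(size=(3, len(sids))),
            index=[f"t{i}" for i in range(3)],
            columns=sids,
        )
        with pytest.raises(ValueError, match="dup"):
            rda_blocked(Y, terms, pd.Series(blocks), n_perm=9)
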