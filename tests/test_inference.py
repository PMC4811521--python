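"""Kaplan-Meier/logrank, classifier HRRs, permutation counting, deviance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cartsurv._cox import cox_fit, two_group_hrr_brentq
from cartsurv.inference import (
    classifier_hrr,
    compare_models,
    kaplan_meier,
    permutation_corrected_p,
    subgroup_analysis,
)
from cartsurv.screening import StepwiseSpec
from cartsurv.synthetic import fig1_profile, generate_cohort
from cartsurv.tree import assign_classes, class_hrrs, group_classes, reference_tree
from cartsurv.cohort import CLINICAL_FLAGS
from conftest import tree_inputs


def _clinical_frame(n, times, events, seed=0, membership=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"os_months": times, "event": events})
    for f in CLINICAL_FLAGS:
        df[f] = rng.integers(0, 2, n).astype(float)
    return df


class TestKaplanMeier:
    def test_curves_start_at_one_and_decrease(self, exp_cohort_factory):
        t, e = exp_cohort_factory(200, censor=0.01, seed=1)
        res = kaplan_meier(t, e, np.repeat(["g1", "g2"], 100))
        for _, (tt, ss) in res.curves.items():
            assert ss[0] == 1.0
            assert (np.diff(ss) <= 1e-12).all()

    def test_single_group_no_test(self, exp_cohort_factory):
        t, e = exp_cohort_factory(50, seed=2)
        res = kaplan_meier(t, e, ["only"] * 50)
        assert res.p is None and len(res.curves) == 1

    def test_uncensored_km_equals_empirical_survival(self,
                                                     exp_cohort_factory):
        t, e = exp_cohort_factory(150, censor=0.0, seed=3)
        res = kaplan_meier(t, e, ["g"] * 150)
        tt, ss = res.curves["g"]
        for q in (20.0, 50.0, 90.0):
            emp = float((t > q).mean())
            km = float(ss[np.searchsorted(tt, q, side="right") - 1])
            assert km == pytest.approx(emp, abs=1e-12)

    def test_null_logrank_p_uniform(self, exp_cohort_factory):
        ps = []
        for s in range(500):
            t, e = exp_cohort_factory(200, censor=0.01, seed=1000 + s)
            g = np.repeat(["a", "b"], 100)
            ps.append(kaplan_meier(t, e, g).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClassifierHRR:
    def _membership(self, n, hr, seed):
        rng = np.random.default_rng(seed)
        mem = pd.Series(np.where(rng.random(n) < 0.5, "II", "I"))
        rate = 0.02 * np.where(mem == "II", hr, 1.0)
        t = rng.exponential(1 / rate)
        e = np.ones(n)
        return mem, t, e

    def test_null_groups_near_one(self):
        mem, t, e = self._membership(2000, 1.0, seed=4)
        df = _clinical_frame(2000, t, e)
        assert 0.85 < classifier_hrr(mem, df).hrr < 1.18

    def test_unadjusted_equals_direct_two_group_fit(self):
        """classifier_hrr(adjust=False) equals the scalar-root oracle of the
        two-group partial likelihood to 1e-8."""
        mem, t, e = self._membership(800, 2.0, seed=5)
        df = _clinical_frame(800, t, e)
        est = classifier_hrr(mem, df, adjust=False)
        oracle = two_group_hrr_brentq(t, e, (mem == "II").to_numpy(float))
        assert abs(est.hrr - oracle) < 1e-8

    def test_fig1_profile_recovers_published_magnitude(self, fig1_cohort,
                                                       default_cutoffs):
        surv, feats, times, events, labels = tree_inputs(fig1_cohort,
                                                         default_cutoffs)
        classes = assign_classes(reference_tree(), feats)
        grouping = group_classes(class_hrrs(classes, times, events))
        est = classifier_hrr(grouping.membership(classes), surv.df,
                             adjust=False)
        assert 2.3 < est.hrr < 3.4

    def test_adjust_retains_forced_class_term(self):
        mem, t, e = self._membership(1500, 2.0, seed=6)
        df = _clinical_frame(1500, t, e, seed=6)
        est = classifier_hrr(mem, df, adjust=True)
        assert "class_II" in est.retained_terms
        assert 1.6 < est.hrr < 2.5

    def test_empty_group_rejected(self):
        mem = pd.Series(["I"] * 10)
        df = _clinical_frame(10, np.arange(1.0, 11.0), np.ones(10))
        with pytest.raises(ValueError, match="non-empty"):
            classifier_hrr(mem, df)


class TestPermutationCounting:
    """Definitional arithmetic of the corrected p-value."""

    def _run(self, perm_p, original):
        from cartsurv.inference import PermutationRun

        count = int((np.asarray(perm_p) < original).sum())
        n = len(perm_p)
        return PermutationRun(n, original, np.asarray(perm_p), count / n,
                              (count + 1) / (n + 1), 0)

    def test_forty_of_ten_thousand(self):
        perm = np.r_[np.full(40, 1e-6), np.random.default_rng(0).uniform(
            0.5, 1.0, 9960)]
        run = self._run(perm, 0.01)
        assert run.corrected_p == 0.004

    def test_original_smaller_than_all(self):
        run = self._run(np.linspace(0.1, 1.0, 500), 1e-9)
        assert run.corrected_p == 0.0
        assert run.summary() == "< 0.002"

    def test_add_one_variant(self):
        run = self._run([0.1, 0.2, 0.3, 0.4], 0.25)
        assert run.corrected_p == 0.5
        assert run.corrected_p_add_one == 3 / 5

    def test_small_n_perm_warns(self, fig1_cohort, default_cutoffs):
        surv, feats, times, events, _ = tree_inputs(fig1_cohort,
                                                    default_cutoffs)
        with pytest.warns(UserWarning, match="resolution"):
            permutation_corrected_p(feats.iloc[:120], times[:120],
                                    events[:120], n_perm=20, seed=0)

    def test_signal_cohort_gets_small_corrected_p(self, fig1_cohort,
                                                  default_cutoffs):
        surv, feats, times, events, _ = tree_inputs(fig1_cohort,
                                                    default_cutoffs)
        run = permutation_corrected_p(feats, times, events, n_perm=200,
                                      seed=11)
        assert run.corrected_p <= 0.01
        assert run.original_p < 1e-6

    def test_strict_mode_reoptimizes_cutoffs(self, fig1_cohort,
                                             default_cutoffs):
        """Strict mode re-derives the cutoffs per permuted dataset; on a
        signal cohort it still finds the construction significant."""
        from cartsurv.cohort import score_column

        surv, feats, times, events, _ = tree_inputs(fig1_cohort,
                                                    default_cutoffs)
        scores = surv.df[[score_column(m) for m in default_cutoffs]].iloc[:300]
        scores.columns = list(default_cutoffs)
        run = permutation_corrected_p(
            feats.iloc[:300], times[:300], events[:300], n_perm=100,
            seed=3, strict_scores=scores)
        assert run.original_p < 1e-4
        assert run.corrected_p <= 0.05

    def test_reproducible_given_seed(self, fig1_cohort, default_cutoffs):
        surv, feats, times, events, _ = tree_inputs(fig1_cohort,
                                                    default_cutoffs)
        a = permutation_corrected_p(feats.iloc[:150], times[:150],
                                    events[:150], n_perm=120, seed=5)
        b = permutation_corrected_p(feats.iloc[:150], times[:150],
                                    events[:150], n_perm=120, seed=5)
        np.testing.assert_array_equal(a.perm_p, b.perm_p)


class TestCompareModels:
    def test_null_classifier_chi2_is_chi2_one(self):
        """With a zero-effect classifier the deviance difference follows a
        one-degree chi-square (Wilks) over repeated simulation."""
        chis = []
        for s in range(200):
            rng = np.random.default_rng(3000 + s)
            n = 400
            mem = pd.Series(np.where(rng.random(n) < 0.5, "II", "I"))
            t = rng.exponential(50.0, n)
            df = _clinical_frame(n, t, np.ones(n), seed=s)
            chis.append(compare_models(df, mem).chi2)
        assert stats.kstest(chis, "chi2", args=(1,)).pvalue > 0.005

    def test_duplicated_column_collapses_df(self):
        rng = np.random.default_rng(1)
        n = 300
        df = pd.DataFrame({"os_months": rng.exponential(50, n),
                           "event": np.ones(n)})
        flag = rng.integers(0, 2, n).astype(float)
        for f in CLINICAL_FLAGS:
            df[f] = flag  # all clinical columns identical to each other
        mem = pd.Series(np.where(flag == 1, "II", "I"))  # and to the class
        res = compare_models(df, mem)
        assert res.degenerate and res.chi2 == 0.0 and res.df == 0

    def test_strong_effect_is_detected(self):
        detected = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            n = 1000
            mem = pd.Series(np.where(rng.random(n) < 0.5, "II", "I"))
            rate = 0.02 * np.where(mem == "II", 3.0, 1.0)
            t = rng.exponential(1 / rate)
            df = _clinical_frame(n, t, np.ones(n), seed=s)
            detected += compare_models(df, mem).p < 0.05
        assert detected >= 19


class TestSubgroups:
    def _cohort(self, n=1200, colon_hr=5.0, rectum_hr=1.0, seed=0):
        rng = np.random.default_rng(seed)
        mem = pd.Series(np.where(rng.random(n) < 0.5, "II", "I"))
        site = np.where(rng.random(n) < 0.6, "colon", "rectum")
        hr = np.where(site == "colon", colon_hr, rectum_hr)
        rate = 0.02 * np.where(mem == "II", hr, 1.0)
        t = rng.exponential(1 / rate)
        df = _clinical_frame(n, t, np.ones(n), seed=seed)
        df["primary_site"] = site
        df["systemic_therapy"] = rng.integers(0, 2, n).astype(float)
        return mem, df

    def test_site_specific_effect_ordering(self):
        wins = 0
        for s in range(10):
            mem, df = self._cohort(seed=s)
            res = subgroup_analysis(df, mem, "primary_site")
            wins += res["colon"].hrr > res["rectum"].hrr
        assert wins >= 9

    def test_homogeneous_strata_recover_full_cohort_hrr(self):
        mem, df = self._cohort(colon_hr=2.0, rectum_hr=2.0, seed=3)
        res = subgroup_analysis(df, mem, "systemic_therapy")
        full = classifier_hrr(mem, df).hrr
        for r in res.values():
            assert r.estimable
            assert r.hrr == pytest.approx(full, rel=0.25)

    def test_empty_stratum_non_estimable(self):
        mem, df = self._cohort(seed=4)
        df["primary_site"] = "colon"
        res = subgroup_analysis(df, mem, "primary_site")
        assert set(res) == {"colon"}

    def test_unknown_stratifier_rejected(self):
        mem, df = self._cohort(seed=5)
        with pytest.raises(ValueError):
            subgroup_analysis(df, mem, "hospital")
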