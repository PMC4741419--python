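import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dgmpv.stats import (ComparisonConfig, RankDeficientDesignError,
                         correct_multiplicity, global_mean_test,
                         manova_group_test, permutation_component_test,
                         permutation_family_test, render_report,
                         run_comparison)

from .oracles import exhaustive_permutation_pvalue


def _two_groups(rng, n1=19, n2=43, shift=0.0, p=1):
    y = np.vstack([rng.normal(0, 1, (n1, p)),
                   rng.normal(shift, 1, (n2, p))])
    g = np.array(["HC"] * n1 + ["PATIENT"] * n2)
    return y, g


class TestManova:
    def test_single_feature_reduces_to_pooled_t_test(self, rng):
        for _ in range(10):
            y, g = _two_groups(rng, shift=0.4)
            res = manova_group_test(y, g)
            t_p = sps.ttest_ind(y[:19, 0], y[19:, 0], equal_var=True).pvalue
            assert res.p_raw == pytest.approx(t_p, abs=1e-12)

    def test_identical_groups_give_null_statistic(self, rng):
        y1 = rng.normal(size=(10, 3))
        y = np.vstack([y1, y1])        # group 2 copies group 1 row-for-row
        g = np.array(["HC"] * 10 + ["PATIENT"] * 10)
        res = manova_group_test(y, g)
        assert res.pillai == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0, abs=1e-12)

    def test_large_separation_is_overwhelming(self, rng):
        y, g = _two_groups(rng, n1=20, n2=20, p=3)
        y[20:, 0] += 5.0               # 5 pooled SDs on one feature
        res = manova_group_test(y, g)
        assert res.p_raw < 1e-6

    def test_matches_statsmodels_with_covariates(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        y, g = _two_groups(rng, p=3)
        age = rng.normal(34, 9, len(g))
        sex = rng.integers(0, 2, len(g)).astype(float)
        res = manova_group_test(y, g, np.column_stack([age, sex]))
        df = pd.DataFrame(y, columns=["f1", "f2", "f3"])
        df["group"] = g
        df["age"] = age
        df["sex"] = sex
        tab = MANOVA.from_formula("f1 + f2 + f3 ~ group + age + sex",
                                  data=df).mv_test().results["group"]["stat"]
        assert res.pillai == pytest.approx(
            float(tab.loc["Pillai's trace", "Value"]), abs=1e-10)
        assert res.p_raw == pytest.approx(
            float(tab.loc["Pillai's trace", "Pr > F"]), abs=1e-10)

    def test_too_few_subjects(self, rng):
        y, g = _two_groups(rng, n1=2, n2=10)
        with pytest.raises(ValueError):
            manova_group_test(y, g)

    def test_missing_values_rejected(self, rng):
        y, g = _two_groups(rng, p=3)
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            manova_group_test(y, g)


class TestPermutationTest:
    def test_constant_feature_gives_p_one(self, rng):
        y = np.full(20, 3.0)
        g = np.array(["HC"] * 10 + ["PATIENT"] * 10)
        res = permutation_component_test(y, g, n_perm=99, rng=rng)
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_p_value_floor(self, rng):
        y = np.r_[np.zeros(15), np.ones(15) * 10]
        g = np.array(["HC"] * 15 + ["PATIENT"] * 15)
        res = permutation_component_test(y, g, n_perm=999, rng=rng,
                                         exhaustive_limit=1)
        assert res.p_raw >= 1.0 / 1000.0

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        y = rng.normal(size=6)
        g = np.array(["HC"] * 3 + ["PATIENT"] * 3)
        res = permutation_component_test(y, g)
        assert res.exhaustive and res.n_perm == 20
        assert res.p_raw == pytest.approx(
            exhaustive_permutation_pvalue(y, 3), abs=1e-12)

    def test_relabeling_invariance(self, rng):
        y = rng.normal(size=30)
        y[15:] += 0.8
        g = np.array(["HC"] * 15 + ["PATIENT"] * 15)
        g_flip = np.where(g == "HC", "PATIENT", "HC")
        p1 = permutation_component_test(y, g, n_perm=500, rng=1).p_raw
        p2 = permutation_component_test(y, g_flip, n_perm=500, rng=1).p_raw
        assert p1 == p2

    def test_seed_determinism(self, rng):
        y = rng.normal(size=40)
        g = np.array(["HC"] * 18 + ["PATIENT"] * 22)
        p1 = permutation_component_test(y, g, n_perm=200, rng=7).p_raw
        p2 = permutation_component_test(y, g, n_perm=200, rng=7).p_raw
        assert p1 == p2

    def test_covariate_effect_is_removed(self, rng):
        # a feature driven purely by age must not look like a group effect
        g = np.array(["HC"] * 19 + ["PATIENT"] * 43)
        age = np.r_[rng.normal(30, 5, 19), rng.normal(45, 5, 43)]
        y = 2.0 * age + rng.normal(0, 1, 62)
        res_adj = permutation_component_test(y, g, covariates=age[:, None],
                                             n_perm=999, rng=3)
        res_raw = permutation_component_test(y, g, n_perm=999, rng=3)
        assert res_raw.p_raw < 0.01       # confounded without adjustment
        assert res_adj.p_raw > 0.05

    def test_family_fwe_not_below_raw(self, rng):
        y, g = _two_groups(rng, p=3)
        y[19:, 1] += 0.7
        fam = permutation_family_test(y, g, n_perm=500, rng=11)
        for res in fam:
            assert res.p_fwe >= res.p_raw

    def test_max_stat_no_worse_than_bonferroni_on_correlated_features(self, rng):
        # strongly correlated null features: single-step max-stat FWE should
        # be clearly less conservative than Bonferroni on average
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            base = r.normal(size=40)
            y = np.column_stack([base + 0.2 * r.normal(size=40)
                                 for _ in range(3)])
            g = np.array(["HC"] * 20 + ["PATIENT"] * 20)
            fam = permutation_family_test(y, g, n_perm=300, rng=seed)
            bonf = correct_multiplicity([t.p_raw for t in fam], family_size=3)
            diffs.append(np.mean([t.p_fwe for t in fam]) - np.mean(bonf))
        assert np.mean(diffs) < 0.0


class TestGlobalMeanTest:
    def test_identical_samples(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["HC"] * 3 + ["PATIENT"] * 3)
        res = global_mean_test(y, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_pooled_t_test(self, rng):
        y = rng.normal(size=30)
        y[12:] += 0.5
        g = np.array(["HC"] * 12 + ["PATIENT"] * 18)
        res = global_mean_test(y, g)
        t_ref = sps.ttest_ind(y[12:], y[:12], equal_var=True)
        assert res.statistic == pytest.approx(t_ref.statistic, abs=1e-10)
        assert res.p_raw == pytest.approx(t_ref.pvalue, abs=1e-12)

    def test_collinear_covariate_raises(self, rng):
        y = rng.normal(size=12)
        g = np.array(["HC"] * 6 + ["PATIENT"] * 6)
        cov = (g == "PATIENT").astype(float)[:, None]
        with pytest.raises(RankDeficientDesignError):
            global_mean_test(y, g, cov)


class TestCorrectMultiplicity:
    def test_bonferroni_arithmetic(self):
        assert correct_multiplicity([0.0004], family_size=4)[0] == \
            pytest.approx(0.0016)

    def test_capped_at_one(self):
        assert correct_multiplicity([0.5], family_size=4)[0] == 1.0

    def test_family_of_one_is_identity(self):
        assert correct_multiplicity([0.31], family_size=1)[0] == \
            pytest.approx(0.31)

    def test_never_decreases(self, rng):
        p = rng.uniform(size=20)
        assert (correct_multiplicity(p) >= p).all()

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            correct_multiplicity([0.1], method="fdr")


class TestRunComparison:
    def _tables(self, rng, regions=("thalamus", "caudate"), effect=0.0,
                n1=10, n2=12):
        n = n1 + n2
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["HC"] * n1 + ["PATIENT"] * n2,
            "age": rng.normal(35, 8, n),
            "sex": rng.choice(["F", "M"], n),
        })
        feats = {"subject_id": cohort["subject_id"]}
        for region in regions:
            for name in ("mu_gm", "mu_wm", "ratio", "mean_t1"):
                base = rng.normal(0, 1, n)
                if region == "thalamus" and name == "mu_gm":
                    base[n1:] += effect
                feats[f"{region}_{name}"] = base
        return pd.DataFrame(feats), cohort

    def test_row_layout(self, rng):
        features, cohort = self._tables(rng)
        cfg = ComparisonConfig(regions=("thalamus", "caudate"), n_perm=99)
        out = run_comparison(features, cohort, cfg)
        assert len(out) == 2 * 5
        per_region = out.groupby("region")["arm"].value_counts()
        assert per_region["thalamus", "pv_component"] == 3
        assert ((out.p_corrected >= out.p_raw) | np.isclose(
            out.p_corrected, out.p_raw)).all()
        report = render_report(out)
        assert "thalamus" in report

    def test_deterministic_given_seed(self, rng):
        features, cohort = self._tables(rng)
        cfg = ComparisonConfig(regions=("thalamus", "caudate"), n_perm=199,
                               seed=5)
        out1 = run_comparison(features, cohort, cfg)
        out2 = run_comparison(features, cohort, cfg)
        pd.testing.assert_frame_equal(out1, out2)

    def test_mismatched_subjects_error_names_them(self, rng):
        features, cohort = self._tables(rng)
        with pytest.raises(ValueError, match="s0"):
            run_comparison(features, cohort[cohort.subject_id != "s0"])

    def test_single_subject_group_fails(self, rng):
        features, cohort = self._tables(rng, n1=1, n2=8)
        cfg = ComparisonConfig(regions=("thalamus", "caudate"), n_perm=49)
        with pytest.raises(ValueError):
            run_comparison(features, cohort, cfg)

    def test_max_stat_correction_selected(self, rng):
        features, cohort = self._tables(rng)
        cfg = ComparisonConfig(regions=("thalamus",), n_perm=99,
                               correction="max_stat_fwe")
        out = run_comparison(features, cohort, cfg)
        comp = out[out.arm == "pv_component"]
        assert (comp.correction_method == "max_stat_fwe").all()
        assert (comp.p_corrected >= comp.p_raw).all()
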