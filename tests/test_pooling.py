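"""Heterogeneity, fixed/random pooling, model selection, strata, sensitivity."""

import math

import numpy as np
import pytest

from snpmeta import (
    EffectEstimate,
    GeneticModel,
    StratificationPlan,
    StudySet,
    TwoByTwo,
    cochran_q,
    leave_one_out,
    pool_auto,
    pool_fixed_iv,
    pool_fixed_mh,
    pool_random_dl,
    stratify,
    study_effects,
)

GM = GeneticModel


def effect(log_or, se, sid=""):
    return EffectEstimate(log_or=log_or, se=se, study_id=sid)


class TestCochranQ:
    def test_identical_effects_no_dispersion(self):
        het = cochran_q([effect(0.3, 0.1), effect(0.3, 0.1)])
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.tau2 == 0.0 and het.i2 == 0.0 and het.p_q == pytest.approx(1.0)

    def test_two_study_closed_form(self):
        # equal weights w: Q = w/2 * (theta1-theta2)^2 = (ln2)^2 / (2*0.01)
        het = cochran_q([effect(0.0, 0.1), effect(math.log(2), 0.1)])
        assert het.q == pytest.approx(math.log(2) ** 2 / 0.02, rel=1e-12)
        assert het.df == 1

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            cochran_q([effect(0.1, 0.2)])

    def test_tau2_matches_statsmodels(self):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        theta = [0.05, 0.4, -0.1, 0.3, 0.22]
        se = [0.1, 0.15, 0.2, 0.12, 0.3]
        het = cochran_q([effect(t, s) for t, s in zip(theta, se)])
        res = sm_meta.combine_effects(np.array(theta), np.array(se) ** 2,
                                      method_re="dl")
        assert het.tau2 == pytest.approx(max(0.0, res.tau2), rel=1e-9)
        assert het.q == pytest.approx(res.q, rel=1e-9)


class TestFixedPools:
    def test_single_study_identity(self):
        t = TwoByTwo(12, 8, 7, 13)
        pooled = pool_fixed_mh([t])
        from snpmeta import odds_ratio
        single = odds_ratio(t)
        assert pooled.or_ == pytest.approx(single.or_, rel=1e-12)
        assert pooled.se == pytest.approx(single.se, rel=1e-12)  # RBG == Woolf at k=1

    def test_copies_of_balanced_table_stay_null(self):
        tables = [TwoByTwo(10, 10, 10, 10)] * 5
        assert pool_fixed_mh(tables).or_ == pytest.approx(1.0)

    def test_two_table_hand_arithmetic(self):
        # R = 3*5/20 + 6*6/20 = 2.55 ; S = 7*5/20 + 4*4/20 = 2.55
        pooled = pool_fixed_mh([TwoByTwo(3, 7, 5, 5), TwoByTwo(6, 4, 4, 6)])
        assert pooled.or_ == pytest.approx(1.0, rel=1e-12)

    def test_mh_matches_statsmodels_stratified_table(self, rs1333049):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        _, tables = study_effects(rs1333049, GM.DOMINANT)
        strat = sm_ct.StratifiedTable(
            [np.array([[t.a, t.b], [t.c, t.d]]) for t in tables])
        pooled = pool_fixed_mh(tables)
        assert pooled.or_ == pytest.approx(strat.oddsratio_pooled, rel=1e-10)
        assert pooled.se == pytest.approx(strat.logodds_pooled_se, rel=1e-10)

    def test_mh_and_iv_agree_on_dense_fixture_tables(self, table1_all):
        for variant in ("rs1333049", "rs4977574"):
            subset = table1_all.filter(variant=variant)
            for model in GM:
                effects, tables = study_effects(subset, model)
                mh = pool_fixed_mh(tables)
                iv = pool_fixed_iv(effects)
                assert mh.or_ == pytest.approx(iv.or_, rel=0.02)


class TestRandomPool:
    def test_dl_equals_iv_when_tau2_zero(self):
        effects = [effect(0.2, 0.1), effect(0.21, 0.12), effect(0.19, 0.11)]
        het = cochran_q(effects)
        assert het.tau2 == 0.0
        dl = pool_random_dl(effects, het=het)
        iv = pool_fixed_iv(effects)
        assert dl.log_or == pytest.approx(iv.log_or, rel=1e-12)
        assert dl.se == pytest.approx(iv.se, rel=1e-12)

    def test_dl_matches_statsmodels(self, rs1333049):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        effects, _ = study_effects(rs1333049, GM.ALLELE)
        theta = np.array([e.log_or for e in effects])
        var = np.array([e.se**2 for e in effects])
        res = sm_meta.combine_effects(theta, var, method_re="dl")
        ours = pool_random_dl(effects)
        frame = res.summary_frame()
        assert ours.log_or == pytest.approx(frame.loc["random effect", "eff"], rel=1e-9)
        assert ours.se == pytest.approx(frame.loc["random effect", "sd_eff"], rel=1e-9)

    def test_pooled_log_or_within_effect_range(self, table1_all):
        for variant in ("rs1333049", "rs4977574"):
            for model in GM:
                effects, _ = study_effects(table1_all.filter(variant=variant), model)
                pooled = pool_random_dl(effects)
                thetas = [e.log_or for e in effects]
                assert min(thetas) <= pooled.log_or <= max(thetas)


class TestPoolAuto:
    def test_homogeneous_studies_select_fixed(self, suleiman):
        from dataclasses import replace
        twin = replace(suleiman, study_id="twin")
        r = pool_auto(StudySet((suleiman, twin)), GM.ALLELE)
        assert r.model_used == "fixed_mh"
        assert r.het.p_q == pytest.approx(1.0)

    def test_heterogeneous_fixture_selects_random(self, rs1333049):
        r = pool_auto(rs1333049, GM.ALLELE)
        assert r.model_used == "random_dl" and r.het.p_q < 0.001

    def test_order_invariance(self, rs4977574):
        fwd = pool_auto(rs4977574, GM.HOMOZYGOUS)
        rev = pool_auto(StudySet(tuple(reversed(rs4977574.records)),
                                 variant="rs4977574"), GM.HOMOZYGOUS)
        assert fwd.log_or == pytest.approx(rev.log_or, rel=1e-12)

    def test_alpha_het_threshold_controls_choice(self, rs4977574):
        west = rs4977574.filter(ethnicity="West Asian")   # p_heter ~ 0.657
        assert pool_auto(west, GM.HOMOZYGOUS).model_used == "fixed_mh"
        assert pool_auto(west, GM.HOMOZYGOUS, alpha_het=0.70).model_used == "random_dl"

    def test_hwe_exclusion_flag_drops_violating_studies(self, rs1333049):
        kept = pool_auto(rs1333049, GM.ALLELE, exclude_hwe_violations=True)
        assert kept.k == 30   # exactly three control arms fail HWE at 0.05
        full = pool_auto(rs1333049, GM.ALLELE)
        assert full.k == 33

    def test_iv_fixed_selectable(self, rs4977574):
        west = rs4977574.filter(ethnicity="West Asian")
        r = pool_auto(west, GM.HOMOZYGOUS, fixed="iv")
        assert r.model_used == "fixed_iv"


class TestStratify:
    def test_ethnicity_strata_cardinalities(self, rs1333049):
        out = stratify(rs1333049, StratificationPlan(by="ethnicity"), GM.HOMOZYGOUS)
        ks = {s: r.k for s, r in out.items()}
        assert ks == {"West Asian": 8, "East Asian": 14, "Caucasian": 10, "African": 1}

    def test_single_study_stratum_uses_own_estimate(self, rs1333049):
        out = stratify(rs1333049, StratificationPlan(by="ethnicity"), GM.ALLELE)
        african = out["African"]
        assert african.model_used == "single" and african.k == 1
        assert african.or_ == pytest.approx(0.90, abs=0.02)

    def test_na_source_stratum_present(self, rs1333049):
        out = stratify(rs1333049, StratificationPlan(by="control_source"), GM.ALLELE)
        assert out["NA"].k == 2
        assert (out["NA"].n_cases, out["NA"].n_controls) == (1266, 1235)

    def test_empty_set_gives_empty_map(self):
        out = stratify(StudySet(()), StratificationPlan(by="ethnicity"), GM.ALLELE)
        assert out == {}

    def test_unknown_plan_rejected(self):
        with pytest.raises(ValueError):
            StratificationPlan(by="genotyping_method")


class TestLeaveOneOut:
    def test_cardinality(self, rs4977574):
        loo = leave_one_out(rs4977574, GM.ALLELE)
        assert len(loo.results) == 17
        omitted = {sid for sid, _ in loo.results}
        assert omitted == {r.study_id for r in rs4977574}

    def test_identical_studies_unmoved(self, suleiman):
        from dataclasses import replace
        trio = StudySet(tuple(replace(suleiman, study_id=f"s{i}") for i in range(3)))
        loo = leave_one_out(trio, GM.ALLELE)
        for _, r in loo.results:
            assert r.log_or == pytest.approx(loo.full.log_or, rel=1e-12)

    def test_requires_three_studies(self, suleiman):
        from dataclasses import replace
        pair = StudySet((suleiman, replace(suleiman, study_id="b")))
        with pytest.raises(ValueError):
            leave_one_out(pair, GM.ALLELE)

    def test_omitting_central_study_moves_pool_least(self):
        from snpmeta import SimScenario, simulate_set
        studies = simulate_set(SimScenario(k=9, or_allelic=1.3, seed=7,
                                           n_case_range=(800, 800),
                                           n_ctrl_range=(800, 800)))
        loo = leave_one_out(studies, GM.ALLELE)
        effects, _ = study_effects(studies, GM.ALLELE)
        center = loo.full.log_or
        closest = min(effects, key=lambda e: abs(e.log_or - center)).study_id
        shifts = {sid: abs(r.log_or - center) for sid, r in loo.results}
        assert shifts[closest] == min(shifts.values())
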