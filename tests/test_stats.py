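"""Co-occurrence, shifts, survival statistics, scorer concordance."""

import numpy as np
import pandas as pd
import pytest

import pdacpheno as pp
from pdacpheno.stats import (cooccurrence_frame, cooccurrence_test, cox_fit, detect_shifts,
                             fisher_exact_2x2, km_logrank, scorer_concordance)
from oracles import fisher_two_sided, km_curve, logrank_chi2


def presence_frame(flags: dict[str, list[bool]]) -> pd.DataFrame:
    n = len(next(iter(flags.values())))
    df = pd.DataFrame({f"present_{p}": v for p, v in flags.items()})
    df["tumor_id"] = [f"T{i}" for i in range(n)]
    return df


SIX_PATIENTS = pd.DataFrame({
    "patient_id": list("abcdef"),
    "time_months": [5.0, 8.0, 12.0, 4.0, 9.0, 15.0],
    "event": [True, True, False, True, False, True],
    "group": ["A", "A", "A", "B", "B", "B"],
})


class TestCooccurrence:
    def test_example_table_matches_enumeration(self):
        _, p = fisher_exact_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(fisher_two_sided(3, 1, 1, 3), abs=1e-12)

    def test_pairs_and_margins(self):
        rng = np.random.default_rng(0)
        flags = {p: list(rng.random(40) < 0.5) for p in pp.PHENOTYPES}
        res = cooccurrence_test(presence_frame(flags))
        assert len(res) == 6  # all phenotype pairs
        for r in res:
            assert r.table.sum() == 40
            assert 0.0 <= r.p_value <= 1.0
            assert r.p_adjusted >= r.p_value - 1e-12

    def test_degenerate_margin_flagged(self):
        flags = {p: [True] * 10 for p in pp.PHENOTYPES}
        flags["Classical"] = [True] * 5 + [False] * 5
        res = cooccurrence_test(presence_frame(flags))
        degenerate = [r for r in res if "Intermediate" in
                      (r.phenotype_a, r.phenotype_b)
                      and "Classical" not in (r.phenotype_a, r.phenotype_b)]
        assert degenerate and all(not r.odds_ratio_defined for r in degenerate)
        assert all(r.p_value == 1.0 for r in degenerate)

    def test_too_few_tumors_raise(self):
        flags = {p: [True] for p in pp.PHENOTYPES}
        with pytest.raises(ValueError):
            cooccurrence_test(presence_frame(flags))

    def test_null_rarely_significant_after_bh(self):
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            rng = np.random.default_rng(5000 + s)
            flags = {p: list(rng.random(200) < 0.5) for p in pp.PHENOTYPES}
            res = cooccurrence_test(presence_frame(flags))
            if min(r.p_adjusted for r in res) > 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_frame_export(self):
        flags = {p: [True, False, True, False] for p in pp.PHENOTYPES}
        df = cooccurrence_frame(cooccurrence_test(presence_frame(flags)))
        assert {"odds_ratio", "p_value", "p_adjusted"} <= set(df.columns)


class TestShifts:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["tumor_id", "slide_id",
                                           "predominant"])

    def test_no_shift_when_agreeing(self):
        shifts, n = detect_shifts(self.frame([
            ("T1", "s1", "Classical"), ("T1", "s2", "Classical")]))
        assert shifts == [] and n == 1

    def test_shift_recorded_with_direction(self):
        shifts, n = detect_shifts(self.frame([
            ("T1", "s1", "Intermediate"), ("T1", "s2", "Basal.S100A2")]))
        assert n == 1 and len(shifts) == 1
        s = shifts[0]
        assert (s.from_phenotype, s.to_phenotype) == ("Intermediate",
                                                      "Basal.S100A2")

    def test_single_slide_tumor_excluded(self):
        shifts, n = detect_shifts(self.frame([
            ("T1", "s1", "Classical"),
            ("T2", "s1", "Classical"), ("T2", "s2", "Intermediate")]))
        assert n == 1 and len(shifts) == 1


class TestKMLogrank:
    def test_six_patient_fixture_matches_hand_enumeration(self):
        res = km_logrank(SIX_PATIENTS, "group")
        # product-limit steps by hand: group A events at 5 and 8 out of 3
        expected_a = km_curve([5, 8, 12], [True, True, False])
        assert expected_a == [(5.0, pytest.approx(2 / 3)),
                              (8.0, pytest.approx(1 / 3))]
        curve_a = res.groups["A"].curve.set_index("time")["survival"]
        for t, s in expected_a:
            assert curve_a.loc[t] == pytest.approx(s)
        chi2 = logrank_chi2([5, 8, 12], [1, 1, 0], [4, 9, 15], [1, 0, 1])
        assert chi2 == pytest.approx((2 - 1.6) ** 2 / 0.74, abs=1e-12)
        assert res.chi_square == pytest.approx(chi2, abs=1e-9)

    def test_identical_groups_give_null(self):
        df = pd.concat([SIX_PATIENTS.assign(group="A"),
                        SIX_PATIENTS.assign(group="B")])
        res = km_logrank(df, "group")
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_curve_shape_invariants(self):
        _, surv, _ = pp.generate_cohort(pp.CohortConfig(n_tumors=200, seed=4))
        res = km_logrank(surv, "basal_present")
        for g in res.groups.values():
            s = g.curve["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert s[0] <= 1.0 + 1e-12
            assert ((g.curve["at_risk"].to_numpy() >= 1)).all()

    def test_all_censored_undefined(self):
        df = SIX_PATIENTS.assign(event=False)
        res = km_logrank(df, "group")
        assert not res.defined
        assert all(np.isnan(g.median) for g in res.groups.values())

    def test_label_swap_invariance(self):
        res = km_logrank(SIX_PATIENTS, "group")
        swapped = SIX_PATIENTS.assign(
            group=SIX_PATIENTS["group"].map({"A": "B", "B": "A"}))
        res2 = km_logrank(swapped, "group")
        assert res.p_value == pytest.approx(res2.p_value, abs=1e-12)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            km_logrank(SIX_PATIENTS.assign(group="A"), "group")


class TestCox:
    def test_planted_hazard_ratio_recovered(self):
        cfg = pp.CohortConfig(n_tumors=500, basal_hazard_ratio=2.0,
                              censoring_rate=0.2, seed=11)
        _, surv, _ = pp.generate_cohort(cfg)
        res = cox_fit(surv, ["basal_present"])
        assert 1.6 <= res.hr("basal_present") <= 2.5

    def test_large_sample_consistency(self):
        # bias of the partial-likelihood estimator on exponential PH data:
        # averaged over independent n=5,000 cohorts so sampling noise
        # (se ≈ 0.04 per cohort) does not masquerade as bias
        coefs = []
        for seed in range(17, 22):
            cfg = pp.CohortConfig(n_tumors=5000, basal_hazard_ratio=2.0,
                                  censoring_rate=0.2, seed=seed)
            _, surv, _ = pp.generate_cohort(cfg)
            res = cox_fit(surv, ["basal_present"])
            coefs.append(res.table.loc["basal_present", "coef"])
        assert abs(np.mean(coefs) - np.log(2)) < 0.05

    def test_null_ci_coverage(self):
        covered = 0
        for s in range(100):
            cfg = pp.CohortConfig(n_tumors=300, basal_hazard_ratio=1.0,
                                  censoring_rate=0.2, seed=1000 + s)
            _, surv, _ = pp.generate_cohort(cfg)
            lo, hi = cox_fit(surv, ["basal_present"]).ci("basal_present")
            covered += lo <= 1.0 <= hi
        assert covered >= 90

    def test_constant_covariate_raises(self):
        _, surv, _ = pp.generate_cohort(pp.CohortConfig(n_tumors=50, seed=0))
        surv["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(surv, ["flat"])

    def test_multivariate_keeps_basal_effect(self):
        from pdacpheno.synthetic import COVARIATES
        cfg = pp.CohortConfig(n_tumors=500, basal_hazard_ratio=2.0,
                              censoring_rate=0.2, seed=11)
        _, surv, _ = pp.generate_cohort(cfg)
        res = cox_fit(surv, ["basal_present"] + list(COVARIATES))
        assert 1.5 <= res.hr("basal_present") <= 2.6
        assert "basal_present" in res.summary()


class TestScorerConcordance:
    def test_identical_vectors(self):
        r, p = scorer_concordance([10, 50, 200, 300], [10, 50, 200, 300])
        assert r == pytest.approx(1.0)

    def test_reversed_ranks_spearman(self):
        r, _ = scorer_concordance([1, 2, 3, 4], [40, 30, 20, 10],
                                  method="spearman")
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize("a,b", [([1, 2], [3, 4]),
                                     ([1, 2, 3], [1, 2]),
                                     ([1, 1, 1], [1, 2, 3])])
    def test_invalid_inputs_raise(self, a, b):
        with pytest.raises(ValueError):
            scorer_concordance(a, b)
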