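"""AUC computation, biomarker filtering, panel intersection, stepwise
selection, combinatorial ROC and the permutation bootstrap."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbdmethyl.biomarker import (
    bootstrap_auc_pvalue,
    combinatorial_roc,
    intersect_contrasts,
    region_auc,
    select_dmr_biomarkers,
    stepwise_aic_logistic,
)


def auc_pair_oracle(case, control):
    case, control = np.asarray(case, float), np.asarray(control, float)
    wins = ties = 0
    for c in case:
        for k in control:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(case) * len(control))


class TestRegionAUC:
    def test_perfect_separation(self):
        r = region_auc([3, 4, 5], [1, 2])
        assert r.auc == 1.0 and r.orientation == "case_high"

    def test_all_ties(self):
        r = region_auc([2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.auc == 0.5

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(200):
            case = rng.integers(0, 6, size=7).astype(float)
            ctrl = rng.integers(0, 6, size=9).astype(float)
            a = auc_pair_oracle(case, ctrl)
            r = region_auc(case, ctrl)
            assert r.auc == pytest.approx(max(a, 1 - a), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        case = rng.normal(1, 1, 8)
        ctrl = rng.normal(0, 1, 6)
        r1 = region_auc(case, ctrl)
        r2 = region_auc(np.exp(case), np.exp(ctrl))
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert r1.orientation == r2.orientation

    def test_arm_swap_invariance_after_orientation(self, rng):
        case = rng.normal(0.5, 1, 8)
        ctrl = rng.normal(0, 1, 6)
        assert region_auc(case, ctrl).auc == pytest.approx(region_auc(ctrl, case).auc, abs=1e-12)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            region_auc([], [1.0])


class TestSelectBiomarkers:
    def _tables(self, rows):
        dmr = pd.DataFrame(
            [(r, p) for r, p, a, c in rows], columns=["region_id", "p_value"]
        )
        auc = pd.DataFrame([(r, a) for r, p, a, c in rows], columns=["region_id", "auc"])
        cpg = {r: c for r, p, a, c in rows}
        return dmr, auc, cpg

    def test_strict_thresholds(self):
        rows = [
            ("keep", 0.005, 0.66, 5),
            ("auc_at_boundary", 0.005, 0.65, 5),
            ("cpg_at_boundary", 0.005, 0.80, 4),
            ("p_at_boundary", 0.01, 0.80, 5),
        ]
        out = select_dmr_biomarkers(*self._tables(rows))
        assert list(out["region_id"]) == ["keep"]

    def test_empty_table(self):
        dmr, auc, cpg = self._tables([])
        assert len(select_dmr_biomarkers(dmr, auc, cpg)) == 0

    def test_matches_brute_force(self, rng):
        rows = [
            (f"r{i}", float(rng.uniform(0, 0.05)), float(rng.uniform(0.5, 1.0)), int(rng.integers(0, 12)))
            for i in range(300)
        ]
        out = select_dmr_biomarkers(*self._tables(rows))
        want = [r for r, p, a, c in rows if p < 0.01 and a > 0.65 and c > 4]
        assert list(out["region_id"]) == want

    def test_missing_cpg_count_rejected(self):
        dmr, auc, cpg = self._tables([("r1", 0.001, 0.9, 8)])
        with pytest.raises(ValueError, match="cpg_count"):
            select_dmr_biomarkers(dmr, auc, {})


def panel_df(ids_and_aucs):
    return pd.DataFrame(ids_and_aucs, columns=["region_id", "auc"])


class TestIntersectContrasts:
    def test_set_algebra(self):
        A = panel_df([("r1", 0.8), ("r2", 0.7)])
        B = panel_df([("r3", 0.9)])
        C = panel_df([("r1", 0.75), ("r2", 0.85), ("r3", 0.8), ("r4", 0.95)])
        panel = intersect_contrasts(A, B, C)
        classes = {m.region_id: m.member_class for m in panel.members}
        assert classes == {"r1": "IIa_defining", "r2": "IIa_defining", "r3": "IIb_defining"}
        # triple intersection empty -> no top member
        assert not any(m.member_class == "IIb_vs_IIa_top" for m in panel.members)

    def test_disjoint_inputs_empty_panel(self):
        panel = intersect_contrasts(panel_df([("a", 0.7)]), panel_df([("b", 0.7)]), panel_df([("c", 0.7)]))
        assert panel.members == []

    def test_top_member_has_highest_auc_in_triple(self):
        A = panel_df([("r1", 0.7), ("r2", 0.7)])
        B = panel_df([("r1", 0.7), ("r2", 0.7)])
        C = panel_df([("r1", 0.95), ("r2", 0.90)])
        panel = intersect_contrasts(A, B, C)
        tops = [m for m in panel.members if m.member_class == "IIb_vs_IIa_top"]
        assert len(tops) == 1 and tops[0].region_id == "r1"

    def test_classes_mutually_exclusive(self, rng):
        ids = [f"r{i}" for i in range(40)]
        def rnd():
            chosen = rng.choice(ids, size=rng.integers(5, 25), replace=False)
            return panel_df([(r, float(rng.uniform(0.66, 1.0))) for r in chosen])
        panel = intersect_contrasts(rnd(), rnd(), rnd())
        seen = [m.region_id for m in panel.members]
        assert len(seen) == len(set(seen))


class TestStepwiseAIC:
    def test_empty_scope_gives_intercept_only(self, rng):
        y = rng.integers(0, 2, 50).astype(float)
        cov = pd.DataFrame({"x": rng.normal(size=50)})
        m = stepwise_aic_logistic(y, cov, scope=[])
        assert m.selected_covariates == []
        p = y.mean()
        null_dev = -2 * (y.sum() * np.log(p) + (len(y) - y.sum()) * np.log(1 - p))
        assert m.aic == pytest.approx(null_dev + 2, abs=1e-6)

    def test_signal_covariates_retained(self):
        rng = np.random.default_rng(101)
        hits = 0
        for _ in range(20):
            n = 200
            age = rng.normal(size=n)
            gender = rng.integers(0, 2, n).astype(float)
            noise = rng.normal(size=(n, 5))
            eta = age + gender
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            cov = pd.DataFrame(
                np.column_stack([age, gender, noise]),
                columns=["age", "gender", "n1", "n2", "n3", "n4", "n5"],
            )
            if {"age", "gender"} <= set(stepwise_aic_logistic(y, cov).selected_covariates):
                hits += 1
        assert hits >= 17

    def test_noise_retention_calibrated_to_aic_penalty(self):
        # AIC keeps a pure-noise covariate when its chi2_1 improvement
        # exceeds 2, i.e. with probability ~0.157
        rng = np.random.default_rng(55)
        kept = total = 0
        for _ in range(30):
            n = 200
            noise = rng.normal(size=(n, 5))
            y = rng.integers(0, 2, n).astype(float)
            cov = pd.DataFrame(noise, columns=[f"n{i}" for i in range(5)])
            sel = stepwise_aic_logistic(y, cov).selected_covariates
            kept += len(sel)
            total += 5
        assert 0.05 < kept / total < 0.30

    def test_too_few_observations_rejected(self, rng):
        y = rng.integers(0, 2, 4).astype(float)
        cov = pd.DataFrame(rng.normal(size=(4, 5)), columns=list("abcde"))
        with pytest.raises(ValueError, match="observations"):
            stepwise_aic_logistic(y, cov)


class TestCombinatorialROC:
    def test_enumeration_count(self, rng):
        X = pd.DataFrame(rng.normal(size=(16, 13)), columns=[f"f{i}" for i in range(13)])
        y = np.repeat([0.0, 1.0], 8)
        res = combinatorial_roc(X, y, clinical_score=rng.normal(size=16), max_subset_size=3)
        want = 2 * sum(comb(13, k) for k in (1, 2, 3))
        assert len(res) == want == 754

    def test_outcome_feature_ranks_first(self, rng):
        y = np.repeat([0.0, 1.0], 8)
        X = pd.DataFrame({"oracle": y, "noise": rng.normal(size=16)})
        res = combinatorial_roc(X, y, max_subset_size=1)
        assert "oracle" in res[0].feature_set
        assert res[0].auc == 1.0

    def test_ranking_matches_independent_rescoring(self, rng):
        from mbdmethyl.biomarker import _score_combo

        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = (rng.random(20) < 0.5).astype(float)
        res = combinatorial_roc(X, y, max_subset_size=2)
        for r in res:
            feats = X[list(r.feature_set)].to_numpy()
            auc, acc = _score_combo(feats, y)
            assert r.auc == pytest.approx(auc, abs=1e-12)
            assert r.accuracy == pytest.approx(acc, abs=1e-12)
        aucs = [r.auc for r in res]
        assert aucs == sorted(aucs, reverse=True)

    def test_cap_enforced(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 13)), columns=[f"f{i}" for i in range(13)])
        y = np.repeat([0.0, 1.0], 5)
        with pytest.raises(ValueError, match="lower max_subset_size"):
            combinatorial_roc(X, y, max_subset_size=13, combo_cap=1000)


class TestBootstrapAUC:
    def test_perfect_separation_small_p(self):
        y = np.repeat([0, 1], 8)
        score = y.astype(float)
        p = bootstrap_auc_pvalue(score, y, n_boot=999, seed=0)
        assert p <= 0.01

    def test_smoothed_p_bounds(self, rng):
        y = np.repeat([0, 1], 8)
        p = bootstrap_auc_pvalue(rng.normal(size=16), y, n_boot=99, seed=1)
        assert 0 < p <= 1

    def test_zero_boot_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_auc_pvalue(np.arange(4.0), np.array([0, 0, 1, 1]), n_boot=0)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            bootstrap_auc_pvalue(np.arange(4.0), np.zeros(4, int), n_boot=10)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 8)
        ps = [
            bootstrap_auc_pvalue(rng.normal(size=16), y, n_boot=199, seed=int(rng.integers(2**31)))
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").statistic < 0.1
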