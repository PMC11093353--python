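"""Unit and property tests for the factorial DE module."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from hifseek import DataError
from hifseek.expression import (
    ContrastSpec,
    ExpressionStudy,
    Thresholds,
    classify,
    dedup_probesets,
    estimate_pi0,
    fit_contrast,
    qvalues,
    signed_fc,
    signed_ratio,
    signed_to_linear,
)

from conftest import make_balanced_study


def ols_contrast_oracle(study, contrast):
    """Brute-force per-gene general linear model fit via statsmodels OLS."""
    sheet = study.samples.loc[study.matrix.columns]
    design = pd.get_dummies(
        sheet[["treatment", "block"]].astype(str), drop_first=False, dtype=float
    )
    # cell-means coding for treatment + effects for block via OLS on dummies
    out = []
    t_levels = sorted(sheet["treatment"].unique())
    w = contrast.vector(t_levels)
    for gene in study.matrix.index:
        y = study.matrix.loc[gene].to_numpy(dtype=float)
        X = pd.get_dummies(sheet["treatment"], dtype=float)[t_levels]
        B = pd.get_dummies(sheet["block"], drop_first=True, dtype=float)
        fit = sm.OLS(y, pd.concat([X, B], axis=1).to_numpy()).fit()
        est = float(w @ fit.params[: len(t_levels)])
        cvec = np.concatenate([w, np.zeros(B.shape[1])])
        tres = fit.t_test(cvec)
        out.append(
            (est, float(np.squeeze(tres.tvalue)) ** 2,
             float(np.squeeze(tres.pvalue)))
        )
    return np.array(out)


class TestFitContrast:
    def test_matches_ols_oracle_on_random_instances(self):
        """Closed-form balanced solution equals a general least-squares fit."""
        rng = np.random.default_rng(42)
        for rep in range(6):
            n_t = int(rng.integers(3, 7))
            n_b = int(rng.integers(2, 5))
            treatments = [f"t{i}" for i in range(n_t)]
            study = make_balanced_study(
                4, treatments=treatments, n_blocks=n_b, seed=int(rng.integers(1e6))
            )
            weights = rng.normal(size=n_t)
            weights -= weights.mean()
            spec = ContrastSpec("c", dict(zip(treatments, weights)))
            res = fit_contrast(study, spec)
            oracle = ols_contrast_oracle(study, spec)
            np.testing.assert_allclose(res["estimate"], oracle[:, 0], atol=1e-8)
            np.testing.assert_allclose(res["F"], oracle[:, 1], rtol=1e-6)
            np.testing.assert_allclose(res["p"], oracle[:, 2], rtol=1e-6)

    def test_constant_matrix_is_degenerate_with_zero_estimate(self):
        study = make_balanced_study(3, seed=1)
        study.matrix.iloc[:, :] = 5.0
        spec = ContrastSpec("c", {"A": 1.0, "B": -1.0})
        with pytest.warns(UserWarning, match="zero residual variance"):
            res = fit_contrast(study, spec)
        assert (res["estimate"] == 0).all()
        assert res["degenerate"].all()
        assert np.isnan(res["p"]).all()

    def test_residual_df_is_14_for_3x8_design(self):
        """With b=3 and t=8 the F test has (1, 14) denominator df."""
        treatments = [f"t{i}" for i in range(8)]
        study = make_balanced_study(500, treatments=treatments, n_blocks=3, seed=3)
        spec = ContrastSpec("c", {"t0": 1.0, "t1": -1.0})
        res = fit_contrast(study, spec)
        # p computed from F with (1, 14) df must reproduce the reported p
        from scipy import stats

        np.testing.assert_allclose(
            res["p"], stats.f.sf(res["F"], 1, 14), rtol=1e-12
        )

    def test_type_one_error_calibrated_under_null(self):
        """Fraction of null genes with p <= alpha stays within 3 binomial SE."""
        study = make_balanced_study(4000, seed=11)
        spec = ContrastSpec("c", {"A": 1.0, "B": -1.0})
        res = fit_contrast(study, spec)
        for alpha in (0.01, 0.05):
            frac = float((res["p"] <= alpha).mean())
            se = np.sqrt(alpha * (1 - alpha) / len(res))
            assert abs(frac - alpha) <= 3 * se

    def test_unbalanced_design_rejected(self):
        study = make_balanced_study(3)
        bad = study.samples.drop(index=["b1_A"])
        with pytest.raises(DataError, match="balanced"):
            ExpressionStudy(study.matrix.drop(columns=["b1_A"]), bad)


class TestQvalues:
    def test_bh_equivalence_when_pi0_forced_to_one(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(qvalues(p, pi0=1.0), [0.04, 0.04, 0.04, 0.04])
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            qvalues(p, pi0=1.0), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(qvalues(np.ones(5), pi0=1.0), np.ones(5))

    def test_pi0_near_one_on_uniform_p(self):
        """pi0 estimates on uniform (null) p-values center on 1 within 0.05.

        Averaged over independent draws: the estimate at one draw carries the
        Monte-Carlo noise of the empirical tail itself.
        """
        ests = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ests.append(estimate_pi0(rng.uniform(size=10_000)))
        assert abs(float(np.mean(ests)) - 1.0) <= 0.05

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.beta(0.5, 3.0, size=300))
        q = qvalues(p)
        assert (np.diff(q) >= -1e-12).all()
        assert ((0 <= q) & (q <= 1)).all()

    def test_q_at_least_p_times_pi0(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        pi0 = 0.7
        q = qvalues(p, pi0=pi0)
        assert (q >= p * pi0 - 1e-12).all()

    def test_rejects_bad_p(self):
        with pytest.raises(DataError):
            qvalues(np.array([0.5, 1.2]))

    def test_too_few_p_falls_back_to_one(self):
        with pytest.warns(UserWarning, match="too few"):
            assert estimate_pi0(np.array([0.2, 0.4])) == 1.0


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "delta,expected", [(0.0, 1.0), (1.0, 2.0), (-1.0, -2.0), (2.0, 4.0)]
    )
    def test_known_values(self, delta, expected):
        assert signed_fc(delta) == pytest.approx(expected)

    @given(st.floats(min_value=-60, max_value=60))
    def test_magnitude_always_at_least_one(self, delta):
        assert abs(signed_fc(delta)) >= 1.0

    @given(
        st.floats(min_value=1.0, max_value=1e6, exclude_min=True).flatmap(
            lambda m: st.sampled_from([m, -m])
        )
    )
    def test_round_trip(self, s):
        back = signed_fc(np.log2(signed_to_linear(s)))
        assert back == pytest.approx(s, rel=1e-9)

    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            # printed relative inductions of well-known HIF-1 targets
            (3.28, -1.43, 4.69),
            (8.55, 1.15, 7.43),
            (93.70, 23.24, 4.03),
            (57.42, 20.34, 2.82),
        ],
    )
    def test_relative_induction_worked_examples(self, s1, s2, expected):
        assert signed_ratio(s1, s2) == pytest.approx(expected, abs=0.01)

    @given(
        st.floats(min_value=1.0, max_value=1e4, exclude_min=True).flatmap(
            lambda m: st.sampled_from([m, -m])
        )
    )
    def test_identity_and_self_ratio(self, s):
        assert signed_ratio(s, s) == pytest.approx(1.0)
        assert signed_ratio(s, 1.0) == pytest.approx(s)

    def test_rejects_magnitude_below_one(self):
        with pytest.raises(DataError):
            signed_ratio(0.5, 2.0)


class TestClassify:
    @staticmethod
    def _results(est_n2, est_hif1, q_inter, q_n2=1e-4):
        genes = ["g"]
        mk = lambda e, q: pd.DataFrame({"estimate": [e], "q": [q]}, index=genes)
        return {
            "n2_hypoxia": mk(est_n2, q_n2),
            "hif1_hypoxia": mk(est_hif1, 1e-4),
            "interaction": mk(est_n2 - est_hif1, q_inter),
        }

    def test_positive_hif1_dependence(self):
        # relative induction 2.40 at q = 2.31e-2 -> positively HIF-1 regulated
        res = self._results(np.log2(3.16), np.log2(1.31), 2.31e-2)
        lab = classify(res)
        assert bool(lab["hif1_positive"].iloc[0])
        assert lab["relative_induction"].iloc[0] == pytest.approx(2.41, abs=0.01)

    def test_negative_hif1_dependence(self):
        # acs-2-like: induction stronger in the hif-1 mutant
        res = self._results(np.log2(5.29), np.log2(16.74), 1.07e-2)
        lab = classify(res)
        assert bool(lab["hif1_negative"].iloc[0])
        assert lab["relative_induction"].iloc[0] == pytest.approx(-3.16, abs=0.01)

    def test_unit_relative_induction_never_labelled(self):
        res = self._results(1.0, 1.0, 1e-6)
        lab = classify(res)
        assert not bool(lab["hif1_positive"].iloc[0])
        assert not bool(lab["hif1_negative"].iloc[0])

    def test_missing_contrast_rejected(self):
        with pytest.raises(DataError, match="missing required contrast"):
            classify({"n2_hypoxia": pd.DataFrame()})

    def test_hypoxia_direction_from_sign(self):
        res = self._results(-1.0, -1.0, 0.9)
        lab = classify(res)
        assert bool(lab["hypoxia_down"].iloc[0])
        assert not bool(lab["hypoxia_up"].iloc[0])


class TestDedupProbesets:
    def test_identity_when_already_one_to_one(self):
        pm = pd.DataFrame({"probeset": ["p1", "p2"], "gene": ["g1", "g2"]})
        mat = pd.DataFrame({"s1": [1.0, 2.0]}, index=["p1", "p2"])
        out = dedup_probesets(pm, mat)
        assert set(map(tuple, out.to_numpy())) == {("p1", "g1"), ("p2", "g2")}

    def test_higher_mean_probeset_wins_shared_gene(self):
        pm = pd.DataFrame({"probeset": ["p1", "p2"], "gene": ["g1", "g1"]})
        mat = pd.DataFrame({"s1": [1.0, 9.0]}, index=["p1", "p2"])
        out = dedup_probesets(pm, mat)
        assert out.to_numpy().tolist() == [["p2", "g1"]]

    def test_injective_both_ways_on_random_maps(self):
        rng = np.random.default_rng(9)
        probesets = [f"p{i}" for i in range(40)]
        genes = [f"g{i}" for i in range(25)]
        rows = [
            (p, g)
            for p in probesets
            for g in rng.choice(genes, size=rng.integers(1, 4), replace=False)
        ]
        pm = pd.DataFrame(rows, columns=["probeset", "gene"])
        mat = pd.DataFrame(
            {"s1": rng.normal(size=len(probesets))}, index=probesets
        )
        out = dedup_probesets(pm, mat)
        assert out["probeset"].is_unique and out["gene"].is_unique
        # every kept pair existed in the original map
        orig = set(map(tuple, pm.to_numpy()))
        assert set(map(tuple, out.to_numpy())) <= orig

    def test_empty_map_rejected(self):
        with pytest.raises(DataError, match="empty"):
            dedup_probesets(pd.DataFrame(columns=["probeset", "gene"]),
                            pd.DataFrame())
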