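"""Alignment, RMSE metrics, SE aggregation, and the eta^2 decomposition."""

import numpy as np
import pandas as pd
import pytest

import irtkit
from irtkit.evaluation import (
    align,
    anova_eta2,
    average_rmse_a,
    average_rmse_b,
    average_rmse_p,
    average_rmse_theta,
    average_se,
)
from irtkit.types import ParameterEstimates, TrueParameters


def _est_from_truth(truth, s=1.0, t=0.0, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    jitter = (lambda x: x + rng.normal(0, noise, size=len(x))) if noise else (lambda x: x)
    return ParameterEstimates(
        abilities=jitter(s * truth.abilities + t),
        difficulties=jitter(s * truth.difficulties + t),
        discriminations=np.abs(jitter(truth.discriminations / s)),
        se_abilities=np.zeros_like(truth.abilities),
        se_difficulties=np.zeros_like(truth.difficulties),
        se_discriminations=np.zeros_like(truth.discriminations),
        method="synthetic", model=truth.model,
    )


@pytest.fixture(scope="module")
def truth_2pl():
    return irtkit.draw_parameters(60, 8, "2PL", 900)


@pytest.fixture(scope="module")
def truth_1pl():
    return irtkit.draw_parameters(60, 8, "1PL", 901)


class TestAlign:
    def test_identity_when_estimates_equal_truth(self, truth_2pl):
        res = align(_est_from_truth(truth_2pl), truth_2pl, "2PL")
        assert res.s == pytest.approx(1.0, abs=1e-3)
        assert res.t == pytest.approx(0.0, abs=1e-3)
        assert res.objective < 1e-6

    def test_recovers_planted_transform(self, truth_2pl):
        est = _est_from_truth(truth_2pl, s=2.0, t=0.5)
        res = align(est, truth_2pl, "2PL")
        # inverse of (s=2, t=0.5): s = 1/2, t = -1/4
        assert res.s == pytest.approx(0.5, abs=1e-3)
        assert res.t == pytest.approx(-0.25, abs=1e-3)
        assert res.objective < 1e-6
        np.testing.assert_allclose(res.aligned.abilities, truth_2pl.abilities, atol=1e-3)
        np.testing.assert_allclose(
            res.aligned.discriminations, truth_2pl.discriminations, atol=1e-3
        )

    def test_noisy_estimates_beat_dense_grid(self, truth_2pl):
        est = _est_from_truth(truth_2pl, s=1.3, t=-0.2, noise=0.15, seed=4)
        res = align(est, truth_2pl, "2PL")
        from irtkit.evaluation import _J

        grid = [
            _J(est, truth_2pl, s, t, True)
            for s in np.linspace(0.4, 2.5, 201)
            for t in np.linspace(-1.5, 1.5, 201)
        ]
        assert res.objective <= min(grid) + 1e-9

    def test_1pl_shift_only(self, truth_1pl):
        est = _est_from_truth(truth_1pl, s=1.0, t=0.8)
        res = align(est, truth_1pl, "1PL")
        assert res.s == 1.0
        assert res.t == pytest.approx(-0.8, abs=1e-6)
        np.testing.assert_allclose(res.aligned.discriminations, 1.0)

    def test_degenerate_truth_warns_and_skips(self):
        truth = TrueParameters(
            abilities=np.zeros(4), difficulties=np.zeros(3),
            discriminations=np.ones(3), model="1PL",
        )
        est = _est_from_truth(truth)
        with pytest.warns(UserWarning):
            res = align(est, truth, "1PL")
        assert res.s == 1.0 and res.t == 0.0


class TestAverageRmse:
    def test_zero_when_estimates_equal_truth(self, truth_2pl):
        est = _est_from_truth(truth_2pl)
        assert average_rmse_theta([est] * 3, [truth_2pl] * 3) == 0.0
        assert average_rmse_b([est], [truth_2pl]) == 0.0
        assert average_rmse_a([est], [truth_2pl]) == 0.0
        assert average_rmse_p([est], [truth_2pl]) == 0.0

    def test_hand_computed_single_replication(self):
        truth = TrueParameters(
            abilities=[0.0, 0.0], difficulties=[0.0, 1.0],
            discriminations=[1.0, 1.0], model="1PL",
        )
        est = ParameterEstimates(
            abilities=[3.0, 4.0], difficulties=[0.0, 1.0],
            discriminations=[1.0, 1.0],
            se_abilities=[0, 0], se_difficulties=[0, 0], se_discriminations=[0, 0],
        )
        # errors (3, 4) over 2 persons: sqrt((9 + 16)/2)
        assert average_rmse_theta([est], [truth]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_then_average_ordering(self, truth_2pl):
        # the reported value is the mean over replications of per-rep RMSEs
        e1 = _est_from_truth(truth_2pl, noise=0.1, seed=1)
        e2 = _est_from_truth(truth_2pl, noise=0.3, seed=2)
        r1 = average_rmse_theta([e1], [truth_2pl])
        r2 = average_rmse_theta([e2], [truth_2pl])
        both = average_rmse_theta([e1, e2], [truth_2pl, truth_2pl])
        assert both == pytest.approx((r1 + r2) / 2, rel=1e-12)

    def test_length_mismatch_rejected(self, truth_2pl):
        with pytest.raises(ValueError):
            average_rmse_theta([_est_from_truth(truth_2pl)], [])


class TestAverageSe:
    def test_constant_ses(self):
        assert average_se([np.full(5, 0.2), np.full(9, 0.2)]) == pytest.approx(0.2)

    def test_nested_means(self):
        assert average_se([np.array([0.1, 0.3]), np.array([0.2, 0.2])]) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_se([])


def _balanced_frame(values_by_cell, reps):
    rows = []
    for (em, ss, tl), vals in values_by_cell.items():
        for r in range(reps):
            rows.append({"EM": em, "SS": ss, "TL": tl, "metric": vals[r]})
    return pd.DataFrame(rows)


class TestAnovaEta2:
    def test_constant_metric_gives_zero_everywhere(self):
        df = _balanced_frame(
            {(em, ss, tl): [1.0, 1.0] for em in "AB" for ss in (1, 2) for tl in (1, 2)},
            reps=2,
        )
        out = anova_eta2(df, "metric")
        assert np.allclose(out["eta2_pct"], 0.0)

    def test_single_factor_explains_everything(self):
        df = _balanced_frame(
            {("A", 1, 1): [0.0, 0.0], ("B", 1, 1): [1.0, 1.0]}, reps=2
        )
        out = anova_eta2(df, "metric").set_index("effect")
        assert out.loc["EM", "eta2_pct"] == pytest.approx(100.0)
        assert out.loc["EM", "size"] == "large"

    def test_hand_computed_two_by_two(self):
        # cells: A1 -> 0, A2 -> 2, B1 -> 1, B2 -> 5 (one rep each).
        # grand = 2; SS_total = 4 + 0 + 1 + 9 = 14
        # EM means: A = 1, B = 3 -> SS_EM = 2*(1 + 1) = 4
        # SS means: 1 -> 0.5, 2 -> 3.5 -> SS_SS = 2*(2.25 + 2.25) = 9
        # interaction = 14 - 4 - 9 = 1 (saturated; no residual)
        df = _balanced_frame(
            {("A", 1, 1): [0.0], ("A", 2, 1): [2.0],
             ("B", 1, 1): [1.0], ("B", 2, 1): [5.0]}, reps=1
        )
        out = anova_eta2(df, "metric").set_index("effect")
        assert out.loc["EM", "SS"] == pytest.approx(4.0, abs=1e-10)
        assert out.loc["SS", "SS"] == pytest.approx(9.0, abs=1e-10)
        assert out.loc["EM x SS", "SS"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["residual", "SS"] == pytest.approx(0.0, abs=1e-10)

    def test_eta2_sums_to_hundred(self):
        rng = np.random.default_rng(10)
        df = _balanced_frame(
            {(em, ss, tl): rng.random(3).tolist()
             for em in "ABC" for ss in (1, 2) for tl in (1, 2, 3)},
            reps=3,
        )
        out = anova_eta2(df, "metric")
        assert out["eta2_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_unbalanced_design_rejected(self):
        df = _balanced_frame(
            {("A", 1, 1): [0.0, 1.0], ("B", 1, 1): [1.0, 2.0]}, reps=2
        )
        df = df.iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            anova_eta2(df, "metric")

    def test_matches_statsmodels_decomposition(self):
        # independent oracle: OLS sums of squares on a balanced factorial
        rng = np.random.default_rng(11)
        df = _balanced_frame(
            {(em, ss, tl): rng.random(2).tolist()
             for em in "AB" for ss in (1, 2) for tl in (1, 2)},
            reps=2,
        )
        out = anova_eta2(df, "metric").set_index("effect")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        model = ols(
            "metric ~ C(EM) * C(SS) * C(TL)", data=df
        ).fit()
        tab = sm.stats.anova_lm(model, typ=1)
        assert out.loc["EM", "SS"] == pytest.approx(tab.loc["C(EM)", "sum_sq"], abs=1e-10)
        assert out.loc["EM x SS", "SS"] == pytest.approx(
            tab.loc["C(EM):C(SS)", "sum_sq"], abs=1e-10
        )
        assert out.loc["residual", "SS"] == pytest.approx(
            tab.loc["Residual", "sum_sq"], abs=1e-10
        )
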