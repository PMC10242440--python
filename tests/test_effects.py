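"""Per-dataset linear models, SMD conversion and partial Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cohortmeta import fit_dataset_lm, partial_spearman, t_to_smd
from cohortmeta.effects import partial_spearman_matrix


def _meta(n, dataset="D1", sexes=None, sites=None, rng=None):
    rng = rng or np.random.default_rng(0)
    half = n // 2
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "dataset_id": dataset,
            "diet_class": ["high_fat"] * half + ["low_fat"] * (n - half),
            "fat_pct": [50.0] * half + [12.0] * (n - half),
            "duration_days": rng.uniform(20, 100, n),
            "age_days": rng.uniform(56, 140, n),
            "sex": sexes if sexes is not None else rng.choice(["f", "m"], n),
            "strain": "B6",
            "body_site": sites if sites is not None else ["feces"] * n,
            "antibiotics": False,
            "mouse_id": [f"m{i}" for i in range(n)],
            "timepoint": np.nan,
        }
    ).set_index("sample_id", drop=False)


def _features(values: np.ndarray, samples) -> pd.DataFrame:
    return pd.DataFrame(
        np.atleast_2d(values), index=[f"F{i}" for i in range(np.atleast_2d(values).shape[0])],
        columns=samples,
    )


class TestTtoSMD:
    def test_zero_t(self):
        d, se = t_to_smd(0.0, 10, 10, 18)
        assert d == 0.0
        assert se == pytest.approx(np.sqrt((19 / 17) * 4 / 20))

    def test_engineered_unit_d(self):
        d, _ = t_to_smd(2.1213203435596424, 10, 10, 18)
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_se_at_unit_d(self):
        # choose t so that d = 1 exactly, then se from the adjusted formula
        t = np.sqrt(10 * 10 * 18) / 20
        _, se = t_to_smd(t, 10, 10, 18)
        assert se == pytest.approx(np.sqrt((19 / 17) * (4 / 20) * 1.125), abs=1e-12)

    @given(st.floats(-50, 50), st.integers(2, 40), st.integers(2, 40))
    def test_odd_in_t(self, t, n1, n2):
        df = n1 + n2 - 2
        d_pos, se_pos = t_to_smd(t, n1, n2, df)
        d_neg, se_neg = t_to_smd(-t, n1, n2, df)
        assert d_neg == pytest.approx(-d_pos)
        assert se_neg == pytest.approx(se_pos)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            t_to_smd(1.0, 2, 1, 1)


class TestFitDatasetLM:
    def test_null_feature_gives_null_t(self):
        meta = _meta(40)
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 0.05, 40)  # independent of diet
        feats = _features(y, meta.index)
        [eff] = fit_dataset_lm(feats, meta, "D1", covariates=())
        assert abs(eff.t) < 2.5
        assert eff.n1 == 20 and eff.n2 == 20

    def test_zero_covariates_equals_pooled_t_test(self):
        meta = _meta(30)
        rng = np.random.default_rng(2)
        y = rng.normal(0.5, 0.1, 30) + 0.1 * (meta["diet_class"] == "high_fat")
        feats = _features(y.to_numpy(), meta.index)
        [eff] = fit_dataset_lm(feats, meta, "D1", covariates=())
        g = (meta["diet_class"] == "high_fat").to_numpy()
        t_ref, p_ref = stats.ttest_ind(y[g], y[~g], equal_var=True)
        assert eff.t == pytest.approx(float(t_ref), abs=1e-10)
        assert eff.p_wald == pytest.approx(float(p_ref), abs=1e-12)

    def test_matches_statsmodels_with_covariates(self):
        sm = pytest.importorskip("statsmodels.api")
        meta = _meta(36, sites=["feces", "cecum"] * 18)
        rng = np.random.default_rng(3)
        y = rng.normal(0.4, 0.05, 36)
        feats = _features(y, meta.index)
        covs = ("age_days", "sex", "body_site")
        [eff] = fit_dataset_lm(feats, meta, "D1", covariates=covs)
        from cohortmeta.effects import build_design

        x, names = build_design(meta, covs)
        fit = sm.OLS(y, x).fit()
        j = names.index("diet")
        assert eff.t == pytest.approx(float(fit.tvalues[j]), abs=1e-10)
        assert eff.df == int(fit.df_resid)

    def test_single_sex_dataset_drops_term(self):
        meta = _meta(24, sexes=["f"] * 24)
        rng = np.random.default_rng(4)
        feats = _features(rng.normal(0.4, 0.05, 24), meta.index)
        with pytest.warns(UserWarning, match="sex"):
            [eff] = fit_dataset_lm(feats, meta, "D1", covariates=("sex", "age_days"))
        assert eff.df == 24 - 3  # intercept + diet + age only

    def test_confounded_body_site_is_adjusted(self):
        # body site correlates with diet; adjustment recovers the diet effect
        rng = np.random.default_rng(5)
        n = 200
        meta = _meta(n)
        high = (meta["diet_class"] == "high_fat").to_numpy(float)
        site_cecum = (rng.random(n) < 0.2 + 0.6 * high)
        meta["body_site"] = np.where(site_cecum, "cecum", "feces")
        diet_beta, site_beta = 0.05, 0.2
        y = 0.4 + diet_beta * high + site_beta * site_cecum + rng.normal(0, 0.05, n)
        feats = _features(y, meta.index)
        [adj] = fit_dataset_lm(feats, meta, "D1", covariates=("body_site",))
        [unadj] = fit_dataset_lm(feats, meta, "D1", covariates=())
        assert unadj.d > adj.d  # confounding inflates the unadjusted effect
        assert adj.d == pytest.approx(diet_beta / 0.05, rel=0.35)

    def test_missing_diet_class_skips_dataset(self):
        meta = _meta(10)
        meta["diet_class"] = "high_fat"
        feats = _features(np.ones(10) * 0.2, meta.index)
        with pytest.warns(UserWarning, match="skipped"):
            assert fit_dataset_lm(feats, meta, "D1") == []

    def test_constant_feature_yields_missing_record(self):
        meta = _meta(12)
        feats = _features(np.full(12, 0.3), meta.index)
        with pytest.warns(UserWarning, match="constant"):
            assert fit_dataset_lm(feats, meta, "D1", covariates=()) == []

    def test_collinear_design_reported(self):
        meta = _meta(20)
        meta["dup"] = meta["age_days"]
        feats = _features(np.random.default_rng(0).normal(0.3, 0.02, 20), meta.index)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_dataset_lm(feats, meta, "D1", covariates=("age_days", "dup"))


def _oracle_partial_spearman(y, x, cov):
    """Rank everything, residualise by explicit matrix algebra, correlate."""
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    z = np.column_stack([np.ones(len(y))] + [stats.rankdata(c) for c in cov.T])
    beta_y = np.linalg.solve(z.T @ z, z.T @ ry)
    beta_x = np.linalg.solve(z.T @ z, z.T @ rx)
    ey, ex = ry - z @ beta_y, rx - z @ beta_x
    return float(ey @ ex / np.sqrt((ey @ ey) * (ex @ ex)))


class TestPartialSpearman:
    def test_monotone_identity(self):
        x = np.arange(10.0)
        rec = partial_spearman(np.exp(x), x)
        assert rec.rho == pytest.approx(1.0)

    def test_no_covariates_equals_spearman(self):
        rng = np.random.default_rng(7)
        y, x = rng.normal(size=50), rng.normal(size=50)
        rec = partial_spearman(y, x)
        rho_ref, p_ref = stats.spearmanr(y, x)
        assert rec.rho == pytest.approx(float(rho_ref), abs=1e-12)
        assert rec.p == pytest.approx(float(p_ref), abs=1e-6)

    def test_matches_matrix_algebra_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            cov = rng.normal(size=(n, 2))
            rec = partial_spearman(y, x, cov)
            assert rec.rho == pytest.approx(_oracle_partial_spearman(y, x, cov), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=["y", "x", "z1", "z2"])
        rec = partial_spearman(df["y"], df["x"], df[["z1", "z2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"], method="spearman")
        assert rec.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert rec.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_conditional_independence_gives_small_rho(self):
        rng = np.random.default_rng(10)
        rhos = []
        for _ in range(200):
            z = rng.normal(size=100)
            y = z + rng.normal(scale=0.5, size=100)
            x = z + rng.normal(scale=0.5, size=100)
            rhos.append(abs(partial_spearman(y, x, z[:, None]).rho))
        assert np.mean(rhos) < 0.1

    def test_constant_input_returns_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            rec = partial_spearman(np.ones(10), np.arange(10.0))
        assert np.isnan(rec.rho)

    def test_matrix_form_consistent_with_scalar(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(30, 5))
        x = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        rho, p = partial_spearman_matrix(Y, x, cov)
        for j in range(5):
            rec = partial_spearman(Y[:, j], x, cov)
            assert rho[j] == pytest.approx(rec.rho, abs=1e-12)
            assert p[j] == pytest.approx(rec.p, abs=1e-12)
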