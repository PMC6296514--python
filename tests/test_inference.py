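"""Hierarchical regression, LMG importance, and bootstrap contrasts."""

import numpy as np
import pandas as pd
import pytest

from readnet import (
    behavioral_summary,
    fit_hierarchical,
    fit_hierarchical_design,
    importance_contrasts,
    lmg_importance,
    lmg_shares,
    nested_f,
)
from readnet.inference import NUISANCE_COLS, build_design, connectivity_columns


def make_subjects(n, rng, pde=None):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:02d}" for i in range(n)],
            "age_months": rng.uniform(94, 164, n),
            "accuracy": rng.uniform(0.51, 0.85, n),
            "latency_ms": rng.uniform(900, 1863, n),
            "pde": rng.normal(90, 9, n) if pde is None else pde,
        }
    )


def make_metrics(n, rng, scheme="significance"):
    rows = []
    for i in range(n):
        for mod in ("VV", "AV", "AA"):
            rows.append(
                {
                    "subject_id": f"s{i:02d}",
                    "modality": mod,
                    "scheme": scheme,
                    "modularity": rng.uniform(0, 0.6),
                    "transitivity": rng.uniform(0.2, 0.9),
                    "global_efficiency": rng.uniform(0.3, 1.0),
                    "stage": "winsorized",
                }
            )
    return pd.DataFrame(rows)


class TestHierarchicalFit:
    def test_noiseless_linear_outcome_recovered_exactly(self, rng):
        subjects = make_subjects(24, rng)
        metrics = make_metrics(24, rng)
        X, _, added = build_design(subjects, metrics, "significance")
        betas = rng.normal(0, 2, size=len(added))
        subjects = subjects.assign(pde=5.0 + X[added].to_numpy() @ betas)
        fit = fit_hierarchical(subjects, metrics, "significance")
        assert fit.r2_step2 == pytest.approx(1.0, abs=1e-10)
        got = fit.coef_table.loc[added, "B"].to_numpy()
        assert np.allclose(got, betas, atol=1e-8)

    def test_nested_f_equals_rss_formulation_and_statsmodels(self, rng):
        subjects = make_subjects(24, rng)
        metrics = make_metrics(24, rng)
        fit = fit_hierarchical(subjects, metrics, "significance")
        # residual-sum-of-squares route
        rss1, rss2 = fit.step1.ssr, fit.step2.ssr
        q, df2 = fit.delta_df
        f_rss = ((rss1 - rss2) / q) / (rss2 / df2)
        assert fit.delta_f == pytest.approx(f_rss, abs=1e-10)
        # statsmodels' own nested comparison
        f_sm, p_sm, df_sm = fit.step2.compare_f_test(fit.step1)
        assert fit.delta_f == pytest.approx(f_sm, abs=1e-8)
        assert fit.delta_p == pytest.approx(p_sm, abs=1e-10)
        assert q == int(df_sm)
        # adjusted R2 identity
        n, p = fit.n, 12
        adj = 1 - (1 - fit.r2_step2) * (n - 1) / (n - p - 1)
        assert fit.adj_r2_step2 == pytest.approx(adj, abs=1e-12)

    def test_step2_r2_never_below_step1(self, rng):
        subjects = make_subjects(20, rng)
        metrics = make_metrics(20, rng)
        fit = fit_hierarchical(subjects, metrics, "significance")
        assert fit.r2_step2 >= fit.r2_step1

    def test_partial_r_matches_direct_residual_computation(self, rng):
        """Dual route: partial r from t stats vs correlating residuals."""
        subjects = make_subjects(24, rng)
        metrics = make_metrics(24, rng)
        fit = fit_hierarchical(subjects, metrics, "significance")
        X, y, added = build_design(subjects, metrics, "significance")
        Xc = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
        target = added[0]
        j = 1 + list(X.columns).index(target)
        others = np.delete(Xc, j, axis=1)
        ry = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        rx = Xc[:, j] - others @ np.linalg.lstsq(others, Xc[:, j], rcond=None)[0]
        expected = np.corrcoef(rx, ry)[0, 1]
        assert fit.coef_table.loc[target, "partial_r"] == pytest.approx(expected, abs=1e-8)

    def test_standardized_betas_scale_free(self, rng):
        subjects = make_subjects(24, rng)
        metrics = make_metrics(24, rng)
        fit_a = fit_hierarchical(subjects, metrics, "significance")
        rescaled = metrics.assign(modularity=metrics["modularity"] * 1000.0)
        fit_b = fit_hierarchical(subjects, rescaled, "significance")
        for mod in ("VV", "AV", "AA"):
            key = f"{mod}_modularity"
            assert fit_b.coef_table.loc[key, "beta"] == pytest.approx(
                fit_a.coef_table.loc[key, "beta"], abs=1e-10
            )

    def test_rank_deficiency_names_columns(self, rng):
        subjects = make_subjects(24, rng)
        metrics = make_metrics(24, rng)
        metrics["transitivity"] = 2.0 * metrics["modularity"]
        with pytest.raises(ValueError, match="transitivity|modularity"):
            fit_hierarchical(subjects, metrics, "significance")

    def test_too_small_cohort_rejected(self, rng):
        subjects = make_subjects(12, rng)
        metrics = make_metrics(12, rng)
        with pytest.raises(ValueError, match="too small"):
            fit_hierarchical(subjects, metrics, "significance")

    def test_nested_f_helper_validates_df(self):
        with pytest.raises(ValueError):
            nested_f(0.1, 0.5, 0, 10)


class TestLMG:
    def test_single_predictor_share_is_r2(self, rng):
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        X = pd.DataFrame({"x": x})
        res = lmg_importance(X, pd.Series(y))
        assert res.shares["x"] == pytest.approx(res.r_squared, abs=1e-12)

    def test_duplicated_predictors_share_equally(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40) * 0.5
        X = pd.DataFrame({"a": x, "b": x.copy()})
        shares = lmg_shares(X, pd.Series(y))
        assert shares["a"] == pytest.approx(shares["b"], abs=1e-10)

    def test_orthogonal_predictors_closed_form(self, rng):
        """With orthogonal predictors the LMG share of each is its squared
        outcome correlation, independently confirmed by enumerating both
        entry orders."""
        z = rng.normal(size=(200, 2))
        q, _ = np.linalg.qr(z - z.mean(axis=0))
        x1, x2 = q[:, 0], q[:, 1]
        y = 3.0 * x1 + 1.0 * x2 + rng.normal(size=200) * 0.1
        yc = y - y.mean()
        r1 = float(np.corrcoef(x1, y)[0, 1])
        r2 = float(np.corrcoef(x2, y)[0, 1])
        X = pd.DataFrame({"x1": x1, "x2": x2})
        shares = lmg_shares(X, pd.Series(y))
        assert shares["x1"] == pytest.approx(r1**2, abs=1e-10)
        assert shares["x2"] == pytest.approx(r2**2, abs=1e-10)

        # manual two-ordering enumeration
        def r2_of(cols):
            A = np.column_stack([np.ones(200)] + cols)
            resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            return 1.0 - resid @ resid / (yc @ yc)

        full = r2_of([x1, x2])
        manual_x1 = 0.5 * r2_of([x1]) + 0.5 * (full - r2_of([x2]))
        assert shares["x1"] == pytest.approx(manual_x1, abs=1e-10)

    def test_shares_sum_to_r2_and_nonnegative(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        y = pd.Series(X @ rng.normal(size=6) + rng.normal(size=30))
        res = lmg_importance(X, y)
        assert res.shares.sum() == pytest.approx(res.r_squared, abs=1e-10)
        assert (res.shares >= -1e-12).all()

    def test_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        y = pd.Series(X["a"] * 2 + X["c"] + rng.normal(size=25))
        shares = lmg_shares(X, y)
        shuffled = lmg_shares(X[["d", "b", "a", "e", "c"]], y)
        for c in "abcde":
            assert shuffled[c] == pytest.approx(shares[c], abs=1e-12)

    def test_normalized_shares_sum_to_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = pd.Series(X["a"] + rng.normal(size=30))
        assert lmg_shares(X, y, normalized=True).sum() == pytest.approx(1.0, abs=1e-12)

    def test_too_many_predictors_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 21)))
        X.columns = [f"p{i}" for i in range(21)]
        with pytest.raises(ValueError, match="20"):
            lmg_shares(X, pd.Series(rng.normal(size=40)))


class TestImportanceContrasts:
    def _design(self, rng, n=40, dominant=None):
        cols = {}
        for met in ("modularity", "transitivity", "global_efficiency"):
            for mod in ("VV", "AV", "AA"):
                cols[f"{mod}_{met}"] = rng.normal(size=n)
        X = pd.DataFrame(cols)
        y = rng.normal(size=n)
        if dominant:
            y = y + 3.0 * X[dominant]
        return X, pd.Series(y)

    def test_exactly_duplicated_pair_gives_null_contrast(self, rng):
        """An identical duplicated predictor pair has difference exactly 0
        and a CI that contains 0."""
        n = 60
        shared = rng.normal(size=n)
        X = pd.DataFrame(
            {
                "VV_modularity": shared,
                "AV_modularity": shared.copy(),
                "AA_modularity": rng.normal(size=n),
            }
        )
        y = pd.Series(shared + rng.normal(size=n))
        res = importance_contrasts(X, y, n_boot=200, seed=1)
        row = res.contrasts[res.contrasts.contrast == "modularity: VV-AV"].iloc[0]
        assert row["difference"] == pytest.approx(0.0, abs=1e-12)
        assert row["ci_low"] <= 0 <= row["ci_high"]
        assert not row["significant"]

    def test_dominant_predictor_detected(self, rng):
        """A predictor with a large planted share gap shows significant
        contrasts against its modality peers in nearly all replicates."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            n = 200
            X = pd.DataFrame(
                {f"{mod}_modularity": r.normal(size=n) for mod in ("VV", "AV", "AA")}
            )
            y = pd.Series(r.normal(size=n) + 3.0 * X["AV_modularity"])
            res = importance_contrasts(X, y, n_boot=300, seed=rep)
            gap = res.shares["AV_modularity"] - res.shares["VV_modularity"]
            assert gap > 0.3
            sub = res.contrasts[
                res.contrasts.contrast.isin(["modularity: VV-AV", "modularity: AV-AA"])
            ]
            hits += int(sub["significant"].all())
        assert hits >= int(0.95 * n_rep)

    def test_contrast_layouts_cover_both_tables(self, rng):
        X, y = self._design(rng)
        res = importance_contrasts(X, y, n_boot=50, seed=0)
        assert (res.contrasts.layout == "between_modalities").sum() == 9
        assert (res.contrasts.layout == "between_metrics").sum() == 9


class TestBehavioralSummary:
    def test_single_subject(self):
        df = pd.DataFrame(
            {"subject_id": ["s00"], "age_months": [120], "accuracy": [0.7],
             "latency_ms": [1200.0], "pde": [91.0]}
        )
        s = behavioral_summary(df)
        assert s["accuracy_mean"] == 0.7
        assert s["latency_mean_ms"] == 1200.0

    def test_mean_of_two(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b"], "age_months": [100, 110],
             "accuracy": [0.5, 0.7], "latency_ms": [1000.0, 1400.0],
             "pde": [80.0, 100.0]}
        )
        s = behavioral_summary(df)
        assert s["accuracy_mean"] == pytest.approx(0.6)
        assert s["accuracy_range"] == (0.5, 0.7)
        assert s["latency_mean_ms"] == pytest.approx(1200.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            behavioral_summary(pd.DataFrame(columns=["accuracy", "latency_ms"]))
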