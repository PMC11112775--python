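import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from admixsib import (
    PhenotypeGenConfig,
    SibPair,
    build_pair_diffs,
    estimate_effects,
    fdr_adjust,
    fit_model_1a,
    fit_model_1b,
    fit_model_2,
    quantile_transform,
    simulate_phenotypes,
    simulate_population,
)
from admixsib.estimators import multi_response_ols


def _sib_table(n_families=60, seed=0, **pheno_kwargs):
    pop = simulate_population(n_families, seed=seed)
    ped = pop.pedigree_frame()
    off = [i.iid for i in pop.offspring]
    sibs = ped.loc[off].copy()
    cfg = PhenotypeGenConfig(**pheno_kwargs)
    sibs = simulate_phenotypes(sibs, cfg)
    sibs = sibs.rename(columns={"q_true": "q"})
    pairs = pop.sibling_pairs()
    return sibs, pairs


class TestQuantileTransform:
    def test_blom_closed_form_n3(self):
        z = quantile_transform(np.array([1.0, 2.0, 3.0]))
        expected = ndtri((np.array([1, 2, 3]) - 0.375) / (3 - 0.75 + 1))
        assert np.allclose(z, expected)
        assert z[1] == pytest.approx(0.0, abs=1e-12)
        assert z[2] == pytest.approx(0.8694, abs=2e-4)

    def test_monotone_and_tie_handling(self):
        z = quantile_transform(np.array([5.0, 1.0, 3.0, 3.0, 9.0]))
        assert z[2] == z[3]
        order_in = np.argsort([5.0, 1.0, 3.0, 3.0, 9.0])
        assert np.all(np.diff(z[order_in]) >= 0)

    def test_missing_propagates(self):
        z = quantile_transform(np.array([1.0, np.nan, 2.0, 3.0]))
        assert np.isnan(z[1]) and not np.isnan(z[0])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            quantile_transform(np.array([2.0, 2.0, 2.0]))


class TestModel1a:
    def test_noiseless_recovers_slope(self):
        sibs, _ = _sib_table(dg=3.0, sigma=0.0, seed=1)
        est = fit_model_1a(sibs)
        assert est.coef == pytest.approx(3.0, abs=1e-9)
        assert est.effect_per_pct == pytest.approx(0.03, abs=1e-11)

    def test_family_environment_biases_delta_y(self):
        sibs, _ = _sib_table(
            dg=1.0, sigma=0.2, e_anc=2.0, e_anc_mode="family", seed=2, n_families=150
        )
        est = fit_model_1a(sibs)
        assert est.coef > 2.0  # absorbs the environmental gradient

    def test_matches_normal_equations_oracle(self):
        """Coefficients agree with an independently coded least-squares solve."""
        rng = np.random.default_rng(3)
        for _ in range(20)          :
            n = int(rng.integers(20, 60))
            df = pd.DataFrame(
                {
                    "y": rng.normal(size=n),
                    "q": rng.uniform(size=n),
                    "age": rng.uniform(18, 80, n),
                    "sex": rng.integers(0, 2, n),
                }
            )
            est = fit_model_1a(df)
            X = np.column_stack([np.ones(n), df["q"], df["age"], df["sex"]])
            beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
            assert est.coef == pytest.approx(beta[1], rel=1e-10, abs=1e-12)

    def test_collinear_design_named(self):
        df = pd.DataFrame(
            {"y": [1.0, 2, 3, 4], "q": [0.5] * 4, "age": [30.0, 40, 50, 60],
             "sex": [0, 1, 0, 1]}
        )
        with pytest.raises(ValueError, match="q"):
            fit_model_1a(df)


class TestModel1b:
    def test_noiseless_recovers_dg(self):
        sibs, pairs = _sib_table(dg=2.0, sigma=0.0, seed=4)
        pd_df = build_pair_diffs(pairs, sibs.set_index("iid"))
        est = fit_model_1b(pd_df)
        assert est.coef == pytest.approx(2.0, abs=1e-9)

    def test_individual_mode_exact_shift(self):
        """With individual-level interaction and no noise, the slope is
        exactly dG + E_anc."""
        sibs, pairs = _sib_table(
            dg=1.0, sigma=0.0, e_anc=0.5, e_anc_mode="individual", seed=5
        )
        est = fit_model_1b(build_pair_diffs(pairs, sibs.set_index("iid")))
        assert est.coef == pytest.approx(1.5, rel=1e-8)

    def test_family_mode_unbiased(self):
        """Family-level environment cancels in within-pair differencing."""
        reps = []
        for s in range(30):
            sibs, pairs = _sib_table(
                n_families=80, dg=1.0, sigma=1.0, e_anc=2.0, e_anc_mode="family", seed=s
            )
            est = fit_model_1b(build_pair_diffs(pairs, sibs.set_index("iid")))
            reps.append(est.coef)
        se = np.std(reps) / np.sqrt(len(reps))
        assert np.mean(reps) == pytest.approx(1.0, abs=3 * se + 0.05)

    def test_sibling_order_invariance(self):
        """Swapping the order of every pair leaves the slope unchanged."""
        sibs, pairs = _sib_table(dg=1.5, sigma=0.5, seed=6)
        t = sibs.set_index("iid")
        est1 = fit_model_1b(build_pair_diffs(pairs, t))
        swapped = [(b, a) for a, b in pairs]
        est2 = fit_model_1b(build_pair_diffs(swapped, t))
        assert est1.coef == pytest.approx(est2.coef, rel=1e-12)
        assert est1.se == pytest.approx(est2.se, rel=1e-12)

    def test_zero_dq_rejected(self):
        df = pd.DataFrame(
            {"dy": np.arange(8.0), "dq": 0.0, "dage": np.arange(8.0) / 2,
             "age1": 30.0, "dsex": 0, "sex1": 1}
        )
        with pytest.raises(ValueError, match="ancestry differences"):
            fit_model_1b(df)

    def test_coverage_of_95_ci(self):
        """Across replicates the 95% CI for the Delta-G slope covers truth at
        the nominal rate (single-pair families, so pair differences are
        independent; correlated multi-pair families are model 2's job)."""
        pop = simulate_population(150, sibs_per_family={2: 1.0}, seed=7)
        ped = pop.pedigree_frame()
        off = [i.iid for i in pop.offspring]
        sibs = ped.loc[off].copy().rename(columns={"q_true": "q"})
        pairs = pop.sibling_pairs()
        t = sibs.set_index("iid", drop=False)
        loc = {iid: k for k, iid in enumerate(t.index)}
        i1 = np.array([loc[min(a, b)] for a, b in pairs])
        i2 = np.array([loc[max(a, b)] for a, b in pairs])
        q = t["q"].to_numpy()
        age, sex = t["age"].to_numpy(), t["sex"].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(i1)), q[i1] - q[i2], age[i1] - age[i2], age[i1],
             sex[i1] - sex[i2], sex[i1]]
        )
        rng = np.random.default_rng(8)
        n_reps = 800
        dg = 1.0
        Y = q[:, None] * dg + rng.standard_normal((len(q), n_reps))
        dY = Y[i1] - Y[i2]
        B, SE = multi_response_ols(X, dY)
        cover = np.abs(B[1] - dg) <= 1.96 * SE[1]
        assert 0.93 <= cover.mean() <= 0.97

    def test_multi_response_ols_matches_single_fit(self):
        sibs, pairs = _sib_table(dg=1.0, sigma=1.0, seed=9)
        pdf = build_pair_diffs(pairs, sibs.set_index("iid"))
        X = np.column_stack(
            [np.ones(len(pdf)), pdf["dq"], pdf["dage"], pdf["age1"], pdf["dsex"], pdf["sex1"]]
        )
        B, SE = multi_response_ols(X, pdf["dy"].to_numpy()[:, None])
        est = fit_model_1b(pdf)
        assert B[1, 0] == pytest.approx(est.coef, rel=1e-10)
        assert SE[1, 0] == pytest.approx(est.se, rel=1e-10)


class TestModel2:
    def test_noiseless_within_equals_between_equals_dg(self):
        import warnings

        sibs, _ = _sib_table(dg=2.0, sigma=0.0, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate zero-variance fit may warn
            within, between = fit_model_2(sibs)
        assert within.coef == pytest.approx(2.0, abs=1e-6)
        assert between.coef == pytest.approx(2.0, abs=1e-6)

    def test_within_close_to_model_1b_for_two_sib_families(self):
        """With only two-sibling families, the within-family mixed-model slope
        tracks the pair-difference slope across replicates."""
        diffs = []
        for s in range(25):
            pop = simulate_population(
                100, sibs_per_family={2: 1.0}, seed=100 + s
            )
            ped = pop.pedigree_frame()
            off = [i.iid for i in pop.offspring]
            sibs = ped.loc[off].copy()
            sibs = simulate_phenotypes(sibs, PhenotypeGenConfig(dg=1.0, sigma=1.0, seed=s))
            sibs = sibs.rename(columns={"q_true": "q"})
            w, _ = fit_model_2(sibs)
            est1b = fit_model_1b(
                build_pair_diffs(pop.sibling_pairs(), sibs.set_index("iid"))
            )
            diffs.append(w.coef - est1b.coef)
        # both estimators target the same quantity: paired comparison of the
        # replicate means is within Monte-Carlo error of zero
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 0.05

    def test_family_mode_between_biased_within_not(self):
        reps_w, reps_b = [], []
        for s in range(15):
            sibs, _ = _sib_table(
                n_families=80, dg=1.0, sigma=0.5, e_anc=2.0, e_anc_mode="family",
                seed=200 + s,
            )
            w, b = fit_model_2(sibs)
            reps_w.append(w.coef)
            reps_b.append(b.coef)
        assert np.mean(reps_b) > 2.0  # absorbs E_anc * Qbar
        se_w = np.std(reps_w) / np.sqrt(len(reps_w))
        assert np.mean(reps_w) == pytest.approx(1.0, abs=3 * se_w + 0.05)

    def test_requires_multisib_families(self):
        df = pd.DataFrame(
            {"y": [1.0, 2.0], "q": [0.5, 0.6], "fid": ["a", "b"],
             "age": [30, 40], "sex": [0, 1]}
        )
        with pytest.raises(ValueError):
            fit_model_2(df)


class TestFdr:
    def test_hand_computed_step_up(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_equal_inputs_unchanged(self):
        assert np.allclose(fdr_adjust([0.3, 0.3, 0.3]), 0.3)
        assert np.allclose(fdr_adjust([0.07]), [0.07])

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=30)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(size=25)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr_adjust(p), adj_sm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestEffectsTable:
    def test_table_layout_and_fdr(self):
        sibs, pairs = _sib_table(n_families=80, dg=1.0, sigma=1.0, seed=13)
        sibs["y2"] = sibs["y"] + np.random.default_rng(14).normal(size=len(sibs))
        t = sibs.set_index("iid", drop=False)
        res = estimate_effects(t, [SibPair(a, b) for a, b in pairs], ["y", "y2"])
        assert set(res["model"]) == {"1a", "1b", "2-within", "2-between"}
        assert (res["p_fdr"] >= res["p"] - 1e-12).all()
        # per-percent convention: raw effect is 100x the per-pct effect
        assert np.allclose(res["effect_raw"], 100 * res["effect_per_pct"])

    def test_inclusion_mask_respected(self):
        sibs, pairs = _sib_table(n_families=60, dg=1.0, sigma=1.0, seed=15)
        t = sibs.set_index("iid", drop=False)
        mask = pd.Series(False, index=t.index)
        mask.iloc[: len(mask) // 2] = True
        res = estimate_effects(
            t, [SibPair(a, b) for a, b in pairs], ["y"],
            include={"y": mask}, run_model_2=False,
        )
        assert res.loc[res["model"] == "1a", "n"].iloc[0] == mask.sum()
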