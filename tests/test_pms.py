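"""Polymethylation scoring: regions, pruning, scores, PC1, logistic evaluation."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from stratewas.config import CohortConfig, ComethConfig, PmsConfig
from stratewas.containers import BetaMatrix
from stratewas.exceptions import DegenerateInputError, InputError, SeparationError
from stratewas.pms import (
    build_cometh_regions,
    compare_models,
    compute_pms_matrix,
    evaluate_pms,
    pms_pc1,
    prune_regions,
)
from stratewas.synth import simulate_cohort


def beta_matrix_from_values(vals: np.ndarray, spacing: int = 300) -> BetaMatrix:
    n = vals.shape[0]
    idx = pd.Index([f"cg{i:06d}" for i in range(n)], name="probe")
    annot = pd.DataFrame({"chrom": "chr1", "pos": 1 + np.arange(n) * spacing, "gene": "G"},
                         index=idx)
    return BetaMatrix(pd.DataFrame(vals, index=idx,
                                   columns=[f"s{j}" for j in range(vals.shape[1])]), annot)


def correlated_pair(rng, n_samples, r, base=0.5, sd=0.05):
    """Two probe rows with Pearson correlation close to r (then exactified)."""
    x = rng.standard_normal(n_samples)
    y = r * x + np.sqrt(1 - r**2) * rng.standard_normal(n_samples)
    # orthogonalize to make the sample correlation exactly r
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    y = r * x + np.sqrt(1 - r**2) * (y - (y @ x) / n_samples * x) / np.sqrt(
        max(1e-12, 1 - ((y @ x) / n_samples) ** 2))
    return base + sd * x, base + sd * y


class TestComethRegions:
    def test_shared_latent_factor_forms_one_region(self):
        rng = np.random.default_rng(0)
        n_s = 200
        latent = rng.standard_normal(n_s)
        vals = 0.5 + 0.02 * rng.standard_normal((6, n_s))
        for i in (1, 2, 3):  # three adjacent probes share the factor, R^2 ~ 0.9
            vals[i] = 0.5 + 0.05 * (0.95 * latent + 0.3 * rng.standard_normal(n_s))
        regions = build_cometh_regions(beta_matrix_from_values(vals))
        assert len(regions) == 1
        assert list(regions[0]) == ["cg000001", "cg000002", "cg000003"]

    def test_r2_boundary_is_strict(self):
        rng = np.random.default_rng(1)
        n_s = 400
        for r2, expect_regions in ((0.29, 0), (0.32, 1)):
            a, b = correlated_pair(rng, n_s, np.sqrt(r2))
            vals = np.vstack([a, b])
            got = build_cometh_regions(beta_matrix_from_values(vals),
                                       ComethConfig(r2_threshold=0.3))
            assert len(got) == expect_regions, r2

    def test_gap_rule_blocks_distant_pairs(self):
        rng = np.random.default_rng(2)
        a, b = correlated_pair(rng, 200, 0.95)
        bm = beta_matrix_from_values(np.vstack([a, b]), spacing=1500)  # > 1000 bp
        assert build_cometh_regions(bm) == []

    def test_iid_probes_rarely_form_regions(self):
        false_regions = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            vals = 0.5 + 0.05 * rng.standard_normal((500, 400))
            false_regions += len(build_cometh_regions(beta_matrix_from_values(vals)))
        assert false_regions <= 1


class TestPruning:
    def test_keeps_minimum_p_probe_per_region(self):
        stats_table = pd.DataFrame({"probe": ["a", "b", "c", "d"],
                                    "p": [1e-5, 1e-3, 0.2, 0.9]})
        kept = prune_regions([np.array(["a", "b", "c"])], stats_table,
                             all_probes=["a", "b", "c", "d"])
        assert list(kept) == ["a", "d"]

    def test_ties_break_to_first_coordinate(self):
        stats_table = pd.DataFrame({"probe": ["a", "b"], "p": [0.01, 0.01]})
        kept = prune_regions([np.array(["a", "b"])], stats_table, all_probes=["a", "b"])
        assert list(kept) == ["a"]

    def test_missing_probes_treated_as_p_one(self):
        stats_table = pd.DataFrame({"probe": ["b"], "p": [0.5]})
        kept = prune_regions([np.array(["a", "b"])], stats_table, all_probes=["a", "b"])
        assert list(kept) == ["b"]

    def test_no_regions_is_identity(self):
        stats_table = pd.DataFrame({"probe": ["a"], "p": [0.5]})
        kept = prune_regions([], stats_table, all_probes=["a", "b"])
        assert list(kept) == ["a", "b"]


class TestScoreMatrix:
    def make_target(self, rng, n_probes=20, n_samples=50):
        vals = np.clip(0.5 + 0.05 * rng.standard_normal((n_probes, n_samples)), 0, 1)
        return beta_matrix_from_values(vals)

    def test_single_passing_probe_column_proportional(self):
        rng = np.random.default_rng(3)
        bm = self.make_target(rng)
        train = pd.DataFrame({"probe": bm.probe_ids, "effect": 2.0,
                              "p": np.r_[1e-7, np.full(19, 0.9)]})
        cfg = PmsConfig(thresholds=(0.5, 5e-2, 5e-4))
        scores = compute_pms_matrix(bm, train, bm.probe_ids, cfg)
        m = bm.values.iloc[0].to_numpy()
        mz = (m - m.mean()) / m.std()
        col = scores["S_0.0005"].to_numpy()
        assert abs(np.corrcoef(col, mz)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_training_effects(self):
        rng = np.random.default_rng(4)
        bm = self.make_target(rng)
        train = pd.DataFrame({"probe": bm.probe_ids,
                              "effect": rng.standard_normal(20),
                              "p": rng.uniform(size=20)})
        s1 = compute_pms_matrix(bm, train, bm.probe_ids)
        train2 = train.assign(effect=train["effect"] * 2)
        s2 = compute_pms_matrix(bm, train2, bm.probe_ids)
        pd.testing.assert_frame_equal(s1, s2)

    def test_planted_effects_shift_case_scores(self):
        """Cases score higher when training signs match planted effects."""
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(500 + seed)
            causal = np.arange(0, 100, 5)
            cfg = CohortConfig(n_cases=100, n_controls=100, n_probes=100, n_causal=0,
                               seed=int(rng.integers(2**31)))
            eff = np.full(len(causal), 2.0)
            bm, sheet = simulate_cohort(cfg, causal_index=causal,
                                        effects_male=eff, effects_female=eff)
            p = np.full(100, 0.9)
            p[causal] = 1e-5
            train = pd.DataFrame({"probe": bm.probe_ids, "effect": np.where(np.isin(np.arange(100), causal), 2.0, 0.0), "p": p})
            scores = compute_pms_matrix(bm, train, bm.probe_ids,
                                        PmsConfig(thresholds=(0.5, 5e-4)))
            col = scores["S_0.0005"]
            is_case = (sheet.set_index("sample_id").loc[bm.sample_ids, "status"] == "case").to_numpy()
            wins += col[is_case].mean() > col[~is_case].mean()
        assert wins >= 45

    def test_no_probe_under_any_threshold_raises(self):
        rng = np.random.default_rng(5)
        bm = self.make_target(rng)
        train = pd.DataFrame({"probe": bm.probe_ids, "effect": 1.0, "p": 1.0})
        with pytest.raises(DegenerateInputError):
            compute_pms_matrix(bm, train, bm.probe_ids, PmsConfig(thresholds=(0.5, 5e-4)))


class TestPc1:
    def test_identical_columns_rank_one(self):
        rng = np.random.default_rng(6)
        col = rng.standard_normal(100)
        scores = pd.DataFrame({f"S{i}": col for i in range(6)})
        pms, frac = pms_pc1(scores)
        assert frac == pytest.approx(1.0, abs=1e-9)
        assert abs(np.corrcoef(pms, col)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_columns_variance_fraction(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(rng.standard_normal((1000, 6)),
                              columns=[f"S{i}" for i in range(6)])
        _, frac = pms_pc1(scores)
        assert frac == pytest.approx(1 / 6, abs=0.05)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((200, 4))
        scores = pd.DataFrame(base, columns=list("abcd"))
        pms1, _ = pms_pc1(scores)
        pms2, _ = pms_pc1(-scores)
        assert np.allclose(pms1, pms2) or np.allclose(pms1, -pms2)
        # orientation rule: positive correlation with the column mean
        assert np.corrcoef(pms1, scores.mean(axis=1))[0, 1] > 0

    def test_constant_columns_rejected(self):
        scores = pd.DataFrame({"a": np.ones(50), "b": np.ones(50)})
        with pytest.raises(DegenerateInputError):
            pms_pc1(scores)


def nagelkerke_oracle(y, x):
    """Direct likelihood evaluation: brute-force 2-parameter logistic MLE."""
    def nll(theta, X):
        eta = X @ theta
        return np.sum(np.log1p(np.exp(eta)) - y * eta)

    X1 = np.column_stack([np.ones(len(y)), x])
    r1 = optimize.minimize(nll, np.zeros(2), args=(X1,), method="BFGS")
    r0 = optimize.minimize(nll, np.zeros(1), args=(np.ones((len(y), 1)),), method="BFGS")
    n = len(y)
    l1, l0 = -r1.fun, -r0.fun
    return (1 - np.exp((2 / n) * (l0 - l1))) / (1 - np.exp((2 / n) * l0))


class TestEvaluate:
    def test_null_pms_r2_near_zero(self):
        r2s = []
        for seed in range(50):
            rng = np.random.default_rng(900 + seed)
            pms = pd.Series(rng.standard_normal(1000))
            status = rng.permutation(np.r_[np.ones(500), np.zeros(500)])
            r2s.append(evaluate_pms(pms, status).nagelkerke_r2)
        assert np.mean(r2s) < 0.01

    def test_matches_likelihood_oracle_on_tiny_fixture(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(20)
        y = (x + 0.5 * rng.standard_normal(20) > 0).astype(float)
        x_z = (x - x.mean()) / x.std()
        ev = evaluate_pms(pd.Series(x), y)
        assert ev.nagelkerke_r2 == pytest.approx(nagelkerke_oracle(y, x_z), abs=1e-8)

    def test_constant_covariate_changes_only_penalty(self):
        rng = np.random.default_rng(11)
        pms = pd.Series(rng.standard_normal(200))
        y = (pms + rng.standard_normal(200) > 0).astype(float).to_numpy()
        base = evaluate_pms(pms, y)
        const_col = pd.DataFrame({"c": np.full(200, 3.0)})  # redundant with intercept
        with_cov = evaluate_pms(pms, y, covariates=const_col)
        assert with_cov.nagelkerke_r2 == pytest.approx(base.nagelkerke_r2, abs=1e-8)
        assert with_cov.aic - base.aic == pytest.approx(2.0, abs=1e-6)
        assert with_cov.bic - base.bic == pytest.approx(np.log(200), abs=1e-6)

    def test_perfect_separation_flagged(self):
        pms = pd.Series(np.r_[np.linspace(-3, -1, 25), np.linspace(1, 3, 25)])
        y = np.r_[np.zeros(25), np.ones(25)]
        with pytest.raises(SeparationError):
            evaluate_pms(pms, y)


class TestCompareModels:
    def _fit(self, rng, signal):
        n = 1000
        pms = pd.Series(rng.standard_normal(n))
        y = ((signal * pms + rng.standard_normal(n)) > 0).astype(float).to_numpy()
        return y, pms

    def test_model_vs_itself_is_null(self):
        rng = np.random.default_rng(12)
        y, pms = self._fit(rng, 1.0)
        ev = evaluate_pms(pms, y)
        z, p = compare_models(ev, ev)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        n = 500
        y = rng.integers(0, 2, n).astype(float)
        ev_a = evaluate_pms(pd.Series(rng.standard_normal(n)), y)
        ev_b = evaluate_pms(pd.Series(rng.standard_normal(n)), y)
        z1, p1 = compare_models(ev_a, ev_b)
        z2, p2 = compare_models(ev_b, ev_a)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_informative_beats_noise(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(1400 + seed)
            n = 1000
            good = pd.Series(rng.standard_normal(n))
            y = ((0.8 * good + rng.standard_normal(n)) > 0).astype(float).to_numpy()
            noise = pd.Series(rng.standard_normal(n))
            z, p = compare_models(evaluate_pms(good, y), evaluate_pms(noise, y))
            wins += (p < 0.05) and (z > 0)
        assert wins >= 40

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(15)
        y1 = rng.integers(0, 2, 100).astype(float)
        y2 = rng.integers(0, 2, 200).astype(float)
        ev_a = evaluate_pms(pd.Series(rng.standard_normal(100)), y1)
        ev_b = evaluate_pms(pd.Series(rng.standard_normal(200)), y2)
        with pytest.raises(InputError):
            compare_models(ev_a, ev_b)
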