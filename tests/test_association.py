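"""Surrogate variables, per-analyte OLS, BH-FDR, effect-size comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from npqflow import (
    CohortSimConfig,
    ProteomicsMatrix,
    adjust_fdr,
    compare_effect_sizes,
    estimate_surrogate_variables,
    fit_associations,
    simulate_cohort,
)
from npqflow.association import _design_for_contrast


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini–Hochberg step-up: p_(i) -> min_{j>=i} m p_(j)/j."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def design_and_matrix(cfg):
    m, meta, truth = simulate_cohort(cfg)
    sub, covar = _design_for_contrast(meta, "AD_vs_CO")
    subm = ProteomicsMatrix(m.values.reindex(covar.index), m.scale)
    return m, meta, truth, covar, subm


class TestSurrogateVariables:
    def test_batch_recovery_canonical_correlation(self):
        """Estimated SVs span the true 2-factor batch space (CCA >= 0.9)."""
        cfg = CohortSimConfig(
            seed=2,
            n_per_group={"AD": 200, "CO": 200, "DLB": 0, "FTD": 0, "PD": 0},
            n_analytes=100,
            missing_rate=0.0,
            outlier_rate=0.0,
            batch_loading_sd=0.3,
        )
        m, meta, truth, covar, subm = design_and_matrix(cfg)
        svs = estimate_surrogate_variables(subm, covar, n_sv=2, seed=2)
        bt = truth["batch_factors"].reindex(covar.index).to_numpy()
        qa, _ = np.linalg.qr(svs.to_numpy() - svs.to_numpy().mean(0))
        qb, _ = np.linalg.qr(bt - bt.mean(0))
        cca = np.linalg.svd(qa.T @ qb, compute_uv=False)
        assert cca.min() >= 0.9

    def test_zero_batch_svs_are_inert(self):
        """Without batch structure, adding SVs barely moves the betas."""
        from npqflow.simulate import default_analyte_ids

        eff0 = pd.DataFrame(
            0.0, index=default_analyte_ids(40), columns=["AD", "DLB", "FTD", "PD"]
        )
        deltas = []
        for seed in range(5):
            cfg = CohortSimConfig(
                seed=seed,
                n_per_group={"AD": 150, "CO": 150, "DLB": 0, "FTD": 0, "PD": 0},
                n_analytes=40,
                effect_matrix=eff0,
                missing_rate=0.0,
                outlier_rate=0.0,
                batch_loading_sd=0.0,
            )
            m, meta, truth, covar, subm = design_and_matrix(cfg)
            svs = estimate_surrogate_variables(subm, covar, seed=seed)
            with_sv = fit_associations(m, meta, "AD_vs_CO", svs=svs)
            without = fit_associations(m, meta, "AD_vs_CO", svs=None)
            j = with_sv.merge(without, on="analyte_id", suffixes=("_sv", "_0"))
            j = j[~j["degenerate_sv"]]
            deltas.append(
                (np.abs(j["beta_sv"] - j["beta_0"]) / j["se_0"]).mean()
            )
        assert np.mean(deltas) < 0.5

    def test_svs_centered_orthogonal_and_deterministic(self, small_cohort):
        m, meta, truth = small_cohort
        sub, covar = _design_for_contrast(meta, "AD_vs_CO")
        subm = ProteomicsMatrix(m.values.reindex(covar.index), m.scale)
        sv1 = estimate_surrogate_variables(subm, covar, seed=7)
        sv2 = estimate_surrogate_variables(subm, covar, seed=7)
        pd.testing.assert_frame_equal(sv1, sv2)
        assert abs(sv1.mean()).max() < 1e-8
        dot = sv1["sv1"] @ sv1["sv2"]
        assert abs(dot) < 1e-8

    def test_n_sv_bound(self, tiny_matrix):
        covar = pd.DataFrame(
            {"predictor": np.zeros(20), "age_at_draw": np.arange(20.0),
             "male": np.zeros(20)},
            index=tiny_matrix.sample_ids,
        )
        with pytest.raises(ValueError):
            estimate_surrogate_variables(tiny_matrix, covar, n_sv=10)


class TestFitAssociations:
    def test_zero_svs_equal_no_svs(self, small_cohort):
        """All-zero SV columns leave the fit coefficient-wise unchanged."""
        m, meta, truth = small_cohort
        zeros = pd.DataFrame(0.0, index=m.sample_ids, columns=["sv1", "sv2"])
        with_z = fit_associations(m, meta, "AD_vs_CO", svs=zeros)
        without = fit_associations(m, meta, "AD_vs_CO", svs=None)
        np.testing.assert_allclose(
            with_z["beta"], without["beta"], atol=1e-10
        )
        np.testing.assert_allclose(with_z["se"], without["se"], atol=1e-10)

    def test_constant_analyte_flagged(self, small_cohort):
        m, meta, truth = small_cohort
        v = m.values.copy()
        v["CONST"] = 1.0
        m2 = ProteomicsMatrix(v, m.scale)
        tab = fit_associations(m2, meta, "AD_vs_CO").set_index("analyte_id")
        row = tab.loc["CONST"]
        assert row["degenerate"] and row["beta"] == 0.0 and np.isnan(row["p_raw"])

    def test_small_contrast_warns_but_fits(self, small_cohort):
        m, meta, truth = small_cohort
        with pytest.warns(UserWarning, match="cases"):
            tab = fit_associations(m, meta, "PD_vs_CO")
        assert len(tab) == m.shape[1]

    def test_phenotype_contrast_uses_available_samples(self, small_cohort):
        m, meta, truth = small_cohort
        tab = fit_associations(m, meta, "amyloid_pet")
        n_avail = meta["amyloid_pet"].notna().sum()
        assert (tab["n_used"] <= n_avail).all()
        assert tab["n_used"].max() >= n_avail - m.values.isna().sum().max()


class TestFDR:
    def test_hand_stepup(self):
        tab = pd.DataFrame({"p_raw": [0.01, 0.02, 0.03, 0.04]})
        out = adjust_fdr(tab)
        np.testing.assert_allclose(out["p_fdr"], [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        out = adjust_fdr(pd.DataFrame({"p_raw": [0.5]}))
        assert out["p_fdr"].iloc[0] == 0.5

    def test_oracle_equivalence_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(1e-12, 1.0, rng.integers(1, 40))
            got = adjust_fdr(pd.DataFrame({"p_raw": p}))["p_fdr"].to_numpy()
            np.testing.assert_allclose(got, bh_stepup_oracle(p), rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr(pd.DataFrame({"p_raw": [0.0, 0.5]}))
        with pytest.raises(ValueError):
            adjust_fdr(pd.DataFrame({"p_raw": [1.5]}))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1, 50)
        a = adjust_fdr(pd.DataFrame({"p_raw": p, "analyte_id": range(50)}))
        perm = rng.permutation(50)
        b = adjust_fdr(
            pd.DataFrame({"p_raw": p[perm], "analyte_id": np.arange(50)[perm]})
        )
        merged = a.merge(b, on="analyte_id")
        np.testing.assert_allclose(merged["p_fdr_x"], merged["p_fdr_y"])


def fake_table(betas, ps, contrast="A"):
    return pd.DataFrame(
        {
            "analyte_id": [f"an{i}" for i in range(len(betas))],
            "contrast": contrast,
            "beta": betas,
            "se": 0.01,
            "p_raw": ps,
            "p_fdr": ps,
        }
    )


class TestCompareEffects:
    def test_self_comparison(self):
        rng = np.random.default_rng(0)
        t = fake_table(rng.normal(0, 0.1, 30), rng.uniform(1e-6, 0.04, 30))
        res = compare_effect_sizes(t, t)
        assert res["r"] == pytest.approx(1.0)
        assert res["band_outliers"] == []
        assert res["discordant_sign"] == []

    def test_planted_discordant_flagged(self):
        """Opposite-sign analytes at 4x residual SD always leave the band."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            base = rng.normal(0, 0.12, n)
            # planted discordant proteins carry a real effect in both tables
            base[:3] = np.sign(base[:3]) * np.maximum(np.abs(base[:3]), 0.1)
            noise_sd = 0.02
            bb = base + rng.normal(0, noise_sd, n)
            # plant 3 discordant analytes: flip sign and push 4x residual SD
            for i in range(3):
                bb[i] = -base[i] - np.sign(base[i]) * 4 * noise_sd
            ta = fake_table(base, np.full(n, 1e-4), "A")
            tb = fake_table(bb, np.full(n, 1e-4), "B")
            res = compare_effect_sizes(ta, tb)
            flagged = {a for a, _ in res["band_outliers"]}
            assert {f"an{i}" for i in range(3)} <= flagged

    def test_discordant_sign_list(self):
        ta = fake_table([0.2, -0.3, 0.1, 0.4], [0.001] * 4)
        tb = fake_table([0.2, 0.3, 0.1, 0.4], [0.001] * 4)
        res = compare_effect_sizes(ta, tb)
        assert res["discordant_sign"] == ["an1"]

    def test_too_few_shared_is_error(self):
        ta = fake_table([0.1, 0.2], [0.01, 0.01])
        with pytest.raises(ValueError, match=">= 3"):
            compare_effect_sizes(ta, ta)

    def test_r_symmetric_under_swap(self):
        rng = np.random.default_rng(4)
        ta = fake_table(rng.normal(0, 0.1, 40), rng.uniform(1e-5, 0.04, 40), "A")
        tb = fake_table(rng.normal(0, 0.1, 40), rng.uniform(1e-5, 0.04, 40), "B")
        assert compare_effect_sizes(ta, tb)["r"] == pytest.approx(
            compare_effect_sizes(tb, ta)["r"]
        )
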