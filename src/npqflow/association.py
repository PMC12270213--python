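"""Differential abundance with surrogate-variable adjustment.

Per analyte, log10 NPQ is regressed on the contrast predictor (a case
indicator with controls as reference, or a continuous endophenotype) plus
age at draw, sex, and the first two surrogate variables.  Surrogate
variables are estimated by residual SVD: each analyte is residualized on
the primary design and the top singular directions of the standardized
residual matrix absorb latent batch/technical structure.  P-values are
two-sided t-tests; multiplicity is handled with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .matrix import ProteomicsMatrix

DISEASE_CONTRASTS = ("AD_vs_CO", "DLB_vs_CO", "FTD_vs_CO", "PD_vs_CO")
PHENOTYPE_CONTRASTS = ("amyloid_pet", "tau_pet", "csf_ab_ratio", "cdr")


class SurrogateVariableEstimator(BaseEstimator, TransformerMixin):
    """Residual-SVD surrogate variables for unmodelled batch structure.

    Missing cells are imputed by seeded random draws from the observed
    values of the same analyte; each analyte is then residualized on the
    primary design (predictor + age + sex + intercept) and standardized to
    unit residual variance.  The top ``n_sv`` right singular directions
    (analyte loadings) of the residual matrix identify the latent
    subspace; the surrogate variables are the projections of the original
    standardized data onto those directions, centered and orthogonalized.
    Scoring on the original data (not the residuals) is what lets an SV
    absorb batch variation that happens to align with the predictor —
    left singular vectors of the residual matrix are orthogonal to the
    design by construction and would leave that confounding in place.

    Because the original data also contain the true design effects, the
    projection is restricted to analytes without strong evidence of design
    association (iteratively reweighted, in the spirit of surrogate
    variable analysis): otherwise real effects would leak into the SVs and
    bias null analytes.  ``weight_alpha`` is the design-association
    p-value below which an analyte is excluded from factor scoring.
    """

    def __init__(self, n_sv: int = 2, seed: int = 0, n_iter: int = 3,
                 weight_alpha: float = 0.01):
        self.n_sv = n_sv
        self.seed = seed
        self.n_iter = n_iter
        self.weight_alpha = weight_alpha

    def fit(self, m: ProteomicsMatrix, design: pd.DataFrame):
        v = m.values
        if self.n_sv >= min(v.shape):
            raise ValueError(f"n_sv={self.n_sv} must be < min(matrix dims) {min(v.shape)}")
        rng = np.random.default_rng(self.seed)
        x = v.to_numpy(dtype=float, copy=True)
        for j in range(x.shape[1]):
            col = x[:, j]
            miss = np.isnan(col)
            if miss.any():
                obs = col[~miss]
                if obs.size == 0:
                    col[miss] = 0.0
                else:
                    col[miss] = rng.choice(obs, size=int(miss.sum()))
        X = np.column_stack([np.ones(len(design))] + [
            np.asarray(design[c], dtype=float) for c in design.columns
        ])
        n, k = X.shape
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        resid = x - X @ beta
        sd = resid.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        resid = resid / sd
        x_std = (x - x.mean(axis=0)) / sd

        def _design_pvalues(Xfull: np.ndarray) -> np.ndarray:
            """Per-analyte two-sided p for the predictor (design column 1)."""
            b, *_ = np.linalg.lstsq(Xfull, x, rcond=None)
            r = x - Xfull @ b
            dof = n - Xfull.shape[1]
            s2 = (r**2).sum(axis=0) / dof
            cov_ii = np.linalg.pinv(Xfull.T @ Xfull)[1, 1]
            se = np.sqrt(np.maximum(s2 * cov_ii, 1e-300))
            t = b[1] / se
            return 2 * stats.t.sf(np.abs(t), dof)

        sv = None
        for _ in range(max(1, self.n_iter)):
            Xfull = X if sv is None else np.column_stack([X, sv])
            pvals = _design_pvalues(Xfull)
            w = (pvals >= self.weight_alpha).astype(float)
            if w.sum() < max(10, 2 * self.n_sv):  # keep enough analytes
                w = np.ones_like(w)
            _, _, vt = np.linalg.svd(resid * w, full_matrices=False)
            # score latent directions on the original (centered, residual-
            # scaled, reweighted) data to retain predictor-aligned batch
            sv = (x_std * w) @ vt[: self.n_sv].T
            sv = sv - sv.mean(axis=0)
            sv, _ = np.linalg.qr(sv)
            sv = sv * np.sqrt(n)  # unit-variance-ish scaling
        # deterministic sign convention: largest-|loading| entry positive
        for k in range(sv.shape[1]):
            i = int(np.argmax(np.abs(sv[:, k])))
            if sv[i, k] < 0:
                sv[:, k] = -sv[:, k]
        self.svs_ = pd.DataFrame(
            sv, index=v.index, columns=[f"sv{k + 1}" for k in range(self.n_sv)]
        )
        return self

    def transform(self, m: ProteomicsMatrix) -> pd.DataFrame:
        return self.svs_


def estimate_surrogate_variables(
    m: ProteomicsMatrix, covariates: pd.DataFrame, n_sv: int = 2, seed: int = 0
) -> pd.DataFrame:
    """Functional wrapper returning the sample × SV score table."""
    est = SurrogateVariableEstimator(n_sv=n_sv, seed=seed)
    return est.fit(m, covariates).svs_


def _design_for_contrast(meta: pd.DataFrame, contrast: str):
    """Rows entering the fit and the predictor column for one contrast."""
    meta = meta.set_index("sample_id", drop=False)
    if contrast.endswith("_vs_CO"):
        case = contrast.split("_vs_")[0]
        sel = meta["diagnosis"].isin([case, "CO"])
        sub = meta[sel]
        predictor = (sub["diagnosis"] == case).astype(float)
    elif contrast in PHENOTYPE_CONTRASTS:
        sel = meta[contrast].notna()
        sub = meta[sel]
        predictor = sub[contrast].astype(float)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    covar = pd.DataFrame(
        {
            "predictor": predictor,
            "age_at_draw": sub["age_at_draw"].astype(float),
            "male": (sub["sex"] == "male").astype(float),
        },
        index=sub.index,
    )
    return sub, covar


def latest_sample_per_participant(meta: pd.DataFrame) -> pd.DataFrame:
    """One sample per participant (latest draw), the default for contrasts."""
    return (
        meta.sort_values("age_at_draw")
        .groupby("participant_id", as_index=False)
        .tail(1)
        .sort_index()
    )


def fit_associations(
    m: ProteomicsMatrix,
    meta: pd.DataFrame,
    contrast: str,
    svs: pd.DataFrame | None = None,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Per-analyte OLS of log10 NPQ on predictor + age + sex (+ SVs).

    Complete-case per analyte.  Constant analytes yield beta 0 with missing
    p and ``degenerate=True``.  Returns one row per analyte with beta, se,
    p_raw, BH-adjusted p_fdr and n_used.
    """
    sub, covar = _design_for_contrast(meta, contrast)
    if contrast.endswith("_vs_CO"):
        n_cases = int(covar["predictor"].sum())
        if n_cases < min_cases:
            warnings.warn(
                f"contrast {contrast}: only {n_cases} cases; fitting anyway",
                stacklevel=2,
            )
    X = covar.copy()
    if svs is not None:
        sv = svs.reindex(X.index)
        sv = sv.loc[:, sv.std() > 0]  # zero-variance SVs carry no adjustment
        X = X.join(sv)
    v = m.values.reindex(X.index)

    Xm = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    colnames = ["const", *X.columns]
    rows = []
    for analyte in v.columns:
        y = v[analyte].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(Xm).any(axis=1)
        n_used = int(ok.sum())
        yk, Xk = y[ok], Xm[ok]
        if n_used < Xk.shape[1] + 1 or np.nanstd(yk) == 0:
            rows.append((analyte, 0.0, np.nan, np.nan, n_used, True))
            continue
        rank = np.linalg.matrix_rank(Xk)
        if rank < Xk.shape[1]:
            # drop-one scan to name the collinear column
            for ci in range(Xk.shape[1]):
                keep = [c for c in range(Xk.shape[1]) if c != ci]
                if np.linalg.matrix_rank(Xk[:, keep]) == rank:
                    raise ValueError(
                        f"rank-deficient design for {analyte}: column "
                        f"{colnames[ci]!r} is collinear"
                    )
            raise ValueError(f"rank-deficient design for {analyte}")
        fit = sm.OLS(yk, Xk).fit()
        # extreme t-statistics underflow to p = 0; keep p in (0, 1]
        p_val = max(float(fit.pvalues[1]), np.finfo(float).tiny)
        rows.append((analyte, fit.params[1], fit.bse[1], p_val, n_used, False))

    table = pd.DataFrame(
        rows, columns=["analyte_id", "beta", "se", "p_raw", "n_used", "degenerate"]
    )
    table.insert(1, "contrast", contrast)
    return adjust_fdr(table)


def adjust_fdr(records: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Attach Benjamini–Hochberg step-up adjusted p-values (one contrast)."""
    records = records.copy()
    p = records["p_raw"].to_numpy(dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] <= 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    adj = np.full_like(p, np.nan)
    if finite.any():
        adj[finite] = multipletests(p[finite], method=method)[1]
    records["p_fdr"] = adj
    return records


def compare_effect_sizes(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    selection: str = "fdr",
    alpha: float = 0.05,
    band: float = 0.95,
) -> dict:
    """Cross-contrast effect-size comparison with a 95% prediction band.

    Analytes significant in at least one table (``p_fdr`` < alpha, or
    ``p_raw`` under the relaxed rule ``selection='nominal'``) enter.  The
    comparison reports the Pearson r of (βA, βB), the OLS regression of βB
    on βA with a per-point prediction band, the analytes falling outside the
    band, and those with discordant effect-sign.
    """
    merged = table_a.merge(table_b, on="analyte_id", suffixes=("_a", "_b"))
    col = "p_fdr" if selection == "fdr" else "p_raw"
    sig = (merged[f"{col}_a"] < alpha) | (merged[f"{col}_b"] < alpha)
    sel = merged[sig].dropna(subset=["beta_a", "beta_b"])
    if len(sel) < 3:
        raise ValueError(f"only {len(sel)} shared significant analytes; need >= 3")
    ba = sel["beta_a"].to_numpy()
    bb = sel["beta_b"].to_numpy()
    r, p_r = stats.pearsonr(ba, bb)

    X = sm.add_constant(ba)
    fit = sm.OLS(bb, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=1 - band)
    outside = (bb < pred["obs_ci_lower"].to_numpy()) | (
        bb > pred["obs_ci_upper"].to_numpy()
    )
    side = np.where(bb > pred["obs_ci_upper"].to_numpy(), "above", "below")
    band_outliers = [
        (a, s) for a, s, o in zip(sel["analyte_id"], side, outside) if o
    ]
    discordant = list(sel.loc[np.sign(ba) * np.sign(bb) < 0, "analyte_id"])
    return {
        "contrast_pair": (
            str(table_a["contrast"].iloc[0]) if "contrast" in table_a else "A",
            str(table_b["contrast"].iloc[0]) if "contrast" in table_b else "B",
        ),
        "r": float(r),
        "p_r": float(p_r),
        "n_selected": int(len(sel)),
        "band_outliers": band_outliers,
        "discordant_sign": discordant,
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
    }
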