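"""Covariate-adjusted logistic classification with bootstrap-CI AUC.

The score for ROC analysis is the fitted linear predictor of a maximum-
likelihood logistic regression of the binary outcome on the protein
feature(s) plus age and sex.  AUC is the Mann–Whitney rank statistic; the
95% CI comes from a stratified nonparametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .matrix import ProteomicsMatrix


@dataclass
class PredictionRecord:
    model: str
    predictors: list
    auc: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    n_controls: int
    separation_flag: bool = False


class AdjustedLogisticAUC(BaseEstimator):
    """Logistic fit whose linear predictor is scored by ROC AUC.

    Parameters
    ----------
    n_bootstrap
        Stratified bootstrap replicates for the AUC confidence interval.
    seed
        Seed for the bootstrap resampling.
    """

    def __init__(self, n_bootstrap: int = 2000, seed: int = 0, ci_level: float = 0.95):
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.ci_level = ci_level

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y).astype(int)
        Xv = np.asarray(X, dtype=float)
        ok = np.isfinite(Xv).all(axis=1)
        Xv, y = Xv[ok], y[ok]
        n_cases, n_controls = int(y.sum()), int((y == 0).sum())
        if min(n_cases, n_controls) < 5:
            raise ValueError(
                f"need >= 5 per class, got {n_cases} cases / {n_controls} controls"
            )
        Xd = sm.add_constant(Xv, has_constant="add")
        separation = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
                score = Xd @ res.params
                if not np.isfinite(res.params).all():
                    raise np.linalg.LinAlgError
            except Exception:
                # perfect separation (or failed MLE): rank the single best
                # linear combination available — fall back to first feature
                separation = True
                score = Xv[:, 0]
        auc = float(roc_auc_score(y, score))
        if auc in (0.0, 1.0):
            separation = True

        rng = np.random.default_rng(self.seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        boot = np.empty(self.n_bootstrap)
        score = np.asarray(score, dtype=float)
        for b in range(self.n_bootstrap):
            ip = rng.choice(pos, size=pos.size)
            ineg = rng.choice(neg, size=neg.size)
            idx = np.concatenate([ip, ineg])
            boot[b] = roc_auc_score(y[idx], score[idx])
        a = (1 - self.ci_level) / 2
        lo, hi = np.quantile(boot, [a, 1 - a])
        self.score_ = score
        self.auc_ = auc
        self.ci_ = (float(min(lo, auc)), float(max(hi, auc)))
        self.n_cases_ = n_cases
        self.n_controls_ = n_controls
        self.separation_ = separation
        return self


def fit_logistic_auc(
    meta: pd.DataFrame,
    features: pd.DataFrame,
    outcome,
    adjust: tuple = ("age_at_draw", "sex"),
    n_bootstrap: int = 2000,
    seed: int = 0,
    label: str = "model",
) -> PredictionRecord:
    """Fit the covariate-adjusted logistic model and report AUC with CI.

    ``outcome`` is a binary Series indexed by sample_id (or aligned with
    ``features``); ``adjust`` columns are pulled from ``meta``.
    """
    meta = meta.set_index("sample_id", drop=False)
    y = pd.Series(outcome).dropna()
    X = features.reindex(y.index).copy()
    for col in adjust:
        v = meta[col].reindex(y.index)
        X[col] = (v == "male").astype(float) if col == "sex" else v.astype(float)
    est = AdjustedLogisticAUC(n_bootstrap=n_bootstrap, seed=seed)
    est.fit(X, y.astype(int))
    return PredictionRecord(
        model=label,
        predictors=list(X.columns),
        auc=est.auc_,
        ci_lower=est.ci_[0],
        ci_upper=est.ci_[1],
        n_cases=est.n_cases_,
        n_controls=est.n_controls_,
        separation_flag=est.separation_,
    )


def ratio_feature(m: ProteomicsMatrix, numerator: str, denominator: str) -> pd.Series:
    """log10 ratio feature: log10(num) − log10(den); missing if either is.

    Equals the log of the linear NPQ ratio.
    """
    if numerator == denominator:
        raise ValueError("numerator and denominator must differ")
    v = m.to_scale("log10").values
    out = v[numerator] - v[denominator]
    out.name = f"{numerator}/{denominator}"
    return out


def horizon_auc(
    meta: pd.DataFrame,
    feature: pd.Series,
    horizon_years: float,
    adjust: tuple = ("age_at_draw", "sex"),
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> PredictionRecord:
    """AUC for predicting conversion to symptomatic AD within a horizon.

    Outcome is 1 if the participant converted within ``horizon_years`` of
    draw; participants censored before the horizon without converting are
    excluded (their status within the window is unknown).
    """
    m = meta.set_index("sample_id", drop=False)
    base = m[(m["diagnosis"] == "CO") & m["age_at_last_followup"].notna()]
    t_onset = base["age_at_onset"] - base["age_at_draw"]
    t_follow = base["age_at_last_followup"] - base["age_at_draw"]
    converted = base["age_at_onset"].notna()
    event_in = converted & (t_onset <= horizon_years)
    known_free = ~converted & (t_follow >= horizon_years)
    if horizon_years >= t_follow.max():
        # horizon beyond every follow-up: degrade to any-time conversion
        event_in = converted
        known_free = ~converted
    keep = event_in | known_free
    y = event_in[keep].astype(int)
    if y.sum() < 5:
        raise ValueError(f"fewer than 5 converters within {horizon_years} years")
    X = pd.DataFrame({feature.name or "feature": feature.reindex(y.index)})
    return fit_logistic_auc(
        meta, X, y, adjust=adjust, n_bootstrap=n_bootstrap, seed=seed,
        label=f"horizon_{horizon_years}y",
    )
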