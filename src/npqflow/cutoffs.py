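"""Data-driven biomarker positivity cutoffs.

Three threshold schemes on a continuous biomarker (here log10 NPQ,
z-scored against the full fitting sample):

* a two-component univariate Gaussian mixture fitted by EM, with the
  cutoff at the point where a sample is equally likely to belong to either
  component (equal posterior probability);
* a single Youden-index cutoff against a binary reference (maximizing
  sensitivity + specificity − 1);
* a dual-cutoff scheme whose lower/upper thresholds hit 95% sensitivity
  and 95% specificity respectively, trichotomizing samples into
  low / intermediate / high zones.

Reference positivity rules: amyloid-PET > 20 Centiloids, tau-PET > 1.5
SUVR, CSF Aβ42/Aβ40 < 0.0673 (boundary values are negative for PET,
positive excluded for CSF strictly-below rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

_VAR_FLOOR = 1e-6


def _em_once(x: np.ndarray, w, mu, var, tol: float, max_iter: int):
    """Run EM from one initialization; returns (params, loglik, n_iter, conv)."""
    n = x.size
    w = np.asarray(w, dtype=float)
    mu = np.asarray(mu, dtype=float)
    var = np.maximum(np.asarray(var, dtype=float), _VAR_FLOOR)
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for stability
        logp = (
            np.log(w)[:, None]
            - 0.5 * np.log(2 * np.pi * var)[:, None]
            - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None]
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        loglik = float(lse.sum())
        resp = np.exp(logp - lse)
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = np.maximum((resp @ x**2) / nk - mu**2, _VAR_FLOOR)
        # converge on total-loglik stall or per-sample change below tol
        if loglik - prev < tol * max(1.0, abs(loglik)) or (loglik - prev) / n < tol:
            converged = True
            break
        prev = loglik
    return (w, mu, var), loglik, it, converged


class GaussianMixtureCutoff(BaseEstimator):
    """Two-component 1-D Gaussian mixture with an equal-posterior cutoff.

    ``fit`` takes log10-scale biomarker values, z-scores them against their
    own mean/SD (the standardization pair is stored so the cutoff is
    expressible on z, log10 and linear scales), runs EM from ``restarts``
    quantile-split initializations and keeps the best log-likelihood.
    Components are relabelled so ``means_[0] < means_[1]``; the positive
    class is the upper component.

    Attributes (after fit): ``weights_``, ``means_``, ``sigmas_`` (z units),
    ``z_cutoff_``, ``cutoff_log10_``, ``cutoff_linear_``, ``standardization_``,
    ``loglik_``, ``n_iter_``, ``converged_``, ``low_confidence_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 5000,
                 restarts: int = 5, seed: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.seed = seed

    def fit(self, values, y=None):
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 20:
            raise ValueError(f"need >= 20 finite values, got {x.size}")
        mean, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0:
            raise ValueError("zero variance input")
        z = (x - mean) / sd

        best = None
        any_converged = False
        for r in range(self.restarts):
            q = 0.3 + 0.1 * r
            split = np.quantile(z, q)
            lo, hi = z[z <= split], z[z > split]
            if lo.size < 2 or hi.size < 2:
                continue
            init = (
                [lo.size / z.size, hi.size / z.size],
                [lo.mean(), hi.mean()],
                [max(lo.var(), _VAR_FLOOR), max(hi.var(), _VAR_FLOOR)],
            )
            params, ll, it, conv = _em_once(z, *init, self.tol, self.max_iter)
            any_converged |= conv
            if best is None or ll > best[1]:
                best = (params, ll, it, conv)
        if best is None:
            raise ValueError("no valid EM initialization")
        (w, mu, var), ll, it, conv = best
        order = np.argsort(mu)
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.sigmas_ = np.sqrt(var[order])
        self.loglik_ = ll
        self.n_iter_ = it
        self.converged_ = conv
        if not any_converged:
            raise RuntimeError(
                f"EM failed to converge in all {self.restarts} restarts; "
                f"best loglik {ll:.4f} with params w={w}, mu={mu}, var={var}"
            )
        self.standardization_ = (mean, sd)
        try:
            self.z_cutoff_ = equal_posterior_cutoff(
                self.weights_, self.means_, self.sigmas_
            )
            self.cutoff_degenerate_ = False
        except ValueError:
            # components too overlapped for a posterior crossing between the
            # means: fall back to the midpoint and mark the fit degenerate
            self.z_cutoff_ = float(self.means_.mean())
            self.cutoff_degenerate_ = True
        self.cutoff_log10_ = mean + sd * self.z_cutoff_
        self.cutoff_linear_ = 10.0 ** self.cutoff_log10_
        # flag poorly separated components: cutoff is low-confidence
        self.low_confidence_ = bool(
            self.cutoff_degenerate_
            or self.means_[1] - self.means_[0] < self.sigmas_[0] + self.sigmas_[1]
        )
        return self

    def zscore(self, values) -> np.ndarray:
        mean, sd = self.standardization_
        return (np.asarray(values, dtype=float) - mean) / sd

    def predict(self, values) -> np.ndarray:
        """1 for above-cutoff (biomarker-positive), 0 below; NaN-safe."""
        z = self.zscore(values)
        return np.where(np.isnan(z), np.nan, (z > self.z_cutoff_).astype(float))


def fit_two_component_gmm(x, tol: float = 1e-8, max_iter: int = 5000,
                          restarts: int = 5, seed: int = 0) -> GaussianMixtureCutoff:
    """Functional wrapper over :class:`GaussianMixtureCutoff` (z-scale input ok)."""
    return GaussianMixtureCutoff(tol=tol, max_iter=max_iter,
                                 restarts=restarts, seed=seed).fit(x)


def equal_posterior_cutoff(w, mu, sigma) -> float:
    """Solve w1·φ(z; μ1, σ1) = w2·φ(z; μ2, σ2) for the root in (μ1, μ2).

    For unequal variances the condition is a quadratic in z; for equal
    variances it reduces to the closed form
    ``(μ1+μ2)/2 + σ²·ln(w1/w2)/(μ2−μ1)`` (a larger prior weight on the
    lower component pushes the boundary toward the upper one).
    """
    w1, w2 = float(w[0]), float(w[1])
    m1, m2 = float(mu[0]), float(mu[1])
    s1, s2 = float(sigma[0]), float(sigma[1])
    if not m1 < m2:
        raise ValueError("components must be ordered mu1 < mu2")
    if math.isclose(s1, s2, rel_tol=1e-12, abs_tol=1e-12):
        z = (m1 + m2) / 2 + s1**2 * math.log(w1 / w2) / (m2 - m1)
        if not m1 < z < m2:
            raise ValueError("equal-posterior point falls outside (mu1, mu2); "
                             "components too overlapped")
        return z
    # quadratic a z^2 + b z + c = 0 from equating log densities
    a = 1 / (2 * s2**2) - 1 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + math.log(w1 / s1)
        - math.log(w2 / s2)
    )
    disc = b**2 - 4 * a * c
    if disc < 0:
        raise ValueError("no real equal-posterior point")
    roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (+1, -1)]
    inside = [z for z in roots if m1 < z < m2]
    if not inside:
        raise ValueError("no equal-posterior root in (mu1, mu2); "
                         "components too overlapped")
    return float(inside[0])


@dataclass
class CutoffResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


class YoudenCutoff(BaseEstimator):
    """Single cutoff maximizing Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the sorted unique observed scores; ``score >=
    threshold`` classifies positive; ties in J break toward the smallest
    threshold.
    """

    def fit(self, scores, labels):
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels).astype(int)
        ok = np.isfinite(s) & (y >= 0)
        s, y = s[ok], y[ok]
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        cand = np.unique(s)
        n_pos = y.sum()
        n_neg = y.size - n_pos
        # vectorized sens/spec over all candidate thresholds
        pred = s[None, :] >= cand[:, None]
        tp = (pred & (y == 1)).sum(axis=1)
        tn = (~pred & (y == 0)).sum(axis=1)
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1
        i = int(np.argmax(j))  # argmax takes first (smallest t) on ties
        self.result_ = CutoffResult(
            threshold=float(cand[i]),
            youden_j=float(j[i]),
            sensitivity=float(sens[i]),
            specificity=float(spec[i]),
            degenerate=bool(cand.size == 1),
        )
        self.threshold_ = self.result_.threshold
        return self

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return (s >= self.threshold_).astype(int)


def youden_cutoff(scores, labels) -> CutoffResult:
    return YoudenCutoff().fit(scores, labels).result_


@dataclass
class DualCutoffResult:
    lower: float
    upper: float
    target_sensitivity: float
    target_specificity: float
    n_low: int
    n_intermediate: int
    n_high: int
    empty_intermediate: bool = False


class DualCutoffs(BaseEstimator):
    """Lower/upper thresholds at target sensitivity and specificity.

    ``lower`` is the largest observed threshold keeping sensitivity ≥ the
    target (classify ``score >= t`` positive); ``upper`` is the smallest
    keeping specificity ≥ the target.  ``predict`` trichotomizes scores:
    below lower → ``low``, within the closed interval [lower, upper] →
    ``intermediate``, above upper → ``high``.
    """

    def __init__(self, target_sensitivity: float = 0.95,
                 target_specificity: float = 0.95):
        self.target_sensitivity = target_sensitivity
        self.target_specificity = target_specificity

    def fit(self, scores, labels):
        import logging

        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels).astype(int)
        ok = np.isfinite(s)
        s, y = s[ok], y[ok]
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        n_pos, n_neg = int(y.sum()), int((y == 0).sum())
        if min(n_pos, n_neg) < 20:
            logging.getLogger(__name__).warning(
                "dual cutoffs with only %d positives / %d negatives", n_pos, n_neg
            )
        cand = np.unique(s)
        pred = s[None, :] >= cand[:, None]
        sens = (pred & (y == 1)).sum(axis=1) / n_pos
        spec = (~pred & (y == 0)).sum(axis=1) / n_neg
        lower_cands = cand[sens >= self.target_sensitivity]
        upper_cands = cand[spec >= self.target_specificity]
        lower = float(lower_cands.max()) if lower_cands.size else float(cand.min())
        upper = float(upper_cands.min()) if upper_cands.size else float(cand.max())
        empty = False
        if lower >= upper:
            # perfectly separable (or crossed) thresholds: no intermediate
            # zone; classification degrades to the single threshold `upper`
            lower = upper
            empty = True
        self.lower_, self.upper_ = lower, upper
        classes = self.predict(s)
        self.result_ = DualCutoffResult(
            lower=lower,
            upper=upper,
            target_sensitivity=self.target_sensitivity,
            target_specificity=self.target_specificity,
            n_low=int((classes == "low").sum()),
            n_intermediate=int((classes == "intermediate").sum()),
            n_high=int((classes == "high").sum()),
            empty_intermediate=empty,
        )
        return self

    def predict(self, scores) -> np.ndarray:
        """Trichotomize; the intermediate interval is closed on both ends.

        When lower == upper there is no intermediate zone and the boundary
        value classifies high (single-threshold ``score >= t`` convention).
        """
        s = np.asarray(scores, dtype=float)
        if self.lower_ == self.upper_:
            out = np.where(s < self.lower_, "low", "high")
        else:
            out = np.where(
                s < self.lower_, "low",
                np.where(s > self.upper_, "high", "intermediate"),
            )
        return np.asarray(out, dtype=object)


def dual_cutoffs(scores, labels, target_sensitivity: float = 0.95,
                 target_specificity: float = 0.95) -> DualCutoffResult:
    return DualCutoffs(target_sensitivity, target_specificity).fit(scores, labels).result_


def pet_reference(meta: pd.DataFrame, modality: str,
                  amyloid_cutoff: float = 20.0, tau_cutoff: float = 1.5,
                  csf_cutoff: float = 0.0673) -> pd.Series:
    """Binary biomarker-positivity labels from PET/CSF reference measures.

    amyloid: Centiloids > 20 positive (exactly 20 is negative); tau: SUVR >
    1.5 positive; csf: Aβ42/Aβ40 < 0.0673 positive.  Missing values are
    excluded (dropped from the returned Series).
    """
    meta = meta.set_index("sample_id", drop=False)
    if modality == "amyloid":
        v = meta["amyloid_pet"]
        lab = v > amyloid_cutoff
    elif modality == "tau":
        v = meta["tau_pet"]
        lab = v > tau_cutoff
    elif modality == "csf":
        v = meta["csf_ab_ratio"]
        lab = v < csf_cutoff
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return lab[v.notna()].astype(int)


def mixture_density(model: GaussianMixtureCutoff, z: np.ndarray) -> np.ndarray:
    w, mu, sg = model.weights_, model.means_, model.sigmas_
    return w[0] * norm.pdf(z, mu[0], sg[0]) + w[1] * norm.pdf(z, mu[1], sg[1])
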