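"""Seeded synthetic mixed-dementia cohorts with NPQ-like statistical structure.

The generator emulates the features the downstream analyses rely on: per-
analyte Gaussian log10-NPQ with disease/age/sex effects and latent batch
structure, a bimodal p-tau217-like biomarker analyte tied to a latent
positivity label, PET/CSF endophenotypes correlated with that label, APOE
genotypes with an ε4-proteoform signal, MCAR missingness with injected
outliers, and exponential conversion-to-AD event times.  Every latent
quantity is returned in a truth record so recovery tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ProteomicsMatrix

DISEASES = ("AD", "DLB", "FTD", "PD")

# Cohort moments: group sizes, age mean/SD at draw, male fraction.
GROUP_PROFILE = {
    "AD": (1092, 77.68, 8.37, 0.4368),
    "DLB": (28, 75.46, 11.57, 0.6429),
    "FTD": (39, 67.28, 9.45, 0.5641),
    "PD": (9, 77.11, 6.79, 0.8889),
    "CO": (1579, 72.88, 10.58, 0.4022),
}

DEFAULT_APOE_FREQS = {
    "e2/e2": 0.005,
    "e2/e3": 0.110,
    "e3/e3": 0.490,
    "e2/e4": 0.020,
    "e3/e4": 0.300,
    "e4/e4": 0.075,
}

NAMED_ANALYTES = [
    "pTau217", "GFAP", "pTau231", "NEFL", "pTau181", "PARK7", "NPTXR",
    "BDNF", "Ab42", "MME", "CRH", "NRGN", "CRP", "OligoSNCA", "APOE4",
]

# Literature-scale disease effects (log10 NPQ) for the named analytes.
NAMED_EFFECTS = {
    "pTau217": {"AD": 0.26, "DLB": 0.08},
    "GFAP": {"AD": 0.16, "DLB": 0.15, "FTD": 0.12},
    "pTau231": {"AD": 0.16},
    "NEFL": {"AD": 0.09, "FTD": 0.27, "DLB": 0.12},
    "pTau181": {"AD": 0.09},
    "PARK7": {"PD": 0.34, "AD": -0.08},
    "NPTXR": {"AD": -0.12},
    "BDNF": {"AD": -0.08, "DLB": -0.15},
    "Ab42": {"AD": -0.10},
    "MME": {"FTD": 0.15, "AD": -0.05},
    "CRH": {"AD": 0.06, "DLB": -0.08},
    "NRGN": {"AD": -0.05, "DLB": 0.08},
    "CRP": {"AD": -0.05, "DLB": 0.06},
    "OligoSNCA": {"AD": -0.05, "DLB": 0.06, "PD": 0.10},
}


def default_analyte_ids(n_analytes: int) -> list[str]:
    ids = NAMED_ANALYTES[:n_analytes]
    ids += [f"PROT{i:03d}" for i in range(len(ids) + 1, n_analytes + 1)]
    return ids


def default_effect_matrix(analyte_ids: list[str]) -> pd.DataFrame:
    """Analytes × diseases true-β grid with 78 AD-affected analytes.

    Named analytes carry literature-scale effects; enough generic analytes
    receive a deterministic ramp of AD effects (alternating sign, 0.02-0.12)
    to bring the AD-affected count to 78 of 123 when the panel is full size.
    Generic AD effects are partially shared with the other dementias
    (attenuated 0.6× for DLB, 0.35× for FTD, 0.1× for PD), emulating the
    strongly correlated cross-disease proteomic profiles with disease-
    specific exceptions carried by the named analytes.
    """
    eff = pd.DataFrame(0.0, index=analyte_ids, columns=list(DISEASES))
    for analyte, d in NAMED_EFFECTS.items():
        if analyte in eff.index:
            for dx, b in d.items():
                eff.loc[analyte, dx] = b
    n_named_ad = int((eff["AD"] != 0).sum())
    want_more = max(0, min(78, len(analyte_ids)) - n_named_ad)
    generic = [a for a in analyte_ids if a.startswith("PROT")]
    for i, analyte in enumerate(generic[:want_more]):
        mag = 0.02 + 0.10 * (i / max(1, want_more - 1))
        b = mag if i % 2 == 0 else -mag
        eff.loc[analyte, "AD"] = b
        eff.loc[analyte, "DLB"] = 0.6 * b
        eff.loc[analyte, "FTD"] = 0.35 * b
        eff.loc[analyte, "PD"] = 0.1 * b
    return eff


@dataclass
class CohortSimConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_per_group: dict = field(
        default_factory=lambda: {g: GROUP_PROFILE[g][0] for g in GROUP_PROFILE}
    )
    n_analytes: int = 123
    effect_matrix: pd.DataFrame | None = None  # None -> default_effect_matrix
    age_effect_sd: float = 0.002      # log10 NPQ per year, drawn per analyte
    sex_effect_sd: float = 0.02       # log10 NPQ offset for males
    batch_k: int = 2
    batch_loading_sd: float = 0.3
    noise_sd: float = 0.15            # residual SD, log10 NPQ
    baseline_range: tuple = (2.5, 4.5)
    # two-component mixture for the biomarker analyte on the z scale;
    # chosen so the standardized mixture has mean 0, variance 1 and a
    # negative fraction near 52%
    biomarker_analyte: str = "pTau217"
    biomarker_mix: tuple = (0.52, -0.80, 0.55, 0.867, 0.548)  # w1, μ1, σ1, μ2, σ2
    biomarker_mean_log10: float = 3.67
    biomarker_sd_log10: float = 0.20
    pos_prob_by_group: dict = field(
        default_factory=lambda: {"AD": 0.85, "DLB": 0.45, "FTD": 0.30, "PD": 0.30, "CO": 0.25}
    )
    # amyloid-PET link (Centiloids): positives intercept + slope·z + noise,
    # negatives background; availability mirrors the ~10% imaging subcohort
    pet_intercept: float = 60.0
    pet_slope: float = 25.0
    pet_noise_sd: float = 15.0
    pet_background: tuple = (5.0, 8.0)
    pet_fraction: float = 0.10
    tau_fraction: float = 0.09
    csf_fraction: float = 0.15
    missing_rate: float = 0.02
    outlier_rate: float = 0.005
    outlier_iqr_mult: float = 10.0
    apoe_freqs: dict = field(default_factory=lambda: dict(DEFAULT_APOE_FREQS))
    apoe_analyte: str = "APOE4"
    proteoform_shift_sd: float = 5.0  # carrier shift in units of noise_sd
    surv_baseline_hazard: float = 0.008  # events per year at z = 0
    surv_log_hr: float = math.log(1.71)  # per z-unit of the biomarker
    surv_followup_range: tuple = (1.0, 23.0)
    # per-run technical measurement noise for replicate runs, chosen so
    # cross-run correlations average near the platform-typical ~0.75
    # given the chi-square spread of per-analyte biological variance
    technical_noise_sd: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("missing_rate", self.missing_rate),
            ("outlier_rate", self.outlier_rate),
            ("pet_fraction", self.pet_fraction),
        ):
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        w1, _, s1, _, s2 = self.biomarker_mix
        if not (0 < w1 < 1 and s1 > 0 and s2 > 0):
            raise ValueError("biomarker_mix needs w1 in (0,1) and positive sigmas")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be non-negative")

    def scaled(self, factor: float) -> "CohortSimConfig":
        """Copy with group sizes scaled down (minimum 3 where nonzero)."""
        n = {g: (0 if c == 0 else max(3, int(round(c * factor))))
             for g, c in self.n_per_group.items()}
        return replace(self, n_per_group=n)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(cfg: CohortSimConfig):
    """Generate (log10 ProteomicsMatrix, metadata table, truth record).

    The truth record stores every latent quantity: true βs, age/sex slopes,
    batch factors and loadings, the biomarker z and positivity label, APOE
    carrier status, and the coordinates of injected outliers/missing cells.
    """
    rng = np.random.default_rng(cfg.seed)
    analytes = default_analyte_ids(cfg.n_analytes)
    effects = (
        cfg.effect_matrix.reindex(index=analytes, columns=list(DISEASES)).fillna(0.0)
        if cfg.effect_matrix is not None
        else default_effect_matrix(analytes)
    )

    groups = [g for g in GROUP_PROFILE if cfg.n_per_group.get(g, 0) > 0]
    n = sum(cfg.n_per_group[g] for g in groups)
    if n == 0:
        raise ValueError("empty cohort requested")

    diagnosis = np.concatenate([[g] * cfg.n_per_group[g] for g in groups])
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    participant_ids = [f"P{i:05d}" for i in range(1, n + 1)]

    age = np.empty(n)
    male = np.empty(n, dtype=bool)
    pos = np.empty(n, dtype=bool)
    start = 0
    for g in groups:
        cnt = cfg.n_per_group[g]
        _, mu_a, sd_a, p_male = GROUP_PROFILE[g]
        sl = slice(start, start + cnt)
        age[sl] = _truncated_normal(rng, mu_a, sd_a, 45, 100, cnt)
        male[sl] = rng.random(cnt) < p_male
        pos[sl] = rng.random(cnt) < cfg.pos_prob_by_group[g]
        start += cnt

    # APOE genotype and ε4 carrier status
    genos = list(cfg.apoe_freqs)
    probs = np.array([cfg.apoe_freqs[g] for g in genos], dtype=float)
    probs /= probs.sum()
    apoe = rng.choice(genos, size=n, p=probs)
    carrier = np.array(["e4" in g for g in apoe])

    # latent batch structure and per-analyte nuisance slopes
    p = len(analytes)
    batch = rng.standard_normal((n, cfg.batch_k))
    loadings = rng.normal(0.0, cfg.batch_loading_sd, (p, cfg.batch_k))
    age_slopes = rng.normal(0.0, cfg.age_effect_sd, p)
    sex_effects = rng.normal(0.0, cfg.sex_effect_sd, p)
    baselines = rng.uniform(*cfg.baseline_range, p)

    beta_dx = np.zeros((n, p))
    for j, dx in enumerate(DISEASES):
        mask = diagnosis == dx
        if mask.any():
            beta_dx[mask] = effects[dx].to_numpy()

    values = (
        baselines
        + beta_dx
        + np.outer(age - age.mean(), age_slopes)
        + np.outer(male.astype(float), sex_effects)
        + batch @ loadings.T
        + rng.normal(0.0, cfg.noise_sd, (n, p))
    )

    # biomarker analyte: two-component mixture on the z scale
    w1, mu1, s1, mu2, s2 = cfg.biomarker_mix
    z = np.where(pos, rng.normal(mu2, s2, n), rng.normal(mu1, s1, n))
    if cfg.biomarker_analyte in analytes:
        jb = analytes.index(cfg.biomarker_analyte)
        values[:, jb] = cfg.biomarker_mean_log10 + cfg.biomarker_sd_log10 * z

    # APOE ε4 proteoform analyte: carrier shift in noise-SD units
    if cfg.apoe_analyte in analytes:
        ja = analytes.index(cfg.apoe_analyte)
        shift = cfg.proteoform_shift_sd * cfg.noise_sd
        values[:, ja] = 2.0 + shift * carrier + rng.normal(0.0, cfg.noise_sd, n)

    # endophenotypes tied to the latent biomarker state
    has_pet = rng.random(n) < cfg.pet_fraction
    amyloid = np.full(n, np.nan)
    amy_pos = has_pet & pos
    amy_neg = has_pet & ~pos
    amyloid[amy_pos] = (
        cfg.pet_intercept
        + cfg.pet_slope * z[amy_pos]
        + rng.normal(0.0, cfg.pet_noise_sd, int(amy_pos.sum()))
    )
    amyloid[amy_neg] = rng.normal(*cfg.pet_background, int(amy_neg.sum()))

    has_tau = rng.random(n) < cfg.tau_fraction
    tau = np.full(n, np.nan)
    tau[has_tau] = 1.45 + 0.35 * z[has_tau] + rng.normal(0.0, 0.15, int(has_tau.sum()))

    has_csf = rng.random(n) < cfg.csf_fraction
    csf = np.full(n, np.nan)
    csf[has_csf] = np.clip(
        0.0673 - 0.02 * z[has_csf] + rng.normal(0.0, 0.012, int(has_csf.sum())),
        0.02, 0.14,
    )

    cdr = np.where(
        diagnosis == "CO",
        rng.choice([0.0, 0.5], size=n, p=[0.88, 0.12]),
        rng.choice([0.5, 1.0, 2.0], size=n, p=[0.50, 0.35, 0.15]),
    )

    # injected outliers: displace cells beyond the Q3 + k·IQR fence
    outlier_cells: list[tuple[str, str]] = []
    if cfg.outlier_rate > 0:
        flat = rng.random(n * p) < cfg.outlier_rate
        idx = np.flatnonzero(flat)
        q1 = np.quantile(values, 0.25, axis=0)
        q3 = np.quantile(values, 0.75, axis=0)
        iqr = q3 - q1
        for k in idx:
            i, j = divmod(int(k), p)
            if rng.random() < 0.5:
                values[i, j] = q3[j] + cfg.outlier_iqr_mult * iqr[j]
            else:
                values[i, j] = q1[j] - cfg.outlier_iqr_mult * iqr[j]
            outlier_cells.append((sample_ids[i], analytes[j]))

    # MCAR missingness
    missing_cells: list[tuple[str, str]] = []
    if cfg.missing_rate > 0:
        miss = rng.random((n, p)) < cfg.missing_rate
        values[miss] = np.nan
        ii, jj = np.nonzero(miss)
        missing_cells = [(sample_ids[i], analytes[j]) for i, j in zip(ii, jj)]

    matrix = ProteomicsMatrix(
        pd.DataFrame(values, index=sample_ids, columns=analytes), scale="log10"
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "participant_id": participant_ids,
            "age_at_draw": age,
            "sex": np.where(male, "male", "female"),
            "diagnosis": diagnosis,
            "apoe_genotype": apoe,
            "cdr": cdr,
            "amyloid_pet": amyloid,
            "tau_pet": tau,
            "csf_ab_ratio": csf,
            "age_at_onset": np.nan,
            "age_at_last_followup": np.nan,
        }
    )
    truth = {
        "beta": effects,
        "age_slopes": pd.Series(age_slopes, index=analytes),
        "sex_effects": pd.Series(sex_effects, index=analytes),
        "baselines": pd.Series(baselines, index=analytes),
        "batch_factors": pd.DataFrame(batch, index=sample_ids),
        "batch_loadings": pd.DataFrame(loadings, index=analytes),
        "biomarker_z": pd.Series(z, index=sample_ids),
        "biomarker_positive": pd.Series(pos, index=sample_ids),
        "apoe_carrier": pd.Series(carrier, index=sample_ids),
        "outlier_cells": outlier_cells,
        "missing_cells": missing_cells,
        "config": cfg,
    }
    return matrix, meta, truth


def simulate_technical_replicates(
    m: ProteomicsMatrix, cfg: CohortSimConfig, n_samples: int = 86
):
    """Re-measure a sample subset in two runs with fresh technical noise.

    The stored matrix value plays the role of the biological measurement
    shared between runs; each run adds independent technical noise of SD
    ``technical_noise_sd``.  Returns (run_a, run_b) on the same subset.
    """
    rng = np.random.default_rng([cfg.seed, 13])
    n = min(n_samples, m.shape[0])
    take = rng.choice(m.shape[0], size=n, replace=False)
    base = m.values.iloc[sorted(take)]
    run_a = base + rng.normal(0.0, cfg.technical_noise_sd, base.shape)
    run_b = base + rng.normal(0.0, cfg.technical_noise_sd, base.shape)
    return (
        ProteomicsMatrix(run_a, m.scale),
        ProteomicsMatrix(run_b, m.scale),
    )


def simulate_survival(meta: pd.DataFrame, truth: dict, cfg: CohortSimConfig,
                      horizon: float | None = None) -> pd.DataFrame:
    """Fill conversion-to-AD event times for the baseline-unimpaired group.

    Event times are exponential with rate ``h0 · exp(logHR · z)`` where z is
    the latent biomarker score; follow-up is uniform over
    ``surv_followup_range`` with optional administrative censoring at
    ``horizon`` years.  Converters get ``age_at_onset``; everyone gets
    ``age_at_last_followup``.
    """
    if cfg.surv_baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if horizon is not None and horizon <= 0:
        raise ValueError("censoring horizon must be positive")
    co = meta["diagnosis"] == "CO"
    if not co.any():
        raise ValueError("survival simulation needs control participants")
    rng = np.random.default_rng([cfg.seed, 7])
    meta = meta.copy()
    z = truth["biomarker_z"].reindex(meta["sample_id"]).to_numpy()
    idx = np.flatnonzero(co.to_numpy())
    lo, hi = cfg.surv_followup_range
    followup = rng.uniform(lo, hi, idx.size)
    if horizon is not None:
        followup = np.minimum(followup, horizon)
    rate = cfg.surv_baseline_hazard * np.exp(cfg.surv_log_hr * z[idx])
    t_event = rng.exponential(1.0 / rate)
    event = t_event <= followup
    draw = meta.loc[co, "age_at_draw"].to_numpy()
    onset = np.where(event, draw + t_event, np.nan)
    last = draw + np.where(event, t_event, followup)
    meta.loc[co, "age_at_onset"] = onset
    meta.loc[co, "age_at_last_followup"] = last
    converted = pd.Series(False, index=meta["sample_id"])
    converted.iloc[idx] = event
    truth["converted_to_ad"] = converted
    return meta
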