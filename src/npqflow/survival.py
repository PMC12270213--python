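"""Progression to symptomatic AD: time-to-event construction, per-protein
Cox proportional-hazards fits, and Kaplan–Meier comparison of cutoff groups.

Time-to-event for baseline cognitively-unimpaired participants is age at
onset minus age at draw for converters, and age at last follow-up minus age
at draw for non-converters.  Hazard ratios are per SD of log10 NPQ, adjusted
for age at draw and sex, with Efron tie handling (annual visits make ties
common) and BH-FDR across analytes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .association import adjust_fdr
from .matrix import ProteomicsMatrix

log = logging.getLogger(__name__)


def build_time_to_event(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-participant (time, event) for progression to symptomatic AD.

    Converters (onset recorded): time = onset − draw, event = True.
    Non-converters with follow-up: time = last follow-up − draw, event =
    False.  Nonpositive times and converter rows with missing onset are
    dropped with a logged count.
    """
    m = meta.set_index("sample_id", drop=False)
    base = m[(m["diagnosis"] == "CO") & m["age_at_last_followup"].notna()]
    event = base["age_at_onset"].notna()
    time = np.where(
        event,
        base["age_at_onset"] - base["age_at_draw"],
        base["age_at_last_followup"] - base["age_at_draw"],
    )
    tte = pd.DataFrame(
        {
            "sample_id": base["sample_id"],
            "participant_id": base["participant_id"],
            "time": time,
            "event": event.to_numpy(),
            "age_at_draw": base["age_at_draw"],
            "male": (base["sex"] == "male").astype(float),
        }
    )
    bad = tte["time"] <= 0
    if bad.any():
        log.info("dropping %d rows with nonpositive time-to-event", int(bad.sum()))
    return tte[~bad].reset_index(drop=True)


def fit_cox_per_protein(
    tte: pd.DataFrame,
    m: ProteomicsMatrix,
    adjust: tuple = ("age_at_draw", "male"),
    tie_method: str = "Efron",
    min_events: int = 10,
) -> pd.DataFrame:
    """Per-analyte Cox PH fit; HR per SD of log10 NPQ, BH-FDR across analytes."""
    if int(tte["event"].sum()) < min_events:
        raise ValueError(
            f"need >= {min_events} events, got {int(tte['event'].sum())}"
        )
    v = m.values.reindex(tte["sample_id"])
    rows = []
    for analyte in v.columns:
        x = v[analyte].to_numpy(dtype=float)
        df = tte[["time", "event", *adjust]].copy()
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            rows.append((analyte, np.nan, np.nan, np.nan, np.nan,
                         int(tte["event"].sum()), len(df), "degenerate"))
            continue
        df["x"] = (x - np.nanmean(x)) / sd
        df = df.dropna()
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"step_size": 0.5})
            s = cph.summary.loc["x"]
            rows.append((
                analyte,
                float(s["exp(coef)"]),
                float(s["exp(coef) lower 95%"]),
                float(s["exp(coef) upper 95%"]),
                max(float(s["p"]), np.finfo(float).tiny),
                int(df["event"].sum()),
                len(df),
                "ok",
            ))
        except Exception as exc:  # convergence failure: flag, do not drop
            log.warning("Cox fit failed for %s: %s", analyte, exc)
            rows.append((analyte, np.nan, np.nan, np.nan, np.nan,
                         int(df["event"].sum()), len(df), "failed"))
    table = pd.DataFrame(
        rows,
        columns=["analyte_id", "hr", "ci_lower", "ci_upper", "p_raw",
                 "n_events", "n_at_risk", "status"],
    )
    return adjust_fdr(table)


def km_by_cutoff(tte: pd.DataFrame, groups: pd.Series, min_events: int = 5):
    """Kaplan–Meier curves and two-sided log-rank test for two cutoff groups.

    ``groups`` maps sample_id to a binary/low-high label.  Returns
    ``(curves, logrank_p)`` where curves is a per-group long table of
    (time, survival).
    """
    g = pd.Series(groups).reindex(tte["sample_id"])
    labels = [lab for lab in pd.unique(g.dropna())]
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    sub = tte.copy()
    sub["group"] = g.to_numpy()
    sub = sub.dropna(subset=["group"])
    if int(sub["event"].sum()) < min_events:
        raise ValueError("too few events for a group comparison")
    curves = []
    parts = {}
    for lab in labels:
        part = sub[sub["group"] == lab]
        if len(part) == 0:
            raise ValueError(f"empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(part["time"], part["event"], label=str(lab))
        sf = kmf.survival_function_
        curves.append(pd.DataFrame({
            "group": str(lab),
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        }))
        parts[lab] = part
    a, b = labels
    res = logrank_test(
        parts[a]["time"], parts[b]["time"],
        event_observed_A=parts[a]["event"], event_observed_B=parts[b]["event"],
    )
    return pd.concat(curves, ignore_index=True), float(res.p_value)


def adjusted_survival_curves(
    tte: pd.DataFrame, groups: pd.Series, adjust: tuple = ("age_at_draw", "male"),
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted curves by direct standardization (g-formula).

    A Cox model with the group indicator plus covariates is fitted; each
    group's curve averages the model's predicted survival over the pooled
    covariate distribution.
    """
    g = pd.Series(groups).reindex(tte["sample_id"])
    labels = list(pd.unique(g.dropna()))
    sub = tte.copy()
    sub["group"] = (g == labels[-1]).astype(float).to_numpy()
    sub = sub.dropna(subset=["group"])
    cph = CoxPHFitter()
    cph.fit(sub[["time", "event", "group", *adjust]], "time", "event")
    if times is None:
        times = np.unique(sub.loc[sub["event"], "time"])
    out = []
    for lab, val in zip(labels, (0.0, 1.0)):
        covs = sub[["group", *adjust]].copy()
        covs["group"] = val
        surv = cph.predict_survival_function(covs, times=times)
        out.append(pd.DataFrame({
            "group": str(lab),
            "time": times,
            "survival": surv.mean(axis=1).to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)
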