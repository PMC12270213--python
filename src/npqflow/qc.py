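"""Quality control: IQR outlier masking, two-step call-rate filtering, CV/LOD.

The procedure is the targeted-proteomics standard: per-analyte values
outside ``[Q1 - k·IQR, Q3 + k·IQR]`` are masked to missing (single pass,
type-7 quantiles), then analytes and samples are filtered on call rate
(the proportion of successful measurements) in two steps — a lenient pass
(65%) followed by a strict pass (85%) with call rates recalculated in
between, which deliberately retains borderline analytes and samples.  CV
and LOD are reported per analyte but never used as filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ProteomicsMatrix


class IQROutlierMasker(BaseEstimator, TransformerMixin):
    """Mask per-analyte values outside ``k`` × IQR Tukey fences.

    Quantiles use linear interpolation (type 7).  Analytes with fewer than
    four observed values are passed through unmasked and flagged in
    ``records_``.  Fit and transform operate on the same matrix (the pass
    is single-shot by design); ``fit`` learns the fences, ``transform``
    applies them.
    """

    def __init__(self, k: float = 1.5):
        self.k = k

    def fit(self, m: ProteomicsMatrix, y=None):
        if self.k <= 0:
            raise ValueError("IQR multiplier k must be positive")
        v = m.values
        q1 = v.quantile(0.25, interpolation="linear")
        q3 = v.quantile(0.75, interpolation="linear")
        iqr = q3 - q1
        n_obs = v.notna().sum()
        defined = n_obs >= 4
        self.lower_ = (q1 - self.k * iqr).where(defined, -np.inf)
        self.upper_ = (q3 + self.k * iqr).where(defined, np.inf)
        self.iqr_ = iqr
        self.fence_defined_ = defined
        return self

    def transform(self, m: ProteomicsMatrix) -> ProteomicsMatrix:
        v = m.values
        outlier = v.lt(self.lower_, axis=1) | v.gt(self.upper_, axis=1)
        out = v.mask(outlier)
        self.n_masked_ = outlier.sum()
        self.records_ = pd.DataFrame(
            {
                "analyte_id": v.columns,
                "n_outliers_masked": self.n_masked_.to_numpy(),
                "iqr": self.iqr_.to_numpy(),
                "fence_defined": self.fence_defined_.to_numpy(),
            }
        )
        return ProteomicsMatrix(out, m.scale)


def mask_iqr_outliers(m: ProteomicsMatrix, k: float = 1.5):
    """Functional wrapper: returns (masked matrix, per-analyte record table)."""
    masker = IQROutlierMasker(k=k)
    out = masker.fit(m).transform(m)
    return out, masker.records_


class CallRateFilter(BaseEstimator, TransformerMixin):
    """Two-step call-rate filter over analytes then samples.

    Each step computes call rates on the current submatrix, drops analytes
    below the threshold, then drops samples below the threshold computed on
    the surviving analyte set.  Step 2 repeats at the stricter threshold on
    the step-1 survivors, so every retained analyte and sample ends with a
    recomputed call rate ≥ ``step2``.
    """

    def __init__(self, step1: float = 0.65, step2: float = 0.85):
        self.step1 = step1
        self.step2 = step2

    def fit_transform(self, m: ProteomicsMatrix, y=None) -> ProteomicsMatrix:
        if not (0 < self.step1 <= 1 and 0 < self.step2 <= 1):
            raise ValueError("call-rate thresholds must lie in (0, 1]")
        if self.step1 > self.step2:
            raise ValueError("step1 must not exceed step2")
        v = m.values
        if v.size == 0:
            raise ValueError("empty matrix")

        analyte_log = pd.DataFrame(
            {"analyte_id": v.columns, "call_rate_initial": v.notna().mean().to_numpy()}
        ).set_index("analyte_id")
        sample_log = pd.DataFrame(
            {"sample_id": v.index, "call_rate_initial": v.notna().mean(axis=1).to_numpy()}
        ).set_index("sample_id")

        removed = {}
        cur = v
        for label, thr in (("step1", self.step1), ("step2", self.step2)):
            a_rate = cur.notna().mean()
            keep_a = a_rate >= thr
            cur = cur.loc[:, keep_a]
            s_rate = cur.notna().mean(axis=1)
            keep_s = s_rate >= thr
            cur = cur.loc[keep_s, :]
            removed[label] = (int((~keep_a).sum()), int((~keep_s).sum()))
            if label == "step1":
                analyte_log["call_rate_after_step1"] = cur.notna().mean().reindex(
                    analyte_log.index
                )
                sample_log["call_rate_after_step1"] = cur.notna().mean(axis=1).reindex(
                    sample_log.index
                )
        if cur.shape[1] == 0 or cur.shape[0] == 0:
            raise ValueError(f"all analytes or samples removed; removals by step: {removed}")

        analyte_log["kept"] = analyte_log.index.isin(cur.columns)
        sample_log["kept"] = sample_log.index.isin(cur.index)
        self.analyte_records_ = analyte_log.reset_index()
        self.sample_records_ = sample_log.reset_index()
        self.removed_ = removed
        return ProteomicsMatrix(cur, m.scale)

    def fit(self, m: ProteomicsMatrix, y=None):
        self.fit_transform(m)
        return self


def call_rate_filter(m: ProteomicsMatrix, step1: float = 0.65, step2: float = 0.85):
    """Functional wrapper returning (filtered matrix, analyte table, sample table)."""
    f = CallRateFilter(step1=step1, step2=step2)
    out = f.fit_transform(m)
    return out, f.analyte_records_, f.sample_records_


def qc_report(
    filtered: ProteomicsMatrix,
    mask_records: pd.DataFrame | None = None,
    analyte_records: pd.DataFrame | None = None,
    sample_records: pd.DataFrame | None = None,
    lod: pd.Series | None = None,
):
    """Assemble per-analyte and per-sample QC summaries.

    CV is SD/mean of the linear-scale values per analyte (sample SD); LOD is
    a pass-through column when supplied.  Neither influences which analytes
    or samples were kept.
    """
    linear = filtered.to_scale("linear").values
    mean = linear.mean()
    sd = linear.std(ddof=1)
    cv = sd / mean
    rep = pd.DataFrame({"analyte_id": filtered.analyte_ids})
    rep["cv"] = cv.reindex(rep["analyte_id"]).to_numpy()
    if lod is not None:
        rep["lod"] = pd.Series(lod).reindex(rep["analyte_id"]).to_numpy()
    if mask_records is not None:
        rep = rep.merge(
            mask_records[["analyte_id", "n_outliers_masked", "iqr"]],
            on="analyte_id", how="left",
        )
    if analyte_records is not None:
        rep = rep.merge(analyte_records, on="analyte_id", how="left")
    else:
        rep["kept"] = True
    samp = (
        sample_records
        if sample_records is not None
        else pd.DataFrame({"sample_id": filtered.sample_ids, "kept": True})
    )
    return rep, samp


def run_qc(m: ProteomicsMatrix, k: float = 1.5, step1: float = 0.65,
           step2: float = 0.85, lod: pd.Series | None = None):
    """Full QC stage: mask → filter → report.

    Returns (filtered matrix, analyte report, sample report).
    """
    masked, mask_rec = mask_iqr_outliers(m, k=k)
    filtered, a_rec, s_rec = call_rate_filter(masked, step1=step1, step2=step2)
    a_report, s_report = qc_report(filtered, mask_rec, a_rec, s_rec, lod=lod)
    return filtered, a_report, s_report
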