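"""Cross-run, cross-matrix and cross-platform reproducibility summaries.

Per-analyte Pearson correlations between paired measurements (same sample
measured twice — different runs, anticoagulants, or platforms), with the
per-analyte IQR of the first run retained so reproducibility can be related
to biological spread.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ProteomicsMatrix


def paired_correlations(
    m_a: ProteomicsMatrix,
    m_b: ProteomicsMatrix,
    pairing: pd.DataFrame | None = None,
    analyte_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-analyte Pearson r across paired samples (pairwise-complete).

    ``pairing`` maps sample IDs of A to B (columns ``sample_a``,
    ``sample_b``); identity pairing on shared IDs by default.
    ``analyte_map`` likewise maps analyte IDs (``analyte_a``, ``analyte_b``)
    for cross-platform comparisons; shared analyte IDs by default.
    Analytes with < 3 complete pairs get missing r and ``flagged=True``.
    """
    va, vb = m_a.values, m_b.values
    if pairing is None:
        shared = [s for s in va.index if s in set(vb.index)]
        pairing = pd.DataFrame({"sample_a": shared, "sample_b": shared})
    if analyte_map is None:
        cols = [c for c in va.columns if c in set(vb.columns)]
        analyte_map = pd.DataFrame({"analyte_a": cols, "analyte_b": cols})
    A = va.reindex(pairing["sample_a"])
    B = vb.reindex(pairing["sample_b"])
    rows = []
    for _, row in analyte_map.iterrows():
        x = A[row["analyte_a"]].to_numpy(dtype=float)
        y = B[row["analyte_b"]].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        xo = x[ok]
        iqr = float(np.subtract(*np.quantile(xo, [0.75, 0.25]))) if n else np.nan
        if n < 3 or np.std(xo) == 0 or np.std(y[ok]) == 0:
            rows.append((row["analyte_a"], row["analyte_b"], np.nan, np.nan, n, iqr, True))
            continue
        r, p = stats.pearsonr(xo, y[ok])
        rows.append((row["analyte_a"], row["analyte_b"], float(r), float(p), n, iqr, False))
    return pd.DataFrame(
        rows,
        columns=["analyte_id", "analyte_id_b", "r", "p_r", "n_pairs",
                 "iqr_run1", "flagged"],
    )


def summarize_reproducibility(records: pd.DataFrame, r_threshold: float = 0.7) -> dict:
    """Mean r across analytes and the fraction above a threshold."""
    r = records["r"].dropna()
    return {
        "mean_r": float(r.mean()),
        "n_analytes": int(len(r)),
        "frac_above_threshold": float((r > r_threshold).mean()),
        "r_threshold": r_threshold,
    }


def iqr_vs_reproducibility(records: pd.DataFrame) -> dict:
    """Pearson correlation of per-analyte IQR with cross-run r."""
    sub = records.dropna(subset=["r", "iqr_run1"])
    if len(sub) < 10:
        raise ValueError(f"need >= 10 analytes with defined r, got {len(sub)}")
    if sub["r"].std() == 0 or sub["iqr_run1"].std() == 0:
        return {"r": np.nan, "p": np.nan, "n": int(len(sub)), "flagged": True}
    r, p = stats.pearsonr(sub["iqr_run1"], sub["r"])
    return {"r": float(r), "p": float(p), "n": int(len(sub)), "flagged": False}
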