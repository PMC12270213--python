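"""Concordance between biomarker classifications and reference statuses.

Covers the 2×2 (single-cutoff) and 2×3 (dual-cutoff, intermediate zone
dropped) confusion summaries against PET/CSF reference status, and the
APOE-ε4 comparison between the ε4-proteoform assay and direct genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cutoffs import GaussianMixtureCutoff
from .matrix import ProteomicsMatrix, normalize_apoe


def _round_half_up(x: float, dp: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -dp, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    n_intermediate: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def concordance_pct(self) -> float:
        """Percent agreement on retained samples, half-up to 2 dp."""
        return _round_half_up(100.0 * (self.tp + self.tn) / self.n)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self):
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def npv(self):
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else None


def confusion(pred, ref, drop_intermediate: bool = False) -> ConfusionSummary:
    """Confusion summary of predicted vs reference binary labels.

    ``pred`` may be binary (0/1) or trichotomous ('low'/'intermediate'/
    'high'); with ``drop_intermediate`` the intermediate zone is removed
    before counting, so concordance is evaluated on high/low calls only.
    """
    pred = pd.Series(list(pred))
    ref = pd.Series(list(ref))
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(ref)}")
    n_inter = 0
    if pred.dtype == object:
        inter = pred == "intermediate"
        n_inter = int(inter.sum())
        if drop_intermediate:
            pred, ref = pred[~inter], ref[~inter]
        pred = pred.map({"low": 0, "high": 1, "intermediate": 1})
    p = pred.astype(int).to_numpy()
    r = pd.Series(ref).astype(int).to_numpy()
    return ConfusionSummary(
        tp=int(((p == 1) & (r == 1)).sum()),
        fp=int(((p == 1) & (r == 0)).sum()),
        tn=int(((p == 0) & (r == 0)).sum()),
        fn=int(((p == 0) & (r == 1)).sum()),
        n_intermediate=n_inter,
    )


def genotype_to_apoe4(genotype):
    """ε4 carrier label from the 6-value genotype vocabulary.

    ε2/ε2, ε2/ε3, ε3/ε3 → negative (0); ε2/ε4, ε3/ε4, ε4/ε4 → positive (1);
    missing stays missing.
    """
    g = normalize_apoe(genotype)
    if g is None:
        return None
    return int("e4" in g)


def classify_apoe4_from_proteoform(
    m: ProteomicsMatrix, apoe_analyte: str = "APOE4", seed: int = 0
) -> tuple[pd.Series, GaussianMixtureCutoff]:
    """ε4 carrier calls from the ε4-proteoform assay via a GMM cutoff.

    The proteoform signal is bimodal (carriers express the ε4 isoform);
    the two-component equal-posterior cutoff splits the modes.  Returns
    (labels indexed by sample_id, fitted cutoff model); the model's
    ``low_confidence_`` flag marks near-unimodal inputs.
    """
    if apoe_analyte not in m.analyte_ids:
        raise ValueError(f"analyte {apoe_analyte!r} not in matrix")
    x = m.values[apoe_analyte]
    model = GaussianMixtureCutoff(seed=seed).fit(x.dropna())
    labels = pd.Series(model.predict(x), index=x.index, name="apoe4_proteoform")
    return labels, model


def apoe_concordance(meta: pd.DataFrame, proteoform_labels: pd.Series) -> ConfusionSummary:
    """Confusion of proteoform-based vs genotype-based ε4 status."""
    meta = meta.set_index("sample_id", drop=False)
    geno = meta["apoe_genotype"].map(
        lambda g: genotype_to_apoe4(g) if pd.notna(g) else None
    )
    both = pd.DataFrame({"pred": proteoform_labels, "ref": geno}).dropna()
    return confusion(both["pred"].astype(int), both["ref"].astype(int))
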