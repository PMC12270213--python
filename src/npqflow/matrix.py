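"""Core containers and file I/O for NPQ proteomics tables.

NPQ (NULISA Protein Quantification) values arrive log2-transformed from the
platform; analyses here work on the log10 scale and back-transform to linear
NPQ where needed.  :class:`ProteomicsMatrix` carries the samples × analytes
grid together with an explicit scale tag so every transform is checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCALES = ("log2", "linear", "log10")

#: tokens accepted as missing on read; "NA" is written
NA_TOKENS = ("", "NA", "NaN", "nan")

LOG10_2 = math.log10(2.0)


class ScaleError(ValueError):
    """A scale transform was requested on data that does not admit it."""


def _check_ids(ids, what: str) -> list:
    ids = list(ids)
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ProteomicsMatrix:
    """Samples × analytes NPQ grid with missingness and a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by sample ID with analyte IDs as columns; missing
        measurements are NaN.
    scale
        One of ``log2``, ``linear``, ``log10``.  Linear values must be
        strictly positive wherever observed.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        _check_ids(self.values.index, "sample")
        _check_ids(self.values.columns, "analyte")
        self.values = self.values.astype(float)
        if self.scale == "linear":
            bad = (self.values <= 0) & self.values.notna()
            if bad.to_numpy().any():
                cells = list(bad.stack()[lambda s: s].index[:5])
                raise ScaleError(f"nonpositive linear NPQ values at {cells}")

    # -- basic views -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ProteomicsMatrix":
        return ProteomicsMatrix(self.values.copy(), self.scale)

    # -- scale transforms --------------------------------------------
    def to_scale(self, target: str) -> "ProteomicsMatrix":
        """Return the matrix re-expressed on ``target`` scale.

        log↔log conversions are a multiplicative change of base; linear→log
        requires strictly positive observed values and raises
        :class:`ScaleError` listing offending cells otherwise.
        """
        if target not in SCALES:
            raise ValueError(f"unknown scale {target!r}")
        if target == self.scale:
            return self.copy()
        v = self.values
        if self.scale == "linear":
            out = np.log2(v) if target == "log2" else np.log10(v)
        elif target == "linear":
            out = np.exp2(v) if self.scale == "log2" else np.power(10.0, v)
        elif self.scale == "log2":  # -> log10
            out = v * LOG10_2
        else:  # log10 -> log2
            out = v / LOG10_2
        return ProteomicsMatrix(out, target)


def transform_scale(m: ProteomicsMatrix, target: str) -> ProteomicsMatrix:
    """Functional alias for :meth:`ProteomicsMatrix.to_scale`."""
    return m.to_scale(target)


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_npq_matrix(path, scale: str) -> ProteomicsMatrix:
    """Read a delimited NPQ table (first column sample IDs, header analytes).

    Delimiter is comma for ``.csv`` and tab otherwise.  Blank/NA/NaN cells
    are missing.  Duplicate IDs or non-numeric cells are hard errors naming
    the offending coordinate.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_ids(header, "analyte")  # pandas would mangle duplicates to A.1
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    _check_ids(df.index, "sample")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        missing = raw.isin(NA_TOKENS)
        try:
            out[col] = pd.to_numeric(raw.where(~missing))
        except (ValueError, TypeError):
            for row, tok in raw.items():
                if tok not in NA_TOKENS:
                    try:
                        float(tok)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric cell at sample {row!r}, analyte {col!r}: {tok!r}"
                        ) from None
            raise
    return ProteomicsMatrix(out, scale)


def write_npq_matrix(m: ProteomicsMatrix, path) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path), na_rep="NA")


def write_table(records: pd.DataFrame, path, allow_empty: bool = False) -> None:
    """Write a result table as delimited text with full-precision floats.

    Column order is preserved as given (deterministic); floats use Python
    ``repr`` precision via pandas' default round-trip formatting.
    """
    if len(records) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table without allow_empty=True")
    path = Path(path)
    records.to_csv(path, sep=_sep_for(path), na_rep="NA", index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), na_values=list(NA_TOKENS), keep_default_na=False)


# ---------------------------------------------------------------- metadata

DIAGNOSES = ("AD", "DLB", "FTD", "PD", "CO")
SEXES = ("male", "female")

#: canonical 6-genotype vocabulary (ASCII 'e' accepted alongside 'ε')
APOE_GENOTYPES = ("e2/e2", "e2/e3", "e3/e3", "e2/e4", "e3/e4", "e4/e4")

METADATA_NUMERIC = (
    "age_at_draw",
    "cdr",
    "amyloid_pet",
    "tau_pet",
    "csf_ab_ratio",
    "age_at_onset",
    "age_at_last_followup",
)


def normalize_apoe(genotype):
    """Map an APOE genotype string onto the canonical ``eX/eY`` form."""
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        return None
    g = str(genotype).replace("ε", "e").replace("E", "e").strip()
    a = sorted(g.split("/"))
    g = "/".join(a)
    if g not in APOE_GENOTYPES:
        raise ValueError(f"unknown APOE genotype {genotype!r}")
    return g


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample-metadata table.

    Requires unique ``sample_id``, known diagnosis/sex vocabulary, and (for
    progression analyses) onset after draw; violations raise ``ValueError``.
    """
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    bad_dx = set(meta["diagnosis"]) - set(DIAGNOSES)
    if bad_dx:
        raise ValueError(f"unknown diagnosis values: {sorted(bad_dx)}")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    if "apoe_genotype" in meta:
        meta["apoe_genotype"] = [
            normalize_apoe(g) if pd.notna(g) else None for g in meta["apoe_genotype"]
        ]
    for col in METADATA_NUMERIC:
        if col in meta:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    if "age_at_onset" in meta and (meta["age_at_onset"].dropna() < 0).any():
        raise ValueError("negative age_at_onset")
    return meta


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(read_table(path))


# ---------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Pipeline thresholds and model options shared by all stages."""

    seed: int = 0
    call_rate_step1: float = 0.65
    call_rate_step2: float = 0.85
    iqr_multiplier: float = 1.5
    fdr_level: float = 0.05
    amyloid_pet_cutoff: float = 20.0   # Centiloids
    tau_pet_cutoff: float = 1.5        # SUVR
    csf_ab_cutoff: float = 0.0673      # Aβ42/Aβ40
    n_sv: int = 2
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    em_restarts: int = 5
    n_bootstrap: int = 2000
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.call_rate_step1 <= 1 and 0 < self.call_rate_step2 <= 1):
            raise ValueError("call-rate thresholds must lie in (0, 1]")
        if self.call_rate_step1 > self.call_rate_step2:
            raise ValueError("step1 threshold must not exceed step2")
        if self.iqr_multiplier <= 0:
            raise ValueError("IQR multiplier must be positive")
        if not (0 < self.fdr_level < 1):
            raise ValueError("FDR level must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import json

        import yaml

        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)
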