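"""Core containers: the feature x sample count matrix and the sample sheet.

A :class:`CountMatrix` couples an integer count table (features in rows,
samples in columns) with the per-feature biotype label that drives
within-biotype normalization downstream.  A :class:`SampleTable` carries the
study design: subject id, sampling group (healthy control, pre-operative,
post-operative) and the clinical variables recorded per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("HC", "PreOp", "PostOp")

#: Clinical variable vocabularies (per-patient, breast-cancer cohort style).
CLINICAL_VOCAB = {
    "ER": ("positive", "negative"),
    "PR": ("positive", "negative"),
    "HER2_IHC": (0, 1, 2, 3),
    "grade": (2, 3),
    "T_stage": (1, 2, 3, 4),
    "TNBC": ("yes", "no"),
    "E_cadherin": ("positive", "negative"),
    "Ki67": ("<=14%", ">14%"),
}


class CountMatrixError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer feature x sample counts with one biotype label per feature."""

    counts: pd.DataFrame  # index: feature_id, columns: sample ids
    biotypes: pd.Series  # index: feature_id -> biotype

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.biotypes.index):
            self.biotypes = self.biotypes.reindex(self.counts.index)
        if self.biotypes.isna().any():
            missing = self.biotypes.index[self.biotypes.isna()].tolist()[:5]
            raise CountMatrixError(f"features without biotype: {missing}")
        if (np.asarray(self.counts) < 0).any():
            raise CountMatrixError("negative counts")
        if self.counts.columns.duplicated().any():
            raise CountMatrixError("duplicate sample ids")
        if self.counts.index.duplicated().any():
            raise CountMatrixError("duplicate feature ids")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)].copy(), self.biotypes.copy())

    def subset_features(self, feature_ids) -> "CountMatrix":
        idx = list(feature_ids)
        return CountMatrix(self.counts.loc[idx].copy(), self.biotypes.loc[idx].copy())

    def biotype_totals(self) -> pd.DataFrame:
        """Per-sample total reads of each biotype (biotype x sample)."""
        return self.counts.groupby(self.biotypes).sum()

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "biotype", self.biotypes)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        if "biotype" not in df.columns:
            raise CountMatrixError(f"{path}: missing 'biotype' column")
        biotypes = df.pop("biotype")
        return cls(df.astype(np.int64), biotypes)


@dataclass
class SampleTable:
    """Per-sample metadata table.

    Required columns: ``sample_id``, ``subject``, ``group`` (HC / PreOp /
    PostOp).  Clinical variables (ER, PR, HER2_IHC, grade, T_stage, TNBC,
    E_cadherin, Ki67) are carried for patient samples and empty for
    controls.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "subject", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise CountMatrixError(f"sample table missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise CountMatrixError(f"unknown groups {sorted(bad)}; valid: {GROUPS}")
        if self.table["sample_id"].duplicated().any():
            raise CountMatrixError("duplicate sample ids in sample table")
        self.table = self.table.reset_index(drop=True)

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def subjects_for(self, sample_ids) -> pd.Series:
        t = self.table.set_index("sample_id")
        return t.loc[list(sample_ids), "subject"]

    def clinical(self) -> pd.DataFrame:
        """One row per patient subject with the clinical variables."""
        pat = self.table[self.table["group"] == "PreOp"]
        cols = [c for c in CLINICAL_VOCAB if c in pat.columns]
        return pat.set_index("subject")[cols]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t"))
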