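"""Expression matrix container and TSV round-trip.

Rows are RNAs (with a class label in {lncRNA, miRNA, mRNA}), columns are
samples.  Values are RPKM before preprocessing and log2(RPKM) after.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")


class EmptyMatrixError(ValueError):
    """Raised when a filter leaves no rows behind."""


@dataclass
class ExpressionMatrix:
    """RNAs x samples expression matrix with per-row RNA class labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix indexed by RNA id with sample ids as columns.
    rna_class : pandas.Series
        Class label per RNA id, values in ``{"lncRNA", "miRNA", "mRNA"}``.
    subtype : str
        Cohort label (e.g. a PAM50 subtype or ``"synthetic"``).
    """

    values: pd.DataFrame
    rna_class: pd.Series
    subtype: str = "synthetic"
    log_scale: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate RNA ids: {dups[:5]}")
        self.rna_class = self.rna_class.reindex(self.values.index)
        if self.rna_class.isna().any():
            missing = self.rna_class.index[self.rna_class.isna()].tolist()
            raise ValueError(f"RNA ids without class label: {missing[:5]}")
        bad = set(self.rna_class.unique()) - set(RNA_CLASSES)
        if bad:
            raise ValueError(f"unknown RNA classes: {sorted(bad)}")

    # -- basic accessors ---------------------------------------------------

    @property
    def rna_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def of_class(self, rna_class: str) -> pd.DataFrame:
        """Sub-matrix of all RNAs of one class."""
        if rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {rna_class!r}")
        return self.values.loc[self.rna_class == rna_class]

    def subset(self, rna_ids) -> "ExpressionMatrix":
        """New matrix restricted to ``rna_ids`` (sample order preserved)."""
        vals = self.values.loc[rna_ids]
        return ExpressionMatrix(
            values=vals,
            rna_class=self.rna_class.loc[vals.index],
            subtype=self.subtype,
            log_scale=self.log_scale,
        )

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write as TSV with a leading ``class`` column."""
        out = self.values.copy()
        out.insert(0, "class", self.rna_class.values)
        out.to_csv(path, sep="\t", index_label="rna_id")

    @classmethod
    def from_tsv(cls, path, subtype: str = "synthetic",
                 log_scale: bool = False) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "class" not in df.columns:
            raise ValueError(f"{path}: expected a 'class' column")
        rna_class = df.pop("class")
        return cls(values=df.astype(float), rna_class=rna_class,
                   subtype=subtype, log_scale=log_scale)
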