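"""Core in-memory containers for the stricture-biomarker pipeline.

The canonical expression container is a genes x samples table of
normalized TPM (or its log2(TPM+1) transform), carried together with an
explicit scale flag so downstream stages can refuse inputs on the wrong
scale instead of silently double-transforming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three matched resection sites of the study design.
SITES: tuple[str, str, str] = ("stricture", "proximal", "distal")

#: Site treated as diseased in every binary (stricture vs margin) coding.
STRICTURE: str = "stricture"

METADATA_COLUMNS = ("sample_id", "patient_id", "site")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with an explicit scale flag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
    scale : {"tpm", "log"}
        ``"tpm"`` for normalized transcripts-per-million (all values >= 0),
        ``"log"`` for log2(TPM + 1).
    """

    values: pd.DataFrame
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log"):
            raise ValueError(f"scale must be 'tpm' or 'log', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains missing or non-finite values")
        if self.scale == "tpm" and arr.size and arr.min() < 0:
            raise ValueError("TPM-scale matrix contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Samples x genes view (the sklearn orientation)."""
        return self.values.T

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], scale=self.scale)


def validate_metadata(meta: pd.DataFrame, allowed_sites=SITES) -> pd.DataFrame:
    """Validate a sample-metadata table (sample_id, patient_id, site).

    Returns the table with sample_id as a plain column; raises ``ValueError``
    naming the offending field otherwise.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("metadata sample_id values are not unique")
    bad = sorted(set(meta["site"]) - set(allowed_sites))
    if bad:
        raise ValueError(f"unknown site labels: {bad} (expected {list(allowed_sites)})")
    return meta.reset_index(drop=True)


def align_metadata(matrix: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reordered to the matrix's sample order."""
    meta = validate_metadata(meta)
    indexed = meta.set_index("sample_id")
    missing = [s for s in matrix.samples if s not in indexed.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    return indexed.loc[matrix.samples].rename_axis("sample_id").reset_index()


@dataclass
class FilterReport:
    """Accounting of the gene filters: input = retained + removed."""

    n_input_genes: int
    n_removed_low_count: int
    n_removed_low_variance: int
    retained_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n_ret = len(self.retained_genes)
        if self.n_input_genes != n_ret + self.n_removed_low_count + self.n_removed_low_variance:
            raise ValueError("filter report does not account for every input gene")
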