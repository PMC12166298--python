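"""TSV readers and writers for the pipeline's table formats.

The canonical expression format is a UTF-8 TSV with a header row of sample
ids and gene ids in the first column (named ``gene``). A GEO series matrix
(e.g. for accession GSE192786) can be exported to this shape by saving the
expression table with genes as rows and samples as columns, tab-separated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_metadata

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_ct_tsv",
]


def read_expression_tsv(path, scale: str = "tpm") -> ExpressionMatrix:
    """Read a genes x samples TSV; reject duplicates and non-numeric cells."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dups}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        raw = df[col]
        if raw.isna().any():
            first = df.index[np.argmax(raw.isna().to_numpy())]
            raise ValueError(f"missing value at gene {first!r}, sample {col!r} in {path}")
        try:
            # str->float via numpy is exact (shortest-repr round trip)
            values[:, j] = raw.to_numpy().astype(float)
        except ValueError:
            for gene, cell in raw.items():
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
                    ) from None
            raise
    frame = pd.DataFrame(values, index=df.index, columns=df.columns)
    frame.index.name = "gene"
    return ExpressionMatrix(frame, scale=scale)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")  # default shortest-repr floats round-trip exactly


def read_metadata_tsv(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)


def read_ct_tsv(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    for col in ("ct_target", "ct_housekeeping"):
        if col in ct.columns:
            ct[col] = pd.to_numeric(ct[col])
    return ct
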