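"""Expression transform and gene filters.

TPM values are log-transformed with a pseudocount of 1 (base 2, so a
two-fold change equals a mean difference of 1). Genes with a transformed
value below 1 in any sample are excluded, then genes in the lowest decile
of per-gene variance among the survivors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix, FilterReport


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every TPM value v by log2(v + 1); shape and ids unchanged."""
    if m.scale != "tpm":
        raise ValueError("input is already log-scale; log_transform expects TPM")
    if m.values.to_numpy().min() < 0:
        raise ValueError("negative TPM value encountered")
    return ExpressionMatrix(np.log2(m.values + 1.0), scale="log")


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Round-trip inverse: v -> 2**v - 1."""
    if m.scale != "log":
        raise ValueError("inverse_log_transform expects a log-scale matrix")
    return ExpressionMatrix(np.exp2(m.values) - 1.0, scale="tpm")


class GeneFilter(BaseEstimator, TransformerMixin):
    """Remove low-count then low-variance genes from a log-scale matrix.

    Operates on samples x genes frames (sklearn orientation). ``fit`` learns
    the retained gene set: first drop any gene whose log2(TPM+1) value is
    below ``min_value`` in any sample, then drop survivors whose variance
    falls strictly below the ``variance_quantile`` quantile of survivor
    variances (zero-variance genes are always dropped when the quantile is
    positive).

    Attributes
    ----------
    retained_genes_ : list of str
    report_ : FilterReport
    """

    def __init__(self, min_value: float = 1.0, variance_quantile: float = 0.10):
        self.min_value = min_value
        self.variance_quantile = variance_quantile

    def fit(self, X: pd.DataFrame, y=None):
        if not 0.0 <= self.variance_quantile < 1.0:
            raise ValueError("variance_quantile must lie in [0, 1)")
        X = pd.DataFrame(X)
        n_input = X.shape[1]
        low_count = (X < self.min_value).any(axis=0)
        survivors = X.loc[:, ~low_count]
        if survivors.shape[1] == 0:
            raise ValueError("empty matrix: every gene removed by the low-count filter")
        var = survivors.var(axis=0, ddof=1)
        if self.variance_quantile > 0:
            thresh = float(np.quantile(var.to_numpy(), self.variance_quantile))
            low_var = (var < thresh) | (var == 0.0)
        else:
            low_var = pd.Series(False, index=var.index)
        retained = var.index[~low_var].tolist()
        if not retained:
            raise ValueError("empty matrix: every gene removed by the variance filter")
        self.retained_genes_ = retained
        self.report_ = FilterReport(
            n_input_genes=n_input,
            n_removed_low_count=int(low_count.sum()),
            n_removed_low_variance=int(low_var.sum()),
            retained_genes=retained,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X).loc[:, self.retained_genes_]


def filter_genes(
    m: ExpressionMatrix, variance_quantile: float = 0.10, min_value: float = 1.0
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply the low-count then low-variance filters to a log-scale matrix."""
    if m.scale != "log":
        raise ValueError("filter_genes expects a log-scale matrix")
    f = GeneFilter(min_value=min_value, variance_quantile=variance_quantile)
    f.fit(m.to_samples_by_genes())
    return m.subset_genes(f.retained_genes_), f.report_
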