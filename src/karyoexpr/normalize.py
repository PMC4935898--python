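"""Normalization shared by all analysis stages.

Two scalings are used downstream: reads-per-million (rpm/CPM) on raw library
totals for chromosome-level and XIST statistics, and median-of-ratios size
factors for gene-level comparisons (differential expression, marker panels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError


@dataclass
class NormalizedMatrix:
    """A genes x samples matrix of normalized values with a method tag."""

    values: pd.DataFrame
    method: str

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def _counts_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def cpm(counts) -> NormalizedMatrix:
    """Reads per million: ``counts * 1e6 / library_total`` per sample."""
    df = _counts_frame(counts)
    totals = df.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"zero total counts for sample(s) {zero}; cannot scale to rpm")
    return NormalizedMatrix(df * 1e6 / totals, method="cpm")


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Per gene with all-positive counts, the geometric mean across samples is a
    pseudo-reference; each sample's factor is the median over those genes of
    count / pseudo-reference.  Genes with a zero in any sample carry no
    information for the estimator and are ignored.
    """
    df = _counts_frame(counts)
    positive = df.gt(0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; "
            "median-of-ratios size factors are undefined (pseudo-reference fallback is disabled)"
        )
    logs = np.log(df.loc[positive].to_numpy(dtype=float))
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_sf = np.median(logs - log_geomean, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1 across samples
    return pd.Series(np.exp(log_sf), index=df.columns, name="size_factor")


def normalize_by_size_factors(counts) -> NormalizedMatrix:
    """Counts divided by their median-of-ratios size factors."""
    df = _counts_frame(counts)
    sf = size_factors(df)
    return NormalizedMatrix(df / sf, method="size_factor")


def log_transform(norm) -> NormalizedMatrix:
    """log2(x + 1) on a NormalizedMatrix (or plain DataFrame) of values >= 0."""
    if isinstance(norm, NormalizedMatrix):
        values, method = norm.values, norm.method
    else:
        values, method = norm, "raw"
    if (values.to_numpy() < 0).any():
        raise ValidationError("log_transform requires non-negative values")
    return NormalizedMatrix(np.log2(values + 1.0), method=f"log2({method}+1)")
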