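"""Size-factor normalization and expression units shared by all stages.

Size factors are median-of-ratios: each sample's factor is the median, over
reference genes (genes with no zero count in any sample), of the ratio of the
sample's count to the gene's geometric mean across samples.  RNA and Ribo
assays are normalized separately but jointly across all species and samples
of the assay; counts are length-adjusted *before* factors are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("ribevol")


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Counts divided by per-sample size factors."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.size_factors.to_numpy()).all():
            raise NormalizationError("non-finite size factor")
        if (self.size_factors <= 0).any():
            raise NormalizationError("size factors must be positive")


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those with a positive count in every sample; with an
    even number of reference genes the median is the mean of the two central
    ratios (numpy convention).
    """
    mat = counts.counts.to_numpy(dtype=float)
    reference = (mat > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference fallback)")
    ref = mat[reference]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    logger.info("size factors over %d reference genes, %d samples",
                int(reference.sum()), mat.shape[1])
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def normalize(counts: CountMatrix, factors: pd.Series | None = None) -> NormalizedMatrix:
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.counts.columns)
    if factors.isna().any():
        missing = factors.index[factors.isna()][0]
        raise NormalizationError(f"no size factor for sample {missing!r}")
    values = counts.counts.div(factors, axis=1)
    return NormalizedMatrix(values, factors)


def length_adjust(counts: CountMatrix) -> CountMatrix:
    """Divide each gene's counts by its length in kilobases."""
    if counts.feature_lengths is None:
        raise NormalizationError("feature lengths required for length adjustment")
    kb = counts.feature_lengths.astype(float) / 1000.0
    adjusted = counts.counts.div(kb, axis=0)
    return CountMatrix(adjusted, counts.feature_lengths)


def fpkm(counts: CountMatrix, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """FPKM[g, s] = count / (length_kb * libsize_millions).

    ``library_sizes`` defaults to the column sums of the matrix (total mapped
    reads assigned to features).
    """
    if counts.feature_lengths is None:
        raise NormalizationError("feature lengths required for FPKM")
    if library_sizes is None:
        library_sizes = counts.counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.counts.columns).astype(float)
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0][0]
        raise NormalizationError(f"zero library size for sample {bad!r}")
    kb = counts.feature_lengths.astype(float) / 1000.0
    per_million = library_sizes / 1e6
    return counts.counts.div(kb, axis=0).div(per_million, axis=1)
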