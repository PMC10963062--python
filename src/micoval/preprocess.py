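"""Missing-data handling and normalization for abundance tables.

The default pipeline applied before any analysis is

1. prevalence filter — drop features that are zero in strictly more than
   80% of samples,
2. zero imputation — replace remaining zeros by one tenth of the smallest
   positive abundance in the table,
3. total-sum scaling (TSS) — divide each sample by its total.

Median-of-ratios (as used by DESeq2) and rarefaction to a fixed library
size are available as alternative normalizations for count tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)


def filter_low_prevalence(
    table: FeatureTable, max_missing_fraction: float = 0.80
) -> FeatureTable:
    """Drop features whose zero fraction strictly exceeds the threshold.

    Zeros are treated as missing. A feature zero in exactly
    ``max_missing_fraction`` of samples is retained; the sample set is
    never changed.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValidationError("max_missing_fraction must lie in [0, 1]")
    zero_frac = (table.data.to_numpy() == 0).mean(axis=1)
    keep = zero_frac <= max_missing_fraction
    return table.with_data(table.data.loc[keep])


def impute_zeros(table: FeatureTable, per_feature: bool = False) -> FeatureTable:
    """Replace zeros by one tenth of the minimum positive abundance.

    The minimum is taken over the whole table by default; ``per_feature``
    switches to each feature's own minimum positive value. Positive
    entries are never modified.
    """
    values = table.data.to_numpy(dtype=float).copy()
    if not (values > 0).any():
        raise ValidationError("cannot impute an all-zero table")
    if per_feature:
        for i in range(values.shape[0]):
            row = values[i]
            pos = row[row > 0]
            fill = (pos.min() if pos.size else np.nan) / 10
            if pos.size:
                row[row == 0] = fill
    else:
        fill = values[values > 0].min() / 10
        values[values == 0] = fill
    data = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    return table.with_data(data)


def tss_normalize(table: FeatureTable) -> FeatureTable:
    """Total-sum scaling: divide each sample column by its total."""
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"zero-sum samples cannot be TSS-normalized: {zero.index.tolist()}")
    return table.with_data(table.data / sums, units="relative")


def rarefy(table: FeatureTable, depth: int | str = "min", seed: int = 0) -> FeatureTable:
    """Subsample each count column without replacement to a common depth.

    ``depth="min"`` uses the smallest library size. Samples whose total is
    below an explicit integer depth are dropped with a warning. Sampling
    is multivariate hypergeometric and fully determined by ``seed``.
    """
    if table.units != "counts":
        raise ValidationError("rarefaction requires a count table")
    counts = table.data.to_numpy(dtype=float)
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    totals = counts.sum(axis=0)
    if depth == "min":
        target = int(totals.min())
    else:
        target = int(depth)
        if target <= 0:
            raise ValidationError("depth must be positive")
    keep = totals >= target
    if not keep.all():
        dropped = table.data.columns[~keep].tolist()
        logger.warning("dropping %d samples below depth %d: %s", len(dropped), target, dropped)
    rng = np.random.default_rng(seed)
    out = np.zeros((counts.shape[0], int(keep.sum())), dtype=np.int64)
    cols = []
    j = 0
    for col_idx, col in enumerate(table.data.columns):
        if not keep[col_idx]:
            continue
        out[:, j] = rng.multivariate_hypergeometric(counts[:, col_idx], target)
        cols.append(col)
        j += 1
    data = pd.DataFrame(out.astype(float), index=table.data.index, columns=cols)
    return table.with_data(data, units="counts")


def median_of_ratios_normalize(table: FeatureTable) -> FeatureTable:
    """Median-of-ratios size-factor normalization for count tables.

    Size factor of a sample = median, over features positive in every
    sample, of count / geometric mean across samples; each column is
    divided by its size factor.
    """
    if table.units != "counts":
        raise ValidationError("median-of-ratios requires a count table")
    values = table.data.to_numpy(dtype=float)
    all_pos = (values > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no feature is positive in all samples; impute zeros first"
        )
    ref = values[all_pos]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geomean[:, None]
    size_factors = np.median(ratios, axis=0)
    data = table.data / size_factors
    return table.with_data(data, units="counts")


def size_factors(table: FeatureTable) -> pd.Series:
    """Median-of-ratios size factors without applying them."""
    values = table.data.to_numpy(dtype=float)
    all_pos = (values > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no feature is positive in all samples; impute zeros first"
        )
    ref = values[all_pos]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    return pd.Series(
        np.median(ref / geomean[:, None], axis=0), index=table.data.columns
    )


def default_pipeline(
    table: FeatureTable, max_missing_fraction: float = 0.80, impute: bool = True
) -> FeatureTable:
    """filter -> impute -> TSS, the predefined preprocessing order."""
    out = filter_low_prevalence(table, max_missing_fraction)
    if impute:
        out = impute_zeros(out)
    return tss_normalize(out)
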