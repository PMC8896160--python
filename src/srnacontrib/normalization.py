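"""Library-depth normalization by the median-of-ratios method.

Sequencing libraries differ in depth, so raw counts are not comparable
across libraries.  The size factor of library *j* is the median, over a set
of reference genes, of the ratio between the gene's count in library *j*
and its geometric mean across all libraries.  Reference genes are those with
strictly positive counts in every library (the geometric mean is zero
otherwise).  Dividing a library's counts by its size factor puts all
libraries on a common depth scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import CountMatrix


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per library.

    Ratios are formed on the linear scale and the median uses midpoint
    interpolation for even reference-set sizes, so the result is
    deterministic.

    Raises
    ------
    ValueError
        If no gene has strictly positive counts in every library.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has positive counts in all libraries; filter libraries or "
            "use an alternative normalization"
        )
    ref_counts = arr[ref]
    log_geomean = np.log(ref_counts).mean(axis=1)
    ratios = ref_counts / np.exp(log_geomean)[:, None]
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=df.columns, name="size_factor")


def normalize(counts: CountMatrix | pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each library's column by its size factor."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if set(df.columns) != set(size_factors.index):
        raise ValueError("size factors and count matrix cover different libraries")
    s = size_factors.reindex(df.columns)
    if not np.all(np.isfinite(s)) or (s <= 0).any():
        raise ValueError("size factors must be positive and finite")
    return df / s


def log2_display(count):
    """``log2(count + 1)`` display transform for normalized counts.

    Accepts scalars or arrays; rejects negative input.
    """
    arr = np.asarray(count, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(count) or arr.ndim == 0 else out
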