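"""Zero-preserving quantile normalization and reads-per-million scaling.

Raw unique-sequence count matrices from libraries of different depth are made
comparable in two steps:

1. ``quantile_normalize`` — quantile normalization restricted to the nonzero
   entries of each library.  A shared reference quantile function is the mean,
   across libraries, of each library's sorted nonzero values interpolated onto
   a common quantile grid; every nonzero entry is replaced by the reference
   evaluated at its within-library quantile.  Zeros are never assigned counts:
   a sequence not observed in a library stays at exactly 0.
2. ``scale_rpm`` — each library is scaled to one million reads, giving
   "reads per million quantile-normalized" (rpmqn) units.

Sparse sRNA matrices are dominated by structural zeros (most unique sRNAs are
absent from most libraries), so full-matrix quantile normalization would let
the zero mass distort the reference distribution; restricting to nonzero
entries sidesteps that.
"""

from __future__ import annotations

import numpy as np

from .core import CountMatrix

RPM = 1_000_000.0


def _rankdata_average(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean rank."""
    from scipy.stats import rankdata

    return rankdata(values, method="average")


def quantile_normalize(matrix: CountMatrix) -> CountMatrix:
    """Quantile-normalize nonzero entries of each library against a common reference.

    Requires a ``raw`` matrix with >= 2 libraries, each with at least one
    nonzero entry.  Ties within a library receive a common (mean) reference
    value; zeros are returned untouched.
    """
    if matrix.stage != "raw":
        raise ValueError(f"expected a raw matrix, got stage {matrix.stage!r}")
    X = matrix.data.to_numpy(dtype=float, copy=True)
    n_rows, n_cols = X.shape
    if n_cols < 1:
        raise ValueError("matrix must have at least one library")

    nonzero_masks = [X[:, j] > 0 for j in range(n_cols)]
    counts = [int(m.sum()) for m in nonzero_masks]
    for j, c in enumerate(counts):
        if c == 0:
            raise ValueError(
                f"library {matrix.data.columns[j]!r} has no nonzero entries"
            )

    # Common quantile grid sized to the densest library.
    m = max(counts)
    grid = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])

    curves = np.empty((n_cols, len(grid)))
    for j in range(n_cols):
        vals = np.sort(X[nonzero_masks[j], j])
        k = len(vals)
        pos = np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.5])
        curves[j] = np.interp(grid, pos, vals)
    reference = curves.mean(axis=0)

    out = X.copy()
    for j in range(n_cols):
        mask = nonzero_masks[j]
        vals = X[mask, j]
        k = len(vals)
        if k > 1:
            u = (_rankdata_average(vals) - 1.0) / (k - 1.0)
        else:
            u = np.array([0.5])
        out[mask, j] = np.interp(u, grid if m > 1 else np.array([0.5]), reference)

    import pandas as pd

    return CountMatrix(
        data=pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        stage="quantile",
    )


def scale_rpm(matrix: CountMatrix) -> CountMatrix:
    """Scale every library to one million reads (rpmqn units)."""
    if matrix.stage != "quantile":
        raise ValueError(f"expected a quantile matrix, got stage {matrix.stage!r}")
    totals = matrix.data.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"libraries with zero total: {bad}")
    scaled = matrix.data * (RPM / totals)
    return CountMatrix(data=scaled, stage="rpmqn")


def rpmqn(matrix: CountMatrix) -> CountMatrix:
    """Convenience: zero-preserving quantile normalization followed by rpm scaling."""
    return scale_rpm(quantile_normalize(matrix))
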