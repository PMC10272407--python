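"""First-order (intensity histogram) statistics of the masked voxels."""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import stats


def first_order(values: np.ndarray, voxel_volume: float = 1.0, n_bins: int = 32) -> Dict[str, float]:
    """The 19 first-order features of a masked voxel sample.

    ``values`` are the gray levels inside the mask; ``voxel_volume`` (in
    mm^3) scales ``TotalEnergy``.  ``Entropy`` and ``Uniformity`` are
    computed on a ``n_bins``-bin discretisation of the value range, the
    same fixed-bin-count rule used for the texture matrices.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("first-order features need at least one masked voxel")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p90 = np.percentile(x, [10, 90])
    mid = x[(x >= p10) & (x <= p90)]

    # discretised probabilities for entropy / uniformity
    lo, hi = x.min(), x.max()
    if hi > lo:
        bw = (hi - lo) / n_bins
        bins = np.minimum((x - lo) // bw, n_bins - 1).astype(np.int64)
    else:
        bins = np.zeros(n, dtype=np.int64)
    p = np.bincount(bins, minlength=n_bins) / n
    nz = p[p > 0]

    return {
        "Energy": float(np.sum(x ** 2)),
        "TotalEnergy": float(voxel_volume * np.sum(x ** 2)),
        "Entropy": float(-np.sum(nz * np.log2(nz))),
        "Minimum": float(lo),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(hi),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "Range": float(hi - lo),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(mid - mid.mean()))) if mid.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "StandardDeviation": float(np.sqrt(var)),
        "Skewness": float(stats.skew(x)) if var > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(x, fisher=False)) if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": float(np.sum(p ** 2)),
    }
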