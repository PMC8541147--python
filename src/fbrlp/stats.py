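"""Shared statistical primitives.

The percentile definition used throughout the package is the weighted-average
(n+1)-based estimator.  It is the single convention used for serving sizes,
frequency bounds and descriptive intake statistics, so that quantities derived
at different pipeline stages are mutually comparable.

The choice is not cosmetic: with this estimator the 95th percentile of a pooled
weekly-frequency distribution is positive exactly when at least 6 of 124
observations (two recalls) or 3 of 62 observations (one recall) are positive,
which is the food-list inclusion rule the rest of the pipeline relies on.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["percentile_weighted", "variance_components"]


def percentile_weighted(values: Sequence[float] | np.ndarray, p: float) -> float:
    """Weighted-average percentile with (n+1) positioning.

    Sort ``values`` ascending with 1-based ranks.  The percentile position is
    ``h = (n + 1) * p / 100``; the result interpolates linearly between the
    order statistics bracketing ``h``.  When ``h`` falls below rank 1 or above
    rank n the result clamps to the smallest / largest observation.

    Parameters
    ----------
    values : sequence of float
        Observations; must be non-empty.
    p : float
        Percentile in [0, 100].

    Returns
    -------
    float
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("percentile of an empty sequence is undefined")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    x = np.sort(x)
    n = x.size
    h = (n + 1) * p / 100.0
    if h <= 1.0:
        return float(x[0])
    if h >= n:
        return float(x[-1])
    lo = int(np.floor(h))
    frac = h - lo
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))


def variance_components(replicates: np.ndarray) -> tuple[float, float, float]:
    """Within/between variance decomposition for k replicate measurements.

    ``replicates`` is an (n_subjects, k) array of repeated daily intakes.
    Returns ``(s2_within, s2_between, grand_mean)`` where

    * ``s2_within``  — mean over subjects of the sample variance (ddof=1) of
      their k replicate values;
    * ``s2_between`` — ``max(0, var(subject means, ddof=1) - s2_within / k)``,
      the method-of-moments between-subject component truncated at zero.

    Truncation is required: sampling noise routinely drives the raw component
    negative when true between-subject spread is small, and a negative variance
    (hence CV) is not reportable.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2:
        raise ValueError("replicates must be a 2-D (subjects x replicates) array")
    n, k = reps.shape
    if n < 2:
        raise ValueError("variance decomposition needs at least 2 subjects")
    if k < 2:
        raise ValueError("variance decomposition needs at least 2 replicates per subject")
    s2w = float(np.mean(np.var(reps, axis=1, ddof=1)))
    means = reps.mean(axis=1)
    s2b = max(0.0, float(np.var(means, ddof=1)) - s2w / k)
    return s2w, s2b, float(means.mean())
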