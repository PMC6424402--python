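"""Periplasmic distance summaries comparing motors and relics.

A large spread of inner-to-outer-membrane distances at relic positions,
relative to intact motors, indicates that relics have no connection to the
inner membrane.  Quartiles use linear interpolation (numpy's default), so
summaries are bit-reproducible on fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DistanceSummary:
    klass: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    range_nm: float  # max - min


def summarize_distances(measurements: pd.DataFrame, klass: str) -> DistanceSummary:
    """Order statistics of the raw distances of one structure class.

    *measurements* needs columns ``klass`` and ``distance_nm``.
    """
    sel = measurements.loc[measurements["klass"] == klass, "distance_nm"]
    x = sel.to_numpy(dtype=float)
    if x.size < 1:
        raise ValueError(f"no measurements of class {klass!r}")
    if np.any(x <= 0):
        raise ValueError("distances must be positive")
    return DistanceSummary(
        klass=klass,
        n=int(x.size),
        mean=float(x.mean()),
        median=float(np.median(x)),
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
        range_nm=float(x.max() - x.min()),
    )


@dataclass(frozen=True)
class RangeComparison:
    difference_nm: float  # |range_a - range_b|
    larger: str | None  # klass with the larger range; None on a tie


def compare_ranges(a: DistanceSummary, b: DistanceSummary) -> RangeComparison:
    """Report the range difference and its ordering; no inferential claim."""
    diff = a.range_nm - b.range_nm
    if diff == 0:
        return RangeComparison(difference_nm=0.0, larger=None)
    return RangeComparison(
        difference_nm=abs(diff), larger=a.klass if diff > 0 else b.klass
    )
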