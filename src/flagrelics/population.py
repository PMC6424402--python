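"""Population-level flagellation accounting and swim-track velocimetry.

Mean flagella per cell with Student-t confidence intervals, absolute
population flagella from CFU counts, pole occupancy-class percentages,
hook-end statistics of shed flagella, and per-track speed estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .simulate import DetachedFlagellum, SwimTrack


@dataclass(frozen=True)
class MeanCI:
    mean: float
    lo: float
    hi: float
    n: int
    confidence: float


def mean_flagella_ci(
    counts: Sequence[int] | np.ndarray, confidence: float = 0.95
) -> MeanCI:
    """Mean per-cell flagella count with a t-based confidence interval.

    With a single observation the interval is undefined (NaN bounds); with
    zero sample variance it collapses to [mean, mean].
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("counts must be a non-empty 1D sequence")
    mean = float(x.mean())
    n = len(x)
    if n == 1:
        return MeanCI(mean=mean, lo=math.nan, hi=math.nan, n=1, confidence=confidence)
    se = float(x.std(ddof=1)) / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    half = tcrit * se
    return MeanCI(mean=mean, lo=mean - half, hi=mean + half, n=n, confidence=confidence)


def absolute_flagella(
    mean_per_cell: float,
    cfu_per_ml: float,
    volume_ml: float = 1.0,
    ci: MeanCI | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Absolute flagella in the population: mean per cell x total cells.

    CFU is treated as exact; when *ci* is given, the mean's confidence
    interval is propagated linearly onto the absolute count.
    """
    if mean_per_cell < 0 or cfu_per_ml < 0 or volume_ml < 0:
        raise ValueError("inputs must be non-negative")
    cells = cfu_per_ml * volume_ml
    total = mean_per_cell * cells
    if ci is None:
        return total, None
    return total, (ci.lo * cells, ci.hi * cells)


def occupancy_percentages(class_counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of poles per occupancy class (both / only filaments /
    only relics / nothing), from raw pole counts."""
    total = sum(class_counts.values())
    if total <= 0:
        raise ValueError("need at least one counted pole")
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("counts must be non-negative")
    return {k: 100.0 * v / total for k, v in class_counts.items()}


def hook_end_fraction(
    flagella: Sequence[DetachedFlagellum],
    ends_sampled: int | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Fraction of sampled filament ends that carry a hook.

    Each flagellum contributes two ends.  With *ends_sampled* omitted (or at
    least 2n) every end is enumerated, which yields exactly
    (#hooked ends) / (2n): 0.5 for a purely base-of-hook-ejected population
    and 0 for mid-filament shearing.  Otherwise that many ends are sampled
    uniformly without replacement.
    """
    hooks = np.array(
        [h for f in flagella for h in f.hook_at_end], dtype=bool
    )
    n_ends = len(hooks)
    if n_ends == 0:
        raise ValueError("no flagella given")
    if ends_sampled is None or ends_sampled >= n_ends:
        return float(hooks.mean())
    if ends_sampled < 1:
        raise ValueError("ends_sampled must be >= 1")
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_ends, size=ends_sampled, replace=False)
    return float(hooks[pick].mean())


def track_speed(track: SwimTrack, method: str = "path") -> float:
    """Swimming speed of one track in um/s.

    ``method="path"`` (default) divides the summed frame-to-frame path
    length by the elapsed time — appropriate for short (~10 s) runs;
    ``method="net"`` uses the net start-to-end displacement instead.
    """
    if len(track.t_s) < 2:
        raise ValueError(f"track {track.track_id!r} needs >= 2 samples")
    elapsed = float(track.t_s[-1] - track.t_s[0])
    if method == "path":
        steps = np.hypot(np.diff(track.x_um), np.diff(track.y_um))
        return float(steps.sum() / elapsed)
    if method == "net":
        net = math.hypot(
            track.x_um[-1] - track.x_um[0], track.y_um[-1] - track.y_um[0]
        )
        return net / elapsed
    raise ValueError("method must be 'path' or 'net'")


@dataclass(frozen=True)
class SpeedSummary:
    mean_um_s: float
    se_um_s: float
    relative_to_baseline: float
    fraction_motile: float
    n_tracks: int
    n_motile: int
    motility_threshold_um_s: float


def cohort_speed_summary(
    tracks: Iterable[SwimTrack],
    baseline_speed_um_s: float | None = None,
    motility_threshold_um_s: float = 5.0,
    method: str = "path",
) -> SpeedSummary:
    """Cohort speed statistics and motile fraction.

    Speed mean and standard error are computed over motile tracks (those
    above the motility threshold, which is configurable and reported);
    ``fraction_motile`` is the share of all tracks above it.  The relative
    speed divides the motile mean by the supplied baseline (NaN if no
    baseline is given).
    """
    speeds = np.array([track_speed(t, method=method) for t in tracks])
    if speeds.size == 0:
        raise ValueError("no tracks given")
    motile = speeds > motility_threshold_um_s
    n_mot = int(motile.sum())
    if n_mot > 0:
        mean = float(speeds[motile].mean())
        se = (
            float(speeds[motile].std(ddof=1)) / math.sqrt(n_mot)
            if n_mot > 1
            else math.nan
        )
    else:
        mean, se = math.nan, math.nan
    rel = (
        mean / baseline_speed_um_s
        if (baseline_speed_um_s not in (None, 0) and n_mot > 0)
        else math.nan
    )
    return SpeedSummary(
        mean_um_s=mean,
        se_um_s=se,
        relative_to_baseline=rel,
        fraction_motile=n_mot / speeds.size,
        n_tracks=int(speeds.size),
        n_motile=n_mot,
        motility_threshold_um_s=motility_threshold_um_s,
    )
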