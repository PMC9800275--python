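"""Repertoire clonality statistics with depth-matched bootstrap rarefaction.

The statistics here summarise how unevenly a T (or B) cell receptor
repertoire is distributed over its clones:

* the Gini index, G = sum_ij |x_i - x_j| / (2 n^2 xbar), of clone read
  counts (0 = perfectly even repertoire);
* clone-size occupancy bands — the fraction of reads held by *small*
  (< 0.05% of the repertoire by default), *mid*, and *large* (> 0.5%)
  clones, with strict inequalities at both edges;
* the count of large clones.

Because every one of these is depth-biased, samples are compared after
rarefaction: all samples are resampled with replacement (multinomially, on
their empirical clone frequencies) to the minimum total read count observed
across samples, the statistic is recomputed per resample, and the mean,
standard deviation and percentile interval over (by default) 1,000
bootstrap iterations are reported.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BandThresholds


class UndefinedMetricError(ValueError):
    """Statistic undefined on this input (e.g. Gini of an all-zero vector)."""


@dataclass(frozen=True)
class BandOccupancy:
    """Read-weighted occupancy and clone counts per size band."""

    small_frac: float
    mid_frac: float
    large_frac: float
    small_n: int
    mid_n: int
    large_n: int
    empty: bool = False


@dataclass(frozen=True)
class BootstrapResult:
    """Rarefied-metric estimate: bootstrap mean, sd and percentile CI."""

    metric_name: str
    point: float
    sd: float
    ci_lo: float
    ci_hi: float
    n_iter: int
    rarefied_depth: int


def gini_index(counts) -> float:
    """Gini index of clone sizes via the sorted O(n log n) form.

    Equals the mean absolute difference between all pairs divided by twice
    the mean: G = sum_ij |x_i - x_j| / (2 n^2 xbar).  A single clone (or a
    perfectly even repertoire) scores 0.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise UndefinedMetricError("gini_index needs a non-empty 1-D vector")
    if np.any(x < 0):
        raise UndefinedMetricError("gini_index needs non-negative counts")
    total = x.sum()
    if total == 0:
        raise UndefinedMetricError("gini_index undefined for an all-zero vector")
    n = x.size
    if n == 1:
        return 0.0
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * xs)) / (n * total) - (n + 1.0) / n)


def occupancy_bands(clones: pd.DataFrame, thr: BandThresholds | None = None) -> BandOccupancy:
    """Partition a single-sample, single-chain clone table into size bands.

    Clones with frequency < ``thr.small_lt`` are small, > ``thr.large_gt``
    large, and everything else (including clones exactly at a boundary)
    mid.  Fractions are read-weighted and sum to 1 for a non-empty table.
    """
    thr = thr or BandThresholds()
    if len(clones) == 0:
        return BandOccupancy(0.0, 0.0, 0.0, 0, 0, 0, empty=True)
    freq = clones["frequency"].to_numpy(dtype=float)
    reads = clones["total_reads"].to_numpy(dtype=float)
    total = reads.sum()
    small = freq < thr.small_lt
    large = freq > thr.large_gt
    mid = ~(small | large)
    return BandOccupancy(
        small_frac=float(reads[small].sum() / total),
        mid_frac=float(reads[mid].sum() / total),
        large_frac=float(reads[large].sum() / total),
        small_n=int(small.sum()),
        mid_n=int(mid.sum()),
        large_n=int(large.sum()),
    )


def count_large_clones(clones: pd.DataFrame, large_gt: float = 0.005) -> int:
    """Number of clones whose frequency strictly exceeds ``large_gt``."""
    if len(clones) == 0:
        return 0
    return int((clones["frequency"].to_numpy(dtype=float) > large_gt).sum())


_METRICS = (
    "gini",
    "large_clone_count",
    "occupancy_small",
    "occupancy_mid",
    "occupancy_large",
)


def _metric_on_counts(counts: np.ndarray, metric: str, thr: BandThresholds) -> float:
    counts = counts[counts > 0]
    if counts.size == 0:
        return float("nan")
    if metric == "gini":
        return gini_index(counts)
    freq = counts / counts.sum()
    if metric == "large_clone_count":
        return float((freq > thr.large_gt).sum())
    small = freq < thr.small_lt
    large = freq > thr.large_gt
    if metric == "occupancy_small":
        return float(counts[small].sum() / counts.sum())
    if metric == "occupancy_large":
        return float(counts[large].sum() / counts.sum())
    if metric == "occupancy_mid":
        return float(counts[~(small | large)].sum() / counts.sum())
    raise UndefinedMetricError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def rarefied_metric(
    samples: dict[str, pd.DataFrame],
    metric: str = "gini",
    n_iter: int = 1000,
    seed: int = 0,
    thresholds: BandThresholds | None = None,
) -> dict[str, BootstrapResult]:
    """Depth-matched bootstrap of a clonality statistic across samples.

    The rarefied depth is the minimum total read count over the supplied
    clone tables.  Every sample — including the minimum-depth one, so all
    estimates carry comparable bootstrap variance — is resampled
    multinomially to that depth ``n_iter`` times from its empirical clone
    frequencies; clones drawn zero times in an iteration are dropped
    before the statistic is recomputed.  Per sample the bootstrap mean,
    standard deviation and 2.5/97.5 percentile interval are returned.

    Each sample draws from its own random stream derived from
    ``(seed, sample_id)``, so results are reproducible and independent of
    dict ordering.
    """
    if metric not in _METRICS:
        raise UndefinedMetricError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    if not samples:
        raise ValueError("need at least one sample")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    thr = thresholds or BandThresholds()

    depths = {sid: int(tab["total_reads"].sum()) for sid, tab in samples.items()}
    depth = min(depths.values())
    if depth < 1:
        raise ValueError("rarefied depth < 1: a sample has no reads")

    results: dict[str, BootstrapResult] = {}
    for sid, tab in samples.items():
        counts = tab["total_reads"].to_numpy(dtype=float)
        probs = counts / counts.sum()
        rng = np.random.default_rng([int(seed), zlib.crc32(str(sid).encode())])
        draws = rng.multinomial(depth, probs, size=n_iter)
        vals = np.array([_metric_on_counts(row, metric, thr) for row in draws])
        results[sid] = BootstrapResult(
            metric_name=metric,
            point=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)) if n_iter > 1 else 0.0,
            ci_lo=float(np.percentile(vals, 2.5)),
            ci_hi=float(np.percentile(vals, 97.5)),
            n_iter=int(n_iter),
            rarefied_depth=depth,
        )
    return results


def gini_delta(pre: BootstrapResult, post: BootstrapResult) -> float:
    """Change in a rarefied statistic between paired samples (post - pre)."""
    if pre.metric_name != post.metric_name:
        raise ValueError(
            f"metric mismatch: {pre.metric_name!r} vs {post.metric_name!r}"
        )
    return post.point - pre.point


def results_to_frame(results: dict[str, BootstrapResult]) -> pd.DataFrame:
    """Flatten per-sample bootstrap results to a tidy table."""
    rows = [
        {
            "sample_id": sid,
            "metric": r.metric_name,
            "point": r.point,
            "sd": r.sd,
            "ci_lo": r.ci_lo,
            "ci_hi": r.ci_hi,
            "depth": r.rarefied_depth,
            "n_iter": r.n_iter,
        }
        for sid, r in results.items()
    ]
    return pd.DataFrame(rows)
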