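"""Frequency histograms with optimized bin width.

Continuous descriptors (MW, LogP) are binned at the width minimizing the
Shimazaki-Shinomoto (2007) cost

    C(width) = (2*mean(k) - var(k)) / width**2

where ``k`` are the bin counts and ``var`` is the biased (population)
variance.  Discrete descriptors (HBA, HBD, RB, arR) use unit bins, one
per integer value.

Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin closed, and
anchored at the data minimum, so the count total always equals the input
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Histogram", "BinWidthCost", "optimal_bin_width",
           "histogram_continuous", "histogram_discrete"]


@dataclass(frozen=True)
class Histogram:
    bin_edges: np.ndarray  # length m+1, strictly increasing, equal widths
    counts: np.ndarray     # length m, non-negative integers
    descriptor: str = ""

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class BinWidthCost:
    width: float
    cost: float


def shimazaki_cost(values: np.ndarray, width: float) -> float:
    """Cost C = (2*mean(k) - biased var(k)) / width^2 for counts k at this width."""
    counts = histogram_continuous(values, width).counts
    k_mean = counts.mean()
    k_var = counts.var()  # biased (divides by number of bins)
    return (2.0 * k_mean - k_var) / width**2


def optimal_bin_width(values, candidate_widths=None) -> BinWidthCost:
    """Select the candidate width minimizing the Shimazaki-Shinomoto cost.

    Ties break toward the smaller width.  The default candidate grid is
    100 widths log-spaced between range/100 and range/2.

    Raises
    ------
    ValueError
        For fewer than 10 values, a degenerate (constant) sample, or an
        empty/invalid candidate set.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError(f"need >= 10 values to select a bin width, got {values.size}")
    data_range = values.max() - values.min()
    if data_range <= 0:
        raise ValueError("all values identical: no bin width selectable")
    if candidate_widths is None:
        candidate_widths = np.geomspace(data_range / 100.0, data_range / 2.0, 100)
    candidate_widths = np.asarray(candidate_widths, dtype=float)
    if candidate_widths.size == 0:
        raise ValueError("empty candidate width set")
    if np.any(candidate_widths <= 0):
        raise ValueError("candidate widths must all be > 0")

    best = None
    # ascending width order makes the strict '<' comparison break ties small
    for w in np.sort(candidate_widths):
        c = shimazaki_cost(values, w)
        if best is None or c < best.cost:
            best = BinWidthCost(width=float(w), cost=float(c))
    return best


def histogram_continuous(values, width: float, descriptor: str = "") -> Histogram:
    """Equal-width histogram anchored at min(values); conserves counts."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value sequence")
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    lo = values.min()
    n_bins = max(1, int(np.ceil((values.max() - lo) / width)))
    edges = lo + width * np.arange(n_bins + 1)
    # np.histogram uses half-open bins with the last bin closed -- the
    # stated convention -- but needs the final edge to actually cover max.
    if edges[-1] < values.max():
        edges = np.append(edges, edges[-1] + width)
    counts, _ = np.histogram(values, bins=edges)
    return Histogram(bin_edges=edges, counts=counts.astype(np.int64), descriptor=descriptor)


def histogram_discrete(values, descriptor: str = "") -> Histogram:
    """Unit-width histogram with one bin per integer from min to max."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty value sequence")
    ints = np.asarray(np.rint(values), dtype=np.int64)
    if not np.allclose(values, ints):
        raise ValueError("histogram_discrete requires integer values")
    if np.any(ints < 0):
        raise ValueError("discrete descriptor values must be >= 0")
    lo, hi = int(ints.min()), int(ints.max())
    counts = np.bincount(ints - lo, minlength=hi - lo + 1)
    edges = np.arange(lo, hi + 2, dtype=float) - 0.5  # bin k covers [k-0.5, k+0.5)
    return Histogram(bin_edges=edges, counts=counts.astype(np.int64), descriptor=descriptor)
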