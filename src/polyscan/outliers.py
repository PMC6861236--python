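"""Empirical outlier calling and permutation tests for outlier-set overlap."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OutlierSet:
    scan_id: str
    metric: str
    quantile: float
    threshold: float
    windows: set[str]
    universe: frozenset[str] = field(default_factory=frozenset)


@dataclass
class OverlapResult:
    size_a: int
    size_b: int
    universe_size: int
    observed: int
    p_value: float
    n_permutations: int
    seed: int


def call_outliers(
    scan_table: pd.DataFrame,
    metric: str,
    quantile: float = 0.99,
    scan_id: str = "scan",
) -> OutlierSet:
    """Windows whose metric is >= the empirical ``quantile`` (ties included).

    The percentile is computed on finite values only; an all-NaN metric is
    an error.
    """
    vals = pd.to_numeric(scan_table[metric], errors="coerce")
    finite = np.isfinite(vals.to_numpy(dtype=float))
    if not finite.any():
        raise ValueError(f"metric {metric!r} has no finite values")
    n_finite = int(finite.sum())
    if quantile >= 0.99 and n_finite < 100:
        logger.warning(
            "only %d finite windows for %s; %.0f%% quantile is noisy",
            n_finite, metric, quantile * 100,
        )
    finite_vals = vals.to_numpy(dtype=float)[finite]
    threshold = float(np.quantile(finite_vals, quantile))
    labels = scan_table["label"].astype(str).to_numpy()
    hit = finite & (vals.to_numpy(dtype=float) >= threshold)
    if np.ptp(finite_vals) == 0:
        logger.warning("metric %s is constant; every window ties at threshold", metric)
    return OutlierSet(
        scan_id,
        metric,
        quantile,
        threshold,
        set(labels[hit]),
        frozenset(labels[finite]),
    )


def combine_metrics(outlier_sets: list[OutlierSet], mode: str = "union") -> OutlierSet:
    """Set algebra over outlier sets from the same scan universe."""
    if not outlier_sets:
        raise ValueError("no outlier sets")
    universe = outlier_sets[0].universe
    for s in outlier_sets[1:]:
        if s.universe != universe:
            raise ValueError("outlier sets have mismatched universes")
    if mode == "union":
        windows = set().union(*(s.windows for s in outlier_sets))
    elif mode == "intersection":
        windows = set.intersection(*(set(s.windows) for s in outlier_sets))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return OutlierSet(
        outlier_sets[0].scan_id,
        "+".join(s.metric for s in outlier_sets),
        outlier_sets[0].quantile,
        np.nan,
        windows,
        universe,
    )


def scan_overlap(out_a: OutlierSet, out_b: OutlierSet) -> set[str]:
    """Window labels extreme in both scans (common-universe intersection)."""
    universe = set(out_a.universe) & set(out_b.universe)
    if not universe:
        raise ValueError("empty common universe")
    return (out_a.windows & out_b.windows) & universe


def overlap_permutation_test(
    universe_size: int,
    size_a: int,
    size_b: int,
    observed: int,
    n_perm: int = 999,
    seed: int = 0,
) -> OverlapResult:
    """Permutation p-value for the overlap of two label subsets.

    Draws two uniform random subsets of the given sizes ``n_perm`` times and
    reports p = (1 + #{overlap >= observed}) / (n_perm + 1).
    """
    if size_a > universe_size or size_b > universe_size:
        raise ValueError("subset larger than universe")
    if observed > min(size_a, size_b):
        raise ValueError("observed overlap exceeds the smaller set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.arange(universe_size)
    hits = 0
    for _ in range(n_perm):
        a = rng.choice(universe, size=size_a, replace=False)
        b = rng.choice(universe, size=size_b, replace=False)
        if np.intersect1d(a, b, assume_unique=True).size >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return OverlapResult(size_a, size_b, universe_size, observed, p, n_perm, seed)
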