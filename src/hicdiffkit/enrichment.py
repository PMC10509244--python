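"""Permutation overlap tests, Simpson-index similarity and DEG clustering.

The permutation test asks whether query elements (DEG TSSs, boundaries of
one type, ...) overlap a feature set (peaks, loop anchors) more or less
often than equally sized random draws from a background set containing
them. Each of the n_perm permutations draws |query| background elements
without replacement and recounts; p-values are two-tailed with the +1
correction, so the smallest attainable p is 1/(n_perm+1) and significance
is read at p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import KMeans

from .intervals import GenomicInterval


@dataclass
class FeatureSet:
    """Named, per-chromosome indexed interval collection."""

    name: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def __len__(self) -> int:
        return len(self.intervals)

    def has_overlap(self, iv: GenomicInterval, window: int = 0) -> bool:
        """Any feature within ``window`` bp of (>= 1 bp overlap with) iv?"""
        tree = self._trees.get(iv.chrom)
        return bool(tree and tree.overlap(iv.start - window, iv.end + window))


@dataclass
class OverlapTestResult:
    observed: int
    null_counts: np.ndarray
    fold: float  # NaN when the null mean is 0
    p: float
    n_perm: int
    window: int


def permutation_overlap_test(
    query: FeatureSet,
    background: FeatureSet,
    features: FeatureSet,
    n_perm: int = 1000,
    window: int = 0,
    seed: int = 0,
) -> OverlapTestResult:
    """Two-tailed permutation test of feature overlap against a background.

    Whether an element hits a feature is a fixed property of that element,
    so the null count for a without-replacement draw of |query| elements is
    the sum of |query| hit indicators — a hypergeometric variable in the
    number of feature-hitting background elements. Null counts are drawn
    from that exact permutation distribution directly, which is
    equivalent to materialising each permutation but far faster.
    """
    if len(query) > len(background):
        raise ValueError(
            f"|query|={len(query)} exceeds |background|={len(background)}"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(features):
        observed = sum(features.has_overlap(iv, window) for iv in query.intervals)
        bg_hits = sum(
            features.has_overlap(iv, window) for iv in background.intervals
        )
    else:
        observed = bg_hits = 0
    rng = np.random.default_rng(seed)
    n_bg, n_q = len(background), len(query)
    null = rng.hypergeometric(bg_hits, n_bg - bg_hits, n_q, size=n_perm).astype(int)
    p_hi = (1 + int((null >= observed).sum())) / (n_perm + 1)
    p_lo = (1 + int((null <= observed).sum())) / (n_perm + 1)
    p = min(1.0, 2 * min(p_hi, p_lo))
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("nan")
    return OverlapTestResult(observed, null, fold, p, n_perm, window)


def simpson_index(a: set, b: set) -> float:
    """|a ∩ b| / min(|a|, |b|); 0 when either set is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def simpson_matrix(sets: Mapping[str, set]) -> pd.DataFrame:
    names = list(sets)
    out = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            s = simpson_index(sets[a], sets[b])
            out.loc[a, b] = out.loc[b, a] = s
    return out


def cluster_deg_signs(m: pd.DataFrame, k: int = 20, seed: int = 0) -> pd.Series:
    """k-means clustering of gene sign vectors ({1, -1, 0} per sample).

    Genes are rows, samples columns. Cluster ids are relabeled by
    decreasing cluster size (ties by first occurrence) so the labeling is
    deterministic under a fixed seed.
    """
    vals = m.to_numpy(dtype=float)
    if not np.isin(vals, (-1.0, 0.0, 1.0)).all():
        raise ValueError("sign matrix entries must be in {1, -1, 0}")
    if len(m) < k:
        raise ValueError(f"{len(m)} genes < k={k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(vals)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    return pd.Series([relabel[int(c)] for c in raw], index=m.index, name="cluster")


def loops_overlapping_peaks(
    loops: pd.DataFrame, peaks: FeatureSet
) -> pd.DataFrame:
    """Keep loops whose BOTH anchors overlap at least one peak (>= 1 bp)."""
    keep = []
    for _, row in loops.iterrows():
        a1 = GenomicInterval(row["chrom1"], int(row["start1"]), int(row["end1"]))
        a2 = GenomicInterval(row["chrom2"], int(row["start2"]), int(row["end2"]))
        keep.append(peaks.has_overlap(a1) and peaks.has_overlap(a2))
    return loops[np.asarray(keep, dtype=bool)] if len(loops) else loops
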