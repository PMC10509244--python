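"""Epigenome-aware clustering of TAD-pair interaction changes.

TADs wider than 100 kbp are annotated with chromatin marks (H3K36me3,
H3K27me3, H3K9me3, Pol2, extensible) when the mark's peaks cover more than
40% of the TAD. For every pair of TADs separated by at most 2 Mbp the
interTAD interaction change is log2(N_treat / N_ctrl) of the summed
contacts in the rectangle between them; the per-pair vector of changes
across depletion samples is clustered by k-means (k = 5 by default), and
each cluster's epigenomic composition is summarized as z-scored fractions
of mark-combination categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import GenomicInterval, covered_bases
from .matrix import ContactMatrix

DEFAULT_COVERAGE_THRESHOLD = 0.40
DEFAULT_MIN_TAD_WIDTH = 100_000
DEFAULT_MAX_SEPARATION = 2_000_000


@dataclass
class AnnotatedTad:
    interval: GenomicInterval
    marks: frozenset[str] = frozenset()
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def category(self) -> str:
        return "+".join(sorted(self.marks)) if self.marks else "none"


@dataclass
class TadPairScore:
    tad_a: AnnotatedTad
    tad_b: AnnotatedTad
    separation: int
    logfc: dict[str, float] = field(default_factory=dict)
    cluster: int | None = None

    @property
    def category(self) -> str:
        """Unordered mark-combination pair, e.g. 'H3K27me3|Pol2'."""
        return "|".join(sorted((self.tad_a.category, self.tad_b.category)))


def annotate_tads(
    tads: Sequence[GenomicInterval],
    peaks: Mapping[str, Sequence[GenomicInterval]],
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    min_width: int = DEFAULT_MIN_TAD_WIDTH,
) -> list[AnnotatedTad]:
    """Assign marks covering strictly more than ``coverage_threshold``.

    TADs at or below ``min_width`` are dropped. Coverage uses the union of
    each mark's peaks, so overlapping peaks are not double counted; a mark
    covering exactly the threshold fraction is NOT assigned.
    """
    out = []
    for tad in tads:
        if tad.width <= min_width:
            continue
        cov = {
            mark: covered_bases(tad, ivs) / tad.width for mark, ivs in peaks.items()
        }
        marks = frozenset(m for m, c in cov.items() if c > coverage_threshold)
        out.append(AnnotatedTad(tad, marks, cov))
    return out


def _tad_bins(tad: AnnotatedTad, resolution: int, n_bins: int) -> slice:
    lo = tad.interval.start // resolution
    hi = min(-(-tad.interval.end // resolution), n_bins)
    return slice(lo, hi)


def intertad_logfc(
    treat: ContactMatrix,
    ctrl: ContactMatrix,
    tads: Sequence[AnnotatedTad],
    max_sep: int = DEFAULT_MAX_SEPARATION,
) -> list[TadPairScore]:
    """Score every TAD pair's interTAD interaction change for one sample.

    N is the sum of matrix entries over (bins of tad_a) x (bins of tad_b);
    pairs with a gap (end of tad_a to start of tad_b) above ``max_sep`` are
    skipped, and pairs with N <= 0 in either sample are dropped (logfc left
    unset). Because the score is a log ratio it is invariant to the common
    normalization scale of the two matrices.
    """
    treat.check_compatible(ctrl)
    res, n = treat.resolution, treat.n_bins
    ordered = sorted(tads, key=lambda t: (t.interval.start, t.interval.end))
    scores = []
    for ai, a in enumerate(ordered):
        for b in ordered[ai + 1 :]:
            gap = b.interval.start - a.interval.end
            if gap > max_sep:
                break
            if gap < 0:
                continue  # overlapping/nested pairs are not interTAD
            sa, sb = _tad_bins(a, res, n), _tad_bins(b, res, n)
            n_t = float(np.nansum(treat.values[sa, sb]))
            n_c = float(np.nansum(ctrl.values[sa, sb]))
            pair = TadPairScore(a, b, gap)
            if n_t > 0 and n_c > 0:
                pair.logfc["value"] = float(np.log2(n_t / n_c))
            scores.append(pair)
    return scores


def intertad_logfc_table(
    samples: Mapping[str, ContactMatrix],
    ctrl: ContactMatrix,
    tads: Sequence[AnnotatedTad],
    max_sep: int = DEFAULT_MAX_SEPARATION,
) -> list[TadPairScore]:
    """Multi-sample TAD-pair scores; keeps pairs defined in all samples."""
    per_sample = {
        s: intertad_logfc(m, ctrl, tads, max_sep) for s, m in samples.items()
    }
    names = list(per_sample)
    n_pairs = len(per_sample[names[0]])
    merged = []
    for idx in range(n_pairs):
        ref = per_sample[names[0]][idx]
        pair = TadPairScore(ref.tad_a, ref.tad_b, ref.separation)
        ok = True
        for s in names:
            v = per_sample[s][idx].logfc.get("value")
            if v is None:
                ok = False
                break
            pair.logfc[s] = v
        if ok:
            merged.append(pair)
    return merged


def cluster_tad_pairs(
    scores: Sequence[TadPairScore],
    k: int = 5,
    seed: int = 0,
    loader_samples: Sequence[str] | None = None,
) -> list[TadPairScore]:
    """k-means on per-pair logfc vectors across samples.

    Clusters are relabeled in decreasing order of the cluster-mean logfc
    averaged over ``loader_samples`` (all samples if not given) so ids are
    deterministic under a fixed seed: cluster 0 has the largest mean change.
    """
    if len(scores) < k:
        raise ValueError(f"{len(scores)} pairs < k={k}")
    sample_names = sorted(scores[0].logfc)
    X = np.array([[p.logfc[s] for s in sample_names] for p in scores])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    rank_samples = list(loader_samples) if loader_samples else sample_names
    cols = [sample_names.index(s) for s in rank_samples]
    order = np.argsort(
        [-X[raw == c][:, cols].mean() if (raw == c).any() else np.inf for c in range(k)]
    )
    relabel = {int(old): new for new, old in enumerate(order)}
    out = []
    for p, c in zip(scores, raw):
        out.append(
            TadPairScore(p.tad_a, p.tad_b, p.separation, dict(p.logfc), relabel[int(c)])
        )
    return out


def cluster_composition(scores: Sequence[TadPairScore]) -> pd.DataFrame:
    """Raw and z-scored mark-category fractions per cluster.

    Rows are clusters, columns a two-level index (raw / zscore) by category.
    Raw fractions sum to 1 per cluster; z-scores are taken across clusters
    per category (ddof=1), zero when the category fraction is constant.
    """
    if any(p.cluster is None for p in scores):
        raise ValueError("scores must be clustered first")
    df = pd.DataFrame(
        {"cluster": [p.cluster for p in scores], "category": [p.category for p in scores]}
    )
    counts = df.groupby(["cluster", "category"]).size().unstack(fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    sd = frac.std(axis=0, ddof=1)
    z = (frac - frac.mean(axis=0)).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
    return pd.concat({"raw": frac, "zscore": z}, axis=1)


def loop_length_distribution(
    loops: pd.DataFrame, edges: Sequence[int]
) -> np.ndarray:
    """Fraction of cis loops per anchor-midpoint-distance class.

    ``loops`` is a BEDPE frame (chrom1,start1,end1,chrom2,start2,end2);
    trans loops are skipped. Fractions sum to 1 over classes.
    """
    cis = loops[loops["chrom1"] == loops["chrom2"]]
    mid1 = (cis["start1"] + cis["end1"]) / 2
    mid2 = (cis["start2"] + cis["end2"]) / 2
    lengths = np.abs(mid2 - mid1).to_numpy()
    hist, _ = np.histogram(lengths, bins=np.asarray(edges, dtype=float))
    total = hist.sum()
    return hist / total if total else hist.astype(float)
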