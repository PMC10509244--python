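"""Multi-scale insulation scores and six-type boundary classification.

The insulation score at distance d is the log2 ratio of the mean contact
in a w x w square spanning each position (w = d / resolution bins, rows
upstream x columns downstream, excluding the position's own row/column)
to the chromosome-wide mean of that sliding statistic. With this sign
convention a *higher* score means more cross-position contact, i.e. a
*weaker* boundary — so a score increase after a depletion marks a lost
boundary, which is what the six-type rule below tests.

Boundary typing compares a depletion's 500-kbp score against control at
each boundary bin and applies, in order: all-dependent, cohesin-dependent,
CTCF-dependent, CTCF-separated, cohesin-separated, robust. Chromosomes X,
Y and M are excluded from boundary analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .intervals import GenomicInterval
from .matrix import BinTrack, ContactMatrix

#: ordered labels of the boundary classifier
BOUNDARY_TYPES = (
    "all-dependent",
    "cohesin-dependent",
    "CTCF-dependent",
    "CTCF-separated",
    "cohesin-separated",
    "robust",
)

EXCLUDED_CHROMS = frozenset({"chrX", "chrY", "chrM", "X", "Y", "M", "MT", "chrMT"})

DEFAULT_T_INS = 0.13


@dataclass
class MultiScaleInsulation:
    """Distance x bin table of insulation scores for one chromosome."""

    chrom: str
    resolution: int
    distances: np.ndarray  # bp, strictly increasing
    scores: np.ndarray  # (n_distances, n_bins), NaN where undefined

    def at_distance(self, d: int) -> BinTrack:
        idx = np.nonzero(self.distances == d)[0]
        if idx.size == 0:
            raise KeyError(f"distance {d} not in profile")
        return BinTrack(
            self.chrom, self.resolution, self.scores[idx[0]], label=f"IS_{d}"
        )


@dataclass
class ClassifierConfig:
    t_ins: float = DEFAULT_T_INS
    samples_required: tuple[str, ...] = ("control", "siNIPBL", "siRad21", "siCTCF")

    def __post_init__(self) -> None:
        if self.t_ins <= 0:
            raise ValueError("t_ins must be positive")


@dataclass
class BoundaryRecord:
    interval: GenomicInterval
    is500: dict[str, float] = field(default_factory=dict)
    label: str = "robust"


def multiscale_insulation(
    m: ContactMatrix,
    d_min: int = 100_000,
    d_max: int = 1_000_000,
    d_step: int = 25_000,
) -> MultiScaleInsulation:
    """Insulation scores across distance scales d_min..d_max.

    For each bin i and window half-width w the sliding statistic is the
    mean of the contact sub-matrix rows (i-w..i-1) x columns (i+1..i+w);
    bins within w of either chromosome end, or whose square has no defined
    entry, are NaN. The score is log2(statistic / chromosome mean of the
    statistic), so it is invariant to global matrix scale.
    """
    res = m.resolution
    for name, d in (("d_min", d_min), ("d_max", d_max), ("d_step", d_step)):
        if d % res:
            raise ValueError(f"{name}={d} is not a multiple of resolution {res}")
    distances = np.arange(d_min, d_max + 1, d_step)
    n = m.n_bins
    vals = m.masked_values()
    scores = np.full((len(distances), n), np.nan)
    for k, d in enumerate(distances):
        w = d // res
        stat = np.full(n, np.nan)
        for i in range(w, n - w):
            sq = vals[i - w : i, i + 1 : i + w + 1]
            if np.any(np.isfinite(sq)):
                stat[i] = np.nanmean(sq)
        ok = np.isfinite(stat)
        mu = np.nanmean(stat[ok]) if ok.any() else np.nan
        if np.isfinite(mu) and mu > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                row = np.log2(stat / mu)
            row[~np.isfinite(row)] = np.nan
            scores[k] = row
    return MultiScaleInsulation(m.chrom, res, distances, scores)


def insulation_500k(m: ContactMatrix) -> BinTrack:
    """The single-distance (500 kbp) insulation score used for typing."""
    prof = multiscale_insulation(m, d_min=500_000, d_max=500_000, d_step=m.resolution)
    return prof.at_distance(500_000)


def classify_boundaries(
    boundaries: Sequence[GenomicInterval],
    is_by_sample: Mapping[str, BinTrack],
    cfg: ClassifierConfig | None = None,
) -> tuple[list[BoundaryRecord], int]:
    """Assign each boundary one of the six perturbation-response types.

    Deltas are (depletion - control) 500-kbp insulation at the boundary's
    midpoint bin; a positive delta means insulation was lost. Returns the
    records plus the number of boundaries dropped because a required score
    was undefined at their bin. Boundaries on chrX/chrY/chrM are skipped.
    """
    cfg = cfg or ClassifierConfig()
    missing = [s for s in cfg.samples_required if s not in is_by_sample]
    if missing:
        raise ValueError(f"missing required samples: {missing}")
    t = cfg.t_ins
    records: list[BoundaryRecord] = []
    dropped = 0
    for b in boundaries:
        if b.chrom in EXCLUDED_CHROMS:
            continue
        res = is_by_sample[cfg.samples_required[0]].resolution
        i = b.bin_index(res)
        vals = {}
        ok = True
        for s in cfg.samples_required:
            tr = is_by_sample[s]
            v = tr.values[i] if 0 <= i < tr.n_bins else np.nan
            if not np.isfinite(v):
                ok = False
            vals[s] = float(v)
        if not ok:
            dropped += 1
            continue
        d_nipbl = vals["siNIPBL"] - vals["control"]
        d_rad21 = vals["siRad21"] - vals["control"]
        d_ctcf = vals["siCTCF"] - vals["control"]
        label = classify_deltas(d_nipbl, d_rad21, d_ctcf, t)
        records.append(BoundaryRecord(b, vals, label))
    return records, dropped


def classify_deltas(
    d_nipbl: float, d_rad21: float, d_ctcf: float, t: float = DEFAULT_T_INS
) -> str:
    """The ordered six-branch rule on insulation-score deltas.

    Exactly one branch fires for any real triple; the final branch is the
    else case (all five inequalities above fail).
    """
    if d_nipbl > t and d_ctcf > t:
        return "all-dependent"
    if d_nipbl > t or d_rad21 > t:
        return "cohesin-dependent"
    if d_ctcf > t:
        return "CTCF-dependent"
    if -d_ctcf > t:
        return "CTCF-separated"
    if -d_nipbl > t or -d_rad21 > t:
        return "cohesin-separated"
    return "robust"


def call_boundary_minima(
    track: BinTrack, min_prominence: float = 0.1
) -> list[GenomicInterval]:
    """Local minima of an insulation track as 1-bin boundary intervals.

    Convenience caller for synthetic cohorts; real boundaries normally come
    from upstream TAD calls. NaN stretches are bridged by treating them as
    +inf (they can never be minima).
    """
    v = track.values
    if np.isfinite(v).sum() < 3:
        raise ValueError("need >= 3 defined bins")
    filled = np.where(np.isfinite(v), v, np.inf)
    if min_prominence > 0:
        idx, _ = find_peaks(-filled, prominence=min_prominence)
    else:
        idx, _ = find_peaks(-filled)
    res = track.resolution
    return [
        GenomicInterval(track.chrom, int(i) * res, (int(i) + 1) * res)
        for i in idx
        if np.isfinite(v[i])
    ]
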