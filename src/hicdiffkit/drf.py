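"""Directional relative frequency (DRF): directional bias of depletion
effects on long-range interactions.

Given a treatment and control contact matrix normalized the same way, the
relative interaction frequency is the entry-wise natural-log ratio
M = log(C_treat) - log(C_ctrl). The DRF of bin i sums M over a downstream
band minus the same band upstream,

    DRF_i = sum_{j=jmin..jmax} M[i, i+j] - sum_{j=jmin..jmax} M[i, i-j],

with the band spanning genomic distances l_min..l_max (defaults 500 kbp
and 2 Mbp). A negative DRF means the depletion removed proportionally more
downstream than upstream contact at i — the signature of a one-sided
(stripe-like) loss. Differential regions are called where the 99%
confidence intervals of the "cohesin and loaders" and "others" sample
groups are disjoint and the loaders' mean magnitude exceeds a threshold
(default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval
from .matrix import BinTrack, ContactMatrix

DEFAULT_T_DRF = 0.7

GROUP_NAMES = ("cohesin_loaders", "unloaders", "others")


@dataclass
class RelativeFrequencyMap:
    """Symmetric log-ratio map; NaN where either input is zero/masked."""

    chrom: str
    resolution: int
    values: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class DrfConfig:
    l_min: int = 500_000
    l_max: int = 2_000_000
    min_valid_fraction: float = 0.5

    def validate(self, resolution: int) -> tuple[int, int]:
        if not (0 < self.l_min < self.l_max):
            raise ValueError("require 0 < l_min < l_max")
        if self.l_min % resolution or self.l_max % resolution:
            raise ValueError("l_min and l_max must be multiples of the resolution")
        return self.l_min // resolution, self.l_max // resolution


@dataclass
class SampleGrouping:
    """Maps sample names to cohesin_loaders / unloaders / others."""

    groups: dict[str, str]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


@dataclass
class GroupDrfStats:
    chrom: str
    resolution: int
    mean: dict[str, np.ndarray]
    ci_lower: dict[str, np.ndarray]
    ci_upper: dict[str, np.ndarray]
    ci_level: float = 0.99


@dataclass
class DifferentialRegion:
    interval: GenomicInterval
    direction: int  # sign of the cohesin_loaders mean
    group_means: dict[str, float] = field(default_factory=dict)


def relative_frequency_map(
    treat: ContactMatrix, ctrl: ContactMatrix
) -> RelativeFrequencyMap:
    """M = ln(C_treat) - ln(C_ctrl), undefined where either entry is <= 0."""
    treat.check_compatible(ctrl)
    if treat.norm_tag != ctrl.norm_tag:
        raise ValueError(
            f"normalization mismatch: {treat.norm_tag} vs {ctrl.norm_tag}"
        )
    a = treat.masked_values()
    b = ctrl.masked_values()
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log(a) - np.log(b)
    m[~np.isfinite(m)] = np.nan
    m[(a <= 0) | (b <= 0)] = np.nan
    return RelativeFrequencyMap(treat.chrom, treat.resolution, m)


def drf(M: RelativeFrequencyMap, cfg: DrfConfig | None = None) -> BinTrack:
    """Directional relative frequency per bin.

    Undefined M terms contribute 0 to either sum, but a bin is voided when
    the defined fraction of either sum falls below ``min_valid_fraction``
    or its band would leave the chromosome.
    """
    cfg = cfg or DrfConfig()
    jmin, jmax = cfg.validate(M.resolution)
    n = M.n_bins
    vals = M.values
    out = np.full(n, np.nan)
    width = jmax - jmin + 1
    for i in range(jmax, n - jmax):
        down = vals[i, i + jmin : i + jmax + 1]
        up = vals[i, i - jmax : i - jmin + 1]
        n_down = np.isfinite(down).sum()
        n_up = np.isfinite(up).sum()
        if n_down / width < cfg.min_valid_fraction:
            continue
        if n_up / width < cfg.min_valid_fraction:
            continue
        out[i] = np.nansum(down) - np.nansum(up)
    return BinTrack(M.chrom, M.resolution, out, label="DRF")


def group_drf_stats(
    tracks: Mapping[str, BinTrack],
    grouping: SampleGrouping,
    ci_level: float = 0.99,
) -> GroupDrfStats:
    """Per-bin group means with Student-t confidence intervals.

    Each group needs at least two member samples; a bin is undefined for a
    group when fewer than two members have a defined DRF there. A zero
    sample variance collapses the interval onto the mean.
    """
    names = list(tracks)
    if not names:
        raise ValueError("no sample tracks given")
    first = tracks[names[0]]
    n = first.n_bins
    mean: dict[str, np.ndarray] = {}
    lo: dict[str, np.ndarray] = {}
    hi: dict[str, np.ndarray] = {}
    for group in GROUP_NAMES:
        members = [s for s in grouping.samples_in(group) if s in tracks]
        if not members:
            continue
        if len(members) < 2:
            raise ValueError(f"group {group!r} has < 2 samples: {members}")
        data = np.vstack([tracks[s].values for s in members])  # (n_samples, n_bins)
        cnt = np.isfinite(data).sum(axis=0)
        filled = np.where(np.isfinite(data), data, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(cnt >= 2, filled.sum(axis=0) / np.maximum(cnt, 1), np.nan)
            resid = np.where(np.isfinite(data), data - mu, 0.0)
            sd = np.sqrt((resid**2).sum(axis=0) / np.maximum(cnt - 1, 1))
            sd = np.where(cnt >= 2, sd, np.nan)
        sem = np.where(cnt >= 2, sd / np.sqrt(cnt), np.nan)
        tcrit = np.where(
            cnt >= 2, stats.t.ppf(0.5 + ci_level / 2, np.maximum(cnt - 1, 1)), np.nan
        )
        half = tcrit * sem
        mean[group] = mu
        lo[group] = mu - half
        hi[group] = mu + half
    return GroupDrfStats(first.chrom, first.resolution, mean, lo, hi, ci_level)


def differential_drf_regions(
    stats_: GroupDrfStats, t_drf: float = DEFAULT_T_DRF
) -> list[DifferentialRegion]:
    """Call regions where cohesin/loader DRF departs from the others group.

    A bin qualifies when (a) the loaders' and others' CIs are disjoint and
    (b) |loaders mean| > t_drf. Runs of consecutive qualifying bins with
    the same sign merge into one region; single-bin regions are allowed.
    """
    for g in ("cohesin_loaders", "others"):
        if g not in stats_.mean:
            raise ValueError(f"group stats missing {g!r}")
    mu_cl = stats_.mean["cohesin_loaders"]
    lo_cl, hi_cl = stats_.ci_lower["cohesin_loaders"], stats_.ci_upper["cohesin_loaders"]
    lo_ot, hi_ot = stats_.ci_lower["others"], stats_.ci_upper["others"]
    with np.errstate(invalid="ignore"):
        disjoint = (lo_cl > hi_ot) | (hi_cl < lo_ot)
        strong = np.abs(mu_cl) > t_drf
    qualifies = disjoint & strong & np.isfinite(mu_cl)
    sign = np.sign(mu_cl)
    regions: list[DifferentialRegion] = []
    res = stats_.resolution
    i = 0
    n = len(mu_cl)
    while i < n:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qualifies[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        iv = GenomicInterval(stats_.chrom, i * res, (j + 1) * res)
        means = {
            g: float(np.nanmean(stats_.mean[g][i : j + 1])) for g in stats_.mean
        }
        regions.append(DifferentialRegion(iv, int(sign[i]), means))
        i = j + 1
    return regions


def cosine_similarity_profiles(
    maps: Mapping[str, RelativeFrequencyMap],
    regions: Sequence[DifferentialRegion],
    flank: int = 2_000_000,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-region cosine similarity of relative-frequency maps per pair.

    For each region, entries of the upper triangle of M within +/- flank of
    the region center are vectorized; each sample pair is compared on its
    common defined support. Returns per-pair arrays of per-region
    similarities (NaN where the common support is empty).
    """
    names = sorted(maps)
    if len(names) < 2:
        raise ValueError("need >= 2 samples")
    if not regions:
        raise ValueError("no regions given")
    first = maps[names[0]]
    res = first.resolution
    f = flank // res
    n = first.n_bins
    vecs: dict[str, list[np.ndarray]] = {s: [] for s in names}
    for reg in regions:
        c = reg.interval.bin_index(res)
        lo, hi = max(0, c - f), min(n, c + f + 1)
        iu, ju = np.triu_indices(hi - lo, k=1)
        for s in names:
            sub = maps[s].values[lo:hi, lo:hi]
            vecs[s].append(sub[iu, ju])
    out: dict[tuple[str, str], np.ndarray] = {}
    for a_i, a in enumerate(names):
        for b in names[a_i + 1 :]:
            sims = np.full(len(regions), np.nan)
            for r in range(len(regions)):
                va, vb = vecs[a][r], vecs[b][r]
                ok = np.isfinite(va) & np.isfinite(vb)
                if not ok.any():
                    continue
                xa, xb = va[ok], vb[ok]
                na, nb = np.linalg.norm(xa), np.linalg.norm(xb)
                if na == 0 or nb == 0:
                    continue
                sims[r] = float(xa @ xb / (na * nb))
            out[(a, b)] = sims
    return out
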