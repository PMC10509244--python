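"""Contact-matrix container, normalizations and compartment analysis.

A :class:`ContactMatrix` holds one chromosome's symmetric binned contact
counts together with a per-bin validity mask and a normalization tag.
Undefined quantities are carried as NaN, never as silent zeros: bins with a
zero raw marginal are masked and excluded from every mean, correlation and
eigendecomposition downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import numpy as np


class NormTag(str, Enum):
    RAW = "RAW"
    VC_SQRT = "VC_SQRT"
    CHROM_TOTAL = "CHROM_TOTAL"
    OE = "OE"


class CompartmentLabel(str, Enum):
    STRONG_A = "StrongA"
    WEAK_A = "WeakA"
    WEAK_B = "WeakB"
    STRONG_B = "StrongB"
    UNASSIGNED = "unassigned"


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome contact matrix at a fixed bin size.

    Parameters
    ----------
    chrom : chromosome name.
    resolution : bin width in bp (25 kb by default across the toolkit).
    values : ``(n_bins, n_bins)`` symmetric non-negative array; NaN marks
        undefined entries (only produced by observed/expected).
    mask : per-bin validity; False for unmappable (zero-marginal) bins.
    norm_tag : which normalization has been applied.
    """

    chrom: str
    resolution: int
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    norm_tag: NormTag = NormTag.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"values must be square, got {self.values.shape}")
        if not np.array_equal(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            marg = np.nansum(self.values, axis=0)
            self.mask = marg > 0
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_bins,):
            raise ValueError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.resolution

    def total(self) -> float:
        return float(np.nansum(self.values))

    def masked_values(self) -> np.ndarray:
        """Copy of values with invalid rows/columns set to NaN."""
        out = self.values.copy()
        out[~self.mask, :] = np.nan
        out[:, ~self.mask] = np.nan
        return out

    def check_compatible(self, other: "ContactMatrix") -> None:
        if (self.chrom, self.resolution, self.n_bins) != (
            other.chrom,
            other.resolution,
            other.n_bins,
        ):
            raise ValueError(
                "incompatible matrices: "
                f"({self.chrom},{self.resolution},{self.n_bins}) vs "
                f"({other.chrom},{other.resolution},{other.n_bins})"
            )


@dataclass
class BinTrack:
    """Per-bin real-valued track on one chromosome; NaN where undefined."""

    chrom: str
    resolution: int
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def vc_sqrt_normalize(m: ContactMatrix) -> ContactMatrix:
    """Square-root vanilla-coverage balancing.

    Each entry is divided by sqrt(r_i * r_j) of the raw marginals over valid
    bins, then the matrix is rescaled to preserve its total sum (the scale
    convention is arbitrary since only ratios and log differences are used
    downstream). Zero-marginal bins are masked out rather than divided.
    """
    if m.norm_tag != NormTag.RAW:
        raise ValueError(f"expected RAW input, got {m.norm_tag}")
    vals = m.masked_values()
    marg = np.nansum(vals, axis=0)
    mask = m.mask & (marg > 0)
    vals[~mask, :] = np.nan
    vals[:, ~mask] = np.nan
    marg = np.nansum(vals, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = vals / np.sqrt(np.outer(marg, marg))
    before = np.nansum(vals)
    after = np.nansum(out)
    if after > 0:
        out *= before / after
    out = np.nan_to_num(out, nan=0.0)
    out[~mask, :] = 0.0
    out[:, ~mask] = 0.0
    return ContactMatrix(m.chrom, m.resolution, out, mask, NormTag.VC_SQRT)


def chrom_total_normalize(
    m: ContactMatrix, target_total: float
) -> ContactMatrix:
    """Scale the matrix so its total equals ``target_total``.

    Mirrors per-chromosome read-count normalization used when comparing
    samples sequenced to different depths.
    """
    total = m.total()
    if total <= 0:
        raise ValueError("cannot normalize a matrix with zero total")
    out = m.values * (target_total / total)
    return ContactMatrix(m.chrom, m.resolution, out, m.mask.copy(), NormTag.CHROM_TOTAL)


def observed_over_expected(m: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean of its distance class over valid pairs.

    Removes the distance-decay background. Distance classes whose mean over
    valid pairs is zero (or with no valid pair) yield NaN entries.
    """
    n = m.n_bins
    vals = m.masked_values()
    out = np.full_like(vals, np.nan)
    for d in range(n):
        diag = np.diagonal(vals, offset=d)
        mu = np.nanmean(diag) if np.any(np.isfinite(diag)) else np.nan
        if not np.isfinite(mu) or mu == 0:
            continue
        idx = np.arange(n - d)
        out[idx, idx + d] = vals[idx, idx + d] / mu
        out[idx + d, idx] = out[idx, idx + d]
    return ContactMatrix(m.chrom, m.resolution, out, m.mask.copy(), NormTag.OE)


def relative_contact_probability(
    m: ContactMatrix, n_classes: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Contact probability as a function of genomic distance.

    Distances (1..n_bins-1 bins) are grouped into ``n_classes`` log-spaced
    classes; within each class the mean contact over valid pairs is taken
    and the curve is normalized to sum to 1 over defined classes. Returns
    ``(distance_bp, fraction)``; empty classes are NaN.
    """
    n = m.n_bins
    vals = m.masked_values()
    edges = np.unique(
        np.geomspace(1, n - 1, n_classes + 1).round().astype(int)
    )
    dists = []
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        pool = [np.diagonal(vals, offset=d) for d in range(lo, hi + (hi == edges[-1]))]
        pool = np.concatenate(pool) if pool else np.array([])
        ok = np.isfinite(pool)
        means.append(np.mean(pool[ok]) if ok.any() else np.nan)
        dists.append(np.sqrt(lo * hi) * m.resolution)
    means = np.asarray(means, dtype=float)
    tot = np.nansum(means)
    if tot > 0:
        means = means / tot
    return np.asarray(dists, dtype=float), means


def compartment_pc1(
    oe: ContactMatrix,
    orientation_track: BinTrack | np.ndarray,
    method: str = "correlation",
) -> BinTrack:
    """First principal eigenvector of the distance-normalized contact map.

    Computed on the Pearson correlation matrix of the observed/expected map
    over valid bins (``method="correlation"``, the default) or directly on
    the OE matrix (``method="oe"``). The sign is oriented so the track
    correlates non-negatively with ``orientation_track`` (an activity proxy
    such as active-mark coverage); positive values then mark the A
    compartment. Invalid bins are NaN.
    """
    if oe.norm_tag != NormTag.OE:
        raise ValueError("compartment_pc1 expects an observed/expected matrix")
    orient = (
        orientation_track.values
        if isinstance(orientation_track, BinTrack)
        else np.asarray(orientation_track, dtype=float)
    )
    valid = oe.mask & np.any(np.isfinite(oe.values), axis=0)
    if valid.sum() < 10:
        raise ValueError(
            f"only {int(valid.sum())} valid bins; need >= 10 for a stable eigenvector"
        )
    sub = oe.values[np.ix_(valid, valid)]
    # neutral fill for entries on empty distance classes
    sub = np.where(np.isfinite(sub), sub, 1.0)
    if method == "correlation":
        with np.errstate(invalid="ignore"):
            mat = np.corrcoef(sub)
        mat = np.nan_to_num(mat, nan=0.0)
    elif method == "oe":
        mat = sub - 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    w, v = np.linalg.eigh(mat)
    vec = v[:, np.argmax(w)]
    track = np.full(oe.n_bins, np.nan)
    track[valid] = vec
    both = valid & np.isfinite(orient)
    if both.any():
        c = np.corrcoef(track[both], orient[both])[0, 1]
        if np.isfinite(c) and c < 0:
            track = -track
    return BinTrack(oe.chrom, oe.resolution, track, label="PC1")


def classify_compartment_bins(pc1: BinTrack) -> list[CompartmentLabel]:
    """Split PC1 into four compartment classes.

    Positive bins are divided into StrongA/WeakA at the median of positive
    values, negative bins into StrongB/WeakB at the median of negative
    values. Zero or undefined bins are unassigned.
    """
    v = pc1.values
    if not np.any(np.isfinite(v)):
        raise ValueError("PC1 track has no defined bins")
    pos = v[np.isfinite(v) & (v > 0)]
    neg = v[np.isfinite(v) & (v < 0)]
    pos_med = np.median(pos) if pos.size else np.inf
    neg_med = np.median(neg) if neg.size else -np.inf
    out = []
    for x in v:
        if not np.isfinite(x) or x == 0:
            out.append(CompartmentLabel.UNASSIGNED)
        elif x > 0:
            out.append(
                CompartmentLabel.STRONG_A if x > pos_med else CompartmentLabel.WEAK_A
            )
        else:
            out.append(
                CompartmentLabel.STRONG_B if x < neg_med else CompartmentLabel.WEAK_B
            )
    return out
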