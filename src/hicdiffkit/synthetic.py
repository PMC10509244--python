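"""Parametric Hi-C simulator with planted ground truth.

A :class:`SyntheticGenomeSpec` describes one chromosome's expected contact
intensity as a product of interpretable factors on a power-law
distance-decay background:

    lambda[i,j] = base * (|i-j|+1)^(-alpha) * tad * plaid * loop * stripe

TAD segments enrich their intra-domain square, compartment labels impose a
plaid (checkerboard) contrast, loops add focal corner enrichment and
stripes multiply a one-sided distance band from a region of anchor rows.
``base`` is set so the expected upper-triangle total (simulated read
pairs) equals ``depth``. Matrices are sampled with independent Poisson
noise per upper-triangle entry and mirrored.

Perturbation operators transform a spec into a depleted counterpart:
removing or gaining TAD boundaries (cohesin/CTCF phenotypes), erasing
intra-TAD enrichment, attenuating a one-sided stripe band (the loader
phenotype behind differential DRF regions), strengthening compartment
contrast, or inverting a stripe (the unloader phenotype).
:func:`make_cohort` samples a condition panel and emits the ground truth
(boundary type labels, differential-DRF intervals, TAD-pair classes)
implied by the design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .insulation import classify_deltas
from .intervals import GenomicInterval
from .matrix import ContactMatrix, NormTag


@dataclass(frozen=True)
class TadSegment:
    start: int  # bp
    end: int
    factor: float = 2.0


@dataclass(frozen=True)
class Loop:
    anchor1: int  # bp, midpoint
    anchor2: int
    factor: float = 4.0
    halfwidth_bins: int = 1


@dataclass(frozen=True)
class Stripe:
    """One-sided multiplicative band from a region of anchor rows.

    Entries (i, j) with i in [start, end) and (j - i) * direction within
    [d_min, d_max] are multiplied by ``factor`` (and mirrored).
    """

    start: int  # bp
    end: int
    direction: int = +1  # +1 downstream, -1 upstream
    factor: float = 1.0
    d_min: int = 500_000
    d_max: int = 2_000_000


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    chrom: str = "chrS"
    length: int = 20_000_000
    resolution: int = 25_000
    decay_exponent: float = 1.0
    depth: float = 500_000.0
    tad_segments: tuple[TadSegment, ...] = ()
    compartment_labels: tuple[str, ...] = ()  # per-bin 'A'/'B'
    plaid_factor: float = 1.5
    loops: tuple[Loop, ...] = ()
    stripes: tuple[Stripe, ...] = ()

    @property
    def n_bins(self) -> int:
        return self.length // self.resolution

    def validate(self) -> None:
        if self.tad_segments:
            pos = 0
            for seg in self.tad_segments:
                if seg.start != pos:
                    raise ValueError("TAD segments must tile the chromosome")
                if seg.factor <= 0:
                    raise ValueError("TAD factors must be positive")
                pos = seg.end
            if pos != self.length:
                raise ValueError("TAD segments must end at chromosome length")
        if self.compartment_labels and len(self.compartment_labels) != self.n_bins:
            raise ValueError("compartment labels must cover all bins")


@dataclass(frozen=True)
class PerturbationSpec:
    """A named transformation of a genome spec.

    kinds: ``tad_loss`` (params: targets=list of bp intervals or None for
    all), ``boundary_removal`` (edge=bp), ``boundary_gain`` (position=bp),
    ``stripe_depletion`` (start, end, direction, factor, d_min, d_max),
    ``compartment_strengthen`` (multiplier), ``unloader_inverse``
    (same params as the stripe_depletion it inverts).
    """

    kind: str
    params: tuple[tuple[str, object], ...] = ()

    @staticmethod
    def make(kind: str, **params) -> "PerturbationSpec":
        return PerturbationSpec(kind, tuple(sorted(params.items())))

    @property
    def p(self) -> dict:
        return dict(self.params)


def expected_matrix(spec: SyntheticGenomeSpec) -> ContactMatrix:
    """Noise-free expected contact matrix, upper-triangle total = depth."""
    spec.validate()
    n = spec.n_bins
    res = spec.resolution
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = (dist + 1.0) ** (-spec.decay_exponent)

    for seg in spec.tad_segments:
        if seg.factor != 1.0:
            lo, hi = seg.start // res, seg.end // res
            lam[lo:hi, lo:hi] *= seg.factor

    if spec.compartment_labels:
        lab = np.asarray(spec.compartment_labels)
        same = lab[:, None] == lab[None, :]
        lam *= np.where(same, spec.plaid_factor, 1.0 / spec.plaid_factor)

    for lp in spec.loops:
        a, b = lp.anchor1 // res, lp.anchor2 // res
        h = lp.halfwidth_bins
        lam[max(0, a - h) : a + h + 1, max(0, b - h) : b + h + 1] *= lp.factor
        lam[max(0, b - h) : b + h + 1, max(0, a - h) : a + h + 1] *= lp.factor

    for st in spec.stripes:
        if st.factor == 1.0:
            continue
        lo, hi = st.start // res, st.end // res
        jmin, jmax = st.d_min // res, st.d_max // res
        for i in range(lo, min(hi, n)):
            if st.direction >= 0:
                j0, j1 = i + jmin, min(i + jmax + 1, n)
            else:
                j0, j1 = max(i - jmax, 0), i - jmin + 1
            if j0 < j1:
                lam[i, j0:j1] *= st.factor
                lam[j0:j1, i] *= st.factor

    lam = (lam + lam.T) / 2  # exact symmetry despite overlapping operators
    upper_total = np.triu(lam).sum()
    lam *= spec.depth / upper_total
    return ContactMatrix(spec.chrom, res, lam, np.ones(n, bool), NormTag.RAW)


def sample_matrix(spec: SyntheticGenomeSpec, seed: int) -> ContactMatrix:
    """Poisson-sampled contact matrix; bit-reproducible under the seed."""
    if spec.depth <= 0:
        raise ValueError("depth must be positive")
    lam = expected_matrix(spec).values
    rng = np.random.default_rng(seed)
    n = lam.shape[0]
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(lam[iu, ju])
    vals = np.zeros_like(lam)
    vals[iu, ju] = counts
    vals[ju, iu] = counts
    return ContactMatrix(spec.chrom, spec.resolution, vals, norm_tag=NormTag.RAW)


def apply_perturbation(
    spec: SyntheticGenomeSpec, p: PerturbationSpec
) -> SyntheticGenomeSpec:
    """Return a new spec with one perturbation applied."""
    prm = p.p
    if p.kind == "tad_loss":
        targets = prm.get("targets")
        segs = []
        for seg in spec.tad_segments:
            hit = targets is None or any(
                seg.start < t[1] and t[0] < seg.end for t in targets
            )
            segs.append(replace(seg, factor=1.0) if hit else seg)
        return replace(spec, tad_segments=tuple(segs))
    if p.kind == "boundary_removal":
        edge = prm["edge"]
        segs = list(spec.tad_segments)
        for k in range(len(segs) - 1):
            if segs[k].end == edge:
                merged = TadSegment(segs[k].start, segs[k + 1].end, segs[k].factor)
                return replace(
                    spec, tad_segments=tuple(segs[:k] + [merged] + segs[k + 2 :])
                )
        raise ValueError(f"no TAD edge at {edge}")
    if p.kind == "boundary_gain":
        pos = prm["position"]
        segs = list(spec.tad_segments)
        for k, seg in enumerate(segs):
            if seg.start < pos < seg.end:
                split = [
                    TadSegment(seg.start, pos, seg.factor),
                    TadSegment(pos, seg.end, seg.factor),
                ]
                return replace(
                    spec, tad_segments=tuple(segs[:k] + split + segs[k + 1 :])
                )
        raise ValueError(f"no TAD segment strictly containing {pos}")
    if p.kind == "stripe_depletion":
        st = Stripe(
            prm["start"],
            prm["end"],
            prm.get("direction", +1),
            prm["factor"],
            prm.get("d_min", 500_000),
            prm.get("d_max", 2_000_000),
        )
        return replace(spec, stripes=spec.stripes + (st,))
    if p.kind == "unloader_inverse":
        inv = PerturbationSpec.make(
            "stripe_depletion", **{**prm, "factor": 1.0 / prm["factor"]}
        )
        return apply_perturbation(spec, inv)
    if p.kind == "compartment_strengthen":
        return replace(spec, plaid_factor=spec.plaid_factor * prm["multiplier"])
    raise ValueError(f"unknown perturbation kind {p.kind!r}")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a sampled cohort."""

    boundaries: list[GenomicInterval]
    boundary_labels: dict[int, str]  # edge bp -> six-type label
    differential_regions: list[tuple[GenomicInterval, int]]  # interval, direction
    compartment_labels: tuple[str, ...]


@dataclass
class Cohort:
    base_spec: SyntheticGenomeSpec
    specs: dict[str, SyntheticGenomeSpec]
    matrices: dict[str, list[ContactMatrix]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Default study cohort: one 20-Mb chromosome at 25-kb bins (800 bins),
# four alternating 5-Mb A/B compartment blocks, twelve TADs per block
# (widths 300-800 kb, intra-TAD factor 2), depth 2.5e6 read pairs per matrix.
# The condition panel mirrors a cohesin-perturbation screen: loaders
# (siNIPBL, siRad21, siMau2) lose a fixed set of boundaries and acquire
# one-sided stripe depletions; siCTCF loses its own boundary set (with an
# overlap defining all-dependent boundaries) and gains others; unloaders
# (siWAPL, siPDS5) invert the stripe effect; siESCO1 and control are
# unperturbed "others".
#
# Geometry constraints, all in bins of 25 kb:
#   - the stripe band starts at 1.05 Mb (42 bins), just beyond the 500-kb
#     insulation square's 40-bin reach, keeping boundary typing orthogonal
#     to the planted stripes;
#   - removable boundaries always sit between two 10-bin TADs, so a
#     removal merges at most 500 kb — strictly below the DRF band's l_min
#     — and leaves no footprint in any DRF sum;
#   - gained boundaries split 750-kb TADs in the first two blocks only,
#     far from every stripe region and its mirror band;
#   - stripe anchor regions are spaced so no region falls inside another
#     region's mirror band (the +/-1-2 Mb zone downstream whose upstream
#     sums also cross the attenuated entries).
# ---------------------------------------------------------------------------

#: per-compartment-block TAD widths in bins (sum 200 = 5 Mb)
_BLOCK_TAD_WIDTHS = (10, 10, 30, 10, 10, 30, 10, 10, 30, 10, 10, 30)

COHESIN_REMOVED_EDGES = (60, 110, 210, 310, 410, 510, 610, 710)
ALL_DEPENDENT_EDGES = (160, 360, 560)
CTCF_REMOVED_EDGES = (260, 460, 660)
COHESIN_GAINED_POSITIONS = (35, 235)  # centers of wide TADs, blocks 0-1
CTCF_GAINED_POSITIONS = (135, 335)

#: stripe-depleted anchor regions (bins) in the last two blocks
STRIPE_REGIONS = ((420, 425), (505, 510), (620, 625), (705, 710))
STRIPE_FACTOR = 0.45
STRIPE_D_MIN = 1_050_000
STRIPE_D_MAX = 2_000_000

LOADER_CONDITIONS = ("siNIPBL", "siRad21", "siMau2")
UNLOADER_CONDITIONS = ("siWAPL", "siPDS5")
OTHER_CONDITIONS = ("control", "siCTCF", "siESCO1")


def default_study_spec(
    depth: float = 2_500_000.0, resolution: int = 25_000
) -> SyntheticGenomeSpec:
    """The unperturbed control genome of the default synthetic study."""
    n_blocks, block_bins = 4, 200
    segs = []
    pos = 0
    for _ in range(n_blocks):
        for w in _BLOCK_TAD_WIDTHS:
            segs.append(
                TadSegment(pos * resolution, (pos + w) * resolution, 2.0)
            )
            pos += w
    labels = tuple(
        "A" if (i // block_bins) % 2 == 0 else "B"
        for i in range(n_blocks * block_bins)
    )
    loops = tuple(
        Loop((s.start // resolution + 1) * resolution,
             (s.end // resolution - 2) * resolution, 4.0)
        for s in segs[::8]
    )
    return SyntheticGenomeSpec(
        chrom="chrS",
        length=n_blocks * block_bins * resolution,
        resolution=resolution,
        decay_exponent=1.0,
        depth=depth,
        tad_segments=tuple(segs),
        compartment_labels=labels,
        plaid_factor=1.5,
        loops=loops,
    )


def _bp(bins: int, resolution: int = 25_000) -> int:
    return bins * resolution


def default_study_design(
    resolution: int = 25_000,
) -> dict[str, list[PerturbationSpec]]:
    """Condition panel of the default synthetic study (see module docs)."""
    mk = PerturbationSpec.make
    stripes = [
        mk(
            "stripe_depletion",
            start=_bp(a, resolution),
            end=_bp(b, resolution),
            direction=+1,
            factor=STRIPE_FACTOR,
            d_min=STRIPE_D_MIN,
            d_max=STRIPE_D_MAX,
        )
        for a, b in STRIPE_REGIONS
    ]
    inverses = [mk("unloader_inverse", **dict(s.params)) for s in stripes]
    cohesin_boundaries = [
        mk("boundary_removal", edge=_bp(e, resolution))
        for e in COHESIN_REMOVED_EDGES + ALL_DEPENDENT_EDGES
    ] + [
        mk("boundary_gain", position=_bp(g, resolution))
        for g in COHESIN_GAINED_POSITIONS
    ]
    ctcf_boundaries = [
        mk("boundary_removal", edge=_bp(e, resolution))
        for e in CTCF_REMOVED_EDGES + ALL_DEPENDENT_EDGES
    ] + [
        mk("boundary_gain", position=_bp(g, resolution))
        for g in CTCF_GAINED_POSITIONS
    ]
    return {
        "control": [],
        "siNIPBL": cohesin_boundaries + stripes,
        "siRad21": cohesin_boundaries + stripes,
        "siMau2": list(stripes),
        "siCTCF": list(ctcf_boundaries),
        "siWAPL": list(inverses),
        "siPDS5": list(inverses),
        "siESCO1": [],
    }


def default_grouping() -> dict[str, str]:
    """Condition -> DRF sample group for the default study design."""
    out = {c: "cohesin_loaders" for c in LOADER_CONDITIONS}
    out.update({c: "unloaders" for c in UNLOADER_CONDITIONS})
    out.update({c: "others" for c in OTHER_CONDITIONS})
    return out


def _boundary_delta_sign(
    design: Mapping[str, Sequence[PerturbationSpec]], condition: str, edge: int
) -> int:
    """+1 if the condition removes the edge, -1 if it gains it, else 0."""
    for p in design.get(condition, ()):
        if p.kind == "boundary_removal" and p.p["edge"] == edge:
            return +1
        if p.kind == "boundary_gain" and p.p["position"] == edge:
            return -1
    return 0


def make_cohort(
    base: SyntheticGenomeSpec,
    design: Mapping[str, Sequence[PerturbationSpec]],
    n_replicates: int = 2,
    seed: int = 0,
) -> Cohort:
    """Sample one matrix per condition per replicate, with ground truth.

    ``design`` maps condition names to perturbation lists; it must contain
    an unperturbed ``control``. Boundary truth labels are derived
    symbolically: each evaluated edge (control TAD edges plus any gained
    positions) gets the six-type label implied by which conditions remove
    or gain it, pushed through the same ordered rule the classifier uses.
    Differential-DRF truth intervals are the stripe-depleted anchor regions
    of the loader conditions.
    """
    if "control" not in design:
        raise ValueError("design must include a 'control' condition")
    if design["control"]:
        raise ValueError("control must be unperturbed")
    base.validate()
    specs: dict[str, SyntheticGenomeSpec] = {}
    for cond, perts in design.items():
        s = base
        for p in perts:
            s = apply_perturbation(s, p)
        specs[cond] = s

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * n_replicates)
    matrices: dict[str, list[ContactMatrix]] = {}
    k = 0
    for cond in specs:
        matrices[cond] = []
        for _ in range(n_replicates):
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            matrices[cond].append(sample_matrix(specs[cond], child_seed))
            k += 1

    # evaluated boundaries: interior control edges + gained positions
    edges = sorted(
        {seg.end for seg in base.tad_segments[:-1]}
        | {
            p.p["position"]
            for perts in design.values()
            for p in perts
            if p.kind == "boundary_gain"
        }
    )
    res = base.resolution
    boundaries = [
        GenomicInterval(base.chrom, e - res // 2, e + res // 2) for e in edges
    ]
    labels = {}
    for e in edges:
        d_nipbl = _boundary_delta_sign(design, "siNIPBL", e)
        d_rad21 = _boundary_delta_sign(design, "siRad21", e)
        d_ctcf = _boundary_delta_sign(design, "siCTCF", e)
        labels[e] = classify_deltas(d_nipbl, d_rad21, d_ctcf, t=0.5)

    diff_regions: list[tuple[GenomicInterval, int]] = []
    seen = set()
    for cond, perts in design.items():
        for p in perts:
            if p.kind == "stripe_depletion":
                key = (p.p["start"], p.p["end"])
                if key in seen:
                    continue
                seen.add(key)
                direction = -1 if p.p["factor"] < 1 else +1
                diff_regions.append(
                    (GenomicInterval(base.chrom, key[0], key[1]), direction)
                )

    truth = GroundTruth(boundaries, labels, diff_regions, base.compartment_labels)
    return Cohort(base, specs, matrices, truth)
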