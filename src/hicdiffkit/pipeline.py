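"""End-to-end convenience pipelines over a synthetic (or real) cohort.

These functions chain the library stages the way the comparative study
runs them: per-chromosome depth normalization, replicate merging for
insulation scoring, per-sample relative-frequency maps against a common
control reference for DRF, group statistics and differential-region
calling, and recovery metrics against a cohort's planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .drf import (
    DifferentialRegion,
    DrfConfig,
    GroupDrfStats,
    SampleGrouping,
    differential_drf_regions,
    drf,
    group_drf_stats,
    relative_frequency_map,
)
from .insulation import BoundaryRecord, ClassifierConfig, classify_boundaries, insulation_500k
from .intervals import GenomicInterval
from .matrix import BinTrack, ContactMatrix, NormTag, chrom_total_normalize
from .synthetic import Cohort, default_grouping, sample_matrix


def merge_replicates(mats: Sequence[ContactMatrix]) -> ContactMatrix:
    """Sum replicate count matrices into one (RAW) matrix."""
    first = mats[0]
    vals = sum(m.values for m in mats)
    return ContactMatrix(first.chrom, first.resolution, vals, norm_tag=NormTag.RAW)


def condition_insulation_tracks(
    matrices: Mapping[str, Sequence[ContactMatrix]],
    target_total: float | None = None,
) -> dict[str, BinTrack]:
    """500-kbp insulation per condition from replicate-merged matrices."""
    merged = {c: merge_replicates(m) for c, m in matrices.items()}
    if target_total is None:
        target_total = float(np.median([m.total() for m in merged.values()]))
    return {
        c: insulation_500k(chrom_total_normalize(m, target_total))
        for c, m in merged.items()
    }


def boundary_typing(
    cohort: Cohort, cfg: ClassifierConfig | None = None
) -> tuple[list[BoundaryRecord], int]:
    """Classify the cohort's evaluated boundaries into the six types."""
    tracks = condition_insulation_tracks(cohort.matrices)
    return classify_boundaries(cohort.truth.boundaries, tracks, cfg)


def boundary_recovery(
    cohort: Cohort, records: Sequence[BoundaryRecord]
) -> dict[str, float]:
    """Per-truth-label fraction of boundaries recovered with that label."""
    truth = cohort.truth.boundary_labels
    hits: dict[str, list[bool]] = {}
    for r in records:
        t = truth[r.interval.midpoint]
        hits.setdefault(t, []).append(r.label == t)
    return {label: float(np.mean(v)) for label, v in hits.items()}


@dataclass
class DrfAnalysis:
    tracks: dict[str, BinTrack]
    grouping: SampleGrouping
    stats: GroupDrfStats
    regions: list[DifferentialRegion]


def drf_differential_analysis(
    cohort: Cohort,
    ref_seed: int = 900_000,
    cfg: DrfConfig | None = None,
    t_drf: float = 0.7,
    grouping: Mapping[str, str] | None = None,
) -> DrfAnalysis:
    """Per-replicate DRF tracks, group stats and differential regions.

    Every condition replicate becomes one sample; its relative-frequency
    map is taken against an independently sampled control-law reference
    (emulating a merged deep control), after normalizing all matrices to a
    common per-chromosome total.
    """
    gmap = dict(grouping) if grouping is not None else default_grouping()
    target = float(
        np.median([m.total() for ms in cohort.matrices.values() for m in ms])
    ) * 2
    ref = chrom_total_normalize(
        sample_matrix(cohort.base_spec, ref_seed % (2**31)), target
    )
    tracks: dict[str, BinTrack] = {}
    groups: dict[str, str] = {}
    for cond, mats in cohort.matrices.items():
        for k, m in enumerate(mats):
            name = f"{cond}_rep{k + 1}"
            M = relative_frequency_map(chrom_total_normalize(m, target), ref)
            tracks[name] = drf(M, cfg)
            groups[name] = gmap[cond]
    sg = SampleGrouping(groups)
    stats = group_drf_stats(tracks, sg)
    regions = differential_drf_regions(stats, t_drf)
    return DrfAnalysis(tracks, sg, stats, regions)


def compartment_recovery(seed: int, depth: float = 2_500_000.0) -> float:
    """Fraction of bins whose PC1 sign matches the planted A/B labels.

    Samples one control-law matrix, runs VC_SQRT -> observed/expected ->
    correlation PC1 oriented by the planted A labels, and scores sign
    agreement over defined bins.
    """
    from .matrix import compartment_pc1, observed_over_expected, vc_sqrt_normalize
    from .synthetic import default_study_spec

    spec = default_study_spec(depth=depth)
    m = sample_matrix(spec, seed % (2**31))
    oe = observed_over_expected(vc_sqrt_normalize(m))
    labels = np.asarray(spec.compartment_labels)
    orient = BinTrack(spec.chrom, spec.resolution, (labels == "A").astype(float))
    pc1 = compartment_pc1(oe, orient)
    ok = np.isfinite(pc1.values)
    planted = np.where(labels == "A", 1.0, -1.0)
    return float(np.mean(np.sign(pc1.values[ok]) == planted[ok]))


def intertad_epigenome_recovery(
    seed: int, depth: float = 1_000_000.0, n_loaders: int = 3
) -> float:
    """Cluster purity of interTAD changes against planted compartment pairs.

    Loader-like conditions strengthen the compartment plaid, depleting
    interactions between active (A, Pol2-marked) and inactive (B,
    H3K27me3-marked) TADs while boosting same-compartment contacts. TAD
    pairs are scored by log2 interTAD fold change per condition and
    clustered at k = 2; purity is measured against the planted
    same-vs-mixed compartment pairing.
    """
    from .intertad import annotate_tads, cluster_tad_pairs, intertad_logfc_table
    from .synthetic import (
        PerturbationSpec,
        apply_perturbation,
        default_study_spec,
    )

    spec = default_study_spec(depth=depth)
    pert = apply_perturbation(
        spec, PerturbationSpec.make("compartment_strengthen", multiplier=1.5)
    )
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_loaders + 1)]
    ctrl = sample_matrix(spec, seeds[0])
    samples = {
        f"loader{k + 1}": sample_matrix(pert, seeds[k + 1]) for k in range(n_loaders)
    }
    res = spec.resolution
    tads = [
        GenomicInterval(spec.chrom, seg.start, seg.end) for seg in spec.tad_segments
    ]
    labels = np.asarray(spec.compartment_labels)
    peaks = {
        "Pol2": [
            GenomicInterval(spec.chrom, s.start, s.end)
            for s in spec.tad_segments
            if labels[s.start // res] == "A"
        ],
        "H3K27me3": [
            GenomicInterval(spec.chrom, s.start, s.end)
            for s in spec.tad_segments
            if labels[s.start // res] == "B"
        ],
    }
    annotated = annotate_tads(tads, peaks)
    table = intertad_logfc_table(samples, ctrl, annotated)
    clustered = cluster_tad_pairs(table, k=2, seed=seed % (2**31))
    truth = np.array(
        [p.tad_a.category == p.tad_b.category for p in clustered]
    )
    assigned = np.array([p.cluster for p in clustered])
    correct = 0
    for c in np.unique(assigned):
        members = truth[assigned == c]
        correct += max(members.sum(), len(members) - members.sum())
    return correct / len(clustered)


def permutation_type_one_error(
    n_tests: int = 1000,
    n_perm: int = 1000,
    n_background: int = 200,
    n_query: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of null permutation tests rejecting at ``alpha``.

    The query is a uniform draw from the background, so the nominal
    rejection rate should match ``alpha``.
    """
    from .enrichment import FeatureSet, permutation_overlap_test

    rng = np.random.default_rng(seed)
    positions = np.arange(n_background) * 10_000
    background = FeatureSet(
        "bg", [GenomicInterval("chr1", int(p), int(p) + 100) for p in positions]
    )
    features = FeatureSet(
        "f",
        [
            GenomicInterval("chr1", int(p), int(p) + 100)
            for p in positions[: n_background // 2]
        ],
    )
    hits = 0
    for t in range(n_tests):
        pick = rng.choice(n_background, size=n_query, replace=False)
        query = FeatureSet("q", [background.intervals[i] for i in pick])
        res = permutation_overlap_test(
            query,
            background,
            features,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        hits += res.p < alpha
    return hits / n_tests


def ci_coverage(
    n_bins: int = 10_000, n_samples: int = 5, ci_level: float = 0.99, seed: int = 0
) -> float:
    """Empirical coverage of the group CIs for a known zero mean."""
    rng = np.random.default_rng(seed)
    tracks = {
        f"cl{k}": BinTrack("chr1", 25_000, rng.normal(size=n_bins))
        for k in range(n_samples)
    }
    tracks.update(
        {
            f"o{k}": BinTrack("chr1", 25_000, rng.normal(size=n_bins))
            for k in range(n_samples)
        }
    )
    grouping = SampleGrouping(
        {s: ("cohesin_loaders" if s.startswith("cl") else "others") for s in tracks}
    )
    stats = group_drf_stats(tracks, grouping, ci_level=ci_level)
    lo = stats.ci_lower["cohesin_loaders"]
    hi = stats.ci_upper["cohesin_loaders"]
    return float(np.mean((lo <= 0) & (0 <= hi)))


def interval_bins(iv: GenomicInterval, resolution: int) -> set[int]:
    return set(range(iv.start // resolution, iv.end // resolution))


def bin_precision_recall(
    truth: Sequence[GenomicInterval],
    called: Sequence[GenomicInterval],
    resolution: int,
) -> tuple[float, float]:
    """Bin-level precision and recall of called vs truth intervals."""
    t_bins: set[int] = set()
    for iv in truth:
        t_bins |= interval_bins(iv, resolution)
    c_bins: set[int] = set()
    for iv in called:
        c_bins |= interval_bins(iv, resolution)
    tp = len(t_bins & c_bins)
    precision = tp / len(c_bins) if c_bins else float("nan")
    recall = tp / len(t_bins) if t_bins else float("nan")
    return precision, recall
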