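# hicdiffkit

Multi-sample Hi-C comparison toolkit: quantify how chromatin-architecture
perturbations (cohesin, its loaders and unloaders, CTCF) reshape contact
maps, at the level of TAD boundaries, directional long-range interaction
changes, and interTAD contacts.

`hicdiffkit` is aimed at analysts who already have per-chromosome binned
contact matrices (and, optionally, TAD/loop calls and ChIP-seq peak sets
from the usual upstream tools) and want to *compare conditions*:

- **Insulation-score boundary typing.** The insulation score at distance
  d is the log2 cross-position contact enrichment in a sliding d x d
  square, normalized to its chromosome mean. Each TAD boundary is typed
  by comparing 500-kb scores between depletions and control with an
  ordered six-branch rule at threshold T_ins = 0.13: all-dependent,
  cohesin-dependent, CTCF-dependent, CTCF-separated, cohesin-separated,
  robust.
- **Directional relative frequency (DRF).** From the log-ratio map
  M = ln C_treat − ln C_ctrl, DRF_i = Σ_j M[i, i+j] − Σ_j M[i, i−j] over
  a 500 kb–2 Mb band measures the directional bias of a depletion's
  long-range effect. Differential regions are bins where the 99%
  confidence intervals of the "cohesin and loaders" and "others" sample
  groups are disjoint and |mean loader DRF| > T_DRF = 0.7, merged into
  runs; perturbation profiles are compared by cosine similarity of M
  around region centers.
- **InterTAD clustering.** TADs (>100 kb) are annotated with epigenomic
  marks covering >40% of their length; TAD pairs ≤ 2 Mb apart are scored
  by log2(N_treat/N_ctrl) of their interTAD rectangle and clustered by
  k-means (k = 5), with z-scored mark-pair composition per cluster.
- **Permutation overlap statistics.** Two-tailed permutation tests
  (n = 1000) of feature overlap against a background, Simpson-index DEG
  overlap, sign-vector k-means (k = 20), and peak-anchored loop
  filtering.
- **A synthetic Hi-C simulator** with planted TADs, A/B plaid, loops,
  one-sided stripes and perturbation operators (boundary removal/gain,
  TAD loss, stripe depletion and its unloader inverse, compartment
  strengthening) that emits ground truth alongside sampled cohorts, so
  the whole analysis stack is testable end to end without downloads.

Inputs are plain text: COO (`bin1 bin2 count`) or dense TSV contact
matrices, BED for TADs/peaks/boundaries, BEDPE for loops; tracks are
written as bedGraph.

## Worked example

Simulate the default synthetic study (8 conditions × 2 replicates on a
20-Mb chromosome) and run the two headline analyses:

```python
from hicdiffkit.pipeline import (
    boundary_typing, boundary_recovery, drf_differential_analysis,
    bin_precision_recall,
)
from hicdiffkit.synthetic import (
    default_study_spec, default_study_design, make_cohort,
)

cohort = make_cohort(default_study_spec(), default_study_design(),
                     n_replicates=2, seed=11)

records, dropped = boundary_typing(cohort)
counts = {}
for r in records:
    counts[r.label] = counts.get(r.label, 0) + 1
print("boundary types:", counts, "| dropped:", dropped)

analysis = drf_differential_analysis(cohort)
truth = [iv for iv, _ in cohort.truth.differential_regions]
called = [r.interval for r in analysis.regions]
p, rec = bin_precision_recall(truth, called, 25_000)
print(f"differential DRF regions: {len(analysis.regions)} "
      f"(bin precision {p:.2f}, recall {rec:.2f})")
for r in analysis.regions[:2]:
    print(f"  {r.interval.chrom}:{r.interval.start}-{r.interval.end} "
          f"direction {r.direction:+d}")
```

prints

```
boundary types: {'robust': 32, 'cohesin-separated': 2, 'cohesin-dependent': 8,
'CTCF-separated': 2, 'all-dependent': 3, 'CTCF-dependent': 3} | dropped: 1
differential DRF regions: 4 (bin precision 1.00, recall 1.00)
  chrS:10500000-10625000 direction -1
  chrS:12625000-12750000 direction -1
```

Reading this: of the 51 evaluated boundaries, the classifier recovers
the planted types — the 8 boundaries removed only in the cohesin/loader
conditions come back `cohesin-dependent`, the 3 removed in both loader
and CTCF depletions come back `all-dependent`, untouched boundaries stay
`robust` (one boundary sits too close to the chromosome end for a 500-kb
score and is dropped). The DRF caller finds exactly the four planted
one-sided stripe anchors, with negative direction: downstream contacts
were depleted in the loader group.

The same stages are scriptable from the shell (`hicdiffkit simulate`,
`hicdiffkit insulation`, `hicdiffkit classify-boundaries`,
`hicdiffkit drf`, `hicdiffkit drf-diff`, `hicdiffkit pc1`,
`hicdiffkit overlap-test`, `hicdiffkit simpson`, `hicdiffkit segments`,
`hicdiffkit normalize`); run `hicdiffkit --help` for flags.

## Tests

```sh
python -m pytest tests/
```

The suite covers hand-computed oracles for every statistic, property
tests (classifier exhaustiveness, DRF antisymmetry, scale invariances),
and end-to-end parameter recovery on the synthetic cohort.

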