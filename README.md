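# eventshift

Analysis pipeline linking human event-boundary strength (across-observer
agreement) to multi-voxel pattern shifts at multiple cortical-hierarchy
timescales during naturalistic movie viewing, including cross-hierarchy
alignment scores and hippocampal boundary-locked responses. A synthetic-data
module with planted ground truth makes every stage testable without access
to the original recordings.

## Modules

| module | purpose |
| --- | --- |
| `eventshift.layout` | session timing map (movies, titles, runs, TR indexing) |
| `eventshift.synthetic` | observer logs, hierarchical cortex data and hippocampal series with graded or binary boundary-response profiles |
| `eventshift.segmentation` | observer logs → agreement series → boundary detection, strength binning, exclusions, TR mapping, rating validation |
| `eventshift.hierarchy` | ISC under temporal scrambling → voxel timescale labels → parcel hierarchy levels |
| `eventshift.patternshift` | pattern-shift correlation series, normalization, level averaging, cross-boundary correlations and shift indicators |
| `eventshift.stats` | Kruskal–Wallis/Dunn/Spearman, between-subject variance, JZS Bayesian one-way ANOVA, Hartigan's dip test (own implementation, bootstrap p), repeated-measures ANOVA, paired t, non-boundary sampler |
| `eventshift.alignment` | strict-nesting / nesting / summation alignment scores, ROI series, boundary-locked responses, grouped response tests |
| `eventshift.io` / `eventshift.pipeline` / `eventshift.cli` | TSV/JSON/YAML/NIfTI I/O, run configuration, fixture study, end-to-end pipeline, CLI |
| `eventshift.recovery` | parameter-recovery helpers used by the validation suites |

## CLI

```bash
# write a miniature synthetic study (layout, observer logs, NIfTIs, truth)
eventshift simulate --out study/ --seed 0

# boundary detection from observer logs
eventshift segment --logs study/observer_logs.tsv --layout study/layout.yaml \
    --out boundaries.tsv --percentile 65 --min-sep 6

# non-boundary control time points
eventshift nonboundary --layout study/layout.yaml --out nb.tsv --per-run 22

# full pipeline (segmentation → hierarchy → pattern shift → stats → alignment)
eventshift all --config study/config.yaml
```

Pipeline outputs (boundary table, agreement series, hierarchy assignment,
shift series, cross-boundary correlation tables, statistics reports,
alignment scores, hippocampal responses, provenance record) are written as
TSV/JSON under the configured output directory.

## Notes

- All times are seconds on the concatenated session timeline; all fMRI
  positions are 0-based, run-global TR indices (HRF shift applied when
  mapping boundary times to TRs).
- The dip statistic is computed with the classic GCM/LCM construction and
  was validated against an independent reference implementation; p-values
  come from a seeded uniform bootstrap.
- The Bayesian one-way ANOVA uses default JZS priors (fixed-effect scale
  0.5) with numerical integration and was validated against an independent
  reference implementation.
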