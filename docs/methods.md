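# Methods

## Data model and normalization

The in-memory container is a genes × cells integer count matrix with
per-cell metadata (`cell_type`, `dataset`); an `anndata` exporter is
provided for interop. Expression is reported as `ln(CPM + 1)` with CPM =
counts / cell total × 10⁶; the pseudocount of 1 sits inside the log so a
zero count maps to exactly 0. The per-cell denominator can exclude a
configurable deny-list (fluorescent reporters, spike-ins) — whether such
genes should contribute to library size is genuinely open, and excluding
them is the conservative default since reporter load varies with labeling
efficiency rather than biology. Cells with zero (post-exclusion) total are
rejected with their identifiers listed, never silently dropped.

Matrices round-trip through MatrixMarket coordinate files (1-based) with
gene/barcode sidecars, or dense CSV; both on-disk orientations are accepted
via a flag because both conventions are common in the wild.

## Marker ranking

Markers of a target cell type are ranked by the ratio of natural logs of
average expression, where "average expression" is computed on the CPM scale
and logged afterwards: `score = ln(mean CPM_in + 1)/max(ln(mean CPM_out + 1), ε)`.
A flag switches to mean-of-logs; the CPM-then-log reading is the default
because the ratio is conventionally quoted against group-mean expression
levels. ε (default 0.01) guards division by zero when a gene is entirely
absent from the comparison group; such genes rank first, which is the
desired behavior for a perfectly specific marker.

Sensitivity/specificity filtering (defaults: detected in > 85% of target
cells, < 5% of comparison cells) precedes ranking. The "< 5%" specificity
criterion is ambiguous between fraction of comparison *cells* and fraction
of comparison cell *types*; both modes are implemented (`spec_mode`), with
per-cell the default and neither asserted as canonical.

Differential expression uses the two-sided Wilcoxon rank-sum test — the
exact null distribution for small tie-free groups, the tie-corrected normal
approximation otherwise (`scipy`'s automatic switch). Correction across
genes defaults to Bonferroni (the convention of the single-cell toolkits
this mirrors) with Benjamini–Hochberg as an option; the adjusted p is
clipped to never fall below the raw p.

## Detection and repertoires

Detection is a strict inequality `statistic > threshold`. The default for
plate-based full-length data is `counts > 0`; a `TPM > 5` preset matches
the convention used for microfluidic validation datasets. The matrices this
package sees carry no transcript lengths, so the `tpm` statistic is the
per-million scaling of counts — for full-length protocols this is the
natural desk-scale stand-in, and it is named so the policy intent is
explicit in configuration files. Strictness at the boundary (a value of
exactly 5 is *not* detected) is deliberate and tested.

Combinations are the distinct per-cell expressed-gene sets, ordered by
descending cell count then lexicographically; cells expressing nothing form
their own flagged combination, and a flag controls whether they enter
"expressing cells" denominators. Repertoire summaries use the sample SD
(n−1); mode ties resolve to the smallest attained count so reports are
deterministic.

Fisher's exact test (two-tailed) is computed by summing hypergeometric
point probabilities ≤ that of the observed table, conditional on margins,
with 1e-7 relative slack for floating-point ties — the convention of the
standard statistical suites. When the observed table is the modal one the
p-value is returned as exactly 1. The test suite checks this implementation
against full-table enumeration in exact rational arithmetic and against
`scipy.stats.fisher_exact`.

## Richness saturation

Each cell is a sampling unit; each panel gene a species; only incidence
(presence/absence) is used. With Q_k the number of genes detected in
exactly k of T cells:

* rarefaction: `S(t) = S_obs − Σ_k Q_k·C(T−k,t)/C(T,t)`, binomial
  coefficients via log-gamma so T ~ 10⁴ is unproblematic; S(1) = U/T and
  S(T) = S_obs analytically.
* Chao2: `Q0 = ((T−1)/T)·Q1²/(2Q2)` (bias-corrected `((T−1)/T)·Q1(Q1−1)/2`
  when Q2 = 0); `S_chao2 = S_obs + Q0`.
* extrapolation: `S(T+t*) = S_obs + Q0·[1 − (1 − Q1/(Q1 + T·Q0))^t*]`,
  which is continuous with rarefaction at t* = 0 and approaches the Chao2
  asymptote; a spectrum without singletons gives a flat curve — the
  operational saturation signal.

Confidence bands bootstrap the sampling units: cells are resampled with
replacement (default N = 200, seed mandatory) and pointwise 2.5/97.5
percentiles taken. This is simpler and more assumption-light than the
estimated-assemblage bootstrap used by ecology packages such as iNEXT,
which augments the data with the estimated undetected species before
resampling; that alternative would widen intervals slightly at strongly
extrapolated points. Because replicates with duplicated cells lose species,
the raw percentile band can sit marginally below the point estimate; bands
are therefore widened, where needed, to bracket it. Genes never detected
stay in the species list but contribute nothing to S_obs or the Q
spectrum.

Validation is oracle-based: rarefaction is checked against the exhaustive
average over all C(T,t) cell subsets for T ≤ 12, and a coverage study
(50 cohorts of T=176 cells drawn from a 40-gene assemblage whose detection
probabilities are log-uniform on [0.007, 0.6] — calibrated so ~90% of genes
are expected in ≥ 2 cells) verifies that the 95% band at 2T covers the true
richness in ≥ 90% of repeats.

## Target mapping

Receptor expression is profiled per (receptor gene, cell type): detection
fraction and mean `ln(CPM+1)` among detecting cells. A receptor unit is
"expressed" in a cell type when its member genes pass the prevalence
threshold — inclusive ≥ 10% by default, all members for multi-subunit
units (`unit_rule="all"`, since a channel needs its subunits; single-gene
units make the two rules coincide). A cell type is a target of a ligand if
any receptor unit of any of its peptides is expressed there; per-cell-type
signal counts deduplicate to distinct ligands by default (`count_by`
switches to distinct receptor genes, since dot-plot conventions differ on
this). Ligands with known receptors but no called cell type are flagged
orphans — candidate circulating signals — and are kept distinct from
ligands with no known receptor at all.

## Isoform classification

Input is a per-cell junction-count table, not alignments: junction
extraction belongs to standard upstream tools, and this module owns only
the classification that is otherwise done by eye in a genome browser. The
mouse *Calca* defaults (exon3→exon4 calcitonin, exon3→exon5 CGRP) are data,
not code. A cell is `<iso>_only` when that isoform's diagnostic reads reach
`min_reads` (default 1) and the other's do not, `both` when both do,
`undetected` otherwise; the CGRP fraction f = c₁/(c₁+c₂) is undefined at
zero coverage and invariant under uniform scaling of a cell's counts.
Summaries are over cells with any detection, with undetected cells counted
separately, and report both category fractions and per-isoform expressing
fractions (these differ: a "both" cell expresses each isoform).

## Carcinoid analyses

Bulk log-count cohorts are quantile-normalized (rank-wise mean of sorted
columns; ties receive the mean of the reference values at the tied ranks),
which is idempotent and rank-preserving per sample. The composite tumor
profile collects panel genes detected in strictly > 15% of tumor cells plus
an explicit, separately flagged manual include list. Coverage of a
reference panel is plain set arithmetic `|detected ∩ reference|/|reference|`.

Matching uses Jaccard similarity between the composite gene set and each
normal cell's expressed set (cosine over the same binary vectors as an
alternative); no similarity metric is canonical for this comparison, and
Jaccard is the natural choice for presence/absence profiles. Ties break to
the first reference cell and are flagged, as is an all-zero score vector.
The validated property is operational: on synthetic tumors generated by
flipping a known seed cell's profile at 5% per gene, the seed cell is
recovered as best match in ≥ 95% of runs.

## Synthetic data

The generator is a zero-inflated log-normal: detection (Bernoulli, per gene
× cell type) is independent of magnitude (log-normal among detecting
cells), matching the two quantities the analyses report — percent of cells
detecting, and mean expression among expressers. Counts are Poisson around
the cell's library-size-scaled expression masses (library sizes log-normal,
default median 5×10⁵); a noise-free rounding mode exists for degenerate
checks. Housekeeping background genes give every cell a realistic library.

The packaged cohorts pin the peptidergic panels to published per-gene
detection percentages where available (mouse: Calca 0.95, Pcsk1n 0.62,
Cartpt 0.34, Igf2 0.72, Ucn2 0.13, Iapp 0.07, Pomc 0.04; human: POMC 0.57,
CARTPT 0.04, near-ubiquitous CALCA/GRP/granins) and fill the remaining
spectrum once so the expected per-cell panel count is ≈7.2 (mouse, 43
genes) and ≈12.2 (human, 40 genes, 26 shared with mouse); the full mouse
catalog is padded to its annotated size of 91 for percent-of-catalog
denominators. Genes are independent — real gene-gene correlation structure,
batch effects and ambient contamination are not emulated — so passing tests
demonstrate the correctness of the computations under the stated generative
model, not robustness to those real-data artifacts. The per-cell SD of
panel counts is consequently somewhat narrower than real cohorts show
(~1.7 vs ~1.9 at matched means).

Default problem sizes mirror the cohorts the analyses describe (176 mouse
cells + 358 other cells, 92 validation cells, 55 human cells, 330 tumor
cells) with 2000-cell runs for parameter-recovery studies; all generators
are bit-reproducible under a fixed seed.

## Pipeline and reporting

`pnec run` executes stages in dependency order from a YAML config; every
stage re-reads its inputs from the output directory, so a single stage can
be re-run from cached artifacts and reproduce the full-run outputs. Tabular
outputs carry a config-hash/seed comment line; outputs are byte-identical
across runs of the same config and seed. Plain files plus a manifest were
chosen over a workflow engine: at this scale inspectability wins.

## Known limitations

* Chao2 is a lower-bound estimator: species far below the singleton regime
  (detection probability ≪ 1/T) leave no Q1/Q2 trace, and no
  incidence-based interval can account for them.
* The `tpm` policy name is a per-million scaling of counts (no length
  correction); with genuinely length-biased quantifications the caller
  should pre-compute TPM upstream.
* Cross-species gene pairing is by explicit tables/case-folded symbols,
  never inferred orthology.
* The per-cell-types specificity mode treats all comparison types equally
  regardless of their cell counts.
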