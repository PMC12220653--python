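# Methods

## The audit model

A chimeric mis-annotation fuses k ≥ 2 real genes into one gene model. Its
homology fingerprint against a curated protein database is distinctive:
each true component's homolog aligns fully (target coverage ≈ 1) but spans
only ≈ 1/k of the fused query, and the aligned spans occupy distinct,
non-overlapping regions of the query protein. An independent single-isoform
annotation of the same assembly tends to predict the components separately,
and those split models are covered near-fully by the same database targets.
The filter cascade encodes exactly this fingerprint; it does not attempt to
re-annotate, and its output is a candidate list with the per-filter
evidence, not a corrected gene set.

Assumptions: the database is trusted (its entries are not themselves
chimeric — violated in practice for low-curation databases, which is what
the coverage-signature screen measures); gene models are assessed via their
longest translated isoform; the alternate annotation carries one isoform
per gene; and hits are reported with BLAST/MMseqs2 tabular semantics
(1-based inclusive aligned spans).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ref_median_cov_max` | 0.60 | reference gene's median per-hit query coverage must be strictly below this; 1/2 coverage of a two-part chimera plus a 10 % size buffer |
| `alt_median_cov_min` | 0.70 | pooled median query coverage of linked alternate models must strictly exceed this |
| `shrink_fraction` | 0.10 | total fraction trimmed from each hit interval before clustering (half per end, floor rounding) |
| `min_clusters` | 2 | minimum distinct hit clusters for retention |
| `min_total_query_cov` | 0.50 | unshrunk hit-interval union must strictly exceed this fraction of the protein |
| `max_e_value` | 1e-5 | hit-loading cutoff for the detection scan; permissive because the filters themselves are coverage-based |
| screen: `max_e_value` / `min_aln_len` / `min_bit_score` | 1e-10 / 100 / 200 | database-screen retention (e inclusive, alignment length inclusive, bit score strictly greater) |
| audit: `max_e_value` | 1e-30 | strict upper bound for the length-ratio audit's high-confidence hits |

All threshold comparisons follow the stated strictness exactly; the
boundary behaviour (rejection at a median of exactly 60 %, retention
requiring ≥ 2 clusters, the classifier's inclusive 0.8 and 0.3 endpoints)
is pinned by tests.

## Procedure details and numerical choices

* **Coordinates.** Internally 0-based half-open for genome intervals;
  1-based inclusive for protein residue spans (the hit-table convention).
  Conversion happens only at file boundaries.
* **Longest isoform** is measured in translated protein length, computed
  from CDS length after phase trimming (a trailing stop codon counts one
  codon uniformly, so the comparison is unaffected); ties break to the
  lexicographically smallest transcript ID. mRNA length would be a
  defensible alternative; protein length was chosen because every
  downstream filter operates on protein coverage.
* **Linking** uses union-of-CDS overlap on the same strand with a ≥ 1 base
  threshold and no minimum fraction, because a chimera component may
  overlap an alternate model only partially. Transcript-level class codes
  of annotation-comparison tools are deliberately not reproduced: only the
  ref↔alt gene mapping feeds the filters. An externally produced two-column
  link table can be substituted.
* **Pooled alternate median.** The > 70 % test is computed over the pooled
  hits of all linked alternate genes rather than per gene. This keeps loci
  where the alternate annotation produced a single model assessable through
  the reference gene's own hit clusters.
* **Interval shrinking** removes `floor(L × shrink/2)` residues per end; an
  interval that would vanish collapses to its midpoint residue, so every
  hit keeps a vote in clustering. Increasing the shrink fraction can only
  split clusters, never merge them (shrunk intervals are nested), which the
  suite checks.
* **Clustering** is single linkage under closed-coordinate overlap (≥ 1
  shared residue; abutting intervals do not merge), delegated to pyranges
  with half-open coordinates and slack −1, and verified against a
  brute-force union-find oracle on 1,000 random instances. Each hit
  contributes one interval — multiple hits to the same target are not
  deduplicated. Total query coverage uses the **unshrunk** union, since
  shrinking exists only to de-noise clustering.
* **Ratio classifier.** log2 ratios are rounded to 3 decimals before
  comparison with the closed category intervals, so integer length pairs
  constructed to land on a boundary (e.g. 1741/1000 targeting 0.8) are
  classified by the boundary they encode rather than by representation
  error of ~1e-4. RBH tie-breaks: bit score, then e-value, then
  lexicographic target ID.
* **Self-hits** (query = target) are excluded from both database screens;
  they carry no mis-annotation signal.
* **Genome metrics.** GC% excludes N from the denominator and averages per
  sequence (pooled GC is available as an option). Intergenic distance is
  the count of bases strictly between adjacent gene *spans* (not CDS),
  strand-agnostic, after excluding genes overlapping any other gene.
  Spearman is computed as Pearson on midranks (scipy), with a hand-ranked
  tied example as the independent check.
* **Degenerate inputs.** Genes without hits are skipped and counted, never
  scored; empty hit lists make the coverage filter fail rather than error;
  an empty alternate target set fails the subset filter (the vacuous subset
  is rejected); genes with no coding transcript are dropped with a warning.

## The synthetic generator

`synthetic.simulate` emulates the audit's study conditions: by default 50
multi-exon genes (120–400 aa, 2–6 exons, both strands) on 2 sequences, 5 of
them planted chimeras whose component counts k = 2..6 are drawn with weights
499:81:12:6:2 — the composition observed across real curated genomes, where
two-gene fusions dominate. A fused gene concatenates complete component CDS
structures with the components' intergenic DNA retained as intron-like
spacers, so the fused protein is the exact concatenation of the component
proteins and every coverage value is analytic (component hits have
q_cov = len_i/Σlen, t_cov = 1). Component proteins are drawn from disjoint
per-protein residue alphabets so they are mutually non-homologous; the
generator verifies (and would refuse) any spurious substring homology.
Output is byte-identical under a fixed seed.

What it does **not** emulate: sequence-level homology noise (hits are exact
by construction, optionally jittered in coverage via `coverage_noise_sd`),
paralogy and shared domains between neighbouring genes, UTRs and
alternative splicing, codon-usage bias, assembly gaps, and annotation
errors other than clean fusion/splitting. Passing the planted-recovery test
therefore demonstrates that the cascade's logic is correct under its own
model of chimerism — not that real-genome precision/recall equals 1; on
real data, shared domains and partial homology are exactly what the shrink
step, the subset filter and manual review downstream exist to absorb.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
instances chosen to make every expected value analytic: bundles of 12–60
genes with 1–10 planted chimeras, 100-query screens, 1,000-instance oracle
comparisons, and 0.01-step ratio grids. The whole suite completes in well
under a minute on one CPU core.

## Known limitations

* The exact-match oracle is not an aligner; real searches (MMseqs2/BLAST)
  must be run externally and imported as m8 tables.
* Per-gene (rather than pooled) alternate medians, and clustering shrunk
  versus unshrunk intervals for the > 50 % coverage test, are genuinely
  open design points; the choices here are documented above and fixed.
* The candidate list is a screen: confirming a chimera still requires
  independent evidence (RNA-seq splice support, structure prediction),
  which is out of scope.
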