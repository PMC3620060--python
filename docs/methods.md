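# Methods

## Model and procedure

The pipeline analyses a transcriptome experiment with exactly one RNA-seq
library per condition. Its statistical core is the observation that, with
a single library, the only noise model one can defend is counting noise:
conditional on the two library totals, a gene's reads in two libraries
form a 2×2 table, and Fisher's exact test on

    [[count_A, total_A − count_A], [count_B, total_B − count_B]]

is an exactly valid — and, because it conditions on a discrete margin,
conservative — test of equal read proportions. All pairwise tests in the
package (gene-level DE, cassette-exon, retained-intron, and the
study-level contingency inferences) use the two-sided
**minimum-likelihood** convention: the P-value sums the probabilities of
all tables with the observed margins whose hypergeometric probability does
not exceed that of the observed table (`scipy.stats.fisher_exact`). A
pooled two-proportion z-test (`stats.two_proportion_normal_p`) is provided
as the asymptotic counterpart; for very large near-null tables the two
agree to within a few percent and historical analyses of this design used
the asymptotic form, so reports quote both where the distinction matters.

### Quantification

Expression is RPKM over the gene's *constitutive exons* — the bases
exonic in every annotated transcript of the gene, computed at base
resolution by interval intersection and reported as merged intervals.
Genes whose constitutive length is zero have no defined RPKM and are
excluded from testing, as are genes without an identifier in the supplied
gene universe. Genes with zero counts in both libraries are tested
(P = 1) but flagged, so downstream set logic can drop them if desired.

### Splicing statistics

A cassette-exon event needs annotation support for both isoforms (the
exon triple spliced consecutively, and the upstream–downstream junction).
Reads are classified per event as *inclusion* (cassette body or an
inclusion junction), *skipping* (the skipping junction), *flanking*
(flanking exon bodies only), or *irrelevant*; the classes are exhaustive
and mutually exclusive, with inclusion evidence taking precedence over
the (rare) contradictory multi-block read. The test contrasts inclusion
against skipping + flanking between conditions. Retained-intron events
are enumerated for every annotated intron (deduplicated by coordinates)
and contrast intronic inclusion reads against flanking reads. Each event
type is Bonferroni-corrected separately, over the events testable in that
comparison (events with all-zero counts are untestable and excluded from
m).

Direction calls and the reported log2 ratio change add +0.5 to each cell
(exclusion:inclusion for cassette exons, inclusion:flanking for introns)
so they are defined for empty cells; the adjustment is *not* applied to
the test itself. Ties after adjustment are reported as "decreased" (no
rise). The choice to pool flanking reads with skipping reads at weight 1
is a documented convention of this package; simulation confirms the
resulting ratio is monotone in the true inclusion level.

### Study-level inference

Counts of significant genes drive the biology-level conclusions:

* **Similarity contingency** — [[sig, nonsig] vs X; [sig, nonsig] vs Y].
  Each comparison keeps its own tested-gene denominator (the universes
  genuinely differ between comparisons).
* **Direction contingency** — [[up, down] per condition].
* **Gain/loss verdict** — overexpression-like iff the significant-gene
  proportion against the overexpression reference is smaller than against
  the knock-down reference *and* the similarity contingency rejects at
  α = 0.05 (exposed as a parameter); symmetric for knockdown-like;
  otherwise indeterminate. Untestable tables yield indeterminate.
* **Venn regions** — disjoint label-subset regions for 2–5 significant
  sets, by direct membership assignment.

### Multiple testing and thresholds

Bonferroni (p·m capped at 1) with m = genes (or events per type) actually
tested in that single comparison; selection at adjusted P < 0.05. The
fold-change threshold used to nominate genes for targeted validation is
log2FC ≥ 0.4 (fold > 2^0.4 ≈ 1.32). Gene-set over-representation uses
the upper-tail hypergeometric P or the EASE variant (overlap reduced by
one before taking the tail; ≥ the plain P for every input, hence
conservative — EASE is the default to mirror DAVID-style reports), with
Benjamini–Hochberg step-up FDR across the collection
(`statsmodels.stats.multitest`). Database content is never bundled: gene
sets (GMT) and the background universe are explicit inputs, because
over-representation results are functions of the database version.

### qPCR arithmetic

ddCt follows Livak: ΔCt = mean Ct(target) − mean Ct(normalizer) per
condition, ΔΔCt relative to the reference condition, relative expression
2^(−ΔΔCt). The sign of the exponent is configurable
(`positive_exponent=True`) because some reports print the opposite
convention. Band-intensity splicing validation averages per-replicate
unspliced:spliced ratios per condition and reports log2 versus the
reference; replicates with zero spliced intensity are dropped with a
warning.

## Synthetic experiment

The generator (`fisherseq.simulate`) emulates the *structure* of the
five-condition transfection design, scaled to desk size:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2,000 | gene universe (full-scale experiments: ~17,000) |
| `library_size` | 1e6 | uniquely mapped reads per library (full scale: 24–31M) |
| `assigned_fraction` | 0.7 | fraction of reads landing in constitutive exons |
| `baseline_log2_mean/sd` | 4 / 2 | log-normal abundance distribution |
| `focal_multipliers` | 2, 2, 2, 0.25 | transfected-gene folds (overexpression ×2, knock-down ×4 reduction) |
| `de_fraction` | 0.05 (0.08 siRNA) | fraction of genes perturbed per condition |
| `up_bias` | 0.9 / 0.1 (mutants) | probability a perturbed gene goes up |
| `effect_log2fc_range` | (1, 3) | uniform magnitude of perturbations |
| `effect_overlap` | mutants: 90% of wildtype | shared effect genes, with identical effects |
| `n_se_events`, `n_ri_events` | 200 each | splicing event universes |
| `inclusion_shift` | 1.5 | log-odds shift of ψ for affected events |
| `mean_event_reads` | 100 | Poisson mean read depth per event |
| `dispersion` | 0 | NB dispersion; 0 = Poisson |

Counts are negative-binomial with mean
`assigned_fraction · library · proportion · 2^log2fc` and variance
`μ + d·μ²`; the default d = 0 gives Poisson, the sampling model the Fisher
test assumes — appropriate because one library per condition measures
technical counting noise only. Setting d > 0 injects extra-Poisson noise
to probe the method's behaviour when that assumption fails (the test is
then anticonservative, which is exactly the known limitation of
replicate-free designs). Expected gene proportions are *not* renormalised
after applying effects, so truth labels stay exact; the induced deviation
of the realised library sum from its nominal total is small at the
default effect fractions and the nominal total is used as the Fisher
margin.

Shared effect genes copy the source condition's log2 fold change, not
just its identity — similarity of *transcriptome response* is what the
gain/loss inference measures. With the default 90% overlap, the two
mutant-like conditions' own up-biases (0.9 / 0.1) apply only to their 10%
private effect genes, so the direction asymmetry between mutants is
deliberately muted under the default configuration; analyses that target
the direction contrast disable the overlap (`effect_overlap={}`).

What the generator does **not** emulate: sequence content and mappability,
GC and length bias within a library, ribosomal contamination, ambiguous
multi-gene reads, isoform-level coupling between expression and splicing,
and biological replicate variance. Passing recovery tests therefore show
that the statistics recover the *structure they model* at realistic
depths — not that the pipeline is robust to artefacts absent from the
generator.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GTF/GFF3 (1-based
  inclusive) is converted on read. BED12 carries no gene grouping, so a
  `gene|transcript` name convention is used (a bare name is both ids).
* Strand is recorded but ignored by all statistics (non-strand-specific
  libraries).
* All enumerations (constitutive exons, events, result rows) are sorted
  by coordinates or (p, id), so outputs are byte-reproducible.
* Degenerate 2×2 tables (a zero margin) are uninformative: pairwise tests
  return P = 1, study-level contingencies return an untestable marker
  (NaN) that propagates to an indeterminate verdict.
* Bonferroni's guarantee is per pairwise comparison (its correction
  family). Null-calibration studies therefore score the fraction of
  *comparisons* with an empty selected set; pooling several comparisons
  bounds the family-wise error only by k·α.
* The published near-null contingency P-values of the modelled study
  match the two-proportion normal approximation rather than the exact
  test (which gives 0.81 / 0.42 / 0.0034 where 0.78 / 0.35 / 0.0031 were
  printed); both routes are implemented and reported side by side.
* Simulation scale (2,000 genes, 1e6 reads, 20 seeds for calibration
  studies) was chosen as the smallest size at which per-gene counts
  (hundreds) put the Fisher test in the regime the full-scale study
  occupies.

## Known limitations

* The replicate-free Fisher test treats biological variability as zero;
  its P-values overstate evidence whenever true replicate variance
  exists. This is a faithful property of the modelled design, not a
  defect of the implementation.
* Read classification operates on simplified alignment records (blocks +
  uniqueness flag); BAM ingestion is out of scope.
* Cassette-exon enumeration requires exact exon-coordinate matches
  between isoforms; fuzzy splice-site variation is not collapsed.
* Only skipped-exon and retained-intron event types are modelled; no
  alternative 5'/3' splice sites or mutually exclusive exons, and no
  PSI-style isoform deconvolution.
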