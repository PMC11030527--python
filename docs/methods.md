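# Methods

## Model and test

The unit of analysis is an *event*: one gene (one tissue/sample dataset)
with an ordered run of phased heterozygous SNPs and the two haplotype base
strings over them. Reads in the pileup at each SNP are assigned to haplotype
1, haplotype 2, or "other" by base identity, and summed over the run to give
the haplotype expression values $a_1$ and $a_2$. "Other" bases (sequencing
error, a third allele) are tallied but never credited to either allele.

Under the null hypothesis of balanced expression, each informative read
falls on haplotype 1 with probability $p_0 = 0.5$ independently, so
conditional on the total $n = a_1 + a_2$, $a_1 \sim \mathrm{Bin}(n, 0.5)$.
The per-event test is the exact two-sided binomial test (minlike two-sided
mass: the sum of all outcome probabilities not exceeding that of the
observed outcome), with Benjamini–Hochberg adjustment across the family of
tested events in one (sample, tissue) dataset (a `global` scope is
available). The effect statistic is
$\mathrm{aeFC} = \log_2 a_1 - \log_2 a_2$, with no pseudocount: a single
zero count gives a signed infinity (stored as ±1e9 plus a flag column in
TSVs), a double zero gives NaN and can never be significant.

Cascade, with defaults:

| step | rule | default |
|---|---|---|
| prefilter | $\max(a_1, a_2) \ge$ `min_count` | 10 reads |
| effect | $\lvert\mathrm{aeFC}\rvert \ge$ `fc_min` (infinite passes) | 2 (i.e. 4-fold) |
| error control | BH-adjusted $p \le$ `alpha` | 0.05 |
| support | $\max(a_1, a_2) \ge$ `exp_min` | 5 reads |

The support rule is implemented verbatim even though the default prefilter
makes it non-binding; it binds when a user lowers the prefilter. The null
$p_0$ is configurable for reference-bias correction, but no bias estimation
is performed: alignment bias toward the reference allele is a known,
uncorrected limitation of counting from alignments.

Sex-chromosome events are excluded from the main analysis (hemizygosity and
X-inactivation break the balanced-expression null) but are written to a
sidecar table rather than deleted.

## Synthetic data generator

The generator is the package's study design: it emulates the input stack a
haplotype-aware ASE study consumes, with known truth.

* **Phased transcriptome** — `n_genes` genes on 31 autosomes plus X
  (`sex_chrom_fraction`, default 5%, on X), each with `loci_per_gene`
  (default 1–5) strictly increasing SNP positions, two distinct alleles per
  locus, and a random choice of which haplotype carries the reference allele
  (so written VCFs contain both `0|1` and `1|0` genotypes).
* **Counts** — per-locus depth $\sim$ Poisson(`mean_depth`, default 50);
  conditional on depth, haplotype-1 reads $\sim$ Binomial with success
  probability 0.5 for balanced genes and $\mathrm{FC}/(1+\mathrm{FC})$ for
  the `ase_fraction` (default 10%) of imbalanced genes favoring haplotype 1
  (mirrored when haplotype 2 is favored; `fold_change` default 4). This is
  exactly the family under which the binomial test is correct. An optional
  `error_rate` (default 0) moves reads to a uniformly random non-haplotype
  base to exercise the "other" tally; counts always sum to depth.
* **Peak tracks** — per mark, a peak with random flanks is placed over
  approximately `coverage_fraction` of event regions, then merged to a
  sorted, disjoint BED track.
* **Validation cohort** — `n_samples` (default 66, a realistic replication
  cohort size) animals, each heterozygous at a discovery locus with
  probability `het_rate` (default 0.85); counts at retained loci reuse the
  discovery gene's haplotype-1 probability, so truly imbalanced loci
  replicate with concordant direction by construction.
* **Transcript models** — one toy transcript per gene (padded exon span,
  interior CDS with length divisible by 3, ~30% two-exon, ~5% non-coding)
  plus a deterministic random reference sequence pinned to each locus's
  reference allele, so codon-level consequences are computable without a
  FASTA on disk.

Determinism: every stage draws from `numpy.random.default_rng([seed, stage])`,
so identical (config, seed) gives byte-identical files and regenerating one
artifact never perturbs another.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: reference-mapping bias, overdispersion beyond
binomial (e.g. extraction batch or UMI-less PCR duplication effects),
linkage between neighboring genes, isoform mixtures, phasing errors, and
realistic genome annotation complexity.

## Consequence classification

A deliberately small stand-in for a full variant effect predictor. Per
overlapping transcript: CDS SNPs are translated in both alleles (synonymous
/ missense / stop_gained / stop_lost; a stop-to-stop change counts as
synonymous); exonic SNPs outside the CDS are 5'/3' UTR strand-aware; exons
of CDS-less transcripts give `non_coding_transcript_exon_variant`;
positions inside the transcript but outside exons are intronic. Splice
regions follow Ensembl's windows — last 3 exonic bases at an intron
boundary, first 8 intronic bases — with the 1–2 bp donor/acceptor core
folded into `splice_region_variant` since the term set does not
distinguish it. Terms are unioned over transcripts. A CDS locus whose codon
context is unavailable (no reference, or CDS length not divisible by three)
is reported as `coding_sequence_variant` with an `AnnotationWarning`
rather than dropped, keeping the term set non-empty.

Loci whose term set is contained in {intron, intergenic} are excluded from
downstream gene-level analyses (an RNA-seq read pile at such a position is
more plausibly an alignment artifact than transcription); mixed annotations
are kept with the intronic/intergenic terms stripped.

## Peak overlap and validation

An event's region runs from its first to last heterozygous position
(1-based inclusive; single-SNP events span 1 bp). A mark is hit when at
least 1 bp of the region intersects at least one peak of that mark from
the matching tissue and sample (tissue-only matching available for sparse
tracks); there is no reciprocal-fraction requirement. Combination counts
are exact (upset-style), with per-mark marginals and any-/multi-mark rates.

Validation re-tests each discovery locus per cohort sample on the two
discovery alleles' counts. A sample counts as heterozygous at a locus when
both alleles have ≥ 1 read and pileup depth ≥ 10 (an explicit genotype mask
can override this read-based rule, which is circular under extreme
imbalance). Significance per sample uses $|\mathrm{aeFC}| \ge 2$ and
BH-adjusted $p \le 0.05$, the BH family being the retained loci within that
sample; there is no additional ≥ 10 prefilter in validation. Direction
concordance is computed among significant calls against the discovery sign.

## Enrichment

Pathway over-representation is a transparent one-sided hypergeometric test:
with $M$ universe genes, $K$ in the pathway and $n$ input ASDEGs of which
$k$ overlap, $p = P(X \ge k)$. The universe defaults to all genes with at
least one tested event. Raw $p \le 0.05$ flags significance, matching
common practice for exploratory pathway screens; a BH option is exposed.

## Numerical and design notes

* Base-quality floor for pileup decoding defaults to Phred 13 (the samtools
  default); the pileup grammar (`^X`, `$`, indel runs, deletions, reference
  skips) is decoded exactly and a bases/qualities length mismatch is a
  parse error naming file, line and position.
* BH adjustment preserves input order; adjusted values are monotone in the
  raw order statistics and thresholding them at $\alpha$ reproduces the
  step-up rejection set. Re-adjusting already-adjusted values is *not* an
  identity and is not relied on anywhere.
* Phase grouping in VCFs uses the `PS` tag with a `GENE` info-tag fallback;
  unphased heterozygotes are skipped with a warning. Indels are ignored
  throughout (the analysis is defined on heterozygous SNPs).
* Events keyed per gene, not per isoform: haplotype sums are aggregated at
  the gene level.
* Test problem sizes (e.g. 5,000-gene null run, 1,000-gene power run,
  10,000-interval overlap oracle) were chosen so the whole suite runs in
  well under a minute on one CPU while keeping binomial counting error on
  measured rates below the asserted margins.

## Known limitations

* **Power at the threshold.** The significance cut $|\mathrm{aeFC}| \ge 2$
  equals $\log_2 4$: for genes simulated at exactly 4-fold imbalance the
  observed log-ratio is centered *on* the cut, so recovery converges to
  ~50% regardless of depth (pilot runs: 0.50–0.56 across seeds; 8-fold
  imbalance is recovered essentially completely). The regular suite
  therefore asserts a pilot-frozen recovery floor of 0.40 at the default
  conditions rather than near-complete recovery.
* No beta-binomial overdispersion or likelihood-ratio alternatives; no
  reference-bias estimation; no UMI handling; no isoform-resolved
  quantification; no peak calling or allele-specific ChIP analysis.
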