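# haplase

Haplotype-aware allele-specific expression (ASE) analysis for bulk RNA-seq.

In a diploid genome, the two copies of an autosomal gene are usually expressed
at similar levels; cis-regulatory variants, epigenetic marks or imprinting can
break that balance. When a gene carries phased heterozygous SNPs, short reads
overlapping those positions can be assigned to one haplotype or the other, and
the two haplotype-level read sums can be compared directly. `haplase`
implements that comparison as a reusable pipeline for anyone working from
phased variant calls (e.g. derived from long-read isoform sequencing) plus
short-read pileups:

1. **Counting** — decode samtools-mpileup text at each heterozygous locus and
   sum nucleotide tallies along the two haplotype base strings of each gene
   (`allele_quant`), excluding sex chromosomes from the autosomal analysis.
2. **Calling** — for each gene with haplotype sums $a_1, a_2$, compute the
   allele-expression fold change
   $\mathrm{aeFC} = \log_2 a_1 - \log_2 a_2$,
   an exact two-sided binomial p-value for $a_1$ successes in $a_1+a_2$
   trials under $p_0 = 0.5$, and Benjamini–Hochberg adjusted p-values.
   Events with $\max(a_1,a_2) < 10$ are excluded up front; an event is
   significant when $|\mathrm{aeFC}| \ge 2$, adjusted $p \le 0.05$ and
   $\max(a_1,a_2) \ge 5$ (`ase_stats`).
3. **Context** — classify each SNP's consequence against transcript models
   (UTR / missense / synonymous / stop / splice-region / non-coding; loci that
   are only intronic or intergenic are excluded), and intersect each event's
   haplotype region with H3K27ac / H3K4me1 / H3K4me3 / H3K27me3 peak tracks,
   tabulating single- and multi-mark combinations (`consequence`,
   `epigenome_overlap`).
4. **Validation** — re-test discovery loci across an independent multi-sample
   cohort with the same significance rule per sample, and report confirmation,
   direction-concordance and per-locus replication rates
   (`cohort_validation`).
5. **Reporting** — per-tissue summary tables, multi-context ASDEG
   (allele-specific differentially expressed gene) detection, and a one-sided
   hypergeometric pathway over-representation test (`reporting`).

A first-class synthetic-data generator (`synthetic_data`) emulates the whole
input stack — phased VCF, mpileup text, BED peak tracks, GTF transcripts,
pathway membership — with known per-gene ground truth (Poisson depth,
binomial allele split at $\mathrm{FC}/(1+\mathrm{FC})$), so every stage is
testable end to end without any external data.

## Worked example

Run the full synthetic study from the command line:

```bash
haplase all --seed 3 --outdir out/
```

which prints

```
events tested: 942, significant: 57
true-ASE recovery: 57/101 (56.4%)
null event false positives: 0/841 (0.00%)
validation: 5587/10773 significant (51.9%), 100.0% same direction
```

Of 1,000 simulated genes, 942 autosomal events pass the read-count prefilter;
57 are called significant, all of them truly imbalanced genes (no false
positives among the 841 tested balanced genes). Recovery is ~56%, not ~100%,
for a structural reason worth knowing about: the default simulated imbalance
(4-fold) coincides exactly with the $|\mathrm{aeFC}| \ge 2$ significance cut,
so the observed log-ratio fluctuates around the threshold — genes with
stronger imbalance are recovered essentially always (see `docs/methods.md`).
In the 66-sample validation cohort, every significant replication call agrees
with the discovery direction.

Each stage also runs standalone (`haplase simulate|count|test|annotate|
overlap|validate`) on plain-text intermediates, e.g.

```bash
haplase count --vcf loci.vcf --pileup counts.pileup --out counts.tsv
haplase test  --counts counts.tsv --out events.tsv
```

or from Python:

```python
from haplase import SimulationConfig, run_study

result = run_study(SimulationConfig(n_genes=1000, seed=3))
print(result.tissue_table)
print(result.validation_summary.pct_same_direction)
```

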