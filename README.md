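# hlacapseq

Genotyping and allele-level RNA quantification of the 12 classical HLA loci
(*HLA-A, -B, -C, -DPA1, -DPB1, -DQA1, -DQB1, -DRA, -DRB1, -DRB3, -DRB4,
-DRB5*) from capture RNA-Seq reads, with differential-allelic-expression
(DAE) statistics. It is written for immunogenetics groups who capture-enrich
cDNA libraries with HLA-specific probes, sequence 2×150 bp paired reads, and
want both the diploid genotype and a quantitative per-allele expression
estimate from the same run.

## Method

The HLA loci are too similar for conventional mappers to separate reliably,
so the pipeline uses a deliberately strict rule set:

1. **Perfect-match assignment.** A read supports an allele only if the full
   read (or its reverse complement) occurs verbatim in that allele's
   reference sequence — a 100 % matched condition that avoids mismapping
   between loci and suppresses PCR crossover artifacts. Genotypes are
   called per locus by choosing the allele pair (a₁, a₂) maximizing the
   number of explained reads, scored by unique support (reads hitting
   exactly one of a₁, a₂), with a deterministic lexicographic tie-break.
2. **In-phase counting over polymorphic exon windows.** RNA levels are read
   counts restricted to the highly polymorphic exons: exons 2+3 (546 bp)
   for class I, exon 2 for class II (239 bp *DRA*, 270 bp *DRB1/3/4/5* and
   *DQB1*, 249 bp *DQA1*, 246 bp *DPA1*, 264 bp *DPB1*). For a heterozygous
   pair, a read counts for allele a₁ only if it perfectly matches a₁'s
   reference, overlaps the window, and does **not** match a₂ (in-phase
   assignment). Homozygous, partially phased and hemizygous configurations
   are excluded — their reads cannot be divided between alleles.
3. **Normalization.** Raw counts c are standardized by the window target
   size L (c/L, reads per base) and scaled within a locus set so each
   sample sums to one million: nᵢ = 10⁶ · (cᵢ/Lᵢ) / Σⱼ (cⱼ/Lⱼ). Four
   standard sets are built: (1) all 12 loci, (2) class I, (3) class II
   without *DRB3/4/5*, (4) class II with *DRB3/4/5*; sets 1 and 4 require
   two distinguishable *DRB3/4/5* alleles per sample.
4. **DAE statistics.** Per locus and per allele: five-number summaries
   (inclusive linear-interpolation quartiles), ratio of hinges Q₃/Q₁, fold
   change (highest/lowest allele median), CV (sample SD / mean), one-way
   ANOVA, Pearson r², and box-whisker summaries with whiskers at 1.5·IQR.

A seeded simulator generates toy allele panels with the canonical window
lengths, diploid genotypes with realistic *DRB3/4/5* haplotype structure
(at most one secondary DRB gene per haplotype), log-normal allelic
expression and capture-bias weights, and error-bearing 2×150 bp paired
FASTQ with the ground truth recorded for recovery testing.

## Worked example

Simulate six samples over six loci and run the full pipeline:

```sh
cat > demo.yaml <<'YAML'
out_dir: demo_out
seed: 11
simulate:
  loci: [A, B, C, DRB1, DRB3, DRB4]
  alleles_per_locus: 3
  divergence: 3
  n_samples: 6
  depth: 4000
  error_rate: 0.001
sets: [1, 2, 3, 4]
min_unique_support: 10
YAML
hlacapseq run --config demo.yaml
```

The run report prints the read accounting:

```
"counts": {
  "reads_in": 48000,
  "reads_in_phase": 19149,
  "reads_matched": 47028,
  "reads_unmatched": 972
}
```

48,000 mates entered; 47,028 matched some allele perfectly (the ~2 %
shortfall is the simulated 0.001/base substitution error — one error
anywhere in a 150 bp read removes it); 19,149 were unambiguously in phase
at a completely phased heterozygous locus. `demo_out/genotypes.tsv` holds
the per-locus calls with per-allele unique support:

```
sample_id  locus  allele1     allele2     zygosity      support1  support2
S000       A      A*01:01:01              homozygous    941       0
S000       B      B*02:01:01  B*03:01:01  heterozygous  550       862
```

and `demo_out/counts.tsv` the normalized expression table, e.g. for S000 in
set 1 the two *HLA-B* alleles at 262,710 and 406,284 normalized reads — a
1.55-fold allelic imbalance at this locus, recovered from the simulated
weights. Per sample and set the `normalized_reads` column sums to
1,000,000. `demo_out/stats/` contains per-set locus summaries (five
numbers, hinge ratio, CV) and allele summaries (lowest/highest allele,
fold change, ANOVA p).

The same stages are available separately (`hlacapseq simulate`,
`genotype`, `quantify`, `stats`) and as library functions.

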