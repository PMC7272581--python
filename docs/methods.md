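# Methods

## Scope and model

The package models the computational half of a capture RNA-Seq HLA assay:
reads are taken as given (FASTQ), and everything downstream — allele
assignment, in-phase counting, normalization, DAE statistics — is
implemented here. Wet-lab steps (probe design and synthesis,
hybridization, library preparation, sequencing) are out of scope; capture
probes appear only as a data type (`ProbeSet`) and as a per-allele
capture-efficiency bias term in the simulator.

## Reference model

Allele names follow the colon-delimited HLA nomenclature
`locus*f1:f2[:f3[:f4]][suffix]` with expression suffixes N/L/S/Q/C/A.
Fields are stored as integers and rendered zero-padded to two digits, so
parsing and rendering round-trip. References carry an exon table in
0-based half-open coordinates; the annotation file is authoritative for
exon numbering (IMGT exon numbering conventions vary by locus, so nothing
is inferred from sequence). Ambiguous IUPAC bases are rejected at load:
the perfect-match rule is undefined for ambiguity codes. References
missing a window exon ("partial references") are retained for genotyping
support but excluded from quantification.

The mapping windows are fixed per locus: exons 2+3 (546 bp) for class I;
exon 2 for class II — 239 bp (*DRA*), 270 bp (*DRB1/3/4/5*, *DQB1*),
249 bp (*DQA1*), 246 bp (*DPA1*), 264 bp (*DPB1*). The window length is
also the "target size" used as the size-standardization denominator; it is
the quantity that makes loci with different window lengths comparable.

## Genotyping

Exact-substring matching is implemented as a k-mer seed table (first k=24
bases) with full-read verification; the contract is exact-substring
semantics only, and a brute-force full-scan oracle verifies equivalence in
the tests. Reads containing N never match. Reads hitting alleles of more
than one locus are excluded from genotype support entirely.

The pair-selection objective is explicit and deterministic: maximize the
number of explained reads, break ties by total unique support (reads
hitting exactly one member of the pair), then lexicographically; remaining
tied pairs are recorded in an ambiguity note. A single allele explaining
every locus read gives a homozygous call. At *DRB3/4/5* a single-allele
call is reported as *hemizygous*: read data cannot distinguish one copy
from two identical copies of a paralog, the single-haplotype configuration
is the common one, and both configurations are excluded from
quantification anyway. A heterozygous partner must reach
`min_unique_support` unique reads (default 10 — small enough for
desk-scale data, large enough that sequencing-error-derived alleles do not
reach it at default error rates); otherwise the call collapses to the
better-supported allele.

Mates of a pair are matched independently; a pair contributes genotype
support once per allele (support is deduplicated by pair id). For
quantification, mates are counted independently and this is deliberate —
the counts are used only in ratios within a sample, where the factor of
two cancels.

Novel-variant flagging aggregates reads that match no allele perfectly but
align to a called allele with exactly one substitution (anchored by exact
occurrence of a read half); a (position, base) pair supported by at least
`min_support` distinct reads becomes a candidate. Positions are reported
in concatenated-window coordinates, and variants outside the window are
ignored. Confirmation (e.g. Sanger) is out of scope.

## Phase classification and in-phase counting

A heterozygous pair is *completely phased* when its window sequences
differ in every window exon, so that reads from each exon are assignable;
differing in only some exons gives *partially phased* (the identical exon
would collect unassignable reads); identical window sequences behave as
*homozygous* even when the names differ at field 4. Only completely phased
heterozygous loci enter comparative datasets; homozygous, partially
phased and hemizygous configurations are excluded.

A read counts for allele X iff it perfectly matches X's
window-containing reference, overlaps the window by ≥1 base (the minimal
defensible overlap; no stricter threshold is defined), and does not
perfectly match the partner allele anywhere. Reads matching both alleles
are out of phase and are discarded rather than split — in-phase counting
means unambiguous assignment; a 50/50 split mode exists behind
`split_ambiguous` for sensitivity analysis and is off by default.

*DRB3/4/5* are treated as one compound paralog group: a sample whose two
haplotypes carry two distinguishable group alleles (e.g. DRB3 + DRB4) is
completely phased for the group and the two alleles are counted against
each other across paralogs; one group allele is hemizygous. Locus sets 1
and 4 require the group to be phased and otherwise exclude the sample from
that set entirely, mirroring how such cohorts shrink when the two-DRB
requirement is imposed.

## Normalization

Per sample and locus set: nᵢ = 10⁶ · (cᵢ/Lᵢ) / Σⱼ (cⱼ/Lⱼ). Normalization
is per sample, not pooled — samples are compared after scaling, so each
sample must carry its own unit. Consequences tested as invariants:
per-sample sums equal 10⁶ (relative tolerance 1e-9), multiplying all raw
counts by a constant leaves normalized values unchanged, and normalized
ratios equal size-standardized ratios exactly. A sample whose qualifying
counts are all zero cannot be normalized and is dropped with a QC record.

## DAE statistics

Quartiles use linear interpolation with the inclusive convention
(h = (n−1)p on the sorted values) — the convention of common spreadsheet
software, fixed explicitly because quartile conventions change hinge
ratios at small n. Ratios and percentages are rounded half-up to one
decimal. The ratio of hinges is undefined (reported missing) when Q₁ ≤ 0.
One-way ANOVA is computed from the sum-of-squares decomposition with the
p-value from the F distribution; the degenerate all-equal input returns
F = 0, p = 1 instead of a division error, and the two-group case satisfies
F = t² of the pooled-variance t test (validated to 1e-10). No
multiple-testing correction is applied by default, matching the way such
tables are usually reported; a Bonferroni factor is available behind a
flag. Group comparisons drop groups with fewer than `min_n = 3`
observations (allele-level summaries likewise require three samples per
allele) and support grouping by column, by callable, or by an
allele→class map — the latter is how a DPB1-allele→rs9277534-class
grouping is expressed without genotyping the SNP itself.

The per-allele summary table exposes both ANOVA modes — lowest-vs-highest
allele only ("extremes", the default) and all alleles at the locus —
since published tables are ambiguous about which is meant.

## Simulator

The generator emulates: per-sample diploid genotypes with at most one
*DRB3/4/5* paralog per haplotype (default per-haplotype probabilities
0.35/0.30/0.20 for DRB3/DRB4/DRB5 and 0.15 for none, chosen to make all
group configurations common at small n); locus-level mean expression
following the ordering seen in healthy PBMC cohorts (B > C > A; DRA and
DRB1 highest in class II, DQ lowest, DRB4/DRB5 above DRB3); log-normal
per-allele deviations with σ = 0.15 (class I) and 0.5 (class II), giving
class II the wider allelic spread; a per-allele log-normal
capture-efficiency bias (σ = 0.1 by default) constant across fragments,
modelling probe-affinity differences; fragments ~ Normal(250, 50) clipped
to [read length, transcript length], drawn from the window-plus-flank
transcript and constrained to overlap the window; 2×150 bp mates with
uniform per-base substitution errors (default 0.001). Truth tables record
the biological weight and the capture bias separately.

It does not emulate: indels (under perfect-match counting an indel-bearing
read behaves exactly like a mismatched read — dropped — so substitutions
suffice to exercise the filter), PCR/optical duplicates, quality-score
decay, position-dependent coverage, hybridization thermodynamics, or real
IMGT allele sequences. Passing recovery tests therefore demonstrate the
correctness of the assignment/counting/normalization logic under the
stated noise model, not robustness to real library artifacts or to the
much denser similarity structure of the full IMGT panel.

Determinism: all randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical FASTQ and
tables.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp: 50 samples × ~2,400 read pairs for genotype
recovery (≥50 pairs per allele in expectation, with uniform locus means
and noise off, the condition under which 100 % field-3 concordance is the
correct expectation); 100 seeded runs at 2,000 pairs for the 2:1
allelic-ratio band [1.8, 2.2]; 200 random panels × 1,000 reads for oracle
equivalence; 1,000 replicates for ANOVA calibration. The binomial bound on
balanced allelic counts is asserted at read-pair level, because mates of
one fragment are correlated and the pair is the independent sampling unit.

## Known limitations

- The pair-selection objective is a reconstruction: the original
  BLAT-based assignment software's selection rule is not published, so an
  explicit, auditable objective is defined instead.
- No gapped alignment; alleles differing from the panel by indels inside
  the window are invisible to both genotyping and counting.
- G-group/P-group ambiguity collapsing and EM-style rescue of ambiguous
  reads are deliberately not implemented.
- Real-cohort quantities (per-locus median levels, cohort p-values,
  PBMC-vs-cord-blood correlations) depend on raw reads that are not
  distributed; the published summary tables are shipped as inputs for the
  arithmetic operations only.
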