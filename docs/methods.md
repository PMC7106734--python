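# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `ppdscan`.

## Study design the package addresses

A recessive congenital trait segregating in a small, closely related
case/control cohort: two families totalling 17 sequenced individuals, 4
affected and 13 unaffected. At this sample size no single statistic is
trustworthy on its own; the analysis therefore combines four tracks —
haplotype-length contrast (XP-EHH), SNP differentiation (F_ST), INDEL
differentiation (F_ST), and allelic association — and requires replication
across tracks before a region is promoted, then applies a segregation filter
(recessive concordance) and a coding-effect filter (nonsynonymous change)
to nominate a causal variant.

## Hard filters

Per-clause evaluation of the GATK-style expressions, with the printed
operators kept exactly (the SNP rule mixes inclusive and exclusive bounds;
the INDEL rule is strict). A record carries the set of clause names it
fails; a clause whose annotation is absent is *skipped*, not failed,
matching the behaviour of the toolkit the expressions come from. The SNP
cluster rule flags every SNP lying in any 10 bp span holding ≥ 3 SNPs
(span counted inclusively: positions 100/105/109 cluster, 100/105/111 do
not). Clause thresholds and the cluster parameters are config keys.

## Weir–Cockerham F_ST

Two diploid populations (cases, controls), the 1984 variance-components
estimator with the observed-heterozygosity correction: per site, among-
population (a), among-individual (b) and within-individual (c) components
from group sizes n_i, allele frequencies p_i and heterozygote proportions
h_i; F_ST = a/(a+b+c), undefined when the denominator is 0 (pooled
monomorphic). Negative per-site estimates are kept — not clamped — so the
windowed ratio of sums matches the convention of the widely used windowed
implementations. Windows are anchored at position 1 of each chromosome
(determinism; no origin is otherwise implied), span 10 kb, slide 2 kb;
weighted window F_ST = Σa/Σ(a+b+c); significant windows require weighted
F_ST strictly > 0.6 and ≥ 10 usable variants, and overlapping passing
windows are merged into regions.

Two algebraically equivalent forms replace the textbook expressions for
numerical stability: s² = 2n₁n₂(p₁−p₂)²/N² and
p̄(1−p̄) − s²/2 = (n₁p₁q₁ + n₂p₂q₂)/N. These are exact rearrangements
(verified in the tests against a rational-arithmetic implementation of the
textbook formulas) and make fixed differences return exactly 1.0 instead of
1 − 1 ulp. Missing genotypes drop the individual at that site; sites with
more than two observed alleles are projected to reference vs the most
frequent alternate, other alleles treated as missing. INDELs are scored
identically as bi-allelic presence/absence.

## EHH, iHH and XP-EHH

EHH at marker x is the probability that two haplotypes drawn without
replacement are identical at every marker from the core out to x
(the core site itself does not partition: EHH(core) = 1). iHH integrates
EHH against physical distance (trapezoid; no genetic map is used) over both
flanks; the curve is truncated at the first marker where EHH < 0.05
(cutoff config-exposed). XP-EHH = ln(iHH_case) − ln(iHH_control), computed
as a log difference so swapping the groups negates scores exactly; scores
are normalized genome-wide to mean 0 / SD 1. Regions are called on the same
10 kb / 2 kb grid as F_ST: windows whose mean normalized score exceeds 2 are
merged.

**Bounded integration.** In a pedigree panel the haplotypes are copies of a
handful of founder haplotypes, so EHH plateaus at the identical-by-descent
sharing level — often above the 0.05 cutoff — and an unbounded integral
would run to the chromosome end and measure segment length rather than
haplotype contrast. Each flank therefore extends at most `max_extend_bp`
(default 100 kb, about twice the haplotype scale of interest here;
config-exposed, `inf` restores the unbounded scan). A cap-stop is part of
the statistic's definition; a chromosome-edge stop while EHH is still above
the cutoff flags the site `edge_truncated`, and such sites are excluded
from the normalization statistics (falling back to all scored sites if none
remain). Sites where either group's iHH is 0 are skipped. Unphased or
missing genotypes are excluded from the scan (the haplotype view refuses
them); the generator emits fully phased data, and real inputs are expected
to be phased upstream.

The genome-wide scan runs through a numba-compiled kernel when numba is
importable; a pure-Python implementation of the same recursion is kept and
the two are asserted equal in the tests. The test oracle for EHH itself is
an independent brute-force enumeration over haplotype pairs.

## Association, DAF, concordance

The allelic test is the Pearson chi-square (1 df) on the 2×2 allele-count
table with no continuity correction — the closed form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) — required to reproduce the published
worked-example statistics from their genotype counts; p is the upper tail of
χ²(1). Missing genotypes are dropped per site, so n varies across sites. No
multiple-testing correction is applied (none is applied in the source
analysis); sparse tables are flagged (`sparse_table` when any expected cell
< 5) rather than gated, since the study's own tables are sparse, and the
asymptotic caveat stands.

The derived allele defaults to the alternate allele
("reference-is-ancestral", the convention implied by 0 = reference / 1 =
altered coding); an `AA` INFO-tag policy is available. Recessive
concordance: every affected homozygous derived AND no unaffected homozygous
derived; a site with no observed derived allele is never concordant.
A dominant variant (every affected carries ≥ 1 copy; optionally no
unaffected carries any) is config-selectable.

## Evidence integration and ranking

Candidates are every gene in the model plus any evidence region overlapping
no gene (reported as `IGR:` candidates). Four flags per candidate: overlap
with an XP-EHH region, a merged passing SNP-F_ST region, a merged passing
INDEL-F_ST region, and containment of a genome-wide top-k association hit
(k = 10 by default). Ranking is deliberately a transparent count — flags
descending, then best association p ascending, then coordinates — rather
than a learned score: the underlying reasoning is qualitative replication
across tracks, and the output keeps full audit columns so single-track
signals are visible as "not replicated". A variant is highlighted as
putatively causal iff it is concordant under the chosen model AND annotated
CDS_nonsynonymous. Gene assignment uses interval overlap with a configurable
flank (default 0 bp). The report is a pure function of its inputs.

## Synthetic-data generator

The generator emulates the *post-calling* state of the study design — it is
the package's test bed, not a sequencing simulator.

* **Cohort.** Default two families: family 1 = 3 affected + 13 unaffected,
  family 2 = 1 affected; 17 samples. Founders (an unsampled carrier sire, a
  carrier dam for the affected litter, a non-carrier dam for the rest) head
  each family. The causal-site genotype composition is fixed by
  construction — affected homozygous derived; 4 heterozygous and 9
  homozygous-reference controls — matching the genotype table published for
  the study's exonic missense site, so downstream per-site statistics land
  in the regime the analysis actually faced. Transmission at the causal
  site is conditioned by relabelling the two parental haplotypes of a
  meiosis when needed (the crossover mosaic is exchangeable in the labels,
  so this conditioning preserves the recombination model). Penetrance
  (default 1) converts causal homozygotes to affected.
* **Variants.** 17,000 background SNPs + 3,000 INDELs on a 5 Mb chromosome
  (~20,000 background variants; INDEL:SNP ratio close to the genome-wide
  ratio reported for the study), positions uniform, frequencies
  Beta(0.5, 0.5).
* **Causal block.** A single 50 kb template haplotype centred on the causal
  site, identical in every carrier founder across families (a recent shared
  ancestral segment). Inside the block the background frequency law is
  rare-skewed (Beta(0.5, 4), reduced diversity as in a swept/IBD region) and
  the template carries its own derived alleles at rate 0.4 (a young
  haplotype with private variants). These two choices reproduce the
  high per-site differentiation observed at such loci; the implanted
  missense site itself gives F_ST ≈ 0.77 under the fixed genotype
  composition.
* **Gene model.** Five genes; the implanted gene is minus-strand with three
  exons and a 900 bp CDS arranged so the causal A>G falls on codon 85,
  second position, reading ATC→ACC (Ile→Thr) — exercising strand-aware
  codon reconstruction. Reference FASTA, GTF, PED and truth file are
  emitted alongside the phased VCF.
* **QC annotations.** Drawn from two mixture components per hard-filter
  clause: pass-like values that satisfy every clause strictly, and
  fail-like values violating exactly the targeted clause, at per-clause
  fractions set in config (defaults: 0.6% per SNP clause, 1% per INDEL
  clause). Zero noise therefore implies zero filter failures, and each
  clause's expected failure count is known by construction. The causal
  variant always passes QC and is kept clear of SNP clusters.
* **Recombination.** Haldane: Poisson crossover count (rate 10⁻⁸/bp ×
  chromosome length), uniform positions, no interference.
* **Determinism.** All randomness flows from one seed through fixed
  substreams; identical configs yield byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: coalescent LD structure outside the pedigree
(background sites are independent given their frequencies), genotyping or
phasing error beyond optional missingness, multi-allelic sites, sequencing
depth structure, and genome-scale feature density (five genes on one
chromosome). Parameter-recovery results therefore demonstrate the
pipeline's correctness and end-to-end sensitivity under a faithful but
simplified null, not field performance on arbitrary cohorts.

## Numerical and policy choices

* Coordinates 1-based inclusive everywhere (VCF/GTF convention); window
  arithmetic half-open internally; BED output 0-based half-open.
* Transcript choice for annotation: longest CDS. Feature precedence when a
  position hits several: CDS > UTR > intron > intergenic. CDS INDELs are
  classed `coding_indel` without protein coordinates.
* Degenerate sites: a site where either group has no usable genotype is
  skipped with a reason; pooled-monomorphic chi-square returns 0 with p = 1
  and a flag; iHH = 0 sites are dropped from the XP-EHH output.
* Tie-breaks in ranking are total (flags, p, chromosome, start), making the
  report byte-reproducible.
* Problem sizes in the shipped tests: the default 5 Mb / ~20k-variant
  configuration is used for end-to-end recovery (20 seeds); unit tests use
  0.4–0.6 Mb configurations. These sizes exercise every code path at full
  default density while keeping the suite quick.

## Known limitations

* XP-EHH normalization over one simulated chromosome is a genome-wide
  normalization in miniature; on real data it should be computed across all
  chromosomes (the scan already accepts per-chromosome panels).
* The INDEL window track rarely fires at the default simulated INDEL
  density (0.6/kb, ~6 per 10 kb window, below the ≥ 10-variant rule); it is
  exercised by unit tests and activates on denser data.
* The concordance filter assumes full penetrance and no phenocopies; with
  penetrance < 1 the causal variant itself can fail it, which is a property
  of the filter, not a bug.
* The allelic test's asymptotic p-values are anti-conservative on very
  sparse tables; the `sparse_table` flag marks them but the values are
  reported as computed.
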