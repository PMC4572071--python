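# Methods

## The problem

Every human genome carries a handful of variants predicted to abolish the
function of a protein-coding gene on both alleles — homozygous
loss-of-function (HLOF) variants, natural gene "knockouts".  Cataloguing
them in healthy cohorts maps the dispensable fraction of the gene
repertoire, but naive calling is dominated by false positives: sequencing
and alignment errors concentrate at exactly the rare, constrained sites
where true HLOFs live, and many called stop-gains or frameshifts do not in
fact destroy the protein (they sit at the end of the reading frame, in one
of several isoforms, or are neutralised by a second nearby indel).
`hlofpipe` implements the conservative discovery workflow for
multi-population exome cohorts: consequence annotation, a ten-filter
artifact cascade, autozygosity (run-of-homozygosity, ROH) enrichment
statistics, gene-set and tissue summaries, and a burden-versus-phenotype
model — together with a synthetic cohort generator that plants ground
truth for every filter, so the whole pipeline is testable end to end
without access to any real exomes.

## Candidate definition and annotation

Raw multi-allelic records are decomposed into biallelic records; for each
alternate allele a sample's genotype is the count of that allele in its
genotype call, which conserves per-sample allele dosage across the split.
Symbolic/breakend alleles are skipped; single-allele calls (e.g. male X)
are treated as homozygous and flagged.

A candidate HLOF is a biallelic variant that is (a) homozygous for the
alternate allele in at least one individual and (b) a stop-gain or
frameshift in at least one transcript.  Consequences are computed against
CDS models (spliced coding sequence plus genomic segment coordinates,
strand-aware):

* SNV — translate the affected codon; alternate codon a stop while the
  reference codon is not ⇒ stop-gain.
* Indel — count the coding bases inserted/removed; not a multiple of
  three ⇒ frameshift, otherwise in-frame (an in-frame indel is *never* a
  frameshift — validation of real candidate sets has repeatedly caught
  3n-bp deletions masquerading as frameshifts).
* Indels are left-aligned VCF-style; the first changed coding base (in
  transcript orientation) defines the affected codon.

The relative position of a variant in a transcript is
(0-based index of the first affected codon) / (protein length), in
[0, 1).  Splice-disrupting variants are out of scope by design.

## The filter cascade

Each filter is a pure predicate with an audit record; survivors are the
candidates passing *every* filter, so the result is order-independent and
the audit reports each filter "applied individually" alongside the
all-filters count.  Defaults (all configurable in `RunConfig`):

| filter | rule | default |
|---|---|---|
| relative_position | before the cutoff in **every** transcript in which the variant is coding | < 0.9 |
| mapability | no overlap with alignability score < 1.0 (either track) or blacklist | — |
| min_samples | genotype called in enough individuals | ≥ 200 |
| capture_intersection | inside both capture kits' padded targets | 50 bp pad |
| ancestral | allele not shared with primate outgroups (see below) | — |
| mnp_codon | stop-gains: no second called SNP in the same codon | — |
| frameshift_rescue | reading frame not restored by nearby frameshifts | < 10 aa |
| hwe | no excess of homozygotes in any population | P < 0.01, depth ≥ 5× |
| coverage | novel variants need one homozygote at high depth | ≥ 20× |
| near_fixed | not (nearly) fixed for the alternate allele | 0 hom-ref, ≤ 1 het |

Decisions made where the rules left room:

* **Relative position across isoforms.**  "First 90% of all transcripts"
  is read conservatively: the variant must fall before 0.9 in every
  transcript in which it is coding (a variant at 0.95 in any isoform
  fails).  The permissive any-isoform reading is a config switch.
* **Ancestral filter.**  Stop-gains fail when ≥ 1 primate (chimp,
  gorilla, orang-utan) carries the human alternate allele.  Frameshifts
  fail only when ≥ 2 primates align over the site *and* all aligned
  primates carry a non-reference indel whose position, length and type
  match the human one within a 5 bp flank comparison.  Sites absent from
  the primate table pass (no evidence), logged.
* **Frame restoration.**  Homozygous frameshifts are grouped per
  transcript and chained when consecutive variants are < 10 amino acids
  apart (distances in affected-codon indices on the linearised CDS).  A
  pair in one chain fails when its signed indel-length sum is ≡ 0 (mod 3);
  chains of ≥ 3 fail wholesale, since frame-restoring subsets are
  possible.  A per-carrier mode (only variants sharing a homozygous
  carrier can rescue each other) is provided; transcript-level chaining is
  the default.
* **"Nearly fixed"** is operationalised as zero hom-ref genotypes and at
  most one heterozygote across all populations combined.
* **min_samples** counts non-missing genotypes by default; counting
  individuals above the depth floor instead is a config switch.

### The exact excess-homozygote test

The Hardy–Weinberg filter needs an exact test: candidate HLOFs are rare,
and the chi-square approximation is worthless at a handful of alternate
alleles.  Conditional on sample size n and alternate-allele count
n_alt, the heterozygote count h follows the Levene–Haldane distribution

    P(h) = n! / (n_aa! · h! · n_bb!) · 2^h · n_alt! n_ref! / (2n)!

over counts of the same parity as n_alt.  The one-sided P-value is the
probability of the observed heterozygote count *or fewer* (fewer
heterozygotes = more homozygotes).  A monomorphic site returns P = 1.
The implementation enumerates the conditional distribution with
log-gamma arithmetic; tests verify it against brute-force enumeration of
every genotype configuration up to n = 12 and, independently, against
direct enumeration of allele placements over the 2n allele slots for
tiny n.  The filter applies the test per population over individuals with
depth ≥ 5×, failing a variant significant at P < 0.01 in *any*
population.

## ROH enrichment

Long (≥ 1.5 Mb) runs of homozygosity mark autozygous segments; rare
alleles inside them surface as homozygotes essentially only there.  The
pipeline consumes PLINK `.hom`-style interval files (overlaps merged on
load) and computes:

* per-carrier localisation of each homozygous call (inclusive interval
  bounds; carriers without ROHs simply count as outside);
* the per-population overall in-ROH frequency of HLOF observations;
* per-variant bias classes via one-sided binomial tails of k-in-ROH out
  of n carriers at the expected in-ROH frequency: upper tail < 0.1 ⇒
  inside-biased, lower tail < 0.1 ⇒ outside-biased, else unclassified.
  Carriers are pooled across populations by default (per-population
  classification is a config mode; expected frequencies are always
  computed per population where reported);
* a Wilcoxon rank-sum contrast of allele frequencies between the two bias
  classes (exact enumeration when group sizes allow and no ties; flagged
  untestable when either class has < 3 variants);
* Fisher's exact test on the 2×2 in/out-ROH × population table.

Allele frequencies use 2 × (individuals with depth ≥ 5) as denominator,
matching the HWE inclusion rule.  A singleton HLOF is a variant
homozygous in exactly one individual cohort-wide.

## Gene-set, tissue and yield summaries

Term enrichment for a target set of n genes against an N-gene background
with B term genes and b target∩term genes is (b/n)/(B/N), with the plain
hypergeometric upper tail P(X ≥ b) and Benjamini–Hochberg FDR across
terms.  (Threshold-optimising GO tools report a refined statistic; the
ratio is the comparable, testable object and is what the package
computes.)  Tissue summaries credit each gene's argmax tissue (ties split
equally), so proportions sum to one; the "expressed in tissue T" fraction
uses a configurable expression threshold, since atlas normalisations
differ.  Per-population yield is HLOFs observed / individuals sampled
(2 dp).  Private LOFs are variants carried (het or hom) in exactly one
population; private HLOFs are homozygous in exactly one population while
shared as heterozygotes with others.  Deleteriousness summaries report
the median C-score and its Spearman correlation (average ranks) with
carrier counts; paralogue-count comparisons use rank-sum tests per
identity cutoff with an optional gene-exclusion set (e.g. olfactory
receptors).

## Burden versus extreme phenotypes

Rare-variant per-variant association is hopeless at 1–2 carriers, so the
model relates each individual's HLOF burden (number of surviving variants
carried homozygous, optionally restricted by C-score > 25 or excluding
olfactory genes) to their number of extreme trait values — values at or
beyond the within-population 1%/99% empirical quantiles (quantiles
include the focal individual; ties at the threshold count as extreme) —
by OLS per population:

    n_extreme ~ burden + n_traits_measured

A rank-deficient design (constant burden, or no trait missingness making
n_traits constant) is flagged rather than estimated.

## The synthetic study generator

The generator emulates the structure of a five-population European exome
study: one large cosmopolitan cohort (844) and four isolates (193, 197,
98, 100), mean depths from 30× to 60× (per-sample per-site depth is
rounded Gamma around the population mean, giving the heterogeneity the
coverage filters need), ~1% genotype missingness, six synthetic 5 Mb
contigs carrying 150 multi-exon genes (2–4 CDS segments, 80–520 codons,
both strands, 1–2 isoforms; extra isoforms are 5'-truncations so relative
positions genuinely differ between transcripts).

ROHs are placed uniformly with shifted-exponential lengths ≥ 1.5 Mb.
Genome fractions default to 0.5% (cosmopolitan) and 1.5–3% (isolates) —
the regime of long-ROH burden in European cohorts — which reproduces
observed overall HLOF-in-ROH frequencies of roughly 3% in the
cosmopolitan sample and 6–14% in isolates.  Genotypes are drawn under
Hardy–Weinberg at the site's allele frequency, except inside a carrier's
ROH, where the genotype is drawn autozygous (homozygous for a single
allele drawn at the allele frequency); heterozygosity inside ROHs is
therefore exactly zero, by construction and by test.  Neutral sites use a
log-uniform (1/x-like) frequency spectrum on [0.002, 0.5]; planted true
HLOFs use [0.002, 0.35], so the survivor set spans rare autozygosity-driven
singletons through common variants with hundreds of carriers — the spread
that makes the ROH-bias contrast meaningful.

Each planted variant is constructed to fail exactly its intended filter
and pass all others.  Every planted LOF is guaranteed one homozygous
carrier; rare true HLOFs get their carrier made autozygous (an ROH added
over the site) with probability 0.6, so singletons are mostly but not
exclusively ROH-borne.  Variants that must pass the HWE filter are
rebalanced after forcing (hom-ref individuals outside ROHs converted to
heterozygotes until every population's excess-homozygote P clears 0.02)
— the same adjustment nature performs, since a variant segregating for
generations accumulates heterozygous carriers.  HWE_EXCESS artifacts
instead receive het→hom-alt miscalls at rate 0.8 in the largest
population.  The truth table maps every planted variant to its category
and intended filter and is the oracle for recovery tests.

Phenotypes are standard-normal traits (150 by default, 2% missing).  A
planted burden effect β adds, in expectation, β extra far-tail values
(|z| > 4) per HLOF carried, planted among an individual's *measured*
traits (an unmeasured trait can never be counted extreme).  Because
extreme-ness is defined by empirical quantiles, extremes are zero-sum
within a trait: planted outliers displace natural ones, leaving the
regression slope essentially unbiased but adding a small (~2%)
attenuation when a push overwrites a value that was already extreme.
Recovery simulations use an 800-trait panel (within the 82–867 range of
real cohort trait counts) to keep that competition small.

All randomness flows from the single config seed; a fixed seed reproduces
every output file byte for byte, and every run logs a config hash.

### What the generator does not emulate

No linkage disequilibrium, no read-level error model (miscalls are planted
directly), no reference sequence beyond the CDS needed for codon logic,
no population substructure within cohorts, and no relatedness beyond the
ROH mechanism.  Passing tests therefore demonstrate that the *logic* of
every filter and statistic is correct and calibrated under the stated
model — not that the thresholds are optimal for any particular real
dataset.

## Problem sizes and numerical choices

The default synthetic study (1432 individuals, ~130 planted variants,
2500 neutral sites) generates in a few seconds and runs through the full
cascade in about one second; the acceptance script's repeated-seed checks
(20 study replicates for the ROH allele-frequency sign, 50 phenotype
replicates for burden recovery) complete in under two minutes on one CPU.
Exact-test enumerations are checked exhaustively at small sizes (HWE
n ≤ 12, binomial n ≤ 8, hypergeometric N ≤ 25, Fisher cells ≤ 4).
Quantiles are numpy linear-interpolation empirical quantiles; the
rank-sum test switches to its exact distribution below 25 per group
without ties; BH q-values come from the standard step-up with enforced
monotonicity.  Degenerate inputs (monomorphic sites, empty survivor
sets, constant scores, rank-deficient designs, zero-margin tables) return
defined values or explicit flags rather than raising mid-pipeline.

## Known limitations

* The consequence classifier is minimal by scope: no splice, UTR or NMD
  logic, no full transcript-effect engine.
* ROH calling itself is out of scope; PLINK-style interval files are
  consumed as given.
* The ancestral filter trusts the supplied primate table's flank-match
  flags rather than re-aligning.
* Burden-model outlier counting includes the focal individual in the
  quantile estimate (negligible at cohort sizes, biased at tiny n).
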