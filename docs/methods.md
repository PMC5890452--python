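# Methods

This note documents the models, parameter choices and numerical
conventions behind hapforge, and what the synthetic cohorts used in the
test suite do and do not establish about real data.

## Depth storage and the one-byte codec

Allelic depths and mean base qualities are held per (site, taxon,
allele) over the fixed space A, C, G, T, I, D.  I and D stand for any
insertion or deletion relative to the reference, regardless of length or
sequence; the quality of an indel allele is the quality of the base
directly preceding it.  Bases enter the depth counts only with base
quality ≥ `baseq_min` (default 10) and mapping quality ≥ `mapq_min`
(default 30, imposed upstream when the pileup is generated).

Each stored count occupies one byte.  Values 0–182 are exact.  The 73
remaining byte states address a geometric grid gₖ = round(183·bᵏ),
k = 1..73, with b = (10000/183)^(1/73) ≈ 1.0563, spanning 183–10 000;
counts above 10 000 saturate.  Encoding maps a count to the *nearest*
representable value over the whole code range, which bounds the relative
round-trip error at half a grid step (≈ 2.9 %, verified exhaustively to
be ≤ 3.1 %) and makes decoding monotone.  In HDF5 the codes are packed
as one-byte slots (0–255); one file per taxon, one group per chromosome,
storing positions with non-zero coverage only.

## Genotype likelihood model

Calls maximize the multinomial likelihood of the 6-allele depth vector
over the 21 unordered genotypes, with uniform per-read error ε:

* hom aa: P(read = a) = 1 − ε, each other allele ε/5;
* het ab: P(read = a) = P(read = b) = (1 − ε)/2 + ε/10, others ε/5.

ε defaults to 0.01.  The prior over genotypes is uniform; ties break
toward the homozygote of the highest-depth allele, then lexicographic
pair order, so calls are deterministic.  Zero total depth is missing.
One consequence worth knowing: at low coverage a single error read can
flip a homozygote call to a heterozygote (at depth 8, one discordant
read already favours the het), while at depth ≳ 12 two discordant reads
are needed.  This drives the residual false-het rate visible in the
simulated cohorts.

Site discovery requires ≥ 10 taxa with coverage and at least one
non-reference called genotype; alternative alleles are ranked by summed
read depth and at most two are kept.  Genotypes carrying a pruned allele
become missing.

## Segregation test

For each allele pair at a site, the 2 × N table of per-taxon depths is
tested for non-randomness.  Columns with zero depth are dropped;
degenerate tables (an empty row) score P = 1.  Pearson chi-square
(df = columns − 1, no continuity correction) is used when its P ≥ 0.2;
below that gate, the exact P is estimated by Monte Carlo: B tables
(default 2000) are drawn with the observed margins (Patefield
algorithm, via `scipy.stats.random_table`), the statistic is the table's
log-probability under the fixed-margins multivariate hypergeometric, and
P = (1 + #{log P(sim) ≤ log P(obs)})/(B + 1), with ties compared at a
1e-9 log tolerance.  The +1/+1 correction keeps P > 0.  The chi-square
gate rests on the empirical observation (asserted in the test suite)
that chi-square is a de-facto lower bound on the exact P in the
insignificant regime.  Per-site RNG streams are derived from
(seed, crc32(chrom), pos), so results are independent of processing
order and parallel chunking.

An alternative allele is kept when its best table has P ≤ 0.01; the
site's PV annotation records the minimum P over all tables.

## IBD windows and the concordance filter

The anchor map is scanned in consecutive non-overlapping windows of 2000
anchor sites per chromosome (a trailing remainder merges into the
previous window).  Pairwise IBS distance uses allele sharing — 0 for
identical genotypes, 0.5 for het-vs-hom overlap, 1 for disjoint — and
requires ≥ 200 comparable sites; pairs at distance ≤ 0.02 are in IBD for
that window.  Candidate sites map to the window containing their
position (positions beyond the anchor span clamp to the chromosome's
first/last window).

At a candidate site, each allele accumulates match(a) (both genotypes of
an IBD pair carry a) and mismatch(a) (exactly one does); a heterozygote
carries both its alleles.  Confirmation requires match/mismatch ≥ 2 for
at least two alleles (infinite ratio when mismatch = 0 and match > 0).
If confirmation fails but at most one allele appears among the IBD
contrasts the site passes weakly with the `IBD1` flag — the variant was
never actually tested, the typical situation at low MAF.  Sites with no
informative contrast at all are treated the same way (no constraint was
violated).

## LD filter

The LD measure is the two-sided Fisher exact P (point-probability
method) of the 2 × 2 haplotype-count table, with heterozygotes collapsed
to minor homozygotes so each taxon contributes one haplotype.  A pair is
testable when the sites are ≥ 2500 bp apart (different chromosomes
always qualify), ≥ 40 taxa are nonmissing at both, and ≥ 2 of those
carry minor alleles at each site.  Up to 20 best hits are collected;
the site is rejected when the best P exceeds 1e-6, and flagged `LLD`
when some collected hit is local — same chromosome, within 1 Mb
(measured site-to-anchor), P < 10 × best P; the best hit itself may be
that local hit.  Untestable sites pass unflagged.  Ties among equal-P
hits are ordered by proximity to the candidate site (then chromosome
and position): when many anchors inside one IBD block are equally
informative, a local confirmation must not be crowded out of the top-20
list by equally good distant hits.  The per-anchor scan is vectorized
(a gammaln-based Fisher test over all anchors at once), which is what
makes genome-wide scans tractable at desk scale.

Note an intrinsic detection floor: with N taxa the smallest achievable
two-sided Fisher P at k minor carriers is ≈ 2/C(N, k), so at N = 40 a
variant needs ≥ 6 carriers before *any* anchor can push it below 1e-6.
Low-MAF sites therefore pass unassessed rather than confirmed, exactly
as intended.

## ">1, >2" depth filter

An alternative allele survives iff its read support is > 1 in at least
one taxon and > 2 summed over taxa.  With two alternative alleles each
is judged separately; the site fails when none survives.

## LD-KNN imputation

For a target site, candidate LD sites are all others on the same
chromosome within ±600 kb with heterozygosity < 3 % and > 50 % taxa
nonmissing; the 70 with highest r² are kept (r² = squared Pearson
correlation of the 0/0.5/1 genotype coding over taxa nonmissing at both
sites; fewer than 2 informative taxa, or zero variance, scores 0; ties
break by site order).  Neighbour distances are mean IBS mismatch over
common LD sites; a neighbour must be nonmissing at the target site, have
≤ 50 % missing LD genotypes, ≥ 10 common LD sites and distance ≤ 0.1;
the 30 nearest are kept (ties by taxon order).  Candidate genotypes are
exact allele pairs, weighted w_g = Σᵢ 1/(1 + 70 dᵢ); the winner is
imputed when w_best ≥ 10 × w_second (an absent runner-up counts as 0),
otherwise the imputation is inconclusive.  Only originally missing
entries change in the output; inconclusive ones at pre-imputation
MAF < 1 % become major-allele homozygotes.  The procedure is
deterministic — no randomness anywhere.

Every genotype, missing or not, is test-imputed to build the transition
matrix (rows: major hom / het / minor hom / indel-containing of the
original nonmissing genotypes; columns: the same classes plus
inconclusive).  Per-site `ImpHomoAccuracy` and `ImpMinorAccuracy` are
the fractions of homozygotes (resp. minor homozygotes) imputed back into
their class among those that could be imputed, following the transition
matrix's convention of excluding inconclusive outcomes.

## Annotations

`MAF` is the summed frequency of non-major alleles among called
genotypes.  `EF` = het_frequency/(presence_frequency × MAF) is reported
as missing when MAF or presence is 0.  `AQ` is the depth-weighted mean
of per-taxon mean base qualities.  The high-coverage subset behind `FH`
is determined once per cohort: taxa with strictly more than 50 %
nonmissing genotypes on a designated chromosome (a parameter, defaulting
to the first chromosome present — the subset's *size* is a property of
the data, not a constant of the tool).  `FH2` marks FH > 0.02, `DUP`
heterozygote frequency > 0.03 computed on unimputed genotypes, `NI5`
indels and SNPs within 5 bp of a putative indel.  No multiple-testing
correction is applied anywhere: the pipeline replicates fixed per-filter
thresholds by design.  The inbreeding coefficient
F = (O − E)/(N − E), E = Σₖ(1 − 2 pₖ qₖ), is undefined (missing) when
N = E.

## The synthetic cohorts

The simulator emulates the population structure the filters assume:
founder haplotypes, taxon genomes as founder mosaics with geometric
block lengths (planting IBD), Poisson read depth with uniform per-base
error, residual heterozygosity (default 1 %, within the 2–3 % expected
of inbred panels), and labelled artifact classes — error-only sites,
paralog-collapse sites (a taxon subset receives a 50/50 allele mixture),
and translocated markers whose genotype vector is copied from an
unlinked region (another chromosome when one exists, since a source a
few Mb away can still lie inside one founder block).  Two structural
options matter for interpretation:

* In clone mode (block length ≥ genome) taxa descend from the founders
  in balanced proportions, as in a designed panel.
* With `single_origin` the minor allele of each variant arises on
  exactly one founder haplotype (infinite-sites).  The default
  (independent Bernoulli draws per founder) produces multi-founder
  carrier patterns with no single mutational origin; such patterns have
  no LD partner anywhere, which is unrealistic for real variation and
  overly pessimistic for LD-based confirmation.

Test problem sizes were chosen to exercise each stage in its designed
regime at desk scale: IBD cohorts of 20–40 taxa from 3–6 founders
(so every taxon sits in IBD pairs and match counts dominate individual
heterozygous contrasts), an LD cohort of 40 taxa / 3 founders /
~5000 anchors at ×15 coverage (keeping minor-carrier counts above the
Fisher detection floor and het miscalls rare), and an imputation cohort
of 50 taxa from 2 founders with ~12 Mb blocks — a biparental
RIL-style panel, the canonical use case for LD-KNN imputation, where
neighbour lists stay large enough for the 10× dominance rule after 30 %
masking.

What passing these tests shows: the algorithms implement their rules
exactly (verified against enumeration and brute-force oracles) and
behave as designed on cohorts with planted truth.  What they do not
show: performance on real aligned reads — the simulator has no mapping
bias, no base-quality miscalibration, no indel-alignment ambiguity, no
population admixture, and its LD structure is cleaner than that of a
diverse panel.  Absolute sensitivity/specificity numbers from the suite
should not be quoted for real data.

## Numerical conventions

Coordinates are 1-based inclusive externally (VCF convention).  All
RNG-dependent steps take explicit seeds; per-site streams keyed by
coordinates make results independent of chunking and worker count, and
reruns byte-identical.  Monte-Carlo ties compare at 1e-9 in log space
(the ≤ convention for the simulated statistic).  Fisher point
probabilities compare with a 1e-7 relative tolerance against
floating-point ties, matching the R convention.  Degenerate inputs
resolve to the conservative side: empty tables P = 1, EF/FH missing
rather than 0, undefined distances excluded rather than guessed.
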