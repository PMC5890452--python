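# hapforge

Variant discovery and population-genetics quality control for panels of
(mostly) inbred lines — the problem faced by large crop haplotype-map
projects, where short reads from hundreds of diverse lines are aligned to
a single reference genome and most "variants" are artifacts of paralogous
misalignment rather than real polymorphism.

hapforge implements the full discovery-and-filtering pipeline as a tested
Python library with a thin CLI:

* **Depth extraction and storage** — per-taxon allelic read depths and
  mean base qualities over the 6-allele space {A, C, G, T, I, D}
  (insertions and deletions are collapsed onto the pseudo-alleles I and
  D).  Depths are parsed from single-sample pileup text and persisted in
  per-taxon HDF5 stores with a one-byte codec: integers 0–182 exactly,
  larger counts (to 10 000) on a geometric grid with ≤ 3.1 % relative
  error.
* **Genotype calling** — maximum-likelihood diploid calls over the 21
  unordered allele pairs under a multinomial read model with uniform
  error rate ε (default 1 %): P(read = a | hom aa) = 1 − ε,
  P(read ∈ {a,b} | het ab) = (1 − ε)/2 + ε/10, all other alleles ε/5.
* **Segregation-test (ST) filter** — in an inbred panel the minor and
  major allele depths of a *real* variant concentrate in different taxon
  subsets.  Each allele pair's 2 × N depth table is tested with a hybrid
  test: Pearson chi-square first, and a Monte-Carlo Fisher exact test
  (fixed-margin Patefield sampling) whenever chi-square P < 0.2.  An
  alternative allele survives at P ≤ 0.01.
* **IBD filter** — a trusted anchor-marker map defines, in windows of
  2000 anchor sites, taxon pairs at IBS distance ≤ 0.02 (≥ 200 comparable
  sites), which are declared identical by descent.  A candidate site
  passes when at least two alleles reach a per-allele match/mismatch
  ratio ≥ 2 over the IBD pairs, or weakly (flag `IBD1`) when the IBD
  contrasts expose at most one allele.
* **LD filter** — each candidate is tested against the anchor map with
  the two-sided Fisher exact P of the 2 × 2 haplotype table (hets count
  as minor homozygotes).  Sites whose best hit is weak (P > 1e-6) or
  only nonlocal (no same-chromosome hit within 1 Mb among the top 20 at
  P < 10 × best) are rejected; confirmed sites get the `LLD` flag.
* **">1, >2" depth filter** — minor-allele read support must exceed 1 in
  some taxon and 2 in total.
* **LD-KNN imputation** — per target site, up to 70 surrounding sites in
  best r² within ±600 kb define a local distance; up to 30 nearest
  neighbours (d ≤ 0.1) vote with weight w = Σ 1/(1 + 70 d), and the top
  genotype is imputed when it outweighs the runner-up 10-fold.
  Inconclusive imputations at sites with MAF < 1 % become major-allele
  homozygotes.  Self-imputation of the nonmissing genotypes yields the
  transition matrix and per-site `ImpHomoAccuracy`/`ImpMinorAccuracy`.
* **Annotation** — per-site `DP NZ AD AC AQ GN HT EF PV MAF MAF0 FH` and
  flags `FH2 IBD1 LLD NI5 DUP INHMP311`; per-taxon inbreeding
  coefficient F = (O − E)/(N − E) with E = Σₖ (1 − 2 pₖ qₖ).
* **Cohort simulator** — synthetic inbred panels with known truth:
  founder mosaics (IBD blocks), Poisson coverage with per-base error,
  residual heterozygosity, paralog-collapse sites, indels, error-only
  sites and translocated markers; every depth observation traceable to a
  ground-truth label.

Two routes mirror the two published styles of output: a **strict** route
(ST → IBD → LD filter) and a **permissive** route (ST → IBD → ">1, >2" →
imputation), with `INHMP311` marking permissive-route sites that also
survived the strict route.

## Worked example

Simulate a 20-taxon cohort (4 founders, one 4-Mb chromosome, ×8
coverage) and run both routes:

```bash
hapforge simulate --config sim.yaml --out cohort
hapforge run --in cohort --config pipe.yaml --out out
```

prints the per-stage attrition:

```
simulated 200 sites x 20 taxa -> cohort
discovery: 200 -> 159 (rejected 41)
st_filter: 159 -> 136 (rejected 23)
ibd_filter: 136 -> 124 (rejected 12)
ld_filter: 124 -> 80 (rejected 44)
minor_depth_filter: 124 -> 124 (rejected 0)
```

Of 200 simulated positions, 159 show tentative variation (≥10 covered
taxa and a non-reference call), the segregation test removes 23 sites
whose minor-allele depths look randomly scattered (sequencing error and
collapsed paralogs), the IBD filter removes 12 that contradict
identical-by-descent pairs, and the LD filter keeps the 80 sites it can
confirm in (or cannot test against) the local anchor map.  A record of
`out/strict.vcf`:

```
1  26016  .  T  G  .  PASS  DP=167;NZ=20;AD=105,62;AC=16;AQ=35,35;GN=12,0,8;HT=0;EF=0;PV=0.00049975;MAF=0.4;FH=0;LLD  GT:AD  0/0:10,0  0/0:3,0  1/1:0,10 ...
```

a clean inbred variant: 20 called taxa, 12 reference and 8 alternative
homozygotes, no heterozygotes, segregation P ≈ 5e-4, confirmed in local
LD (`LLD`).  The same directory's `permissive.vcf` carries the imputed
genotypes with `MAF0`, `ImpHomoAccuracy`/`ImpMinorAccuracy` and `DUP`
annotations, and `report.json` the attrition table above.

Each stage is also exposed separately (`hapforge extract | call |
stfilter | ibdfilter | ldfilter | depthfilter | impute | annotate`),
exchanging plain-text VCF so a run can be resumed or a single stage
re-examined.

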