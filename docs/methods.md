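# Methods

## Overview

`kinseq` implements a closed loop for assessing kinship inference from
transcriptome-derived genotypes: a generative model of pedigrees and
RNA-seq-like allele counts with exact identity-by-descent (IBD) ground
truth, and the analysis stack (genotype calling, site filtering,
moment-method IBD estimation, relationship classification) whose recovery
of that truth is what the test suite measures.

## Simulation model

**Variant panel.** Sites are biallelic autosomal SNPs grouped into genes
(default 2,500 genes × 4 SNPs over 22 × 100 Mb chromosomes). Minor-allele
frequencies are drawn from a configurable law, default U(0.05, 0.5); the
alt allele is the minor allele. A configurable fraction of genes/sites is
flagged "imprinted"/"repeat" so the exclusion filters operate on
non-trivial input. Panels of 2,000–10,000 sites keep runs at desk scale
while leaving, after filtering, per-pair SNP counts in the low thousands
— the same order as real transcriptome genotyping yields.

**Founders and gene drop.** Founder haplotypes are independent draws per
site with P(alt) = MAF — linkage equilibrium, the cleanest null for a
moment estimator that assumes independent sites. (An LD-carrying founder
model can be emulated by copying haplotype blocks between founders, but is
deliberately not the default; IBD expectations are unchanged either way.)
Non-founders receive one recombinant gamete per parent: a uniformly chosen
starting haplotype, then crossovers as a homogeneous Poisson process at
`recombination_rate` cM/Mb (default 1.0, i.e. Poisson mean
L_Mb/100 per meiosis per chromosome), no interference. The phrase
"1 cM per Mb" is treated strictly as a recombination rate during
transmission. Origin labels (founder × haplotype) travel with every
allele, so for any pair the realized Z0/Z1/Z2 is computable exactly; the
per-site IBD state is the maximum bipartite matching between the two
origin-label pairs, which stays well defined for inbred pedigrees.

**Pedigree presets.** Four family structures span the relationship
degrees of interest: `type1` (16 members: two founder couples, a parental
couple, ten children — first and second degree plus unrelated), `type2`
(16 members adding avuncular and half-sib second-degree relationships,
no cousins), `type3` (16 members with two five-child sibships of first
cousins: 25 third-degree pairs), `type4` (12 members over four
generations: great-grandparental and first-cousin third-degree pairs plus
a fourth-degree cousin-once-removed pair). `trio` and `pair_unrelated`
mirror minimal datasets. Expected relationships come from the kinship
recursion φ(i,j) = ½(φ(father_i, j) + φ(mother_i, j)) with founder base
cases; degree = round(−log₂ 2φ), with the parent-link check separating
parent-offspring from full siblings. Degrees beyond the third are mapped
to "unrelated" because neither the estimator nor the classifier resolves
them.

**Allele counts.** Read-level simulation is replaced by site-level count
simulation, which preserves exactly the statistics genotyping sees:

* depth at a site ~ Poisson(μ), with μ = total_reads × capture_per_site ×
  (gene weight / mean site weight). `capture_per_site` (default 7.5 × 10⁻⁷)
  is the package's scale constant: a 40M-read library then averages ~30×
  at a site of average expression.
* gene expression weights are log-normal (σ = 1.5) with a 10% silent-gene
  tail, emulating the skewed RPKM distribution of a lymphoblastoid
  transcriptome; zero-weight genes get zero depth.
* at heterozygous sites, alt reads ~ Binomial(depth, θ) with θ drawn once
  per gene per individual from Beta(κ/2, κ/2), κ = `ase_concentration`
  (default 20, giving an allelic-balance SD of ≈ 0.11). A
  `monoallelic_fraction` (default 0.02) of genes per individual instead
  draws θ from Beta(1, 99), randomly mirrored — the "one allele masked"
  regime in which a heterozygote is confidently miscalled homozygous.
  ASE acts at the gene level, hence per-gene not per-site draws.
* at homozygous sites the absent allele appears with per-read probability
  ε (default 0.01).
* males receive Poisson(0.002 × total_reads) Y-mapped reads, females
  Poisson(10⁻⁵ × total_reads) as mismapping background; sex inference
  thresholds the Y fraction at 10⁻³ (male) and 10⁻⁴ (female), in between
  is "unknown".

Depth titration is binomial thinning of every count cell with the kept
fraction, the count-level equivalent of subsampling reads; thinning
composes (a then b ≡ a·b), which the tests verify.

## Genotype calling

Likelihoods are binomial in the alt count: per-read alt probability ε
under hom-ref, 0.5 under het, 1 − ε under hom-alt. The caller takes the
maximum-posterior genotype under a uniform prior (a Hardy–Weinberg prior
from allele frequencies is available but off by default, keeping GQ
interpretable as a likelihood ratio). GQ = round(−10 log₁₀ P(call wrong)),
capped at 99, so GQ 20 is exactly a 1% error probability. Calls with
DP < 10 or GQ < 20 become missing (both thresholds inclusive,
configurable). Deliberately, allelic imbalance is *not* modelled in the
caller — ASE is a nuisance the downstream filters must absorb, which is
precisely the failure mode under study. With ε perturbing the het model,
the alt-read probability stays 0.5 by symmetry, so the simpler het model
is exact, not an approximation.

## IBD estimation

For a pair, over the L pairwise-complete sites, the observed IBS tallies
(N0, N1, N2) are matched to expectations conditional on IBD state. With
alt frequency a and b = 1 − a:

| | IBS 0 | IBS 1 | IBS 2 |
|---|---|---|---|
| IBD 0 | 2a²b² | 4a³b + 4ab³ | a⁴ + b⁴ + 4a²b² |
| IBD 1 | 0 | 2ab | a² + b² |
| IBD 2 | 0 | 0 | 1 |

Summing each entry over sites gives E[s|k]; the moment equations are
solved sequentially (Z0 = N0/E[0|0]; Z1 = (N1 − Z0·E[1|0])/E[1|1];
Z2 = (N2 − Z0·E[2|0] − Z1·E[2|1])/L), then each Z is clamped to [0, 1]
and the triple renormalized. This simple bounding rule — no projection
away from the "impossible" region of the simplex — is intentional:
bounded-but-unprojected estimates occur in practice and are exactly what
the classifier must cope with. PI_HAT = Z2 + Z1/2.

Numerical notes: estimation fails loudly (flagged row, not an abort, in
matrix mode) when a pair shares no non-missing sites or when all shared
frequencies are degenerate (E[0|0] = 0). No small-sample
allele-frequency corrections are applied: with panel-truth frequencies
(the default source) they are unnecessary, and reference implementations
apply version-specific corrections that would blur what is being tested.
Sample-estimated frequencies (from non-missing calls across all samples)
are available as an option. Sites are treated as independent — consistent
with the linkage-equilibrium founder model; with real, LD-carrying data an
LD-pruning step before estimation is the user's responsibility.

## Classification and diagnostics

Pairs with PI_HAT below the relatedness cutoff t (default 0.2; 0.375 as
the strict variant for densely related pedigrees) are unrelated. The rest
take the nearest centroid by Euclidean distance in (Z0, Z1, Z2):
duplicate (0,0,1), parent-offspring (0,1,0), full sibling (¼,½,¼),
second degree (½,½,0), third degree (¾,¼,0), unrelated (1,0,0). The
unrelated corner participates as a centroid so that classification is
total even at t = 0; ties break toward the lower degree. Distances are
measured on the simplex, equivalent up to scale to distances in the
ternary plane.

Ternary coordinates use the standard barycentric embedding with corners
Z0 → (0,0), Z1 → (1,0), Z2 → (½, √3⁄2); the map is affine and invertible
on the simplex. Class separability is decided by convex-hull intersection
in that plane, with single points and collinear clouds handled as
degenerate hulls. Pedigree consistency cross-tabulates called against
pedigree-expected classes and reports per-class sensitivity. Full
pedigree-topology reconstruction is out of scope; classification plus
consistency checking against a supplied pedigree covers the pairwise
separability questions that are testable at desk scale.

## Pipeline and reproducibility

`run_pipeline` executes panel → pedigree → gene drop → expression →
counts → calling → filtering → estimation → classification → reporting
under one master seed, with named `SeedSequence` substreams per stage;
identical configs give byte-identical outputs. Stage counts are logged
and must be non-increasing along the filter cascade. The depth titration
reuses one simulated dataset and re-analyses thinned copies; the
extra-unrelated experiment appends founder-like individuals drawn from
the same panel frequencies before count simulation.

Default problem sizes (10,000-site panel, 16-member pedigrees, 40M-read
libraries) run in seconds; the test suite's heavier checks (200 replicate
grandparent-grandchild chains, 50 replicate pairs per relationship class
at 5,000 sites) were sized to keep Monte-Carlo standard errors well below
the tolerances they assert.

## What the simulation does and does not show

The generator reproduces the statistical structure that matters for
genotyping and IBD estimation — expression-skewed depth, gene-level
allelic imbalance, per-read error, Mendelian transmission with
recombination — but not: mapping artefacts (multi-mapping, reference
bias), splicing structure, PCR duplicates, indels/multi-allelic sites,
population structure or LD among founders, or sex-chromosome
transmission (chrY appears only as a read-count tally). Passing tests
therefore demonstrate the soundness of the estimator and classifier under
a faithful noise model, not end-to-end performance on any particular real
dataset; per-pair usable-SNP counts here (≈ 1,600 at full depth) map the
read-depth axis onto real data only approximately.

## Known limitations

* Second-degree estimates sit on the Z0–Z1 axis between the second- and
  third-degree centroids; with a few hundred SNPs their scatter crosses
  the midpoint and sensitivity drops — an intrinsic limit of
  moment-based classification, visible in the titration.
* The classifier does not disambiguate half-sib / avuncular /
  grandparental (all "second-degree"), and fourth-degree pairs are
  indistinguishable from unrelated.
* Inbred pedigrees: kinship coefficients are computed exactly, but the
  degree/class mapping assumes no inbreeding and is flagged approximate.
* The convex-hull overlap test is a conservative separability criterion:
  a single outlying pair merges two otherwise distinct classes.
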