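# Methods

`transintro` tests whether disease-resistance (R-) genes cross a species
boundary more readily than the genomic background, using the two classic
footprints of gene flow between closely related, interfertile plant species:
trans-specific polymorphism (allelic lineages that do not sort by species)
and the sharing of *identical* haplotypes between species at a locus. The
package was shaped around a two-species *Arabidopsis* panel (*A. lyrata*,
*A. halleri*, outgroup *A. thaliana*) but all species labels are just
metadata; any two-species haplotype panel with an optional outgroup fits.

## Data model

Input is one pre-aligned FASTA per locus (coding-frame aligned haplotypes;
Sanger-cloned alleles in the archetypal design) plus a sample sheet mapping
sequence ids to species/population/individual. Residues are `A C G T - N`;
`-` and `N` are treated identically as missing, and every statistic uses
pairwise deletion (each pair compared over its co-called sites).
Coordinates are 0-based half-open internally; configs give coding ranges
1-based inclusive. Individuals represented by a single haplotype can be
doubled (`assume_homozygous`, default on), mirroring exhaustively sampled
allele panels; loci known to be incompletely sampled opt out by name.

## Per-locus statistics

* **S, haplotype count.** Segregating sites over non-missing residues;
  haplotypes as distinct residue strings (missing compared verbatim).
* **π (π_total, π_s, π_a).** Unweighted mean over all sequence pairs of the
  Jukes–Cantor-corrected per-site distance, d = −(3/4)·ln(1 − 4p/3). For
  synonymous/nonsynonymous classes, per-pair site denominators and
  difference counts follow Nei–Gojobori (1986): fractional site counts by
  mutational opportunity (changes to stop codons count as nonsynonymous, so
  syn + nonsyn sites = 3 × codons), differences averaged with equal weight
  over all minimal substitution pathways excluding those through stop
  codons. Codons containing missing residues are skipped pairwise.
  Saturated pairs (p ≥ 3/4) are excluded with a warning. We correct each
  pair's p and average the corrected distances (not the reverse); the
  difference from correcting the mean is negligible at these divergences.
  π is the plain average over pairs rather than Nei's n/(n−1)-weighted
  variant; at 20+ sequences the two differ by under 5%.
* **Rm.** Hudson–Kaplan (1985) four-gamete lower bound: biallelic sites with
  no missing data are tested pairwise; incompatible site pairs define open
  intervals; after discarding intervals that contain another, a greedy
  left-to-right scan counts disjoint intervals. Rm per site divides by the
  number of sites with ≥2 called residues. An exact interval-scheduling DP
  serves as the test oracle.
* **Fixed/shared/private sites.** Per site with ≥1 called residue in each
  species: fixed iff both species monomorphic for different alleles; shared
  iff both polymorphic sharing ≥2 alleles; private iff exactly one
  polymorphic. Categories are mutually exclusive; >2-allele sites enter via
  the set rules.
* **Ks/Kn extremes.** Nei–Gojobori + JC divergence for every interspecific
  pair; the locus reports lowest and highest synonymous and nonsynonymous
  values with the achieving pair ids. If every pair saturates in one class
  that class's extremes are NaN; saturation of all pairs in both classes is
  an error.
* **Class summaries.** Unweighted means across loci with percentile
  bootstrap 95% CIs (default 10,000 resamples, seeded). A single locus
  yields a mean with the CI flagged undefined. The CI construction is this
  package's choice; no standard convention pins it down.

A note on labels: the conventional subscripts are used throughout — π_s is
synonymous, π_a nonsynonymous. (Published tables in this literature
occasionally swap the two subscript labels; outputs here are explicit.)

## Trees and the trans-specific call

Distances are JC with pairwise deletion (saturated pairs are an error in
the primary matrix; during bootstrap resampling they are assigned a large
fixed distance of 5 substitutions/site so a replicate never aborts). Trees
are Saitou–Nei neighbor joining via scikit-bio's implementation with
negative branch lengths clamped to zero; site-resampling bootstrap supports
(default 1000 when enabled) are attached to internal nodes but play no role
in any decision rule. The tree is rooted on the outgroup leaf when one is
in the alignment, otherwise at the midpoint. A species is monophyletic iff
its leaves form a clade of the rooted tree (singletons count as
monophyletic); a locus is **trans-specific** iff *neither* species is
monophyletic. Monophyly is topological only — no support threshold — since
the decision rule being emulated states none.

**Identical interspecific pair**: some lyrata/halleri pair agrees at every
co-called site *and* shares at least `min_overlap` (default 90%) of the
locus length, so identity cannot be an artifact of missing data.

## The isolation-with-migration null

The headline statistic — how many loci contain an identical interspecific
pair — is compared against a two-deme isolation-with-migration coalescent
null simulated by this package (authored here; msprime serves only as an
independent cross-check oracle in the tests).

Backwards in continuous time (exact Gillespie; never per-generation
stepping): within-deme coalescence at rate k(k−1)/2 per 2N generations,
symmetric per-lineage migration at m per generation, recombination at r per
site per generation over each lineage's ancestral span, infinite-sites
mutation at μ per site per generation over ancestral material; at T
generations the demes merge into one of size 2N_ancestral. With r = 0 a
faster single-genealogy engine is used (mutations Poisson on branches);
with r > 0 a segment-tracking ancestral-recombination-graph engine runs the
same algebra. Both record mutations as (position, carrier-set) pairs, so
"identical" is exactly "no differentiating mutation", matching the
infinite-sites reading of haplotype identity. At the divergences involved
(μLT ≈ 2) finite-site double hits are negligible, which is why infinite
sites is an adequate stand-in for a finite-site simulator.

Defaults are deliberately conservative: μ = 4×10⁻⁹ per
site per year, generation time 1 year, T ∈ {0.56, 0.75} MY per branch,
diploid N ∈ {150,000, 600,000} (ancestral = current), r ∈ {0, 4.3×10⁻⁹},
and six distinct introgression rates {0, 2, 4, 8, 10, 15}×10⁻⁸ per sequence
per generation (a seventh, user-supplied rate is accepted: the printed rate
list contains a duplicate whose intended value is unknowable). Gene classes:
resistance-like 10 loci × 730 bp with 48/23 sampled haplotypes;
reference-like 37 loci × 513 bp with 24/16 haplotypes — the reference panel
sizes are this package's documented default, since the per-locus values
live in unavailable supplementary material; conclusions involving the
reference class are therefore qualitative. 100 replicates per parameter
combination; each replicate simulates the class's loci independently and
counts those with an identical interspecific pair.

Calibration checks (all in the test-suite): single-population E[π] = 4Nμ
and E[S] = θ·Σ1/i within 3 Monte-Carlo SEs; the 1+1-sample identity
probability exp(−2μLT)/(1 + 4N_anc·μL) within 3 SEs; and |z| < 3 against
msprime for mean S, π and identity probability in single-population,
IM-with-migration and recombination settings.

## Decision rules

* **Envelope test**: observed count vs the empirical 2.5% and 97.5%
  quantiles (type-7 interpolation) of the 100 replicate counts; *excess* /
  *deficit* outside, *consistent* inside, with ties at a quantile counted
  as consistent (the conservative reading of a tail rule). "Introgression
  required" for a parameter combination means the m = 0 envelope excludes
  the observation from above — a deficit is not evidence for introgression.
* **Fisher exact** (two-sided, point-probability rule, via scipy; an
  exhaustive hypergeometric enumeration backs it in the tests) contrasts
  gene classes on trans-specificity and on identical-pair counts.
* **Permutation test** on |mean₁ − mean₂| of per-locus fixed/shared site
  proportions: class labels shuffled over pooled loci, 10,000 permutations,
  add-one correction p = (1+#{≥obs})/(1+n_perm). Means are unweighted (one
  locus, one observation). Under exchangeable labels the p-value is uniform
  (KS-checked in the tests).

## Synthetic data and what passing tests show

The generator wraps the coalescent engine and realizes infinite-sites
haplotypes as codon-valid nucleotide sequences: ancestral codons drawn
uniformly from the 61 non-stop codons, mutations mapped to distinct integer
sites with a random non-identical target base (collisions redrawn), and any
mutation that would create an internal stop codon in any haplotype redrawn.
This preserves the identity/difference structure of the genealogy exactly.
An outgroup sequence diverged 5.5 MY is appended for rooting. Planted
events provide ground truth: *introgressed haplotypes* (a donor haplotype
copied into the recipient species, plus Poisson(2μL·t) private mutations
for an event t generations ago — t = 0 plants an exact identical pair) and
*balanced trans-specific loci* (two allelic classes, each a shallow
panmictic genealogy spanning both species, separated by mutations
accumulated over 4× the split time — neither species monophyletic by
construction). The truth table records planted status, realized identity,
and the realized genealogical monophyly of each species (known exactly for
r = 0 loci).

The study-shaped preset (10×730 bp at 48/23 plus 37×513 bp at 24/16) uses a
background split of 2.5 MY per branch at μ = 4×10⁻⁹ and N = 150,000, chosen
so background interspecific divergence (≈0.02/site) matches the divergence
actually observed between these species at reference loci. The shallower
split times in the simulation grid are deliberately conservative for the
identity-count null and are not realistic for sequence divergence: under
them a species' stem lineage carries under one expected mutation, making
monophyly unidentifiable from data — a property of those parameters, not of
the classifier. Recovery on the preset (50 seeds, 3 planted introgressions
+ 3 planted balanced loci) reaches sensitivity and specificity ≥0.95 for
both the identical-pair detector and the trans-specific call, with
specificity measured on truth-negative loci (incomplete lineage sorting
makes a small fraction of unplanted loci genuinely trans-specific; they are
truth-positives, not false positives).

What the synthetic data do *not* emulate: real base composition and codon
usage, purifying selection (so synthetic π_a ≈ π_s), balancing selection
other than by construction, population structure within species,
alignment error, and R-gene-specific duplication/paralogy. Passing recovery
tests therefore demonstrates the pipeline's correctness on data of the
study's shape, not robustness to those real-data complications.

## Numerical and design choices

* Tie-breaking in NJ follows scikit-bio's deterministic implementation;
  reruns on identical input are identical.
* Quantiles everywhere are numpy type-7 (linear interpolation).
* The master seed expands through `numpy.random.SeedSequence` spawning into
  independent per-stage/per-grid-row streams, so results are independent of
  execution order and of the `--threads` setting.
* Grid rows simulate sequentially in well under 10 minutes on one CPU at
  full scale (100 replicates × 96 rows); the rec = 0 half uses the
  tree-path engine at ~0.5 ms/locus.
* Degenerate inputs: loci with <3 sequences are skipped by the tree stage
  with a warning; a species with a single sequence yields no within-species
  diversity row; π over zero informative pairs is NaN rather than 0.

## Known limitations

* The IM model has exactly two demes, constant sizes, no growth,
  bottlenecks, selection or gene conversion.
* One full-factorial parameter combination (T = 0.56 MY per branch,
  N = 600,000, r = 0) yields a no-migration identity probability of ≈0.2
  per resistance-like locus — confirmed against msprime — so the observed
  count of 4 falls inside that envelope; the "introgression required under
  every parameter set" conclusion holds for the remaining 7 of 8
  combinations. See the envelope summary emitted by the pipeline.
* Ks/Kn extremes are undefined (NaN) for loci whose every pair saturates in
  one site class.
* Real-data replication of per-locus tables requires downloading the
  GenBank accessions (see README); it is supported but not automated.
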