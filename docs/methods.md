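# Methods

`beanchip` re-creates, as a tested library, the computational chain of an
Infinium SNP-array project in a selfing crop: filtering discovered SNPs to
assayable candidates, choosing a maximally informative variety panel,
building an F2 linkage map, anchoring and orienting draft-assembly
scaffolds with that map, and thinning validated markers to a core set.
This note documents the models, the defaults and why, and what the
synthetic world does and does not establish.

## The synthetic world

The simulators provide ground truth for every downstream stage.  The
defaults are a deliberately scaled-down bean-like genome, chosen so the
full chain runs in minutes on one CPU:

| parameter | default | rationale |
|---|---|---|
| chromosomes | 11 | the karyotype of the target crop |
| scaffolds per chromosome | 27 (lognormal lengths, median ~15 kb) | ~300 scaffolds total; same order-of-magnitude shape (many small, few large) as a real draft |
| inter-scaffold gap | 100 bp | conventional placeholder |
| SNP density | 0.003 per bp | ~3 SNPs/kb, the genome-wide density seen in diverse-panel resequencing |
| market classes / varieties | 9 classes x 2 | a ~18-variety discovery panel spanning the major classes |
| class divergence | 0.3 | fraction of SNPs near-fixed within classes; produces the within-class vs between-class polymorphism contrast the chip-design objective needs |
| genetic length | 94.7 cM per chromosome | the per-group mean of an 11-group, ~1042-cM consensus map |
| F2 plants | 267 | a realistic large mapping population |
| missing rate / error rate | 0.02 / 0.002 | arbitrary but realistic array-data defaults; configurable |

Meiosis is a **no-interference (Poisson) crossover process**: per F1
gamete and chromosome, the crossover count is Poisson(length in Morgans)
and positions are uniform in cM; an F2 genotype is the sum of two
independent gametes.  Consequently the *true* map function of the
simulator is Haldane's; recovery tests therefore always compare estimated
recombination fractions to the Haldane-transformed true spacing, never
estimated cM to true cM.  Kosambi distances (the package's reporting map
function, chosen because the real project reported Kosambi cM) are
slightly compressed relative to this simulated truth — a documented
mismatch, not a bug.

Parents are fully inbred; genotyping error is a symmetric swap among
{AA, AB, BB}; missing calls are independent Bernoulli.  The generator does
**not** emulate read-level sequencing artifacts, segregation distortion,
paralog collapse, or crossover interference, so a green truth-recovery
test establishes correctness of the estimators under a clean Mendelian
model — not robustness to those real-data pathologies.

A known visible consequence of the error model: with ~3000 markers at
sub-cM spacing, independent call errors inflate adjacent recombination
estimates, and the summed map length comes out well above the simulated
1042 cM (the multipoint/regression-mapping cleanup performed by dedicated
mapping software, which we deliberately do not implement, is what keeps
real maps short).  Recovery metrics are therefore
order/grouping/orientation-based, not length-based.

## Filtering (Infinium candidate cascade)

Order: proximity -> allele type -> flank N, then genome-wide arm
uniqueness, then an optional design-score hook.

* **Proximity**: a SNP with another variant within 25 nt (|Δpos| <= 25 on
  the same scaffold) is removed *symmetrically* — either SNP's 25-nt probe
  arm would cover the other variant, so both are unassayable.  A
  `keep_first` mode retains the leftmost of each run for users who prefer
  density over safety.
* **Allele type**: A/T and G/C SNPs cannot be distinguished by the
  single-color Infinium readout and are removed (order-insensitive).
* **Flank N**: any N in either 60-nt flank removes the SNP; flanks shorter
  than 60 nt (scaffold edge) are treated as containing N and logged with a
  `short_flank` reason.
* **Uniqueness**: both proximal 25-mers (the probe arms) must occur
  exactly once in the genome counting both strands, with a k-mer and its
  reverse complement identified.  Requiring *both* arms is the
  conservative reading; it is implemented with a sorted 2-bit-encoded
  k-mer index and cross-checked in tests against a quadratic `str.find`
  scan.  Uniqueness sits after the three-count cascade and is separately
  switchable, since published cascade counts conventionally list only the
  first three stages.
* **Design score**: vendor assay-design scores are proprietary; the stage
  is a pluggable hook (default pass-through) plus an illustrative
  GC/homopolymer surrogate that is *not* a reimplementation of any vendor
  tool.

## Panel selection (max-coverage genotype subsets)

A SNP is *detected* by a genotype subset iff the subset contains at least
two non-missing calls and both alleles are observed (a heterozygote
carries both; a lone het is still a single call and detects nothing).
This resolves an ambiguity between "calls differ" and "polymorphic within
the subset" in favor of allele content, which is what an array screens
for.

The objective (detected SNPs by a per-class quota of genotypes) is *not*
submodular — every singleton has zero gain — so the textbook greedy
guarantee does not apply and a single myopic pass would start from an
arbitrary genotype.  The `greedy` method is therefore a deterministic
multi-start greedy: one marginal-gain completion per admissible first
genotype, each polished by within-class single swaps, best coverage wins,
ties to the lexicographically smallest set.  On random 12-genotype x
200-SNP instances with k=4 this matches the exhaustive optimum on 99/100
seeds and always exceeded (1-1/e) of it; both facts are empirical
observations on the tested instance class, not theorems.  The phylogeny
"well-distributed across clusters" side-constraint of real projects is
not inferred; callers can express it through per-class quotas.

## Linkage mapping

* **QC**: markers with missing fraction > 0.10 or a 1:2:1 chi-square
  (2 df, no continuity correction) p < 0.01 are dropped, not
  down-weighted.
* **Two-point estimation**: the coupling-phase F2 codominant likelihood
  has nine observable classes; the double heterozygote merges the 0- and
  2-recombinant phases with probability ((1-r)^2 + r^2)/2.  The EM on the
  sufficient statistics (n0, n1, n2, n5) iterates
  r <- (n1 + 2 n2 + 2 n5 r^2/((1-r)^2+r^2)) / (2n)
  to |Δr| < 1e-8 (max 200 iterations), clamped to [0, 0.5].  Two
  numerical guards: the initializer is capped at 0.49 because r = 0.5 is
  an (unstable) fixed point of the update, and the n1 = n2 = 0 case
  returns exactly 0 (the likelihood is decreasing in r there), which keeps
  cosegregation bins exact.  LOD = log10 L(r̂) - log10 L(0.5).  All-pairs
  estimation is vectorized over the sufficient-statistic matrices with an
  active-set EM (3000 markers in ~15 s).
* **Grouping**: connected components of the graph with an edge when
  LOD >= 6 and r̂ <= 0.35.  Both thresholds are defaults, not published
  values, and are configurable.
* **Ordering**: zero-recombination bins are collapsed; two initial orders
  (greedy chain from the max-LOD pair; classical-MDS principal-coordinate
  order) are each polished by 2-opt on the sum of adjacent r̂ (SARF), and
  the lower SARF wins.  The spectral start exists because dense maps can
  trap a pure greedy chain in "folded" local optima that 2-opt cannot
  unfold; on <= 8 markers the combination matches the exhaustive SARF
  optimum in >= 95% of random instances.  Orientation of a finished order
  is normalized (lexicographically smaller terminal marker first).
* **Distances**: cM positions are cumulative Kosambi transforms of
  adjacent r̂ — an adjacent-two-point map, deterministic and testable,
  explicitly *not* a multipoint/regression-mapping reimplementation.
  Kosambi: d = 25 ln((1+2r)/(1-2r)); r >= 0.5 maps to +inf (sentinel).
  Optional anchor files (marker -> chromosome) name groups by strict
  majority vote; others get sequential `LG` labels.

## Anchoring

Markers are re-located by exact search for flank+allele+flank (both
alleles, both strands, 25-mer seed + full verification); only a unique
single hit yields a location, and the variant-site coordinate is
strand-symmetric (construct offset + 61).  Scaffolds take the linkage
group of a *strict majority* of their located mapped markers (no majority
-> conflict, reported rather than resolved) and anchor at the median cM.
Orientation is the sign of the Kendall concordance between marker bp and
cM, requiring >= 2 markers at >= 2 distinct cM; cosegregating scaffolds
stay unoriented (the real project's synteny fallback is out of scope).
AGP v2.1 output alternates W and N lines (100-bp "scaffold" gaps,
linkage "yes", evidence "map"); within a chromosome, scaffolds order by
anchor cM with ties broken by length then id — deterministic but
arbitrary for cosegregating scaffolds.  Unoriented scaffolds are written
with orientation `?` and built as `+`.

## Chip content selection

* **Diversity chip**: greedy by (classes polymorphic, new scaffold,
  scaffold > 10 kb, MAF, id) with within-scaffold spacing > 5.5 kb.  The
  published objective ("optimize polymorphism among market classes") is
  informal; this scoring is our formalization and reproduces its outcome
  shape (every chosen SNP polymorphic in >= 1 class, multi-class share
  enriched over random).
* **Gap-filling chip**: after removing first-chip and cross-monomorphic
  SNPs, scaffolds are served category by category — no first-chip SNP;
  first-chip SNPs all cross-monomorphic; exactly one cross-polymorphic
  marker (add one distal partner); large scaffolds with too few markers —
  preferring the candidates closest to the scaffold's two ends so that
  recombination between them can orient it.  Per-category quotas are
  config inputs (the published per-category counts are not derivable from
  any stated rule).
* **Core set**: hard filters are strict — MAF > 0.05 and
  missing-plus-ambiguous < 0.10, where *ambiguous* counts heterozygous
  calls in an inbred panel (configurable).  Greedy preference: polymorphic
  in > 1 class, new scaffold, new map bin; map bins whose window cM/Mb
  ratio falls below 20% of the genome median (our operationalization of
  "very low recombination") accept at most one SNP, which thins
  heterochromatic redundancy.

## Reporting

All printed percentages funnel through two functions (`validation_rate`,
`percent`) using half-up rounding at the printed precision; table totals
are recomputed from the body rows and stored totals are *flagged*, never
silently corrected, when inconsistent.  MAF counts two alleles per
homozygote and one each per het, over non-missing calls.

## Known limitations

* Adjacent-two-point cM accumulation inflates map length under call
  errors (see above); lengths are reported, not validated against truth.
* The uniqueness filter and marker location are exact-match only — no
  near-match (1-mismatch) specificity screening.
* Conflict scaffolds (markers split across groups) are flagged and
  excluded from AGP rather than split.
* The (1-1/e) and optimality statements for panel selection are empirical
  on the tested instance distributions.
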