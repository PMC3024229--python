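# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `dupcensus`.

## Homology census

**Alignment kernel.** Duplicate detection uses exact global alignment
(Needleman–Wunsch with Gotoh affine gaps) rather than a heuristic seeded
search. Rationale: the divergence statistic downstream is defined as
100 − whole-protein percent identity, which presupposes a global alignment,
and an exact kernel is deterministic and directly checkable against
enumeration. Defaults follow gapped BLASTP: BLOSUM62, gap open 11, gap
extend 1 (a gap of length *k* costs 11 + *k*); all are configurable.
Percent identity uses **all alignment columns including gap columns** as the
denominator — the literature rarely states this choice, so it is fixed here
explicitly for reproducibility. Traceback ties resolve match >
gap-in-subject > gap-in-query, making alignments bit-stable.

**E-values.** Karlin–Altschul form E = K·m·n·e^(−λS) with the published
gapped-BLOSUM62 constants λ = 0.267, K = 0.041. These are scoring-scheme
constants supplied in config, not re-estimated from data; the E-value serves
as a length-aware significance filter, not a database statistic.

**Thresholds and families.** A hit survives at E ≤ 10⁻²⁰ *and* identity
≥ 30%, and an edge requires the hit in both directions (reciprocity).
Families are connected components of the reciprocal graph; the field reports
copy classes but no clustering rule, so the transitive closure is the
package's own (documented) choice. Two-copy families become duplicate pairs;
curated sub-threshold pairs can be forced in by locus tag.

**Location classes.** Chromosomes are ranked CI, CII, … by decreasing
length; pairs classify as CI-CI, CI-CII, CII-CII, C-P or P-P. Coordinates
are 1-based inclusive, with CDS sequences stored strand-resolved so codon
arithmetic never touches strand. The genetic code is fixed to bacterial
table 11; every bundle is validated so that each protein equals its
translated CDS.

## COG statistics

COG letters come from the 25-letter alphabet grouped into four general
classes (information storage and processing; cellular processes; metabolism;
poorly characterized), with unclassified genes in class 0. Multi-COG genes
count once per category, so tallies can exceed gene counts. The χ²
goodness-of-fit compares the duplicated genes' distribution to genome-wide
proportions with no continuity correction; categories that are impossible
under the null (zero expected, zero observed) are dropped from both the
statistic and the degrees of freedom, and a zero-expectation category with
observations is an error rather than an infinite statistic. Tail
probabilities come from `scipy.stats` (cross-checked in the tests against an
independent incomplete-gamma series and Monte Carlo).

Positional clusters of same-class duplicated genes use fixed non-overlapping
100 kb windows tiled from coordinate 0 with a minimum of 3 genes per
(window, class) cell. Both knobs are config values; reported cluster
intervals in the field are 0.1 Mb granules, which motivated the defaults.

## Quartet dating

For each pair, each paralog's best ortholog is chosen by lowest E-value,
then highest score, then id (a total order). If both paralogs share the same
best database sequence, the weaker-scoring paralog takes its next-best
distinct ortholog; with fewer than two distinct orthologs the pair is
reported Unresolvable rather than guessed.

The four proteins are aligned progressively (closest pair first by global
identity distance, then profile Needleman–Wunsch with the same affine
scheme). The three unrooted quartet topologies are fit under WAG with
stationary frequencies, a single rate category and unit expected rate, so
branch lengths are amino-acid substitutions/site. Likelihoods use
Felsenstein pruning over compressed site patterns; gaps and unknown residues
are marginalized as missing data, and all-gap columns are skipped with a
warning. Branch lengths are optimized coordinate-wise by golden-section
search on [10⁻⁸, 10], cycling until the log-likelihood improves by less than
10⁻⁶ (at most 50 cycles); while one branch moves, the other subtree
conditionals are frozen, so an evaluation costs one P(t) and one
pattern-by-state product.

The call is Type-B iff the maximum-likelihood topology makes the paralogs
sisters; both mixed topologies are Type-A, since a binary ancient/recent
classification cannot distinguish them. Ties within 10⁻⁹ log-units resolve
toward the Type-A topologies in a fixed order and are flagged.

**Bootstrap.** Support is the percentage of 100 column-resampling replicates
whose ML topology matches the full-data one. Resampling columns with
replacement is realized as a multinomial redraw of site-pattern weights
(identical distribution, no re-encoding). Replicates are refit with warm
starts from the full-data branch lengths under a lighter schedule
(tolerance 10⁻³, ≤3 cycles, golden-section resolution 10⁻²) — topology
choice, not branch-length precision, is what a replicate contributes. Each
pair's bootstrap seed is derived from the master seed plus the pair index
and recorded in the output for replay.

## Ka/Ks and selection

`backtranslate_pair` maps an aligned protein pair onto its source codons,
dropping gap columns, and verifies translation consistency.

**NG86 (reference estimator).** Classical Nei–Gojobori counting: per codon,
each position contributes one site split by the synonymous fraction of its
non-stop single-nucleotide changes (so S + N = 3 × codons exactly);
differences are averaged over all shortest mutational pathways with equal
weights, pathways through stop codons excluded and the remainder
re-weighted; Jukes–Cantor correction d = −¾ ln(1 − 4p/3), flagged undefined
at p ≥ ¾ (saturation).

**MYN-style (headline estimator).** Three modifications: (i) κ (the
transition/transversion rate ratio) is estimated from the data by applying
the Kimura two-parameter formulas inside the fourfold-degenerate and
nondegenerate site classes — within either class every change is of one
selective type, so the ts/tv pattern reflects mutation undistorted by ω —
and combining the two estimates weighted by site counts (clamped to
[0.1, 20], defaulting to 1 when fewer than 10 class sites exist);
(ii) site counting weights each possible mutation by κ^ts × the observed
position-specific target-nucleotide frequency; (iii) pathway-averaged
differences are split into transitions and transversions per class and
corrected with the Kimura two-parameter distance. With κ = 1 and uniform
frequencies the estimator collapses to NG86 up to the correction formula.
At ~300 codons, κ̂ has sampling noise of roughly ±0.35 (about 100
substitution events inform it), so individual Ka/Ks estimates scatter a few
percent around NG86 on κ = 1 data while the means agree to ~1–3%; this is
intrinsic to counting estimators at this length, not a defect of either
method. ω = Ka/Ks is undefined when Ks = 0 and labeled against the 0.3 / 1 /
3 landmarks (purifying ≤ 0.3, positive ≥ 3, neutral zone between).

**ANOVA.** The cross-strain comparison is a standard one-way fixed-effects
decomposition with the p-value from the F upper tail and the pooled standard
deviation √(SSW/df_within). ω is computed per pair per strain (the two pair
members compared within each strain). A float-noise guard treats
within-group sums of squares below 10⁻¹² × n × (|mean|+1)² as zero so that
identical groups give F = 0, p = 1 exactly.

## Synthetic cohorts

The generator emulates the study system: a focal strain with chromosomes CI
and CII and a plasmid (placement probabilities 0.67/0.20/0.13, matching the
genome-size proportions of a two-chromosome alpha-proteobacterium), gene
families of 300 codons by default, ~77% of duplications predating the
speciation, ω drawn lognormal with mean 0.13 and sd 0.033 (the purifying
regime), κ = 2 (a typical bacterial transition bias; the study system's
value is not published), three related strains at 0.05 substitutions/site
with per-copy loss probability 0.3, and two ortholog species.

Sequences evolve under a GY94-style codon Markov process (rate ∝ π_codon ×
κ^transition × ω^nonsynonymous, stop codons inaccessible), normalized to one
expected substitution per codon site; endpoint states are sampled exactly
from P(t) = e^(Qt) via the spectral decomposition of the reversible
generator. Ancestral sequences draw codons from the equilibrium frequencies
(uniform over the 61 sense codons by default; a GC-content knob reweights
them for high-GC genomes). Branch-length defaults — 0.6 from duplication to
speciation for ancient duplications, 0.3 from duplication to present for
recent ones, 0.8 from speciation to present per lineage — put ancient-pair
protein identities near 50% and recent pairs near 85%, inside the detectable
range of the 30%-identity census threshold.

Age classes are generated **structurally**: ancient families duplicate on
the root branch and each copy then speciates; recent families duplicate
inside the focal lineage after the split. The emitted topology is therefore
a consequence of event order, never a target, so topology recovery is a
genuine test. Everything flows from one master seed; identical seeds yield
byte-identical bundles and truth tables.

**What the simulator does not emulate:** insertions/deletions (alignment
inference is exercised on substitution-only truth), recombination and gene
conversion, rate heterogeneity across sites, codon-usage selection, tandem
placement bias of young duplicates, and annotation noise. Passing tests
therefore demonstrate correctness of the estimators under the stated models,
not robustness to misalignment or model violation on real genomes.

## Pipeline and reporting

Stages run strictly in order (homology → pairs → COG → quartets → strains →
selection → HGT → report); a stage failure aborts with the stage name. All
percentages are computed by one function, `pct`, which rounds half-up at the
requested number of decimals so that printed ratios are exactly
reproducible. Tree-type tables band bootstrap support at [90, 100], [70, 90)
and [0, 70), with an "undefined" band for pairs lacking a value. Every
output file carries a SHA-256 hash of the canonicalized config plus the
master seed, and reruns are byte-identical.

Problem sizes in the test suite and acceptance script (e.g., a 220-family
cohort at 200 codons for the Type-A-fraction experiment, 200 replicates per
ω grid point, a 50-family cohort for the determinism check) were chosen so
the binomial/sampling error of each check is comfortably below its
tolerance while the whole suite stays desk-scale.

## Known limitations

- The homology search is O(n²) exact alignment; it is meant for
  genome-scale censuses of thousands of proteins at most, not metagenomes.
- The MYN-style estimator uses the HKY/K2P family of corrections; the full
  Tamura–Nei purine/pyrimidine rate split is not implemented.
- Quartets only: expanded trees with more taxa per family are out of scope,
  as are rooted trees and substitution-model selection.
- HGT intervals are consumed, not predicted; compositional scanners must be
  run externally.
- The published genome-wide counts of the original census depended on a
  2010-era annotation and database and are not reproducible at desk scale;
  the package treats them as fixture inputs for its ratio arithmetic and
  validates the algorithms on synthetic truth instead.
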