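# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want recorded.

## Family census

Membership is a conjunctive domain test: a protein is a family member iff
it has at least one hit at e ≤ `domain_e_cutoff` (default 10⁻⁵) for every
required domain id. The default required set — the trehalose-synthase
catalytic domain plus the phosphatase-like domain — encodes the structure
of plant TPS proteins, which carry both; both ids are configurable because
domain-database accessions vary. An empty required set is rejected rather
than silently retaining everything.

Molecular weight is the sum of average residue masses plus one water, in
kDa; the residue-mass and pKa tables ship in `census.py`. The isoelectric
point solves net-charge(pH) = 0 by bisection on [0, 14] to 10⁻⁴, using a
Bjellqvist-style pKa set (N/C termini, D, E, C, Y, H, K, R); the charge
function is strictly decreasing in pH, so bisection is exact up to
tolerance (verified against a 10⁻⁵-step grid search in the tests).
Ambiguous residues (X, B, Z) raise in strict mode and are skipped with a
warning in lenient mode.

PROSITE patterns are compiled to regular expressions (character sets,
exclusions, `x` wildcards, bounded repeats, `<`/`>` anchors) and counted
over *all* start positions, overlaps included, via look-ahead matching —
the convention that makes the count equal to a brute-force all-positions
matcher. The six census columns default to the canonical phosphorylation /
amidation / N-glycosylation patterns; published per-protein counts are not
used as oracles because site scanners differ in whether high-probability
patterns are excluded.

## Ortholog naming

p-distance is mismatches over compared columns, excluding columns with a
gap in either row; zero comparable columns is an error, not a zero.
Naming maps each query to its argmin-distance reference; suffixes are
assigned per reference stem in ascending distance, ties broken
lexicographically by query id and flagged in the output table. Distance
ordering (rather than genomic-position ordering, which the convention
leaves open) was chosen because it is computable from the distance matrix
alone and reproduces "relative similarity" suffixes.

The tree is neighbor joining on the same matrix (scikit-bio's
implementation), with negative branch lengths clamped to zero afterwards
and taxon ids sorted before agglomeration so input order cannot change the
topology. A maximum-likelihood tree would need the alignment and a
substitution model; the naming procedure and the two-cluster memberships
only need the distances, so NJ is the deliberate stand-in here. Cluster
labels come from midpoint-rooting and cutting the longest internal
branches until the requested number of tip groups remains.

Alignment construction is out of scope: the naming stage consumes an
aligned FASTA and errors on unequal lengths. Synthetic family proteins are
generated at one fixed length precisely so the identity "alignment"
suffices in tests.

## Expression correlation

Pearson r over shared samples, two-sided p from t = r·√((n−2)/(1−r²)),
significance at α (default 0.05, the conventional level; the source
figures size their dots by p without naming a cutoff). Constant vectors
yield r = NaN, reported as missing rather than zero, so flat genes cannot
masquerade as uncorrelated ones. Raw TPM is used by default with
log2(TPM+1) optional, and replicates stay separate samples; an optional BH
column is available since multiple-testing handling is not standardized
for this kind of panel. Ranking (`top_expressed`) is by mean TPM with
lexicographic tie-break.

## Allele mining

Gene-relative coordinates: +1 is the first base of the start codon on the
coding strand, −1 the immediately upstream base, no position 0. This is
the coordinate system of the published haplotype tables and of all outputs.
All alleles in a table are coding-strand oriented (complemented for
minus-strand genes).

VCF-level records are decomposed into per-base rows: SNPs one row;
left-anchored deletions one row per deleted base (carriers show `-`);
left-anchored insertions one row per inserted base at consecutive
relative positions adjacent to the anchor, reference `-` — matching the
published representation of a multi-base insertion as a run of
consecutive positions. An insertion row can therefore share its
relative position with the following reference base's row; rows are kept
in stable sorted order. `-` is a *comparable* deletion allele; the
distinct `.` marks a missing call and disqualifies a row from
trait-specific flagging. Heterozygous diploid calls collapse to IUPAC
codes (single-base alleles) or to missing, configurable.

The trait-specific rule is exact: uniform within group 1, uniform within
group 2, different between, no missing call. Typing is indel iff any
allele is `-` or longer than one base. Consequences map exonic
substitutions through cumulative exon lengths to the spliced CDS, codon
index ⌈pos/3⌉, standard codon table; single-base indels in the CDS are
frameshifts; agreement with a translate-whole-CDS-before/after oracle is
tested on 1,000 random substitutions. The stability report is arithmetic
only (ΔE = E_mut − E_wt) with a ±0.5 kcal/mol neutral band — the published
label for −7.03 implies only that the band is well below 7; 0.5 is a
conventional homology-model noise floor.

## Promoter enrichment

Promoters are the ≤ 2,000 bp upstream of the start codon, coding-strand
oriented, truncated at chromosome edges; sequences < 500 bp or with
> 1,500 ambiguous bases are excluded and logged, and retained + excluded
always equals the gene count.

Per-sequence motif score: the *affinity* — the mean over both strands and
all start positions of the odds product ∏ₖ M[k, base]/π[base], with
ambiguous bases contributing odds 1. The mean-odds choice makes the log
score approximately normal across promoters, which is what the log-normal
background comparison assumes; it is isolated behind one function so a
max-score variant could be swapped in. Because all full-length promoters
are 2 kb, no length stratification is applied; truncated promoters
≥ 500 bp share the same background.

Background: per motif, μ and σ of ln(affinity) over all promoters
(family included, matching the genome-wide-background design). Zero
scores are floored at (smallest positive score)×10⁻³ before the log —
small enough not to shape the fit, large enough to keep it defined. The
family set tests z = (mean ln A − μ)/(σ/√n) against the upper normal
tail; σ = 0 degenerates to p ∈ {0, 1} by the sign of the mean difference.
BH adjustment, enrichment at q ≤ 0.1.

Presence calls (for the universally-present-motif report) count a promoter
as carrying a motif when some window's log-odds reaches 85% of the motif's
maximum achievable log-odds; the scanning tool behind the published
per-promoter counts does not state its threshold, so this one is explicit
and configurable.

The window scanner is a numba kernel (with an equivalent numpy path kept
and tested for agreement); this is what makes the calibration and power
simulations cheap.

## Synteny

Anchors are homolog hits filtered to e ≤ 10⁻⁵ and the top 5 per query.
Chaining is per chromosome pair: dynamic programming over anchors sorted
by genome-A rank, a transition legal when both rank gaps lie in
[1, max_gaps+1] and genome-B ranks move consistently up (plus) or down
(minus); chain score = 50·anchors − 1·intervening genes. The
highest-scoring chain is emitted repeatedly (score ties resolved toward
the longer chain); chains need ≥ 5 anchors and positive score; leftover
anchors within the 5-gene overlap window of an emitted block are absorbed
into it rather than seeding duplicates. Intra-genome comparisons drop the
self-diagonal and mirror anchors. Block-level e-values of the original
chainer are not reproduced (they are unpublished); retention is by size
and score with the same parameter names. Equivalence with an exhaustive
chain search is tested on 500 random ≤ 12-anchor instances.

The gene collinearity network has family genes as nodes and direct anchor
pairs within retained blocks as edges (co-membership edges available
behind a flag); components are reported largest-first. QTN ids parse as
`<chromosome>_<position>`; distance is 0 inside the gene span, else the
gap to the nearest boundary, reported inclusively at ≤ 1.0 Mb and also in
Mb at two decimals.

## Synthetic data: what it emulates, and what it does not

The generator emits every input format the pipeline consumes with planted
truth: a ~1,000-gene backbone over five chromosomes (genes
reverse-translated from random proteins, 2–3 exons, random strands,
~2.2 kb intergenic spacing), an 18-member family split across four
duplicated segment groups (copy counts 6/4/4/4, mixed orientations, each
copy a 10-gene segment), a 30-residue family signature driving the
domain-hit table (plus decoy proteins with one domain or above-cutoff
e-values), a VCF with planted trait-specific positions and deliberately
sub-threshold records on both sides of the QUAL 30 / DP 5 boundary, a TPM
matrix whose module genes are positive affine transforms of a shared
latent profile (so zero noise gives r = 1 exactly), and one PWM consensus
planted in every family promoter at rate 1.0 vs 0.02 in the background.
Thirty non-homologous spacer genes separate segment copies appended to
the same chromosome so separately planted blocks cannot legally chain
into one. Paralog pairs differ by one private mutation each on top of a
per-pair shared set whose size grows with pair index, which makes pairs
mutual nearest neighbors with consecutive suffix ranks.

One seed drives one named RNG stream per output type (genome, variants,
expression, motifs, hits), so outputs are byte-reproducible and adding an
output type does not shift the others.

Deliberately not emulated: read-level data and sequencing error (the VCF
is consumed, not called), codon-usage bias, realistic intron/intergenic
composition, gene-length and family-size distributions, population
structure beyond the two phenotype groups, and inter-species divergence
(synteny is exercised intra-genome). Passing the planted-truth tests
therefore shows the *algorithms* recover what was put in under clean
conditions; it does not validate robustness to alignment artifacts,
calling error, or promoter composition bias in real genomes.

## Simulation sizes used in the checks

The calibration and power checks run on reduced problem sizes chosen to
exercise the same statistics at interactive cost: null calibration uses
200 replicates of 18 target + 200 background promoters of 400 bp against
20 informative-width-8 PWMs with equal planting rates; power uses 100
replicates of 18 targets (rate 0.8) vs 500 background (rate 0.05) against
25 PWMs. The type-I bound is 0.1 + 2·SE on the pooled motif count; power
requires detection of the planted motif at q ≤ 0.1 in ≥ 95/100
replicates. The Pearson null calibration uses 10,000 replicates at
n = 10. The end-to-end planted-truth checks run on the full default
bundle (~1,400 genes after segment copies and spacers).

## Known limitations

* The NJ stand-in can differ from an ML topology on real, rate-variable
  alignments; only distance-derived conclusions (naming, two-way cluster
  membership) should be read from it.
* The enrichment z-test treats promoters as independent; shared upstream
  windows of adjacent divergently-transcribed genes mildly violate this.
* Insertion rows share the relative-position axis with reference bases;
  consumers sorting strictly by position must keep the stable row order
  for multi-base insertions.
* The chainer's greedy repeated-extraction is exact for the top chain
  (tested against exhaustive search) but, like the original tool, makes
  no global-optimality claim over the full block set.
* The pI and MW values depend on the shipped tables; alternate pKa sets
  change pI by up to ~0.3 units and are selectable per call.
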