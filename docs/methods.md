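# Methods

## Dosage and segregation model

The cross is modelled as a pseudo-testcross between two autopolyploid
parents of ploidy `2m` (default octoploid, m = 4). Meiosis follows pure
random chromosome segregation: homologs pair into bivalents uniformly
at random each meiosis, with no preferential pairing and no double
reduction. Under that model a gamete misses a dose-`d` allele with
probability `C(2m−d, m)/C(2m, m)`; for the octoploid the absence
fractions for doses 1–4 are exactly 1/2, 3/14, 1/14 and 1/70. All such
probabilities are evaluated with exact rational binomial coefficients
and converted to float at the interface, so tests can assert exact
values.

Pooling reads over a balanced F1 family samples the two parents'
`4m` haplotypes uniformly, giving a pooled minor-allele fraction
`(d1 + d2)/4m` (1/16, odds 1:15, for a simplex site). Depth–detection
arithmetic uses `P = 1 − (1 − p)^n`; `min_depth` returns the smallest
integer `n` meeting a target certainty with an explicit boundary check
(72 reads at p = 1/16, c = 0.99; 23 reads at p = 1/8, c = 0.95 — the
formula needs 23, not 22, to clear 95%).

## Synthetic cross generator

The simulator defines the study conditions all end-to-end tests run
under; its defaults are the design point of the emulated experiment:

| parameter | default | rationale |
|---|---|---|
| progeny | 59 | F1 family size of the emulated cross |
| ploidy / chromosomes | 8 / 10 | autooctoploid over a 10-chromosome reference gene space |
| dosage mixture (d = 1..4) | 0.70/0.20/0.07/0.03 | ~70% of SNPs single dose in such genomes |
| genetic length | 100 cM/chromosome | grass-like chromosome map length |
| depth/gene/progeny library | NB(mean 40, size 8) | RNA-seq depth acts per gene and is overdispersed |
| parent depth factor | 4× | parents are sequenced as merged multi-tissue libraries |
| base-call error | 0.001 | post-filter Illumina error scale |
| base qualities | Q40 98%, Q20 2% | small low-quality tail exercised by the >28 filter |
| expressed genes | 90% | leaf transcriptome does not express every model |

Meiosis transmits, per chromosome and parent, `m` chromatids — one per
random bivalent — each a mosaic of its bivalent's two homologs with a
Poisson(L/100) number of crossover breakpoints at uniform cM positions.
This process has no crossover interference, so the generative
recombination fraction over distance `d` is Haldane's
`(1 − e^(−2d/100))/2`; simulator self-tests check against that
expectation, while map construction converts rf to cM with Kosambi's
function (the field's convention for these maps). At the short
adjacent-bin distances that dominate map building the two functions
differ by a few percent, which is the dominant (and documented)
downward bias in recovered map lengths.

Pileups are written in a pinned 6-column mpileup dialect (name, 1-based
position, ref base, depth, read bases with `.`/`,` for reference,
Phred+33 qualities; `^`/`$` tolerated, no indels) and only at variant
sites — invariant columns carry no marker information. Genes, not
sites, carry the depth draw: all sites of a gene share an individual's
depth. Every random draw flows through one `numpy` generator seeded
from the config, so a (seed, config) pair reproduces byte-identical
files. Per-haplotype expression weights exist as an optional knob
(uniform by default) because homolog expression dominance is a known
bias in transcriptome-based marker discovery; no published model exists
for it, so none is imposed.

Injected translocations move blocks of ≥ 3 consecutive genes between
chromosomes of a species' gene order while anchors keep ancestral
coordinates; a shared flag applies an event to both simulated species.
Genetic positions are rank-based per chromosome, which keeps positions
well defined after blocks move.

What the generator does **not** emulate: read-level alignment artefacts
(mismapping, paralog collapse, reference bias), splice isoforms,
allele-specific expression, segregation distortion, and crossover
interference. Passing tests therefore certify the statistical chain
from pileup columns to maps and dates under clean alignment — not
robustness to alignment pathology.

## Single-dose screen

Bases at Phred ≤ 28 are excluded from all counts; a sample's column
needs filtered depth > 7 to be scored, else the sample is missing at
the site. The merged-progeny screen takes major = most frequent base,
minor = runner-up, and keeps sites with `minor/major` in the inclusive
window [1/30, 1/6] at merged depth ≥ 72 (the detection-formula bound).
The ratio is minor/major — odds notation — not minor/total. Residual
third-allele reads above 1% of depth reject a site as multi-allelic
(the upstream analysis leaves this unspecified; a small error budget is
the robust choice). The window deliberately admits duplex sites (pooled
ratio 2:14 ≈ 0.143 < 1/6); the later 0.3–0.7 segregation filter is the
stage that removes them (duplex presence ≈ 11/14 ≈ 0.79), mirroring the
two-stage screen of the emulated analysis.

Parent of origin requires the carrier parent's own ratio in the window
while the other parent's minor fraction stays within a 1% error budget;
anything else is ambiguous and excluded from mapping. Because the true
carrier-parent ratio is 1/7 ≈ 0.143 — close to the window's 1/6 upper
edge — moderate parental depth loses some true markers here; this
trims marker count, not correctness, and is why parents are simulated
deeper than progeny. Progeny presence needs ≥ 2 minor reads (one read
is within reach of a single sequencing error at 40× depth).

## QC, binning, linkage

The segregation filter keeps markers with presence fraction in
[0.3, 0.7] among non-missing calls and ≥ 39 genotyped individuals; a
separate ≤ 10% missing cap gates entry to binning. The two completeness
thresholds are deliberately independent knobs (their combination is
over-determined for a 59-progeny population, so neither is derivable
from the other).

Binning is greedy leader clustering over id-sorted markers, with
conflicts counted on jointly genotyped progeny and minimised over phase
orientation (a simplex marker's presence coding is phase-arbitrary, so
a vector and its complement co-segregate). Greedy-leader rather than
transitive closure keeps a nonzero conflict allowance from chaining;
with the default `max_conflicts = 0` the two coincide. Representative =
member with least missing data, ties to the smallest id.

Two-point linkage minimises mismatches over phase
(`R = min(M, n−M)`), with `LOD = (n−R)·log10(2(1−rf)) + R·log10(2rf)`
and the R = 0 limit `n·log10 2`. Grouping is single-linkage transitive
closure at LOD ≥ 6; unplaced bins then join the group of their single
strongest link at LOD ≥ 4 (strongest-cross-link rescue, evaluated
against the pre-rescue groups so rescues cannot chain). Ordering is not
a multipoint maximum-likelihood map: the contract is greedy chain
extension from the strongest pair, appending at either end the bin with
minimal rf to that end, then 2-opt segment reversals minimising the sum
of adjacent rf, with cumulative Kosambi positions. Orders are validated
against simulation truth (full rank correlation at n = 200 collinear
bins; homolog map length within 15% at n = 500). Adjacent rf is capped
just below 0.5 before the Kosambi transform to keep degenerate pairs
finite; groups of one bin are reported unplaced rather than ordered.

## Synteny and rearrangements

A linkage group's homologous group is its majority anchor chromosome;
count ties break toward the chromosome with the longest run of
map-adjacent anchors, then the smallest chromosome id, and are flagged.
Congruous = anchored to the majority chromosome; unplaced-scaffold
anchors ("other") count in totals only. One rearrangement event is
called per foreign chromosome with ≥ 3 anchored markers in a group;
foreign markers need not be map-adjacent (an optional adjacency
constraint is out of scope of the default rule). Cross-species sharing
matches events by unordered chromosome pair: the shared percentage is
(shared events summed over both species)/(all events of both species),
so one conserved translocation seen in both maps contributes two shared
events — the bookkeeping that makes per-species shared fractions and
the combined fraction mutually consistent. Collinearity is reported
descriptively as Spearman rho between map order and reference position
of congruous markers, computed only for groups with ≥ 5 of them.

## Ks dating

Orthologs are paired by reciprocal best hit on global translated
alignment score (BLOSUM62, gap open −10, extend −0.5); tied best hits
drop the query. Pairs must exceed 50% coverage of the reference-side
CDS (strict inequality). Codon alignments are back-translated protein
alignments with gap columns removed. Nei–Gojobori counting uses the
standard nuclear code: per codon, synonymous sites = silent one-step
changes/3 (averaged over the two sequences); differences are averaged
with equal weight over all minimal mutational pathways avoiding stop
codons (if every pathway is blocked — which does not occur for
sense-codon pairs — the stop rule is relaxed). Counts stay exact
rationals until `ps = sd/S`, then
`Ks = −(3/4) ln(1 − (4/3) ps)`, with a saturation error at ps ≥ 3/4.
Dating divides the median Ks (lower-median convention for even counts)
by twice the grass synonymous rate 6.5e−9/site/year, exposed as a
parameter. Redundant-transcript clustering is reduced to exact
validation (frame, internal stops, minimum length) plus RBH tie
dropping — deterministic and sufficient for curated CDS sets.

## Problem sizes used by the test suite

End-to-end certification runs at the design point (59 progeny,
10 chromosomes, ~1150 genes, ~2900 sites of which ~2060 simplex) once
per session; unit-level cross fixtures use 32 progeny over 150 genes;
Ks recovery uses 200 pairs of 300 codons at true Ks 0.01 and 0.1;
Monte-Carlo segregation oracles use 1e5 gametes. These sizes were
chosen so each property is measured with comfortable statistical margin
while a full run of the suite stays well under a minute of simulation
time.

## Known limitations

* Dosage is screened, never genotyped by likelihood: the ratio window
  plus segregation filter is the whole dosage decision.
* Ordering is heuristic seriation; no multipoint likelihood, no
  imputation of missing genotypes.
* The simulator's meiosis has no interference while maps use Kosambi;
  recovered map lengths run a few percent short by construction.
* Saturated ortholog pairs (ps ≥ 3/4) are excluded from dating rather
  than corrected with a codon model.
* Breakpoint resolution of rearrangements is marker-level, not
  base-pair level, and fusion/fission mechanisms are not inferred.
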