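# Methods

`allokit` analyzes paleo-allotetraploid genomes: species formed by the
hybridization of two diverged diploid progenitors followed by genome
doubling, long enough ago that the species now behaves genetically as a
diploid. The package implements five analysis stages — subgenome phasing
from diagnostic k-mers, homeologous-exchange calling, molecular dating,
subgenome retention/expression-bias statistics, and ancestry-dosage
painting of admixed accessions — together with a synthetic-data generator
that plants known truth for every stage. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic allotetraploid genomes

The generator builds a common ancestor as an i.i.d. nucleotide sequence at
a configurable GC content, evolves two progenitor lineages from it under
Jukes–Cantor (JC69) substitution, plants transposable-element bursts, and
merges the two progenitors into a tetraploid.

**Mutation model.** A site evolved for time *t* at rate *r*
(substitutions/site/year) differs from its ancestor with probability
p = (3/4)(1 − e^(−(4/3)rt)), and a changed site takes the other three bases
uniformly — the exact JC transition kernel, applied per site. This makes
`jukes_cantor(p)` the exact inverse of the simulation's expected
divergence, which the tests exploit (round-trip identity to 1e-12). Rates
`r·t ≥ 0.7` are rejected as saturating.

**TE bursts.** A family is a consensus sequence; a burst of age *a* plants
`n_copies` copies at uniform random positions, each copy independently
mutated for *a* at the configured rate. For LTR retrotransposon families
the leading `ltr_length` bp of the consensus is the long terminal repeat;
each planted copy carries a second, independently mutated LTR appended at
its 3′ end, so the two LTRs of one copy diverge with expectation `2·r·a` —
the quantity LTR insertion dating inverts. Insertions do not nest
(re-drawn on overlap), and within the bundled presets the three family
consensi are drawn to share no canonical 13-mer (rejection sampling; two
random 1 kb sequences share one with probability ≈1.5%). Both guarantees
exist for the same reason: the planted truth must be clean — a
"subgenome-specific" family that accidentally contains a 13-mer of the
genome-wide family is not subgenome-specific.

**Hybridization and exchanges.** Progenitor chromosomes are paired by
index; pair *i* becomes (`chr{2i+1}`, `chr{2i+2}`). A reciprocal exchange
swaps equal-length distal segments (the last `f·min(L1,L2)` bp,
0 < f < 0.5), conserving total length and dosage; registry entries for TE
copies inside a swapped segment move with it. The default preset is 4
homeolog pairs × 500 kb, one A-specific and one B-specific LTR family of
200 copies (age 4 My), one shared family of 200 copies (age 2.5 My,
planted half on each progenitor — equivalent, for every genome-wide
statistic, to planting on the merged tetraploid, and it keeps exchange
coordinates final), progenitor split 7.2 My, rate 2.1 × 10⁻⁸
substitutions/site/year, and one reciprocal distal exchange at 20% of
length. These mirror the event timeline the dating stage is meant to
recover (split ≫ specific burst > hybridization).

**Expression counts.** Homeolog pairs receive a lognormal baseline
(log-mean log 100, log-sd 1.0); the B member is scaled by a per-pair
lognormal ratio whose median is the planted bias (log-sd 0.1). Counts are
gamma–Poisson with CV² = 0.01 (interpreted as residual overdispersion
*after* replicate pooling), libraries default to 5 × 10⁶, and 30% of
gene-sample cells are silenced. The noise calibration matters: a wide
per-pair ratio spread interacts with the cpm > 0.5 both-members filter
(pairs whose B member is pushed over the threshold by a high ratio are
preferentially retained), inflating the recovered median by ~+0.02, and
heavy overdispersion makes the pooled median's seed-to-seed spread ~0.006.
With the defaults the planted median is recovered within ±0.008 across 20
seeds. What this shows about real data is correspondingly limited: the
generator demonstrates estimator correctness under calibrated noise, not
robustness to the larger regulatory divergence real homeologs carry.

**Admixed accessions.** Ancestry blocks assign each marker a dosage vector
(d₁, d₂) summing to the ploidy; read depth is Poisson(`depth_mean`) and
species-1 reads are binomial with success probability
(d₁/m)(1−ε) + (1−d₁/m)ε. The admixture preset is 4 chromosomes × 5 Mb,
5000 markers each, dominant dosage (m−1, 1) with one complementary block
per chromosome covering 5% of its length at a random, deliberately
non-window-aligned position.

## Subgenome phasing by diagnostic k-mers

Relict repeats active in only one progenitor leave k-mers enriched on one
member of every homeologous chromosome pair. A k-mer (k = 13; canonical =
lexicographic minimum of the k-mer and its reverse complement, windows
containing N skipped) is **diagnostic** when (1) its genome-wide count
reaches `min_total` and (2) for *every* pair, its density is at least
`min_fold` = 2 higher on one member (ties kept, matching an "at least
twofold" rule; pseudocount 1 avoids division by zero while preserving the
2-fold semantics). Density is counts per bp by default — homeolog lengths
differ — with raw counts available by flag. `min_total` = 100 is
calibrated to a ~2 Gb genome and scales linearly with genome size
(floor 10) in the presets.

Chromosomes are then clustered on length-normalized diagnostic-k-mer
profiles (correlation distance, average linkage) and cut into two
clusters; a separation score (mean silhouette) and a pair-integrity flag
(one member of each pair per side) are reported. Which cluster is called
"A" is arbitrary on synthetic data and fixed by a deterministic rule (the
cluster containing the lexicographically smallest chromosome name); on
real data an anchor chromosome should be supplied. A consistency filter
finally removes k-mers whose per-pair favored side conflicts with the
partition on more than `max_conflicts` = 0 pairs.

## Homeologous-exchange HMM

Each chromosome is summarized as windowed (default 10 kb at preset scale)
counts of A- and B-labelled diagnostic k-mer occurrences. The hidden state
is window ancestry (A/B); the emission is binomial on the A count given
the window total — chosen over a bivariate Poisson because it is invariant
to window-to-window repeat-density fluctuation. Windows with zero total
emit likelihood 1 in both states rather than being dropped, preserving
coordinates. Transitions use a per-boundary switch probability (default
10⁻³); Viterbi ties break toward the previous state, favoring fewer
segments. Runs shorter than `min_windows` = 3 merge into the flank with
the higher adjacent posterior.

Emissions are estimated by pooling windows of bulk-assigned chromosomes
after trimming the distal 25% at each end (where exchanges would
contaminate the estimate), optionally refined by EM (≤50 iterations,
tolerance 10⁻⁶, transitions held fixed). Two numerical guards matter on
sparse tracks, where occurrences concentrate inside repeat copies
separated by empty windows:

* **Emission noise floor (0.05).** Raw pooled estimates approach 0.999;
  at that extreme, one or two stray opposite-label occurrences (each
  diagnostic k-mer hits the wrong subgenome about once per ~70 chromosome-
  Mb by chance) outweigh the transition penalty and flip the path.
* **Call polishing.** A segment whose state differs from its chromosome's
  bulk assignment becomes an exchange call only if it contains ≥25
  occurrences of its own state (a genuine exchanged segment carries
  hundreds per repeat copy). Non-terminal call edges are refined to the
  midpoint between the last window with ≥5 opposite-state occurrences and
  the first with ≥5 own-state occurrences — the data localize a breakpoint
  only to the gap between flanking repeat copies, and the midpoint halves
  the expected error relative to either edge. Calls are flagged
  `reciprocal` when the partner chromosome carries a complementary
  opposite-state call with ≥50% reciprocal overlap, and the two members of
  a reciprocal distal pair are jointly refined to a common end-offset
  (balanced exchanges swap equal-length segments), which again roughly
  halves boundary error. Across 20 preset seeds this yields zero false and
  zero missed calls, mean boundary error ~0.5 windows, and all boundaries
  within ~1.6 windows except one at 2.2 — a seed whose breakpoint falls in
  an unusually long copy-free stretch, the irreducible localization limit
  of copy-based evidence.

## Molecular dating

* `p_distance` / `jukes_cantor`: complete-case columns (pairwise deletion
  of gaps and ambiguity); d = −(3/4)ln(1 − 4p/3), rejected at p ≥ 0.75.
* LTR insertion age = d(LTR, LTR) / (2r), reported in My. The default rate
  2.1 × 10⁻⁸ is interpreted as substitutions/site/year — the only unit for
  which ages land in the My range — and the unit is spelled out in every
  interface.
* Rate calibration: families active genome-wide and in an outgroup give
  per-family rates d/(2·T_split) against a known split (default 10 My);
  the working rate is the median across families.
* Ks/Ka: Nei–Gojobori (1986) pathway counting, chosen over ML codon
  models because it is fully specifiable and oracle-checkable: per-codon
  site fractions count mutations to stop codons as nonsynonymous
  (denominator 3, the original convention — also what Biopython's NG86
  implementation uses, which serves as an independent cross-check in the
  tests); multi-hit codons average over equally weighted mutational
  pathways, excluding pathways through stops unless all are blocked;
  JC correction applied to pS and pN separately; proportions ≥ 0.75 are
  flagged saturated and reported missing.
* Event dating: the mode (not the mean — Ks distributions are
  right-skewed by saturation) of a Gaussian KDE with Silverman bandwidth,
  divided by 2r; all local maxima are reported so bimodal inputs are
  visible; percentile bootstrap CI (200 resamples, seeded). Degenerate
  all-equal input short-circuits to the exact value.

## Retention and expression bias

Retention treats an outgroup gene as the preduplication unit: it is
retained on a subgenome when at least one co-ortholog survives there. The
A-vs-B retained/lost table is tested with a two-sided Fisher exact test
implemented by explicit hypergeometric enumeration (all tables with the
observed margins whose point probability does not exceed the observed
one); `scipy` agrees to 4 × 10⁻¹⁶ over every table with margins ≤ 30.

Expression uses cpm after summing replicates within a sample group. Two
pair sets are deliberately different: the **median B/A ratio** uses pairs
where *both* members exceed 0.5 cpm (a silent member makes the ratio
degenerate), while **X-fold counts** (X = 2, 5, 10) use pairs where at
least one member passes, flooring the silent member at a 0.5-cpm
pseudocount so a (10 cpm, 0 cpm) pair counts as ≥10-fold. The B-favored
excess is reported both as a share of qualifying pairs (stable, used for
null checks) and relative to the A-favored count (comparable to "X% more
pairs" phrasing, but ill-conditioned when fold counts are small). Both
pooled and per-group medians are emitted, since either convention is
defensible. For pairs in exchanged regions the ratio is re-oriented by
*source* subgenome (the member now on A came from B), which turns "does
bias follow the DNA or its location?" into the sign of a difference of
stratum medians, bootstrapped for a CI.

## Ancestry painting

Markers are fixed differences between two species: sites where every
non-missing diploid exemplar of species 1 is homozygous for one allele and
every non-missing exemplar of species 2 homozygous for another, with ≥1
non-missing exemplar per species, outside repeat-masked intervals. For an
accession of ploidy m, each window's dosage g ∈ {0..m} of species-1
chromosome sets is scored by a read-level binomial log-likelihood with
success probability (g/m)(1−ε) + (1−g/m)ε (ε = 0.01 default); windows with
no reads are missing. A dosage HMM (stay 1−τ, switch τ/m to each
alternative, τ = 10⁻³, ties toward the previous state) smooths windows
into segments, bridging missing windows with the flanking state. Every
emitted dosage vector sums to the ploidy by construction. The genome
summary reports length-weighted ancestry fractions, the modal dosage
(e.g. 2:1 for a triploid interspecific hybrid), and windows deviating from
it — candidate introgressions or conversions, which the tool reports
without interpreting. When called genotypes are supplied instead of
depths, dosages follow the 0..1 fractional coding per ploidy.

## Problem sizes and limitations

Tests and the acceptance run use desk-scale data: 8 × ~0.6 Mb genomes,
5000 homeolog pairs, 200 LTR pairs × 1 kb, 500 codon pairs × 300 codons,
and 20 000 markers at depth 10 — sizes chosen so a full pass completes in
minutes on one core while leaving every estimator comfortably identified.
Known limitations: the mutation model is substitutions-only (no indels or
rearrangements beyond the planted exchanges); the k-mer stage assumes
chromosome-level assemblies; one-to-many homeolog relations (fused
chromosomes) are handled only by exclusion; the HMM is two-state and does
not genotype non-balanced exchanges; NG86 underestimates Ks at high
divergence relative to ML codon models; and the expression generator does
not model tissue-specific regulatory divergence, so bias recovery there
says nothing about confounding in real multi-tissue designs.
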