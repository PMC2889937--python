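# Methods

This note documents the models and procedures implemented in `mirspot`, the
choices made where the design was genuinely open, and what the test suite
does and does not demonstrate.

## Duplex energy model

Intermolecular microRNA:mRNA hybrids are scored with a self-contained
nearest-neighbor model; intramolecular structure within either strand is
ignored. An admissible structure is an ordered list of base pairs
(mi_pos, t_pos), mi_pos strictly increasing and t_pos strictly decreasing
(antiparallel, no pseudoknots), each pair Watson-Crick or G:U wobble, with

- no lonely pairs: every maximal helix (run of directly stacked pairs) has
  length >= 2;
- no G:U among the first eight pairs, and at most four G:U pairs in total
  (structures violating either rule are discarded outright).

The energy is

    dG = dG_init + sum(stack terms) + sum(loop penalties)
         + terminal AU/GU penalty at both ends of every maximal helix.

Parameters ship as a versioned TSV (`mirspot/data/nn_params_v1.tsv`, schema:
kind / key1 / key2 / value). Watson-Crick stacking free energies are
Turner-2004-style values (kcal/mol, 37 C); stacks involving one G:U pair are
weakened to clamp(0.45 w, [-1.50, -0.25]) and with two G:U pairs to
clamp(0.25 w, [-0.80, -0.20]), where w is the Watson-Crick stack for the
same guide dinucleotide. This rule is deliberately approximate: the pipeline
only consumes energies *relative* to each microRNA's perfect-complement
floor, and the weakening guarantees two properties the pipeline relies on
(verified by property tests):

- monotonicity: extending a helix by a stacked Watson-Crick pair never
  raises the energy (min |WC stack| 0.93 > terminal penalty 0.45);
- global floor: the perfect reverse-complement duplex bounds every
  admissible structure's energy from below.

Loop penalties are affine: bulge(l) = 3.20 + 0.60 (l - 1) and
interior(t) = 1.70 + 0.50 (t - 2) kcal/mol with t the total unpaired count;
dG_init = 4.09, terminal AU/GU = 0.45. `max_loop_side` defaults to 40,
which never binds inside the anchored search window (window length =
microRNA length + 16 <= 42): unpaired runs are effectively bounded by the
window alone. The cap still guards `score_structure` against pathological
user-supplied structures. Affinity of the penalties is what lets the
all-anchors profile use exact prefix-minimum recurrences (below); a
user-supplied non-affine table transparently falls back to the per-anchor
exact kernel.

## Anchored minimisation

The anchor of a duplex is the mRNA position paired with the 5'-most paired
microRNA nucleotide. `anchored_minimum` finds the minimum-energy admissible
structure at a given anchor by dynamic programming over states
(mi_pos, t_pos, helix-state, c), where helix-state records whether the
current helix has reached length 2 and c in {ordinal 1..7} union
{G:U count 0..4} encodes the two G:U rules exactly. Ties are broken by
(energy, fewer pairs, first-reached in a fixed scan order); the result is
bit-deterministic. The per-anchor 3'-side search window is
[anchor - span, anchor] with span = microRNA length + 15.

Two implementations exist and are cross-checked against each other and
against exhaustive enumeration on small instances:

- an exact per-anchor kernel with backpointers (used for representative
  structures and seed-forced optimisation);
- an all-anchors profile kernel that computes, for every UTR position, the
  minimum energy over all structures and over structures starting at
  microRNA position 1 or 2, using running prefix minima for the three loop
  channels (target bulge, microRNA bulge, interior); with affine penalties
  these recurrences are exact. A 100-nt UTR profiles in ~5 ms.

Seed preference: where the first seven microRNA bases can form a perfect
Watson-Crick helix at an anchor (seed region), seedless structures at that
anchor are discarded; the profile then records the best seed-forced
structure (`prune_anchor_group` implements the same rule on explicit
structure lists).

## Candidate zones

raw_energy[p] is the pruned anchored minimum at p, or 0.0 where no
admissible structure anchors (0.0 is maximally unfavorable since real
energies are negative; such positions break runs). Smoothing is a centred
window of 3, truncated at the ends. With E_perfect the perfect-complement
energy, zones are maximal runs with smoothed energy <= x * E_perfect
(x = 0.24); within a run, eligible representatives have raw energy
<= y * E_perfect (y = 0.25) and a 5'-most pairing at microRNA position 1 or
2; the minimum-energy eligible structure represents the zone, and the zone
interval is the run extended to cover the representative's target footprint
(this makes downstream overlap merging well defined). Runs without an
eligible representative are dropped. Note the ratio convention: both
energies are negative, so a *larger* x is the stricter cut, and tightening x
can split a zone in two — zones nest under tightening but their count is not
monotone. Threshold comparisons carry a 1e-9 kcal/mol slack because the two
kernels and the Python scorer accumulate floating-point terms in different
orders.

Merging unions intervals that share at least one position; the constituent
with the highest classifier score contributes the representative and score
of the merged zone. Adjacent-but-disjoint zones stay separate.

## Features

43 canonical features cover pairing extent (seed 8-mer pairings, 3'-end
pairings, the 3'-end run with a two-unpaired budget, longest stretch, total
pairings, G:U count, binding asymmetry over the terminal 8-mers with a
pseudocount (paired3' + 1)/1 when the 5' side is empty), per-strand bulge
statistics (a bulge is a maximal unpaired run strictly between paired
positions of one strand; an interior loop contributes one bulge to each
strand; symmetric bulges have equal counts on both sides), positional
features (the anchor's percentile bin 1..100 via ceil(100 anchor/|UTR|);
t1/t9 site nucleotides read through the pairing register, projecting
unpaired positions from the nearest 5'-side pair and encoding
{none, A, C, G, U} as 0..4; the t1/t9 "S/W" indicators flag A or U,
following the training convention rather than IUPAC lettering), and
composition (G+C of site and 50-nt flanks; G+C ratio microRNA/site, with a
G+C-free site treated as carrying half a G/C base; site-vs-20-nt-upstream
and first-8-vs-last-8 G+C differences; CpG counts in site and 20-nt flanks,
counted as occurrences of 5'-CG-3', which is alphabet-independent).

Compactness is mean(n/miRLen, n/tsLen) for n pairs; when the site is
shorter than the microRNA the mean is multiplied by tsLen/miRLen, which
keeps the range [0, 1], continuity at tsLen = miRLen, and monotonicity in n;
the value is 1 exactly when both strands are fully paired. Zero pairs give 0.

RISC-accessibility features require an intramolecular folding backend; a
registration hook (`register_accessibility_hook`) is the only surface, and
the catalogue omits them by default.

## Feature selection

ReliefF uses range-normalised Manhattan distance, k = 10 nearest hits and
misses, and all instances (deterministic; a seeded subsample is available).
Constant features contribute zero difference. CFS maximises
merit(S) = k r_cf / sqrt(k + k (k - 1) r_ff) with feature-class and
feature-feature symmetrical uncertainties computed on equal-frequency
discretised features (min(10, sqrt(n)) bins), searched best-first with a
stop after 5 consecutive non-improving expansions; ties break
lexicographically. On <= 12-feature tables the search is verified to attain
the exhaustive-search optimum. Equal-frequency discretisation gives noise
features a small positive uncertainty, so on pure-noise tables the optimal
subset can exceed two features while its merit stays near zero; the tests
assert oracle equivalence and small merit rather than a subset size.

## Classifier and calibration

MultiBoost trains T = 200 decision stumps in ceil(sqrt(T)) = 15
subcommittees (boundaries ceil(k T / n_sub)). Within a subcommittee,
AdaBoost.M1: the base learner picks the stump minimising weighted error over
all features and midpoints between consecutive distinct values, ties broken
by (error, feature index, split position, polarity); misclassified weights
scale by 1/(2e), correct by 1/(2(1-e)), floored at 1e-8; alpha =
ln((1-e)/e). A subcommittee terminates early on e >= 0.5 (stump discarded)
or e = 0 (stump kept with alpha = ln(1e10)). At each boundary, weights
restart by continuous-Poisson wagging (standard exponential draws,
standardised to sum n). With one subcommittee the procedure is exactly
AdaBoost, which the tests verify stump-for-stump against an independent
loop. Scores map the committee margin to [0, 1] via (margin/sum(alpha)+1)/2;
an empty committee scores 0.5.

Cross-validation is stratified (shuffled folds, seeded); fold models use
seeds derived as (seed * 100003 + 7919 (fold+1)) mod 2^31. ROC and AUC come
from scikit-learn; the Mann-Whitney rank formulation serves as the test
oracle. The sensitive threshold is the smallest score whose out-of-fold
false-positive rate is < 5%; the specific threshold the smallest with
FPR <= 1% (and >= the sensitive one). Thresholds are placed just above the
critical negative score (`nextafter`), so ties fall below. Because the
threshold is an empirical quantile of roughly n/2 out-of-fold negatives, its
true FPR fluctuates around the nominal bound with sd ~ sqrt(p(1-p)/n_cal);
a fresh-sample measurement adds sqrt(p(1-p)/n_fresh). The acceptance checks
use the two-stage tolerance 2 sqrt(p(1-p)/n_cal + p(1-p)/n_fresh); under
the default problem size (2000-row table, 2000 fresh negatives) the measured
rates centre on 5% and 1% with sd ~1.0 and ~0.4 percentage points.

## Pipeline and post-filters

For every (microRNA, UTR) pair: profile -> zones -> features ->
committee score -> merge -> ranked records. A record's seed flag marks a
perfect Watson-Crick 7-mer match (microRNA positions 1-7 or 2-8, no G:U)
anywhere in the merged zone interval; the conserved-seed flag requires a
6-mer match (positions 2-7) inside the interval whose alignment columns are
gap-free and identical across all species of the panel, with the reference
additionally matching microRNA base 1 (3' of the 6-mer on the site) or base
8 (5' of it). Stringency is "spec" at or above the specific threshold,
"sens" at or above the sensitive one, else "below". Class and stringency
subsets nest by construction.

Training-set construction from validated intervals: candidates of a site's
microRNA family that overlap the interval (>= 1 shared position) contribute
one positive — the energetically most favorable; the most favorable
non-overlapping candidate of the same interaction contributes one negative.
Sites without any candidate are skipped with a log entry.

Proteomics evaluation (`psilac_accuracy`) is the fraction of predicted
interactions with measured log2 fold change < -0.1; unmeasured interactions
are excluded from both counts, and zero measurable predictions yield NaN
with a warning.

Coordinates are 1-based inclusive internally; BED export is 0-based
half-open, GFF3 1-based inclusive; transcripts are the coordinate system.

## Synthetic data

The corpus generator emulates the tool's input surface, not real biology:
i.i.d. background sequence at a configurable G+C content (optionally a mild
first-order Markov chain), implanted sites of four qualities (perfect
reverse complement; seed-only = reverse complement of positions 1-8 with
random remainder; 3'-compensatory = complementary block for positions 10..m
with a deliberately mismatched 9-nt seed region; dinucleotide-shuffled
complement via Altschul-Erickson), species copies derived by i.i.d.
substitution at a per-species rate (gap-free; gapped alignments are
exercised by hand-built fixtures), labeled Gaussian feature tables with
per-feature mean shifts (defaults give a "moderate" separation,
cross-validating near AUC 0.85), and fold-change tables realising a chosen
down-regulated fraction. Real 3'UTRs differ in composition beyond G+C,
site density, and alignment structure, so passing tests demonstrate
correctness of the machinery and calibration under controlled conditions —
not predictive accuracy on real transcripts, which requires real validated
training data.

## Numerical and degenerate-input conventions

Energies are float64 throughout; profile/exact-kernel agreement is asserted
to 1e-9. Empty inputs return empty outputs with warnings; single-class
tables, degenerate (constant) score distributions, unknown feature names,
ragged alignments and out-of-range anchors raise with diagnostics. All
stochastic steps accept explicit seeds and are bit-reproducible.

## Known limitations

- The energy table is a plausible Turner-style parameterisation, not a
  fitted or literature-complete one; absolute kcal/mol values should not be
  interpreted, only relative ones.
- No intramolecular folding: accessibility features are a hook only.
- The conserved-seed filter assumes per-transcript alignments with a
  designated reference row; no liftover or whole-genome alignment parsing.
- Genome-scale throughput was not a design goal; the profile kernel handles
  ~200 UTR-nt per millisecond per microRNA on one core, adequate for
  transcript panels rather than whole transcriptomes.
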