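# Methods

## Scope and model

`mirprio` implements a desk-scale miRNA–target prioritization pipeline
and the downstream qPCR relative-quantification analysis. The pipeline
treats target recognition as seed-driven: the seed is mature-miRNA
positions 2–7 (1-based, biological convention; everything else in the
package is 0-based half-open). Database mining is explicitly an input —
evidence tables (database-hit counts, prior cancer/CRC/gene
associations, direct validation, miRNA annotation validity) are supplied
by the caller, never fetched.

## Seed scanning

Every target hexamer is aligned antiparallel to the seed. Per position
the pair is Watson–Crick, G:U wobble, or non-pairing. Wobbles are
consumed 5′→3′ along the seed up to a budget (default 1); wobbles beyond
the budget count as mismatches, which unifies the manual-alignment rule
(at most one seed mismatch) with the constrained-search setting (one
G:U wobble). Site classes: 7mer adds a Watson–Crick pair at miRNA
position 8; 8mer additionally requires an A on the target opposite
position 1 (the A is an unpaired anchor, still counted in the site
span). Overlapping sites are all reported; deduplication is left to
report-level options because no principled tie-break exists at scan
level.

One subtlety worth knowing: a single target substitution opposite a
seed G or U produces a *wobble*, not a mismatch. Recovery tests that
want a true mismatch must substitute opposite an A or C seed position.

## Duplex and folding energies

Both the heteroduplex score and the internal folder use one embedded
nearest-neighbor stack table: the ten published Watson–Crick RNA/RNA
ΔG°₃₇ stack free energies (kcal/mol). Stacks containing a G:U pair are
scored with a single uniform term (−1.3 kcal/mol). The full wobble
tables are context-dependent; collapsing them to a constant keeps the
table small, hand-summable in tests, and swappable (it is one module
constant), while preserving the qualitative ordering that wobble stacks
stabilize less than canonical stacks. Unpaired duplex positions cost
+0.5 kcal/mol each. Note this penalty means a duplex with a single weak
stack and several unpaired positions can score slightly above zero;
fully paired duplexes are always ≤ 0.

The internal folder is a Nussinov-style dynamic program over nested
structures scored by stack terms only (loops and unpaired bases are free
— no loop-entropy penalties), minimum hairpin loop 3 nt, no pseudoknots.
Consequences: ΔG ≤ 0 always, isolated pairs contribute nothing, and the
optimum is exactly enumerable at small n, which the tests exploit
(exhaustive enumeration up to length 14). Traceback tie-breaks are
deterministic: leave the 5′-most base unpaired first, then pair to the
5′-most partner, preferring stacked continuations; rerunning a fold is
byte-stable. An adapter to ViennaRNA's thermodynamic engine satisfies
the same `FoldResult` contract for callers who want Turner-complete
energies; every downstream rule takes the fold backend as a parameter,
so swapping engines changes no contract. Absolute ΔG values from the
internal folder are systematically shallower than Turner-model values
(no dangles, no coaxial stacking, no loop penalties); the pipeline's
rules compare windows folded by the *same* backend, which is the use
case the defaults target.

## Accessibility rules

Three windows are folded per site: the site alone, site + 70 nt
upstream, site + 70 nt downstream (windows truncated at UTR ends are
used as-is, with the achieved flank lengths recorded; never padded).
The energy-gap rule passes when |ΔG(site) − ΔG(flank window)| ≥
10 kcal/mol on *either* side; because the helpful direction is
arguable, both signed differences are reported and the pass flag uses
the absolute value. Folding the flank jointly with the site is the
default (`flank_mode="alone"` folds the bare flank instead).

The site ± 30 nt window is folded, decomposed into stems (maximal
helices) and loops, and labelled. Loop lengths count unpaired
nucleotides (an interior loop is the sum of both sides); destabilising
elements are hairpin ≥ 11, interior ≥ 9, bulge ≥ 7, multibranch ≥ 11,
exterior segment (free end or joint between exterior stems) ≥ 11 nt.
Stems are stabilising. A junction with zero unpaired nucleotides emits
no loop element, so elements always partition the positions: loop
lengths + 2 × stem pairs = window length (a tested invariant).

The −6 kcal/mol occlusion rule defaults to substructure granularity:
any stem whose enclosed span overlaps the site and whose summed stack
energy is below −6 kcal/mol marks the site as occluded (under
stack-only scoring the stem's closed loops contribute nothing, so the
stem sum is the substructure energy). `inhibition_granularity="window"`
instead tests the whole ±30 window MFE.

## Prioritization

Gating keeps pairs whose miRNA is validly annotated and that have
either a known cancer association or ≥ 2 reporting databases. The four
decision flags are: two-databases (db_count ≥ 2); energy (energy-gap
pass OR DSE present — configurable to AND); constrained-search (a
tri-state — *pass* when any 7mer/8mer site meets the duplex cutoff,
*near-miss* when sites exist but none do, *fail* otherwise; near-miss
counts as positive only when configured); direct validation. Inclusion
requires DSE present AND prior gene association AND prior CRC
association. Selection requires inclusion plus ≥ `min_flags` (default
2) positive flags; the default is a documented heuristic consistent
with the packaged seven-pair reference matrix, where every row carries
exactly two positive flags. Aggregation is order-invariant (outputs
sorted by gene, then miRNA) and pure, both property-tested.

## qPCR analysis

Efficiency: Cq is regressed on log₁₀ of relative concentration
(−log₁₀ dilution factor); E = 10^(−1/slope). A perfect-doubling assay
on a 5-fold series gives slope −1/log₁₀2 = −3.3219 and E = 2 exactly.
Fits need ≥ 3 distinct dilutions; a non-negative slope is an error, and
fits outside E ∈ (1, 2.3] are flagged as not accepted.

Normalization: ΔCq = Cq(target) − arithmetic mean of reference Cq
values, which is the geometric mean of the linear reference quantities
(the standard multi-reference normalizer); a literal geometric mean of
Cq values is available for sensitivity checks. Optional efficiency
correction rescales each assay to a common log₂ basis via
log₂(E)·Cq before differencing (E = 2 is a no-op); the exact published
correction formula is not standardized, so this choice is documented
rather than asserted. Samples missing any reference are excluded with a
logged reason; missing targets remain not-detected and are dropped from
comparisons, never imputed as a ceiling Cq.

Comparisons: ΔΔCq is a difference of group means (medians optional);
fold = 2^(−ΔΔCq), strictly decreasing in ΔΔCq, with downregulation
displayed as the reciprocal ("6.20-fold down") while machine output
keeps the signed value. Paired comparisons use the Wilcoxon signed-rank
test on lesion-vs-corresponding-normal pairs; independent comparisons
use Mann–Whitney U. The N0-vs-N+ contrast first computes each
carcinoma's ΔΔCq against its own normal, then compares those per-sample
values by Mann–Whitney U. Exact p-values are used for n ≤ 12 without
ties, otherwise the normal approximation with tie correction and no
continuity shift (so identical groups give p = 1 exactly); all-zero
paired differences short-circuit to p = 1. Spearman correlation (average
ranks on ties, two-tailed) serves both the miRNA–mRNA anticorrelation
question and the ordinal level-of-malignancy trend (normal = 0,
adenoma = 1, adenoma with early carcinoma = 2, CRC N0 = 3, CRC N+ = 4).
No multiple-testing correction is applied by default, matching the
p ≤ 0.05 convention of the validation design; a Benjamini–Hochberg
helper exists for sensitivity analyses.

## Synthetic data: what it emulates, and what it does not

`SyntheticSpec` defaults encode the study design the pipeline targets:
five groups at cohort sizes 23/11/13/10/13, Cq noise 0.25 cycles,
assay baselines drawn once in [18, 32] cycles, 200-nt UTRs at 40% GC
with one planted site per UTR (the packaged table of seven mature miRNA
sequences supplies the seeds). Planted sites write the exact reverse
complement of the seed over i.i.d. background, with requested
mismatches/wobbles introduced at recorded positions and the
class-determining context (position-8 partner, A anchor) pinned
explicitly so the truth table is exact. Cq tables are
baseline + group shift + Gaussian noise, with reference assays forced
to shift 0; CRC samples carry a paired normal link (round-robin over
the normal samples). Rank coupling between a miRNA and a gene assay
uses a Gaussian copula with ρ_pearson = 2 sin(π ρ_spearman/6),
degenerating to exact comonotonicity at ρ = ±1; the coupling is planted
on the raw Cq of the two assays.

The generator does **not** emulate FFPE RNA degradation, technical
duplicate wells, amplification-curve artefacts, assay dropouts
correlated with group, or between-patient baseline heterogeneity.
Passing recovery tests therefore demonstrate correctness of the
computations under an idealized noise model, not robustness to
real-tissue artefacts.

A quantitative consequence of the noise model worth stating: with noise
on every assay (targets and both references), a per-sample ΔCq carries
sd = σ√1.5 ≈ 0.306 cycles at σ = 0.25, so the ΔΔCq estimate at
n = 10/group has sd ≈ 0.137 cycles and the recovered fold for a true
4-fold shift lands within [3.5, 4.6] in only ~85% of replicates (the
acceptance script reports the measured rate). Detection is unaffected —
the 2-cycle effect gives Mann–Whitney p < 0.01 essentially always. A
tighter recovery band requires lower noise, larger groups, or modelling
technical replicates, not a different estimator.

## Problem sizes used in tests

Oracle equivalence runs 100 random miRNA/UTR pairs (UTR ≤ 200 nt);
planted-site recovery 500 sites over 100 UTRs; decomposition checks
1,000 random structures (length < 80); folder optimality 50 sequences
of length ≤ 14 against exhaustive enumeration; statistical recovery
200 replicates each. These sizes give exact oracles and stable Monte
Carlo rates while keeping the full suite fast on one CPU.

## Known limitations

- Stack-only folding underestimates loop destabilization; DSE calls are
  driven by the dot-bracket geometry, which is the part the labels use.
- The uniform wobble-stack constant is a first-order simplification;
  swap the table or the ViennaRNA backend where wobble context matters.
- "One unpaired position in the seed" is read as one unpaired
  nucleotide, not one unpaired block.
- The constrained-search significance statistic of pattern-based tools
  is not implemented; the reported flag is the energy-cutoff pass (with
  the near-miss tri-state), a documented divergence.
- Cross-species conservation is carried as an input evidence flag, not
  computed.
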