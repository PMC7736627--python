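# Methods

`mitocomp` implements a comparative analysis of congeneric fish mitochondrial
genomes: annotation-table accounting, base-composition asymmetry, codon usage,
synonymous/nonsynonymous divergence, control-region tandem repeats, and a
distance-based phylogeny on the concatenated protein-coding genes. This note
records the models, conventions, and numerical choices, and what the synthetic
data do and do not establish.

## Coordinate model and the bundled reference tables

All coordinates are 1-based inclusive on the heavy (H) strand, the convention
of published mitogenome annotation tables; 0-based half-open arithmetic is
confined to sequence slicing. Features never wrap across the circular origin
in the canonical vertebrate layout (tRNA-Phe first, D-loop ending at the last
base), so wrap-around features are rejected rather than supported half-way.
Element names are resolved through a frozen registry with aliases
(`ATPase6`≡`ATP6`, `Cyt b`≡`CYTB`, `O_L`≡`OL`, …) because published labels are
inconsistent across tables and prose.

The package ships the annotation tables of the three *Sebastiscus* rockfish
mitogenomes (*S. tertius* 16910 bp, *S. albofasciatus* 17056 bp,
*S. marmoratus* 17580 bp) as a TSV: per element, the published start/end for
each species plus the published Size and Intervening-spacer columns, the
per-PCG amino-acid counts, and initiation/termination codons. Six printed
Size cells contradict the printed coordinates of their own rows (all tRNAs,
e.g. tRNA-Cys 65 vs a 5340..5406 span of 67). Because the spacer column is
consistent with the coordinates for all 114 adjacent cells and the max-end
genome lengths match the published totals, the coordinates are treated as
authoritative and the six cells are frozen as an errata list
(`reference.SIZE_ERRATA`); tests assert exact agreement everywhere else and
assert that the errata set is exactly the set of internal contradictions.

## Composition and skew

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), computed on the strand the
sequence is given on; A+T content is a percentage of unambiguous bases.
IUPAC ambiguity codes are excluded from the four counts and from skew
denominators and reported separately; a skew whose denominator is empty is
*undefined* (`None`), never zero. Codon-position partitions concatenate the
13 PCGs on their coding strands in table order, exclude incomplete terminal
stop bases (T/TA), include complete terminal codons, and split positions
1/2/3. Whole-genome and per-region summaries stay on the H-strand, so the
strand asymmetry of the one L-strand PCG (ND6) is visible rather than
normalized away.

## Codon usage

Translation follows the vertebrate mitochondrial code (NCBI table 2: TGA=Trp,
AGA/AGG=stop, ATA=Met), with the recognized alternative initiators (GTG, ATA,
ATT, …) rendered as Met at position 1. Incomplete stops are resolved from CDS
length mod 3: remainder 1 → terminal `T`, remainder 2 → terminal `TA`,
remainder 0 → a complete terminal codon (counted as the stop when it is one).
Sense-codon counts include the initiator and exclude the stop; under that
reading the published per-gene amino-acid column sums to 3800 over the 13
PCGs in each species, which the tests verify from the sizes alone.

RSCU(codon *j*, family *i*) = n_i·X_ij / Σ_j X_ij. Stop codons are excluded
from RSCU and amino-acid usage. Leu and Ser are split into their two- and
four-fold sub-families (Leu(UUR)/Leu(CUN), Ser(UCN)/Ser(AGY)) by default, the
convention of RSCU plots, with a switch to pool six-fold families. A family
observed zero times has undefined RSCU, reported as 0 with a flag.

## Divergence: p-distances and NG86

p-distances use pairwise deletion of ambiguous sites; the codon-position
variant pools positions {1,2} and reports position 3 separately, on in-frame
alignments with incomplete stops trimmed.

Ka/Ks uses Nei–Gojobori (1986) counting, in the normalized form: at each
codon position the three single-base changes are classified under the
mitochondrial code, changes creating stops are excluded from the denominator,
and the position contributes exactly one site split between S and N. This
makes S + N = 3·(codons) an exact identity, kept in rational arithmetic.
Multi-difference codons are averaged over all minimal substitution pathways
with stop-transit pathways excluded (all pathways weighted equally); in the
degenerate case where every pathway crosses a stop, the average falls back to
all pathways and the result is flagged. pS and pN receive the Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3), undefined (flagged) at p ≥ 3/4.
Classification: Ka/Ks < 1 purifying, = 1 (±1e−9) neutral, > 1 positive;
Ks = 0 leaves the ratio undefined. The estimator assumes equal mutation rates
across change types; no transition/transversion or rate-heterogeneity
correction is applied, which is the classical NG86 trade-off.

## Tandem repeats

The detector targets slipped-strand repeat arrays in control regions, where
the consumed outputs are unit length and copy number. For each candidate
period *d* it scores the self-match profile seq[i] vs seq[i+d] (+1 match, −3
mismatch), extracts maximal positive-scoring segments, and converts a segment
of matched length L into an array of span L+d, i.e. (L+d)/d copies. The
consensus unit is a per-offset majority vote; identity is the mean per-copy
match fraction against the consensus. Overlapping calls at harmonically
related periods are resolved by highest copies×identity, then smallest
period; the whole procedure is deterministic. Defaults: min_period 10,
max_period 600, min_copies 1.8, min_identity 0.8, and a minimum of
2·min_period matching positions per segment — the last threshold is what
keeps i.i.d. sequence from yielding chance calls at short periods (a −3
mismatch penalty with a 20-match floor puts the expected number of chance
segments far below one per control region). Substitutions within copies are
modeled; indels are not — an indel truncates the matched segment rather than
being bridged. Copy numbers are reported fractionally (partial terminal
copies included).

## Phylogeny

The supermatrix concatenates the 13 PCGs in canonical order on their coding
strands, incomplete stops trimmed, and requires per-gene length identity
across taxa (true for congeners here); length mismatches raise with an
instruction to align externally rather than silently mis-stacking codons.

TN93 distances use the Tamura–Nei (1993) closed form with empirical base
frequencies averaged over the two sequences (verified against an independent
implementation during development to ~1e−11). Saturated pairs (non-positive
logarithm argument) fall back to the p-distance with a flag. Gamma and
invariant-site corrections are deliberately omitted: the shape parameters are
not recoverable from the published material, and the tree's acceptance
surface is topology, not branch lengths.

Neighbor joining is the Saitou–Nei Q-criterion agglomeration, with two
determinism guarantees: Q ties break on the lexicographically smallest
cluster-label pair (clusters labeled by their smallest leaf), and negative
branch lengths are clamped to zero. NJ is consistent on additive matrices,
which the tests exercise on 100 seeded random trees of 5–8 taxa with exact
topology recovery. Bootstrap resamples columns with replacement under a
seeded generator; support is the percentage of replicate NJ trees containing
each internal bipartition. Trees are stored unrooted (bipartition-based
operations are root-invariant); a clade constraint is satisfied iff it is one
side of some edge. Likelihood and Bayesian tree building are out of scope:
NJ on TN93 is the in-package surrogate whose claims are the topology
constraints (here: the two congeners forming a sister pair, and ingroup
monophyly against the outgroup).

## Synthetic data: what it emulates, what it does not

Defaults are chosen once to mirror the study system: the *S. tertius* element
sizes (hence exactly 3800 sense codons over the 13 PCGs), A+T 55%, AT-skew
+0.05 and GC-skew −0.28 on the H-strand, a 22 bp × 6 control-region repeat at
2% per-base noise, ω = 0.05, κ = 2, and the tree
`((ST:0.02,SA:0.02):0.03,SM:0.08,OUT:0.25)` (substitution proposals per
site). Elements are laid out contiguously; the real table's small overlaps
(e.g. ATP8/ATP6, −10 bp) are not reproduced, because overlapping dual-frame
ORFs would constrain the sampler without testing anything the analyses need.
L-strand elements are sampled through the complement so genome-wide skew
targets still hold on the H-strand.

Evolution is codon-level rejection sampling: Poisson(branch × sites) proposal
events, HKY-weighted target bases (transition weight κ), stop-creating
proposals always rejected, nonsynonymous proposals accepted with probability
ω; the initiation codon and terminus are held fixed so the planted start/stop
conventions survive. Non-coding and RNA elements evolve neutrally under the
same proposal process. Every accepted and rejected event class is counted per
branch in the ledger, alongside the planted repeat coordinates and the true
tree, so recovery tests compare against recorded truth rather than
re-simulation. One seed drives a single generator consumed in a fixed
traversal order, making outputs byte-identical across runs.

The ω-recovery calibration (mean NG86 ratio within 25% of ω ∈ {0.1, 0.5}
over 20 replicates of 500-codon genes) is run at κ = 1, the equal-rate regime
NG86's site counting assumes; with κ = 2 the known transition-bias of NG86
would fold an estimator artifact into a generator test. The generator default
stays κ = 2 (typical for mtDNA) for all other purposes. Observed recovery is
within ~3% at both ω values.

What passing these tests shows: the arithmetic, counting, and tree machinery
are correct on data whose truth is known exactly. What they do not show:
robustness to misannotation, indels, alignment error, rate heterogeneity
across sites, or saturation regimes typical of deeper phylogenetic spans —
real-data properties the generator deliberately does not model.

## Degenerate inputs and tie-breaks (summary)

* Empty or all-ambiguous sequence → errors / undefined skews, never silent 0.
* Zero comparable sites (p-distance, TN93) → error naming the condition.
* NG86 with Ks = 0 or p ≥ 3/4 → flagged, ratio undefined, classification
  "undefined".
* Repeat finder on sequence shorter than 2·min_period → error; equal-scoring
  overlapping repeat calls → smallest period, then leftmost start.
* NJ ties → lexicographic cluster pair; star-like inputs resolve
  deterministically.
* Pipeline stages with unmet preconditions (no sequence, <3 taxa, missing
  D-loop) are skipped with a notice in the summary, not fatal.

## Problem sizes

Tests and the acceptance script run on desk-scale inputs: the three bundled
39-row tables; synthetic genomes of ~16.9 kb; 500-codon genes × 20 replicates
for ω recovery; 20 seeded repeat-recovery trials; 100 random additive
matrices (≤8 taxa) for NJ consistency; 100 bootstrap replicates on a
4-taxon × ~11.4 kb supermatrix. The full suite completes in well under a
minute on one CPU.
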