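# Methods

This note documents the models and conventions behind `kaks`: what each
estimator computes, the choices made where the underlying methods admit
variants, what the simulator does and does not emulate, and the numerical
details that affect results.

## The quantities

For a pair of aligned protein-coding sequences, **Ka** is the number of
nonsynonymous substitutions per nonsynonymous site and **Ks** the number
of synonymous substitutions per synonymous site; their ratio
**ω = Ka/Ks** measures selection strength (ω < 1 purifying, ω > 1
positive). All eight estimators consume the same input: a
`CodonAlignment` in which codon columns containing gaps, ambiguous bases
or stop codons in either sequence have been removed whole.

## Input handling and quality control

- Sequences are upper-cased and U is mapped to T; the alphabet is
  restricted to `ACGTN-`.
- Back-translation threads each ungapped CDS through its gapped protein
  alignment codon-by-codon, verifying that every codon translates to the
  aligned residue; terminal stop codons are stripped first because stop
  codons would otherwise contaminate site counting.
- Percent identity is computed over columns where neither sequence has a
  gap; percent gap over all columns (gap in either sequence); the N
  fraction over the pooled non-gap characters of both sequences. The
  identity denominator convention (gaps excluded) is a package decision —
  it makes identity a pure mismatch measure, independent of indel
  content.

## Counting methods

**NG** (equal-weight pathway counting). Synonymous sites per codon are
(number of synonymous single-base changes)/3 summed over positions, with
changes to stop codons counted as nonsynonymous, so that N + S = 3 ×
n_codons exactly; sites are averaged between the two sequences.
Differences are counted by enumerating all orderings of the differing
positions between each codon pair (k differences → k! pathways), with
each single-base step labelled synonymous or nonsynonymous; orderings
passing through a stop codon are discarded and the remainder re-weighted
equally. If *every* ordering crosses a stop (rare), the unfiltered
enumeration is used so the counts stay defined. The two raw proportions
pn = Nd/N and ps = Sd/S are corrected separately with the one-parameter
(Jukes-Cantor) formula d = −(3/4)ln(1 − 4p/3). Proportions at or beyond
3/4 yield NA flags, never exceptions.

**LWL family.** Each codon position is classified non-degenerate (0),
two-fold (2) or four-fold (4) by counting synonymous alternatives (all
three → 4-fold, none → 0-fold, otherwise 2-fold; the three-fold
isoleucine position folds into the two-fold class). Class site totals
L0/L2/L4 are averaged between the sequences. Pathway steps contribute
transition/transversion difference counts half to the class of the
position in the step's source codon and half to that in its destination
codon. Per class, the two-parameter (Kimura) correction splits the
distance into a transition part A_i and a transversion part B_i:

- **LWL**: Ks = (L2·A2 + L4·(A4+B4)) / (L2/3 + L4),
  Ka = (L0·(A0+B0) + L2·B2) / (L0 + 2·L2/3) — two-fold sites are fixed at
  1/3 synonymous, 2/3 nonsynonymous.
- **LPB**: Ks = (L2·A2 + L4·A4)/(L2+L4) + B4,
  Ka = A0 + (L0·B0 + L2·B2)/(L0+L2) — the two-fold transition/transversion
  weighting is data-driven instead of fixed.
- **MLWL/MLPB** repair the arginine irregularity: at the first position of
  CGA, CGG, AGA and AGG the degeneracy table says "two-fold", but the
  synonymous alternative is reached by a transversion (AGR ↔ CGR) while
  both transitions are nonsynonymous — the inverse of the two-fold pattern
  the parent formulas assume. The modified methods swap the
  transition/transversion roles at exactly those four sites when
  accumulating class-stratified counts (the reassignment table is the
  frozen set `ARGININE_SITES` in `kaks.counting`). **MLWL** additionally
  replaces the fixed 1/3 weight with κ/(κ+2), with κ estimated from
  K2P-corrected proportions pooled over all site classes; when that
  estimate is undefined the method falls back to κ = 2 (a conventional
  mammalian value) and proceeds.

## Model-based methods

**GY** fits a 61-state reversible Markov codon model by maximum
likelihood. Off-diagonal rates for single-base changes are π_j times 1
(synonymous transversion), κ (synonymous transition), ω (nonsynonymous
transversion) or ωκ (nonsynonymous transition); multi-base changes have
rate 0. Codon frequencies are F3x4 — products of position-specific
nucleotide frequencies estimated from both sequences, renormalized over
sense codons, with epsilon smoothing of zero positional frequencies. The
generator is scaled to mean rate 1, so the divergence t is measured in
expected substitutions per codon (stated in every output header). The
pairwise log-likelihood Σ log(π_i P(t)_{ij}) is maximized over
(log t, log κ, log ω) with bounded L-BFGS-B from three fixed starting
points (the pairwise surface can be flat in ω at low divergence);
transition probabilities come from an eigendecomposition of the
symmetrized generator. Fitted parameters convert to rates by the
mutational-opportunity convention: Ka = t·ρ_N/(3·f_N) and
Ks = t·ρ_S/(3·f_S), where ρ_N/ρ_S are the scaled generator's
nonsynonymous/synonymous flux fractions and f_N/f_S the same fractions at
ω = 1 (κ and π held fixed). This matches the site convention of the
counting methods, so cross-method comparisons are meaningful.

**YN / MYN** are iterative approximate methods built from the same
ingredients:

1. κ (YN) or κ_R/κ_Y (MYN) is estimated from nucleotide comparisons at
   positions that are non-degenerate or four-fold degenerate in both
   sequences — sites whose synonymous status does not depend on the
   transition/transversion ratio — via the K2P correction (YN) or a
   numerical inversion of the Tamura-Nei two-transition-class model
   (MYN). Undefined estimates fall back to 2.
2. Sites: each single-base mutational opportunity is weighted by its κ
   class multiplier and the positional frequency of the target base
   (stop targets excluded), preserving N + S = 3 × n_codons.
3. Differences: pathway enumeration as in NG, but pathways are weighted
   proportionally to the product over steps of the κ-class multiplier and
   ω per nonsynonymous step.
4. Correction: K2P on the synonymous and nonsynonymous
   transition/transversion proportions (YN); Tamura-Nei with separate
   purine/pyrimidine transition classes for MYN, using whole-sequence
   base frequencies. When the three-class inversion is unidentified
   (an empty difference class), MYN degrades to K2P for that component
   rather than reporting NA.
5. ω is updated to Ka/Ks and steps 3–4 repeat until the relative change
   falls below 1e-8 or 100 iterations.

The Tamura-Nei inversion solves for (d, κ_R, κ_Y) from the observed
(A↔G, C↔T, transversion) proportions by root-finding on the expected
proportions of the 4-state model, which keeps the recovered κ's on the
same per-target multiplier scale used everywhere else in the package.

## NA semantics

Two distinct rules, mirroring two distinct analysis stages:

- **Consistency analyses** eliminate a gene whenever any method's Ka or
  Ks is NA (saturated correction, zero denominator, non-convergence).
- **Classification** maps NA Ka to 0 before sorting, because undefined
  estimates overwhelmingly come from (near-)identical pairs.

Ks = 0 with Ka > 0 yields an NA ratio, not infinity.

## Consistency statistics

Per gene, the divergence index over the eight methods is either the
sample (n−1) standard deviation over the mean or the range over the mean
(the sd convention is not intrinsic to the definition; the range form is
convention-free and serves as the cross-check). The shared-gene
percentage between two methods ranks genes by a statistic under each
method, takes the top (fast) or bottom (slow) ⌊cutoff·n⌋ genes, and
reports 100·|intersection|/⌊cutoff·n⌋; ties break deterministically by
(value, gene_id). Canonical cutoffs are 5–50% of the gene set; others are
permitted but flagged. The Ka-vs-Ks index comparison uses the two-sided
rank-sum test, exact (no ties, combined n ≤ 20) or normal-approximated
with tie correction.

## Classification and the species network

With k = ⌊cutoff·n⌋ (default cutoff 10%), slow = ranks 1..k, fast = the
top k, intermediate = the k genes centered on the median rank (window
start ⌈(n−k)/2⌉, chosen because "middle" admits several readings and the
centered window is symmetric and deterministic). Between two species the
class coefficient is |shared genes of that class| / |shared genes|;
"both" is the fast and slow coefficients summed. Because "the largest two
coefficients for each pair" is ambiguous, both retention modes are
shipped: per-species top-2 marking (default) and per-pair top-class; the
edge list records which edges each mode retains.

## Enrichment and expression

Each category with at least one class gene gets a 2×2 Fisher exact test
(class/background × in/out of category), two-sided by the
probability-not-exceeding-observed rule. Holm (Bonferroni step-down)
correction is applied within one annotation level (the family an analyst
would test together); the default threshold 0.1 applies to the adjusted
p, with a switch for raw p. Enrichment additionally requires observed >
expected, so depleted categories never flag. The background defaults to
all genes with an estimated Ka. Expression comparisons are rank-sum tests
of TPM between class pairs, with per-class means and medians reported
(skewed expression distributions make the mean exceed the median).

## The simulator

`simulate_pair` draws ancestral codons i.i.d. from π and evolves two
independent lineages for t/2 each under the scaled generator (equivalent,
by reversibility, to one lineage at distance t). One root seed plus a
fixed per-gene splitting rule makes every gene reproducible independent
of iteration order. `expected_rates` computes the exact model-implied
Ka/Ks with the same flux/site formulas the GY conversion uses, giving
every estimator a ground truth.

Default study conditions for the cross-method experiments: 300-codon
genes, t = 0.5 substitutions per codon (roughly a human–rodent-like
coding divergence), κ = 2, per-gene ω drawn uniformly from [0.05, 0.5]
(predominantly purifying selection, as in real mammalian ortholog sets);
parameter-recovery experiments use 500 codons at t = 0.3 with ω = 0.25.
The simulator deliberately omits indels, among-site rate variation,
codon-position-specific GC evolution and alignment error, so passing
tests demonstrate correctness of the estimators and statistics under the
model, not robustness to real-data artifacts such as misalignment or
annotation error.

## Problem sizes and numerics

The packaged experiments use 500 genes for the consistency analyses, 100
genes per divergence level across t ∈ {0.1, 0.3, 0.6, 1.0, 1.5}, and 100
replicates for parameter recovery — sizes at which the qualitative
patterns (Ka's cross-method dispersion below Ks's; ranking overlap rising
with cutoff; Ka overlap stabler across divergence) are decisively
resolved. `scripts/acceptance.py` re-runs exactly these experiments from
scratch. Other numerical choices: GY convergence tolerance 1e-10 in
log-likelihood with parameter bounds t ∈ [1e-4, 60], κ ∈ [0.05, 100],
ω ∈ [1e-4, 60]; YN/MYN fixed-point tolerance 1e-8; TN93 inversions
rejected beyond d = 30 or when residuals exceed 1e-8; likelihood
probabilities clamped at 1e-300.

## Known limitations

- Pairwise only: no phylogeny, no branch/site models, no likelihood-ratio
  tests.
- The standard genetic code only.
- Counting methods inherit their published biases (e.g. NG's neglect of
  the transition/transversion ratio biases ω downward by roughly 15–20%
  at κ = 2); the package reports what the methods compute rather than
  recalibrating them.
- Gamma-distributed rate variation across sites is out of scope.
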