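# Methods

This package implements a two-track analysis of the modular evolution of
the F1Fo ATP synthase: (1) co-evolution clustering of subunit phylogenetic
profiles, and (2) canonicalization and frequency/significance analysis of
bacterial transcription units (TUs) containing the synthase genes.  Both
tracks run on synthetic data whose generators encode realistic study conditions,
so every stage is testable end to end without database access.

## Phylogenetic profiles and distances

A phylogenetic profile is a binary vector `X ∈ {0,1}^n` recording presence
or absence of a gene's homolog in each of `n` genomes.  Presence is called
from best BLASTP hits at an E-value strictly below a threshold (default
10⁻³; 0.1, 10⁻², 10⁻⁴ as alternates — profiles are nested across
thresholds, which is property-tested).  The reference species' own genes
are present in its column by definition.

Six distances between profile pairs `X, Y`:

| measure | definition | notes |
|---|---|---|
| Minkowski `L_p` | `(Σᵢ |xᵢ−yᵢ|^p)^{1/p}` | `p=1` Manhattan, `p=2` Euclidean; on binary data = (Hamming)^{1/p}, so `d₁ = d₂²` |
| Jaccard | `1 − |X∧Y| / |X∨Y|` | empty union → 0 (identical all-absent profiles are not distant) |
| mutual information | `1 − I(X;Y)` | plug-in cell probabilities, log₂, `0·log 0 := 0`, so `I ≤ 1` bit and `d ∈ [0,1]` |
| Kendall tau | discordant index pairs / `n(n−1)/2` | binary values used directly as rankings; tied pairs concordant; on binary data the discordant count is `n₁₀·n₀₁` |
| Pearson | `1 − |cor(X,Y)|` | constant vector → 1 (no correlation information) |

Conventions the formulas do not fix — the mutual-information log base, the
Kendall tie rule and normalization, the Jaccard empty-union value, and the
Pearson constant-vector value — are our documented choices, applied
uniformly.  The distance matrix is computed from the 2×2 contingency
counts of every pair via matrix products and agrees elementwise with the
pairwise definitions, including the diagonal: the mutual-information
self-distance is `1 − H(X)`, nonzero for unbalanced vectors, and the
Pearson self-distance of a constant gene is 1.  Clustering consumes
off-diagonal entries only, so these diagonal conventions never affect the
merge tree.

## Module detection

Hierarchical clustering uses an agglomerative merge tree (scipy linkage;
average linkage by default, configurable to single/complete/ward — the
linkage criterion is a package choice) cut to exactly `k` nonempty groups
for `k` in 5..50 (step 5).  Cuts of one tree are nested: the partition at
a larger `k` refines the one at a smaller `k` (tested).  PCA grouping
projects the column-centered binary matrix onto the top 2 components and
partitions the scores with seeded k-means; the grouping mechanism behind
the 2-D embedding is likewise a package choice.  The gene–gene Pearson
correlation matrix flags constant genes explicitly rather than returning
silent NaNs.

Robustness across the six measures is formalized as co-clustering
consensus: over all (method, k) runs, the fraction of runs in which a gene
pair shares a group; gene sets whose every pair co-clusters in ≥ f of runs
(default f = 0.8) are grown greedily in gene order.  Greedy growth makes
the sets deterministic and disjoint; with identical runs it returns that
partition at any f.

## Transcription-unit canonicalization

Gene annotation tables carry (genome, replicon, gene id, position index,
strand, TU id, subunit label).  The position index counts along the
replicon over *all* genes, so a gap between recorded genes implies
unrecorded genes in between.  Raw TU predictions are fragmented, so
adjacent units are merged transitively when they share a strand and their
position indices are consecutive; a unit consisting only of foreign
("other") genes is an interrupting run, never a merge partner.

Unit strings are then normalized in three steps: (1) δ/b fusion genes
expand to their two motifs in reading order (reversed on the minus
strand, since labels are stored in ascending-position order); (2) maximal
runs of one subunit collapse to a single gene, with b and b′ treated as
one label throughout (so ε-β-γ-α-δ-b-b′ → ε-β-γ-α-δ-b); (3) transcription
direction is discarded by taking the representative of {string, reversed
string} that is lexicographically smaller under the rank
ε<β<γ<α<δ<b<c<a — any deterministic tie-break works since direction is
explicitly ignored (δ-α-γ-β-ε ≡ ε-β-γ-α-δ).

The standard order ε-β-γ-α-δ-b-c-a defines 9 cut positions and therefore
C(9,2) = 36 contiguous *standard modules*.  A canonical string is
classified as a standard module (with its cut pair) iff it equals one of
those runs; as a minor complete unit iff it contains all eight subunits in
a non-standard order (e.g. β-ε-a-c-b-δ-α-γ); as a chimera iff it contains
two or more but not all subunits in an order matching no contiguous run
(e.g. the N-ATPase-like β-ε-a-c-b-α-γ); otherwise as "other".

## Frequency and significance

Each canonical unit counts once.  Minor units, chimeras and "other"
strings share an other-bin that participates in the total `N` but is never
significance-tested (it has no null probability).  A module is significant
when its frequency strictly exceeds the binomial upper bound

    CI_up = p + Z_α · √(p(1−p)/N),   p = 1/36,  α = 0.05,

with `Z_α` the one-sided standard normal quantile (≈ 1.6449; a two-sided
variant is configurable — both print as 0.03 at study-scale `N`).  Under
the uniform null the per-module flag probability is ≈ 0.048 ≤ α at
N = 1500; note that the *maximum* rate over all 36 modules can exceed
α + 3·SE(α) in a few percent of experiment replications purely through
multiplicity.

δ/b Rosetta-stone fusions are called from a motif-hit table: any gene
whose protein carries ≥ 2 distinct subunit motifs, with δ/b calls tagged
separately.  Sequence-level motif scanning is out of scope; the label
column of the annotation input is trusted.  Per-taxon summaries report the
modal per-genome multiset of canonical unit strings (ties break to the
lexicographically smallest signature) and can be attached to a Newick
class tree as node annotations.

## Synthetic data

**Profiles.**  Species are exchangeable draws within the three domains of
life (82 Archaea / 614 Bacteria / 63 Eukaryota out of 759 by default);
there is no tree-based gain/loss process, because the clustering operates
on the flat matrix.  Each planted module draws one Bernoulli presence per
species (probability set per domain) shared by all its genes; every cell
then flips independently with noise ν (default 0.05, < 0.5 so the planted
signal dominates).  The four synthase modules are:

| module | genes | P(presence) A/B/E | rationale |
|---|---|---|---|
| alpha_beta | ATP5A1, ATP5B | 0.90/0.95/0.95 | near-universal; archaeal A/B subunits are homologs |
| c_ring | ATP5G1/G2/G3 | 0.45/0.70/0.95 | widespread, but short hydrophobic c subunits are missed by strict-threshold search in many prokaryotes |
| f1_stalk | ATP5C1, ATP5D, ATP5E, ATP5O | 0.05/0.75/0.90 | stalk subunits have no significant archaeal homologs |
| fo_rest | ATP5F1, ATP6, ATP5H, ATP5I, ATP5J2, ATP5L, ATP5J, ATP8 | 0.05/0.25/0.85 | mitochondria-specific Fo accessories are eukaryote-confined |

The scaled-down complement embeds these among 46 background modules of 5
genes (247 genes total rather than the ~1000 of a full mitochondrial
complement; group numbers up to 50 remain meaningful and the suite stays
fast).  Background probabilities are mid-range ([0.15, 0.85] per domain),
frozen, and rejection-sampled to keep an expected per-species mismatch of
at least 0.45 from every synthase signature: a background module sharing a
synthase module's gain/loss probabilities would be a genuine co-evolution
partner rather than background, and the planted structure would not be
identifiable even in principle.

**Genomes.**  Each genome draws a named combination pattern — the
standard complete unit; the documented splits (F1 + Fo; ε-β + the rest;
ε-β-γ-α-δ-b + c-a; the triple split ε-β-γ-α-δ-b + c + a; ε-β + γ-α +
δ-b-c-a; ε-β + γ-α-δ + b-c-a); two minor complete units
(ε-β-γ-α-δ-b-a-c and β-ε-a-c-b-δ-α-γ); and an N-ATPase-like chimera
carried next to a standard unit.  The default mixture weights were solved
analytically so the expected per-unit shares of the standard unit, the Fo
module and the F1 module are 34.6%, 9.8% and 6.5% — the consensus
composition a broad bacterial panel exhibits.  A second, class-structured
default assigns per-class mixtures whose dominant shares mirror the
reported per-class composition (e.g. Gammaproteobacteria 94.0% standard,
Alphaproteobacteria 89.1% F1+Fo, Epsilonproteobacteria 97.8% triple split,
Bacilli 65.9% standard / 30.8% minor), with class weights approximating
relative panel sizes (Bacilli 396 of 2248 genomes).

Orientation is randomized (a reversed unit has reversed gene order and
minus strand); optional events add tandem b-b′ duplicates (p = 0.05), δ/b
fusion genes (p = 0.01), intervening foreign genes between units
(p = 0.5), and raw-prediction splits in which one planted unit is emitted
as two adjacent same-strand raw TUs (p = 0.3) that the merge rule must
undo.  Distinct planted units are always separated by a position-index
gap, so they survive merging even with no explicit foreign gene.  The
planted truth (pattern, taxon, fusion gene ids) is returned beside the
table, and merge → collapse → canonicalize maps every genome back to its
planted pattern (tested).

**What the generators do not emulate.**  No sequence evolution, no
tree-correlated gain/loss, no E-value magnitudes beyond the two-point
present/absent mixture, no genome rearrangement process, and no
within-class phylogenetic autocorrelation of patterns.  Passing tests
therefore show that the pipeline recovers structure of this planted form
at realistic sizes and noise, not that it would resolve arbitrarily
entangled real profiles.

## Numerical and degenerate-input conventions

Seeds are explicit in every spec and flow from a single `--seed` via
`numpy.random.SeedSequence` in the acceptance script; no global RNG state.
Distance matrices are symmetrized (`(D+Dᵀ)/2`) against floating round-off
and mutual information is clipped at 0.  Merge-tree ties follow scipy's
deterministic agglomeration order.  Degenerate inputs are rejected with
messages naming the offending object (mixed-strand raw TU, duplicate
position, genome missing from the taxon map, out-of-range group number,
empty gene set).

## Problem sizes

Defaults used by the analysis drivers and acceptance script: 247-gene ×
759-species profiles for the consensus analysis, a 17-gene × 400-species
panel for per-method module recovery, 2000 pooled and 2248
class-structured genomes for the TU track, 200 replicates × 1500 units for
the null calibration.  These are the package's chosen desk-scale
conditions; all are configurable upward.

## Known limitations

* The Kendall tie/normalization convention and the MI log base are choices
  consistent with, but not dictated by, the distance definitions.
* Consensus sets are greedy in gene order; a different growth order can
  split borderline cliques differently near the threshold f.
* Paralogy curation (F-type vs V/A-type assignment) is taken from the
  input labels, not re-derived from sequences.
* The binomial bound is a normal approximation; at very small N an exact
  binomial quantile would be preferable.
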