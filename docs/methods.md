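# Methods

## Model and procedure

`ldblocks` operates on unphased diploid genotypes at biallelic SNPs, one
chromosome per panel, coded as minor-allele dosage {0, 1, 2} with a
missing code.  The pipeline has four stages.

**1. Pairwise r².**  For each marker pair the four two-locus haplotype
frequencies are estimated by EM over the 3×3 genotype table of the
pairwise-complete samples (per-pair deletion; no imputation).  Only the
double-heterozygote class is phase-ambiguous; each E-step splits it
between the coupling (AB/ab) and repulsion (Ab/aB) phases in proportion to
the current haplotype-product weights.  The iteration starts at linkage
equilibrium (products of the subsample allele frequencies), which keeps
the estimator deterministic, and stops when the largest frequency change
falls below `tol` (default 1e−10, `max_iter` 1000; non-convergence is
reported by a flag, not an exception).  The observed-data log-likelihood
is non-decreasing across iterations and is recorded per step.  Then
D = p_AB·p_ab − p_Ab·p_aB (the determinant identity, exact when the
frequencies sum to one) and r² = D²/(p_A(1−p_A)p_B(1−p_B)), clamped to
[0, 1].

Two exactness refinements protect perfect-LD detection from rounding.
When the two dosage vectors are identical or mirrored (g₂ = 2 − g₁) on the
pairwise-complete subsample — and at least one sample is not a double
heterozygote — the maximum-likelihood solution places all mass on one
diagonal of the haplotype table and is returned in closed form, giving
r² = 1.0 exactly with zero iterations.  (All-double-heterozygote data are
excluded from the shortcut because there the likelihood is symmetric and
the equilibrium start is the conventional stationary point, all four
frequencies 0.25.)  Independently, `r2_pair` returns exactly 1.0 whenever
one diagonal of the haplotype table is exactly empty, which is an algebraic
identity.  Together these make "duplicate column ⇒ r² = 1" hold bit-for-bit
even at ε = 0.

A marker is dropped from LD analysis when it is monomorphic, entirely
missing, or below the MAF threshold (MAF = minor-allele count over twice
the non-missing sample count).  Undefined pairs (monomorphic in the
pairwise-complete subsample, or no overlapping samples) are masked, never
silently zero.  Externally precomputed r² tables (id1 id2 r2 triples) can
be loaded in place of native estimation, reproducing a
precomputed-measures-in, clusters-out workflow.

**2. Clusters.**  Clusters are connected components of size ≥ 2 of the
graph joining markers with defined r² ≥ 1 − ε (default ε = 1e−6, which
absorbs floating-point noise in EM-derived values).  Components rather
than maximal cliques: with complete data perfect correlation is
transitive, so components *are* cliques, and the component formulation is
O(E) and deterministic.  A clique-verification pass covers the
missing-data edge case with a warning naming the offending component.
Clusters are named after their leftmost member and sorted by leftmost
position; everything else is a singleton.

**3. Hierarchical ordering.**  The distance between two blocks is
1 − mean(r² over their defined cross-pairs).  With exact perfect LD inside
blocks all cross-pairs agree, so the mean coincides with any
representative pair; under ε-tolerant blocks the mean is the more robust
choice, and it is the one exposed.  A block pair with no defined
cross-pair (a missing-data artifact) is assigned the maximal distance 1.0
with a warning — UPGMA has no well-defined notion of "excluding" a single
pair.  Agglomeration is average-linkage UPGMA with ties in the merge queue
broken by the smallest (row, column) node-id pair, making the output
platform-independent; it is implemented directly (the Lance–Williams
update) rather than delegated to `scipy.cluster.hierarchy.linkage`
precisely because that tie-break is part of the contract — scipy serves
as an independent cross-check in the tests.  Leaf order is the depth-first
traversal visiting first the child with the smaller minimum leaf index.
The tree can be exported as Newick with ultrametric branch lengths (node
height = merge height / 2).

**4. Architectures and export.**  The MAF filter runs *before* cluster
construction (filtering afterwards could split blocks).  Gene-centered
queries build clusters chromosome-wide and retain a cluster iff at least
one member lies in [tx_start − flank, tx_end + flank] (inclusive, 1-based;
flank default 10 kb); retained clusters are displayed in full, including
members outside the window, while singletons are shown only when inside
it.  Genes are resolved by Entrez id, then RefSeq id, then case-insensitive
symbol, with ambiguity reported as an error listing the candidates.
SNP-centered queries keep variants with defined r² ≥ r2_min (default 0.5)
to the reference, place the reference and its perfectly linked SNPs
(r² ≥ 1 − ε) on the second track, and order the remaining
clusters/singletons by decreasing r² to the reference — taken from each
cluster's first member, the documented representative, since members tie
under exact perfect LD — with ties broken by genomic position.  The names
track always lists every displayed marker.

Export is always 12-column BED: positions are 1-based internally and
0-based half-open in BED (SNP at `pos` → `[pos−1, pos)`), each cluster is
one record with a 1-bp block per member (duplicate positions collapse with
a warning), strand is fixed to `+`, score to 0, r² values in track names
are rendered with 3 decimals, round-half-up.  Record order within a track
is by chromStart, tracks keep architecture order, newlines are Unix,
encoding UTF-8 — identical inputs give byte-identical files.  Optional
coloring maps MAF to a 5-bin light-to-dark blue ramp (bin width 0.1;
clusters take the mean member MAF).

## Synthetic panels

The generator plants structure; it does not model evolution (no
recombination maps, no demography).  Each block has one latent binary
haplotype indicator per chromosome drawn at the block's MAF, and every SNP
in the block copies it, so within-block r² is exactly 1 at zero
missingness.  Between-block dependence uses a Gaussian copula: one
standard normal per block, thresholded at the MAF quantile, with each
pairwise Gaussian correlation solved by tetrachoric inversion (brentq on
the bivariate normal CDF) so the binary indicator correlation hits its
target in expectation; infeasible specifications (non-PSD, or above the
Fréchet bound for unequal MAFs) fail before sampling.  Chromosomes are
paired randomly into diploids, and missingness is i.i.d.  Dosage columns
are recoded after missingness so the coding matches the reader's
observed-minor-allele rule.  Defaults: 1 kb marker spacing from position
10,001; all randomness from one integer seed; the planted partition is
returned with the panel.

Pairwise tetrachoric inversion cannot represent a dense "ladder" of many
variants all correlated with one reference (the implied Gaussian matrix
loses positive semidefiniteness), so `reference_ld_ladder` provides a
one-factor construction for that design: each variant's haplotype copies
the reference with probability √r²_target and is otherwise an independent
draw at the same MAF, which is consistent for any number of variants.

`balanced_independent_pair` is the exact-zero-LD construction: equal
counts of the four two-locus haplotypes paired into diploids with no
double heterozygote (homozygote pairs, plus one (0,1)/(2,1) pair when
counts are odd), so the haplotype table is exact, r² = 0 exactly, and EM
converges in one iteration.

What passing tests on these panels do **not** show about real data:
realistic decay of LD with distance, allele-frequency spectra, genotyping
error, Hardy–Weinberg violations, or relatedness between samples (all
individuals are treated as unrelated; pedigree columns are parsed and
discarded).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1e−6 | r² ≥ 1 − ε joins the perfect-LD graph; absorbs EM rounding |
| `maf_min` | 0 | markers with MAF below this are excluded before clustering |
| `r2_min` | 0.5 | SNP-centered inclusion threshold on r² to the reference |
| `flank_bp` | 10,000 | gene-window extension on each side (bp) |
| `tol`, `max_iter` | 1e−10, 1000 | EM stopping rule |
| `include_singletons` | true | show unclustered SNPs on their own track(s) |

The flank default is a pragmatic choice for cis-regulatory
neighbourhoods; it is always user-adjustable.  The r2_min default of 0.5
matches the conventional cut for "in LD with" a reference variant.

## Numerical choices and degenerate inputs

Minor-allele ties (exact 0.5/0.5) resolve to the lexicographically greater
symbol, so recoding is deterministic; true orientation invariance holds
whenever frequencies differ.  Duplicate marker positions are an input
error (positions must strictly increase).  Monomorphic markers are kept by
the reader — it stays a pure parser — and excluded by the LD stage.  An
empty LD matrix, an empty architecture window and a panel with no blocks
are all legal, warned-about outcomes rather than exceptions.  A
single-cluster hierarchical query attaches a trivial one-leaf dendrogram.

## Problem sizes

The test suite and the acceptance script run at desk scale: panels of
tens to a few thousand samples and up to ~20 markers, 100-seed recovery
sweeps, and Monte-Carlo checks at 10,000 samples for the copula
calibration.  Pairwise EM is O(m²) in markers, which is the intended
regime for region- and gene-scale panels; chromosome-scale inputs are
better served by the precomputed-r² loader.

## Known limitations

No trio-aware phasing, no X-chromosome hemizygotes, no multi-allelic
markers, no D′/LOD statistics or D′-based block definitions (Gabriel
blocks, four-gamete tests), no VCF input, and no association-p-value
clumping.  The tool is genome-build-agnostic: coordinates in are
coordinates out.
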