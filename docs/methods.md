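# Methods

## Phenotype model

Competition between a tester and a reference strain is summarized by
nodule occupancy. For each plant with at least one nodule, the per-plant
fractions are f_c = n_c / (n_green + n_red + n_mixed) for
c ∈ {green, red, mixed}; they sum to one by construction. Plants with
zero nodules are **excluded** rather than scored 0 — occupancy is
undefined for them and zeros would bias the competition mean. The
phenotype of a (tester, reference) pair is the arithmetic mean of the
per-plant fractions over the replicates (default six plants), either of
f_green alone (`single`) or f_green + f_mixed (`single_plus_mixed`);
the mixed mode can only increase a cell, which is asserted as an
invariant. A pooled-count estimator (summing counts over plants before
dividing) is available behind a flag for sensitivity analysis; the mean
of per-plant ratios is the default because each plant is the natural
replicate unit. Competitor classes put the boundaries into the middle
class: good is strictly above 0.60, weak strictly below 0.20, medium is
the closed interval [0.20, 0.60].

Phenotypes entering the GWAS must lie in [0, 1]; percent-scale tables
(any value > 1) are divided by 100, values above 100 are rejected.

PCA of strain occupancy profiles is column-mean-centred SVD without
variable scaling (occupancy columns share a scale already); component
signs are fixed by making the largest-magnitude loading positive.
PERMANOVA uses Euclidean distances between strain rows (configurable),
pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)) computed from squared
distances, and the permutation p-value (1 + #{F* ≥ F}) / (1 + n_perm)
with seeded label permutations; with more than two groups all pairwise
tests are run and Bonferroni-corrected. Note that a permutation that
happens to reproduce the planted grouping ties the observed F, so the
minimal attainable p-value 1/(1 + n_perm) is reached with certainty
only when the group sizes make such a coincidence negligible.

## k-mer association

k = 13 by default; every window over {A, C, G, T} is collapsed to its
canonical form (lexicographic minimum of window and reverse complement)
so strand orientation of assemblies is irrelevant. Windows containing
IUPAC ambiguity codes are skipped; characters outside IUPAC raise a
parse error with record and offset. Presence means count ≥ 1 — the
association semantics are presence/absence, not abundance. The min/max
filter keeps a k-mer only if it is present in ≥ 2 and absent from ≥ 2
strains; with 13 strains this also removes every strain-singleton
pattern.

Clonal structure correction: pairwise Jaccard distances
d = 1 − |K_i ∩ K_j| / |K_i ∪ K_j| on the **unfiltered** presence
profiles (the exact quantity that genome sketching approximates), UPGMA
with merge height d/2 (ultrametric by construction, ties broken by the
lowest pair of original strain indices), then GSC weights: each leaf
starts with its terminal branch length and every internal edge's length
is distributed among descendant leaves proportionally to their
accumulated weights (equally while all are zero, i.e. among exact
clones). Weights are normalized to sum to n, so equal-weight panels
reduce the weighted test exactly to the classic Welch test; clones at
distance zero split one strain's weight between them.

Weighted Welch test per k-mer, groups = strains with/without the k-mer:
W_g = Σ w_i, μ_g = Σ w_i x_i / W_g, n_eff,g = W_g²/Σ w_i² (Kish),
s_g² = Σ w_i (x_i − μ_g)² · n_eff,g / ((n_eff,g − 1) W_g),
t = (μ₁ − μ₂)/√(s₁²/n_eff,1 + s₂²/n_eff,2), Welch–Satterthwaite df on
the (s_g²/n_eff,g, n_eff,g − 1) pairs, two-sided Student-t p-value.
Degenerate cases are explicit: a group with effective size ≤ 1 skips
the k-mer (logged); zero variance in both groups gives p = 1 when the
means agree and a p clamped to the smallest positive normal float when
they differ. k-mers with p > 0.05 are discarded with **no**
multiple-testing correction — raw-p filtering is the convention this
pipeline follows; Benjamini–Hochberg is available behind a flag. The
retained table is sorted by ascending p, ties by descending |t| then
k-mer string, which makes the output fully deterministic.

## Predictive model

With ~13 strains and up to 1,000 k-mer features, ordinary least squares
is unidentifiable, so the regression family is the lasso
(L1-regularized linear regression), the family used by k-mer GWAS
association tools for continuous phenotypes. Outer 3-fold CV uses a
seeded shuffled partition (each strain in exactly one test fold); the
inner 3-fold CV selects the regularization strength from a log-spaced
grid 10⁻³…10 (9 points) by mean squared error; the final model is
refit on all strains with the modal inner-selected strength (ties go to
the smaller strength). Reported metrics per fold and averaged: MSE, an
out-of-sample R² computed against the **training-mean** baseline
(1 − Σ(y − ŷ)²/Σ(y − ȳ_train)²), and Spearman rank correlation. The
training-mean baseline is used because with 4–5 test strains the
test-set mean is a noisy and occasionally degenerate reference (a test
fold can be phenotypically constant), whereas the training mean is what
an intercept-only model would actually predict; a null model then
scores ≤ 0 by construction. By default the feature ranking is global
(top-1,000 over all strains) before CV; this leaks ranking information
into the folds, so the CV
estimate is optimistic — recomputing the ranking inside each training
fold is available via `rank_in_fold`-style usage of `select_top` on
fold-restricted tables.

## Mapping

Coordinates are 1-based inclusive (GFF3) internally; BED output is
converted at the boundary. Each occurrence of a query k-mer (searched
on both strands; the scan compares 2-bit window codes against the
sorted query codes in a single pass per replicon) is classified:
overlap of ≥ 1 base with a gene interval makes a CDS row per overlapped
gene (one k-mer may tag several genes); otherwise overlap of ≥ 1 base
with the strand-aware upstream window ([start−600, start−1] for +
genes, [end+1, end+600] for − genes, truncated at replicon ends) makes
a regulatory row with distance_to_start ∈ [1, 600] measured from the
match's nearest base to the CDS start; otherwise the occurrence is
intergenic. CDS takes precedence over regulatory at the same
occurrence. Upstream windows are not truncated at neighbouring genes;
a window that overlaps an adjacent CDS is simply superseded when the
occurrence itself touches that CDS.

Summaries count **distinct** tagged genes per strain by COG category
and ortholog group (genes without a COG id fall into an "unannotated
CDS" bucket), count regulatory hits per target gene, and report
per-strain hit fractions by replicon role — for all hits and restricted
to ortholog-annotated gene hits. Ortholog groups are consumed from GFF3
attributes; no ortholog inference is performed here. Carrier-exclusive
regions cluster hit positions per (strain, replicon) with an inter-hit
gap ≤ 5 kb (smaller than the target accessory region, larger than gene
spacing) and keep regions whose ortholog-group content is annotated in
exactly the carrier strains; a carrier set equal to the whole panel has
no exclusive region by definition.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: 13 tester
strains, three replicons (chromosome 60 kb, pSymA-like 40 kb,
pSymB-like 30 kb at desk scale), a shared core (90 % of each replicon)
with point substitutions, strain-private tails, and accessory blocks
inserted at fixed loci in carrier subsets — by default a 2-kb causal
block on the pSymA-like replicon carried by four strains (standing in
for the ~26-kb accessory region of real panels), plus two decoy blocks
with different carrier sets. Each block carries annotated genes sharing
ortholog groups across carriers; the first gene sits 700 bp into the
block so its 600-nt upstream window is clear. The phenotype is
base + β·carrier + N(0, σ) clipped to [0, 1], defaults base = 0.25,
β = 0.40, σ = 0.05. Nodule counts per plant are zero-truncated
Poisson totals (mean 20) split multinomially with
p_green = φ(1 − p_mix), p_red = (1 − φ)(1 − p_mix), p_mixed = p_mix
(default 0.15; mixed nodules are common in such assays but no rate is
established, so it is configurable), six plants per competition.

A deliberate design property: **multi-strain k-mer patterns arise only
from planted structure.** Substitutions are strain singletons placed
≥ k apart and ≥ 2k away from insertion loci, and their mutated windows,
the blocks, and the private tails are all kept k-mer-disjoint from
previously generated content (colliding windows are repaired). Without
this, chance coincidences — two tails sharing a 13-mer, two strains
substituting within the same window — create small spurious presence
patterns whose tight phenotype groups can out-score the planted signal
under Welch. Real panels *do* contain such confounders (plus
tree-structured variation), so recovery results on this generator
certify the pipeline's correctness, not its power on real data. Other
simplifications: linear replicons (no origin-spanning k-mers),
uniform base composition, no rearrangements or gene-content phylogeny.
The ground-truth causal k-mer set is computed empirically as the
canonical 13-mers of windows overlapping the inserted block (including
junction-spanning windows) that occur in every carrier and in no
non-carrier, and is verified by exhaustive scan in the tests.

Substitution density defaults to 0.001 per core bp per strain — a
clonal-panel scale at which the structure-correction machinery is
exercised without overwhelming the planted accessory signal; it is a
free parameter of the config.

## Determinism and problem sizes

All randomness flows from a single integer seed (phenotype and count
streams are derived sub-streams, so stages can be re-run
independently). Outputs are written with fixed orderings and float
formats; two runs with the same configuration are byte-identical,
which the test suite asserts end to end. The test suite runs the
pipeline at the default desk-scale genome sizes (130 kb per strain),
20 independent panels for recovery checks, 1,000 datasets for the
PERMANOVA calibration (199 permutations each) and 1,000 datasets for
the Welch reduction check; the whole suite completes in about a minute
on one CPU.

## Known limitations

- The generator's exact-pattern guarantee removes confounders that real
  data contain; power estimates on it are optimistic.
- GSC-on-UPGMA is one realization of "clonal structure correction"; it
  is pinned by its reduction and symmetry properties (equal weights on
  balanced trees, clone-pair weight splitting), not by comparison with
  any external tool.
- The global top-k-mer ranking before CV leaks information (see above).
- p-values are raw; with ~10⁵ tested k-mers the retained set under the
  0.05 rule contains many false positives by construction — the
  downstream carrier-set selection and mapping, not the threshold, do
  the real filtering.
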