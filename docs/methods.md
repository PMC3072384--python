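# Methods

## The assignment problem

Given diploid biallelic SNP genotypes for reference individuals of known
breed, we want small marker panels and a decision procedure that assign a
new individual to its breed of origin. The package decomposes the task
hierarchically: a decision tree of nested breed groups is built once from
the reference data, and classification descends the tree one vote at a
time. Hierarchy matters twice over — it matches how breed structure is
actually organised (species groups, then regional clades, then single
breeds), and it lets each node use a panel tuned to exactly the contrast
it must resolve.

## Encoding and quality control

Genotypes are encoded as minor-allele counts in {0, 1, 2}. The minor
allele is determined per SNP from the non-missing calls (ties go to the
lexicographically smaller allele character, making the encoding
deterministic). Any linear diploid coding differs from this one only by
a per-column affine transform, which centring absorbs, so principal
components and leverage scores are unaffected by the choice.

QC removes SNPs whose missing-call fraction *strictly exceeds* 10% (a
SNP missing in exactly 10% of samples is retained) and SNPs monomorphic
among non-missing calls — zero-variance columns carry no PCA signal and
break centring-based computations. No Hardy–Weinberg or minor-allele-
frequency filter is applied. Missing entries are imputed with the
column mean of the non-missing entries and every column is centred; the
column means are stored with each fitted basis so that out-of-sample
individuals are imputed and centred with *training* statistics. An
entirely missing sample therefore projects exactly to the origin.

## PCA and the number of significant components

Each node's centred matrix is decomposed by exact SVD (LAPACK `gesdd`;
singular-vector signs are normalised so the largest-magnitude loading is
positive, though every downstream quantity — distances and squared
loadings — is sign-invariant). Training coordinates are `A·V_k = U_kΣ_k`,
i.e. true PC scores, so dominant axes dominate Euclidean distances just
as they dominate a PC scatter plot.

The number of significant components `k` is chosen by the task itself:
the candidate maximising leave-one-out 5-NN classification accuracy on
the node's training data. Accuracy ties are broken toward the candidate
with the largest relative spectral gap `σ_k/σ_{k+1}`, then toward
smaller `k`. The gap rule is a stability guard: when the accuracy
profile is flat, cutting the spectrum inside a near-degenerate block of
singular values retains a subspace that rotates arbitrarily under a
one-sample change of the data (the per-fold refits of cross-validation),
which silently degrades held-out projections; cutting at a gap does not.

## Marker scores and panels

The PCA score of SNP `j` is its leverage on the top-`k` right singular
subspace, `p_j = Σ_{i≤k} V[j,i]²` — equivalently the squared norm of the
coefficient vector when the SNP's centred column is regressed on the
top-`k` PC coordinates. Scores are non-negative, sum exactly to `k`, and
are invariant to sample permutation and singular-vector signs. The
`n_top` highest-scoring SNPs are kept as candidates (default
`min(2000, n_snps/3)`, scaling the reference 2,000-candidate step down
to simulated data sizes; ties by SNP id).

Because high-scoring SNPs travel in LD packs, panels are cut from the
candidates by column subset selection: the candidate submatrix is
re-decomposed, and column-pivoted QR on the `k × n_cand` matrix `V_kᵀ`
orders columns by residual contribution to the significant subspace — a
duplicate of an already-pivoted column has zero residual and is never
chosen while an independent informative column remains. QR pivoting
ranks `min(k, c)` columns; when the requested panel is larger than `k`
the remaining positions are filled in descending leverage order (ties by
SNP id). The order is deterministic, so truncations at different sizes
are nested prefixes; the reported tiers P1 ⊂ P2 ⊂ P3 default to sizes
`p1 : 2·p1 : 3·p1`. A bundled alternative configuration uses 10/25/50
markers at every node (prefix-nested, ratio relaxed).

## Tree construction

At each internal node, breeds are grouped by k-means (20 restarts,
seeded) on the training individuals' PC coordinates, and each breed
joins the cluster holding the plurality of its members — breeds are
atomic and never split across children. Clustering is restricted to the
node's *dominant* PC block: the leading components up to the largest
relative gap in the singular-value sequence (consulting `σ_{k+1}` when
available). A hierarchical decomposition wants the coarsest
well-supported split at each level — one dominant axis yields a
two-cloud split, a flat leading block a multi-way split — and finer
structure is deliberately left to the recursion; clustering on all
significant PCs instead resolves every breed at once and flattens the
tree. The cluster count, when not fixed, maximises the mean silhouette
over 2..min(6, #breeds) on the dominant block. If plurality assignment
ever collapses all breeds into one cluster the node falls back to
one-leaf-per-breed children to guarantee termination (not observed in
the simulated regimes). An explicit topology can be supplied instead;
the bundled `paper` preset carries the 19-breed worldwide cattle tree
with its per-node significant-PC counts and panel sizes.

Each node stores a full-SNP basis plus per-tier bases *refit on the
panel SNPs alone* (centred with the same training means). Classification
in a panel mode uses the panel-refit basis, since a deployed assay
measures only the panel markers.

## Classification and metrics

At a node, the five nearest training neighbours (Euclidean in the node's
PC space; distance ties broken by sample id) vote; a child group needs a
strict majority — at least 3 of 5 — to win, otherwise the sample is
unassigned and the descent stops. With fewer than five training samples
all of them vote and the threshold is the strict majority `m//2 + 1`.
Unassigned outcomes count as incorrect in every accuracy figure (the
conservative reading). The neighbour count is a free parameter; on
separable data accuracy is flat across 3–11 neighbours.

Leave-one-out cross-validation holds each individual out in turn and
refits every node on its root-to-leaf reference path — PCA, candidate
ranking, CSSP panels, and panel bases all recomputed from the remaining
individuals — with the tree topology and per-node `k` held fixed from
the full-data build (refitting only path nodes changes nothing measured;
off-path nodes never see the sample). Two statistics are reported per
node, mode, and breed: accuracy `A` (the node decision is correct iff
the predicted child contains the reference breed; denominators are all
samples whose breed belongs to the node) and average correct neighbours
`N̄` (same-breed neighbours out of five). The LOOCV loop itself is
deterministic; the run seed governs simulation and k-means only.

## The simulator

The generator emulates a multi-breed SNP survey: ancestral frequencies
uniform on (0.1, 0.9); along each branch of a planted breed tree with
differentiation `F`, child frequencies drawn from the Balding–Nichols
distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)`, so the expected
between-population frequency variance is `F·p(1−p)` and multi-SNP F_ST
estimates recover `F`. Frequencies are clamped to [0.01, 0.99] after
each draw to avoid fixation (a small downward bias on realized
differentiation); fixed SNPs can still arise in finite genotype samples
and are left for QC to remove. Genotypes are Binomial(2, p_breed);
missing calls are MCAR at a fixed per-entry rate.

LD is emulated by noisy duplication rather than coalescent haplotypes:
a fraction of base SNPs (default 20%) is copied `r−1` times, each
duplicated entry independently resampled from the breed frequency with
a small corruption probability (default 5%). This reproduces precisely
the failure mode redundancy removal targets — blocks of
near-interchangeable high-scoring markers — without recombination
machinery. The simulator therefore does *not* produce realistic decay
of LD with distance, allele-frequency spectra, selection, or admixture;
passing tests show the pipeline recovers planted structure and prunes
planted redundancy, not that it handles those unmodelled features.

The standard study conditions used by the test suite and the acceptance
script: six breeds in two groups (between-group F 0.15, within-group
0.05 — a strongly structured livestock scenario), 40 individuals per
breed, 2,000 base SNPs (2,800 columns after duplication), 5% missing
calls. Reduced-scale variants of the same conditions (fewer individuals
and SNPs) are used where an experiment is replicated many times; the
replicate sizes are stated in the tests that use them.

## Numerical choices and limitations

* Exact SVD everywhere (no randomized sketching); numerical rank uses a
  relative tolerance of 1e-10. Repeated runs agree bitwise.
* All orderings (candidate ranking, CSSP tail, neighbour ties) break
  ties lexicographically by id for reproducibility.
* Degenerate inputs fail loudly: >2 alleles at a SNP, all-missing or
  monomorphic columns entering centring, `k` above rank, all-zero
  candidate matrices, clustering on coincident points, breeds with a
  single individual entering LOOCV.
* Breeds absent from the reference tree cannot be detected
  ("out-of-reference" samples are forced to a breed or left unassigned);
  no admixture fractions or soft assignments are produced.
* Real-survey accuracies depend on the reference genotypes and are not
  reproduced here; the bundled 19-breed preset replays the reference
  *configuration* (topology and panel sizes) on simulated data only.
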