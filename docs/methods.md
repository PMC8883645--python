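# Methods

## Pipeline overview and assumptions

`hicmag` bins assembled contigs from a microbial community using metagenomic
Hi-C. The method assumes (i) inter-contig Hi-C read pairs are mostly
intra-genome, with biases that factorize multiplicatively over the two
contigs of a pair; (ii) a partial species-level annotation of contigs is
available to calibrate the normalization and the clustering resolution
(in practice from a taxonomic assignment tool; the pipeline consumes a
two-column contig→species table and never runs annotation itself); and
(iii) cross-species ("spurious") contacts are systematically weaker than
same-genome contacts after bias removal.

Stages run strictly in order: alignment filtering → raw map → contig
filtering → ZINB fit on intra-species samples → normalization → spurious
threshold and removal → resolution tuning → final Leiden clustering →
valid-bin extraction → optional contaminated-bin post-processing. Every run
report echoes the configuration and the conventions listed below.

## Alignment filtering and the raw map

A read pair is kept iff both mates are mapped, primary and
non-supplementary (SAM flag mask `0x904`), have ≥ 30 aligned bases
(CIGAR M/=/X on the primary alignment) and MAPQ ≥ 30, and map to two
*different* contigs. `c_ij` counts the retained pairs bridging contigs i
and j. The per-contig *signal* is the row sum of the raw map — i.e. each
retained pair contributes one read to each mate's contig, so signals total
twice the pair count. We count reads rather than pairs per contig; since
every retained pair is inter-contig the two definitions differ only by a
factor shared across contigs, and the read convention keeps the row-sum
identity exact.

Contig filtering removes contigs with length < 1000 bp or signal < 2 in a
**single pass** on signals computed from the full map. Signals are not
recomputed after removal and the filter is therefore idempotent; a
fix-point iteration would remove additional contigs whose signal drops only
because a filtered neighbour vanished, which conflates two distinct
quality criteria.

PCR-duplicate removal is expected upstream; `extract_hic_pairs` can
optionally drop exact positional duplicates behind a flag (default off).

Restriction sites are counted on the forward strand only (the shipped
enzymes — HindIII, NcoI, Sau3AI, MluCI — all have palindromic sites),
overlapping occurrences included, multiple enzymes summed. Contigs with
zero sites are given an effective count of 1 before any log transform.
Contigs with zero reported coverage receive the smallest positive coverage
in the table, again so log-covariates stay finite.

## The ZINB normalization model

Intra-species samples are all unordered pairs of same-species labeled
contigs, *including zero-count pairs* — the zeros identify the inflation
mass. Counts follow a zero-inflated NB2 law:

    P(C=0)   = π + (1−π) · NB(0; μ, θ)
    P(C=c>0) = (1−π) · NB(c; μ, θ),          Var = μ + μ²/θ
    ln μ     = β₀ + β₁ z₁ + β₂ z₂ + β₃ z₃

with z₁ = standardized ln(s_i s_j), z₂ = standardized ln(l_i l_j),
z₃ = standardized ln(cov_i cov_j). Standardization (mean 0, sd 1 over the
training samples) is stored in the model and reused verbatim when
normalizing unlabeled contigs, which is what makes the residuals invariant
to global rescalings of a covariate. Zero inflation is intercept-only:
nothing in the data generating intuition suggests the *excess*-zero
probability should scale with the bias covariates, and the simpler form is
markedly better conditioned; the choice is isolated in one place if a
covariate-dependent gate is ever wanted. In LC mode (enzymes unknown) the
site covariate is dropped and the model has three coefficients.

Fitting is direct maximization of the ZINB likelihood (L-BFGS-B on
(β, ln θ, logit π), tolerance 1e-6 on the objective, cap 1000 iterations)
initialized EM-style: β from a Poisson log-linear GLM, θ by method of
moments on the Poisson residual variance (clipped to [0.05, 50]), π at half
the observed zero fraction (clipped to [0.02, 0.9]). On failure the fitter
falls back to a plain NB (π = 0), then to the Poisson coefficients, each
with a warning recorded in `fit_info`. A floor of 50 intra-species samples
(configurable) guards against meaningless fits.

The normalized contact is the ratio residual `n_ij = c_ij / μ_ij`. A ratio
(rather than, say, a Pearson residual) keeps downstream thresholds
scale-free and strictly positive wherever a raw count exists; zero counts
never produce stored entries.

## Spurious-contact threshold

Calibration uses only the *non-zero* intra-species normalized contacts
("valid contacts"). With n calibration values and acceptable loss
percentage p (default 5), the threshold is the k-th smallest value with
k = ⌊p·n/100⌋ (t = 0 when k = 0), and entries strictly below t are
discarded. This lower-order-statistic / strict-inequality convention
guarantees #{v < t} ≤ p·n/100 exactly, with no percentile-interpolation
ambiguity; ties at the threshold are never discarded. Removal is symmetric;
contigs isolated by removal stay in the index and are reported unbinned.

## Clustering

The despursed normalized map is a weighted graph. The objective is the
Reichardt–Bornholdt Potts modularity over ordered node pairs including
i = j (the diagonal is zero, so it contributes only the null term):

    Q = Σ_ij (A_ij − γ k_i k_j / 2m) δ(c_i, c_j)

Consequences used by the tests: one community at γ = 1 scores exactly 0,
and an all-singleton unit triangle scores −2. Optimization uses the Leiden
algorithm (via `leidenalg`'s RB-configuration partition, which optimizes
exactly this objective), iterated until no improvement; Leiden guarantees
connected communities and is deterministic given the seed. The pipeline
seed (default 0) is shared by tuning and the final run.

γ is tuned over candidates {1, 5, 10, 15, 20, 25, 30}: the whole graph is
clustered at each candidate, ARI and NMI are computed on the labeled subset
and averaged, and the argmax wins with ties to the smallest γ. After
tuning, the graph is re-clustered at γ\* with the pipeline seed (rather
than reusing the tuning run's partition — same result for the shared seed,
but the contract is cleaner). Clusters with total contig length strictly
greater than 150 kbp — just under the smallest known bacterial genomes —
become valid genome bins; the rest are unbinned, and zero-degree contigs
are reported unbinned rather than as size-0 bins.

## Evaluation

Metrics are computed on contigs having both a truth label and a bin
assignment; the dropped fraction is logged. Over unordered pairs of those
contigs: Fowlkes–Mallows = TP/√((TP+FP)(TP+FN)), plus the standard ARI.
NMI is 2·I(U;V)/(H(U)+H(V)) with natural logs — the arithmetic-mean
normalization, the most common convention; the normalization is a single
call-site if a different mean is preferred. The doubly degenerate case
(both labelings single clusters, H = 0) is defined as 1 with a warning.
The implementations delegate to scikit-learn; the test suite checks them
exactly against brute-force pair and entropy enumeration.

CheckM-style ranks: near-complete (≥ 90% completeness, ≤ 10%
contamination), substantially complete (≥ 70%, < 90%; ≤ 10%), moderately
complete (≥ 50%, < 70%; ≤ 10%), weak-complete (≥ 20%, < 50%; ≤ 10%),
contaminated (≥ 20% completeness, > 10% contamination), else unranked.
Boundaries are inclusive as written.

Split-half validation randomly divides the labeled contigs into two equal
halves (sampling without replacement; an odd extra contig goes to the
calibration half), runs the pipeline with the calibration half only, scores
the held-out half, and repeats (default 10 repetitions, seeds derived from
one master seed via `SeedSequence`). Species missing from a held-out half
are logged and the repetition is scored on the rest.

## Post-processing

Bins with completeness > 50% and contamination > 10% (strict) are
re-clustered individually at γ = 1 — the expected number of genomes inside
one bin is small — on the induced subgraph of the *despursed* normalized
map, the same graph the main clustering saw, keeping the pipeline
internally consistent. Sub-bins above the size cutoff replace the parent;
sub-bins below it are reported as unbinned-after-post-processing. A flagged
bin that does not split (one community, or an edgeless subgraph) is
retained unchanged and listed as unresolved rather than deleted: removing a
bin the procedure cannot improve would silently lose genuine sequence.
One round only; output bin count = unflagged parents + retained sub-bins
(+ unresolved parents).

## The synthetic community

`CommunitySpec` defaults: 10 species × 40 contigs; lengths lognormal
(ln-mean 8.5, ln-sd 1.0; median ≈ 4.9 kbp, floored at 1 kbp), matching the
skew of short-read metagenome assemblies; species coverages lognormal
(ln-mean 3.0, ln-sd 0.5; ≈ 20×) with 10% per-contig jitter; restriction
sites Binomial(length, 2.5e-4) — roughly one six-cutter site per 4 kbp;
intensity coefficients β = (−10.5, 0.8, 0.6, 0.4) giving mean intra-species
counts of order 10 for median contigs; θ = 2, π = 0.3. Half the contigs are
labeled, emulating a partial taxonomic annotation.

Intra-species pair counts are drawn from the same ZINB law the fitter
assumes, on **unstandardized** covariates — the fitter's standardization
must still recover the slopes. Spurious contacts: each inter-species pair
is independently selected with probability ρ (default 0.05) and selected
pairs draw from the ZINB law with μ scaled by the spurious intensity
(default 0.15); by default selection is preferentially concentrated on a
random fifth of the species pairs, mimicking noise between closely related
species, with the marginal selection rate rescaled so the expected selected
fraction stays ρ (a uniform option exists). The marginal fraction of
selected inter-species pairs is therefore Binomial-testable against ρ.

A separate helper, `simulate_intra_samples`, draws fitting samples with
standard-normal covariates so fitted slopes are directly comparable to the
generating ones; it backs the coefficient-recovery experiments (20 seeds ×
5000 samples).

What the simulator does *not* emulate: sequence content (no read-level
simulation, no mis-assembly or chimeric contigs), annotation errors in the
label table, shared or horizontally transferred sequence between species,
within-genome contact structure (distance decay along a replicon, plasmid
vs chromosome), and uneven strain mixtures. Passing tests therefore show
the pipeline's statistical machinery is correct under its own model
assumptions — not that real libraries satisfy those assumptions.

## Numerical and problem-size choices

Optimizer parameters are bounded inside the likelihood (ln θ ∈ [−10, 12],
logit π ∈ [−30, 8], linear predictor clipped at ±30) to keep the objective
finite far from the optimum. The exhaustive-optimality check enumerates all
4140 partitions of an 8-node graph; metric and modularity oracle checks use
n ≤ 12 labelings and ≤ 6-node graphs where brute force is exact and
instant. Pipeline-level tests and the acceptance script use the default
400-contig community and 20 × 5000-sample recovery runs — sizes at which
every stage's behaviour is already fully exercised while the whole suite
runs in seconds.

## Known limitations

- The ZINB fit assumes independent pair counts; in reality counts sharing a
  contig are correlated. Standard errors of β are not reported for this
  reason — only point estimates are used downstream.
- Threshold calibration inherits any bias in the label table: if labeled
  species are systematically better-assembled than the community at large,
  the 5% loss guarantee applies to them, not to all valid contacts.
- Resolution tuning optimizes agreement with the labeled subset; a labeling
  that is coarser than true species (e.g. genus-level) will bias γ low.
- One round of post-processing only; recursively contaminated bins remain.
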