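# Methods

`rhizoecol` implements the statistical workflow used to characterise
soil–root continuum microbiomes along environmental gradients: how
community composition shifts from bulk soil through the rhizosphere and
rhizoplane into the root endosphere, which environmental factors drive
those shifts, and which ecological processes (selection, dispersal,
drift) assemble each community. This note records the models, the
parameter choices that matter, and the design decisions taken where the
methodology is genuinely open.

## Data model

All analyses operate on three aligned objects: an integer ASV count
table (samples × taxa), a rooted phylogeny with branch lengths whose
tips cover the taxa, and per-sample metadata (microhabitat ∈ {soil,
rhizosphere, rhizoplane, endosphere}, grassland type, site, and numeric
covariates such as MAP, MAT, altitude, SOC, TN, NO3, pH, BD, AGB, BGB).
`align()` intersects the three and prunes the tree; zero-sum samples are
rejected, zero-sum taxa are allowed in subsets so that per-habitat
tables remain comparable over one taxon universe. No rarefaction is
applied by default; `rarefy()` exists for sensitivity analysis only.

## Diversity and ordination

Shannon diversity uses natural logarithms (nats), the convention of the
vegan-style toolchain this package mirrors. Bray–Curtis is computed on
counts as 1 − 2Σmin/Σ(x+y). UniFrac is computed from an explicit
branch × tip incidence decomposition: unweighted UniFrac is the branch
length unique to one community over the length covered by either;
weighted UniFrac is Σ_b l_b |p_b^A − p_b^B| over abundance fractions,
divided (by default) by its maximum attainable value
Σ_b l_b (p_b^A + p_b^B) so distances are depth-comparable in [0, 1].
This per-branch formulation is exactly the brute-force enumeration, and
the test suite verifies equality with an independent dendropy-based
oracle over >10⁴ exhaustive small-tree cases.

PCoA reports all eigenvalues; negative eigenvalues (non-Euclidean
input) are excluded from the proportion-explained denominator and no
Cailliez correction is applied, matching common practice for UniFrac.
PERMANOVA uses free permutation of labels (no strata) with the
+1-smoothed p-value; the pseudo-F permutation loop is vectorised via a
group-membership quadratic form. CAP is discriminant analysis on the
leading PCoA axes; because "the percentage" of a CAP can mean either
leave-one-out classification success or constrained inertia, both are
reported and neither is privileged. The axis count defaults to the
value maximising leave-one-out success subject to m < n − g.

## Environmental association

db-RDA regresses the positive-eigenvalue PCoA embedding on centred
covariates; significance is by permutation of covariate rows, and
collinearity is screened with variance-inflation factors (threshold 10,
optional drop-and-refit). Variance partitioning solves the full
seven-cell Venn system of Ezekiel-adjusted R² values over the climate /
edaphic / plant covariate groups; unique fractions may be slightly
negative (an adjusted-R² artifact) and are reported as computed, and
the seven fractions plus residual sum to one by construction.
Random-forest importance uses 1000 trees, mtry = p/3 and permutation
importance (mean increase in squared error). Spearman screens report
unadjusted p (masked at 0.05, the figure-level convention) with BH
q-values alongside for transparency.

## Community assembly

βMNTD is the abundance-weighted mean cophenetic distance from each
taxon to its nearest neighbour in the other community, symmetrised as
the mean of the two directions. βNTI standardises observed βMNTD
against a null that shuffles taxon labels across all tree tips (the
"taxa.labels" convention), preserving topology, branch lengths and
abundances; 999 iterations by default (199 in desk-scale tests).
Pairs with zero null spread are reported missing rather than forced.

RC_bray assembles null community pairs probabilistically: each null
community draws the observed richness of taxa with probability
proportional to metacommunity occupancy — each drawn taxon seeded with
one individual so null richness matches exactly — then fills to the
observed total abundance with probability proportional to
metacommunity relative abundance. RC is the fraction of null
Bray–Curtis values below the observed one (ties half-counted),
rescaled to [−1, 1]. Metacommunity weights default to the table but
can be supplied explicitly when the regional pool is known — the
self-consistency test exploits this: data generated by the null
process itself yields uniform RC (KS) and ≈95% of pairs inside ±0.95.

The five-way process classification: βNTI > +2 variable selection,
< −2 homogeneous selection; otherwise RC > +0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, else undominated. Boundary values
(βNTI exactly ±2) count as stochastic. The ±0.95 RC bounds follow the
null-model partitioning framework this analysis descends from; both
thresholds are configurable.

The Sloan neutral model predicts a taxon's occurrence frequency from
its metacommunity mean relative abundance p as
1 − BetaCDF(d; N m p, N m (1 − p)), with N the mean sample depth and m
the migration rate estimated by bounded least squares (m ∈ (10⁻⁶, 1]).
The detection limit defaults to **d = ln 2 / N**: under binomial read
sampling at depth N, a taxon at relative abundance a is detected with
probability 1 − (1 − a)^N, and ln 2/N is the abundance at which that
probability crosses ½, so it is the consistent hard-threshold analogue
of read-sampled counts. (The naive choice d = 1/N systematically
overstates the detection limit and biases m̂ upward by ≈30% on
communities simulated from the model itself.) d is configurable. The
95% envelope around the prediction is the binomial sampling band of an
observed frequency at the fitted value.

## Differential abundance

Taxon enrichment between a root compartment and bulk soil uses a
self-contained negative-binomial Wald pipeline in the DESeq idiom:
median-of-ratios size factors (normalised to geometric mean 1),
per-taxon method-of-moments dispersions shrunk on the log scale toward
a fitted a₀ + a₁/mean trend (weights reflecting the sampling variance
of a moments estimator), a vectorised IRLS fit of the two-condition
log-linear model with size-factor offsets, a Wald z-test on the
condition coefficient, and BH adjustment at cutoff 0.01. Exact
numerical parity with any external implementation is a non-goal; the
calibration targets are uniform null p-values and controlled empirical
FDR with high sensitivity on planted fold changes, which the test
suite checks on simulated NB data.

## Source attribution

A collapsed Gibbs sampler assigns each sink read a latent source
environment among the known sources plus an explicit unknown source
whose profile is learned from its currently assigned reads. The full
conditional for a read of taxon t is
(m_vt + n_vt^(−i) + α)(n_v^(−i) + β) normalised over environments,
where m are the fixed source training counts (absent for the unknown,
whose pseudocount is α₂). Defaults follow the canonical tool:
α₁ = 0.001, α₂ = 0.1, β = 10, 10 restarts, 100 burn-in sweeps, 10
retained draws thinned by 10. Sinks are rarefied to 1000 assignments
by default for tractability (recovery tests run at 10⁴, where 70/30
mixtures of well-separated sources are recovered within a few points
and fully novel sinks route ≥95% to unknown). The inner loop is
numba-compiled; posterior means are deterministic for a fixed seed.

## Co-occurrence networks and cohesion

Inner (taxon) networks: taxa below mean relative abundance 0.001 are
removed; SparCC estimates basis correlations from log-ratio variances
under the sparsity approximation, with Dirichlet(counts + 1)
resampling of fractions per iteration (20 iterations, median), and
iterative exclusion of pairs above |r| = 0.8 from the basis system.
Pseudo-p-values come from a null that permutes each taxon's counts
across samples independently (destroying association, preserving
marginals) with +1 smoothing. Edges require |r| > 0.6 and p below the
threshold (0.05 inner, 0.01 outer — both stated conventions appear in
the literature this follows, so both are parameters). Outer (sample)
networks connect only cross-compartment sample pairs by Spearman
correlation of shared-taxon profiles.

Topology: path metrics on the unweighted skeleton of the largest
connected component; global average local clustering; modularity by
greedy (CNM) community detection on absolute weights. Closed forms
anchor the tests (two disconnected 3-cliques: Q = 0.5; K4: clustering
1, diameter 1; star: clustering 0) plus a Floyd–Warshall oracle on
random graphs ≤12 nodes.

Cohesion follows the taxon-shuffle construction: pairwise Pearson
correlations between taxa are corrected by their mean under a null
permuting each taxon's abundances independently (200 shuffles); a
taxon's positive (negative) connectedness is the mean of its positive
(negative) corrected correlations, and a sample's cohesion is its
abundance-weighted sum of connectedness. The headline statistic is
|mean negative cohesion| / mean positive cohesion. The null is applied
in a canonical (sorted-by-id) sample order so results are exactly
invariant to row order at finite shuffle counts.

## Synthetic data: what it emulates, and what it does not

The generators provide ground truth for every estimator:

* **Neutral communities** — local relative abundances drawn from
  Beta(N m p, N m(1−p)) around a log-series metacommunity (θ = 0.995,
  giving the skewed abundance structure with the rare taxa a neutral
  fit needs), multinomial reads at depth N = 1000, 50 taxa × 200
  samples by default.
* **Niche communities** — Gaussian filtering along a gradient with
  optima evolved by Brownian motion on a Yule tree, so selection is
  phylogenetically conserved; selection strength 1 by default ("strong
  filtering" scenarios use 4 with niche breadth 0.5 and samples at the
  two gradient extremes).
* **Correlated compositions** — log-normal basis abundances with a
  specified correlation matrix, closed and multinomially sampled. The
  SparCC recovery scenario uses depth 10⁴: the field's typical
  sequencing depth is tens of thousands of reads per sample, and count
  noise at three-digit per-taxon counts would otherwise dominate the
  attenuation of the estimate.
* **Source/sink mixtures** — sinks drawn multinomially from explicit
  mixtures of source profiles, remainder from a held-out unknown.
* **Continuum** — nested taxon filtering soil → endosphere (retain
  fractions 0.6/0.3/0.1, biased toward abundant taxa) plus a 0.3
  colonisation carryover from each parent compartment, emulating the
  colonisation cascade by which root interiors are seeded from the
  root surface; site-level log-normal wobble (σ = 0.3) keeps samples
  non-iid.

All generators are pure functions of (config, seed) and return
integer-identical tables across runs. They deliberately omit
sequencing error, chimeras, taxonomy, spatial autocorrelation and
real-data compositional pathologies (e.g. structural zeros); passing
recovery tests therefore demonstrates estimator correctness under the
stated models, not robustness to every artifact of real amplicon data.

## Problem sizes and numerical choices

Desk-scale defaults keep the full test suite and the reproduction
script in the minutes range: 199 null iterations for βNTI in tests
(999 in production defaults), 999 for RC_bray, 200 samples for
parameter-recovery scenarios, 1000 replicate label draws for the
PERMANOVA calibration. Distance matrices are validated to symmetry
1e-12 with exactly zero diagonals; the Sloan optimiser uses bounded
scalar minimisation with xatol 1e-8; IRLS steps are clamped to ±3 on
the log scale for stability at extreme counts; SparCC basis variances
are floored at 1e-12 before the correlation division. Pipeline stages
derive per-stage seeds from the global seed through a counter-based
`SeedSequence`, so any stage can be re-run in isolation and two runs
of the same config are byte-identical.

## Known limitations

* βNTI nulls are computed over whatever sample set is passed; the
  package does not decide for the user whether nulls should be built
  within or across microhabitats (the pipeline defaults to grouping by
  microhabitat when summarising).
* The NB pipeline tests one coefficient at a time (compartment vs
  reference) and does not model zero inflation or compositional
  effects beyond size factors.
* SparCC p-values use a column-permutation null rather than resampling
  rows, since row resampling preserves the very associations under
  test.
* The unknown source in Gibbs attribution absorbs systematic lack of
  fit; attribution percentages are only interpretable relative to the
  supplied source panel.
* Per-site differential calls pool sites within grassland type as
  replicates; within-site contrasts have no replication and are not
  attempted.
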