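# Methods

## Scope and model

micronet infers and compares *signed interaction structure* between two
groups of microbiome samples. The statistical object is, per group, the
semi-weighted matrix W: W_ij equals the Spearman rank correlation of
taxa i and j across the group's individuals when the two-sided test is
significant, and 0 otherwise. Positive entries are read as mutualism /
co-occurrence, negative entries as competition / co-exclusion. All
downstream quantities — degree, strength, hubs, transitivity, cohesion,
the M-C ratio, stability — are functionals of W and of the per-sample
relative abundances.

The method is correlational: an "interaction" is a reproducible
monotone statistical association, not a demonstrated mechanism, and
compositional effects (see Limitations) are part of the measured
signal, as they are in the upstream literature this design follows.

## Pipeline stages and the parameters that matter

**Core selection.** A taxon is core for a group when it is observed
(count > 0, no minimum-count floor) in at least `threshold` of the
group's samples. Default 0.75; the comparison is inclusive
(prevalence ≥ threshold) so a taxon present in exactly 75 % of samples
is kept. Per-group networks are built on the *overlap* of the two
group cores so that node sets match.

**Normalization.** Relative abundance divides each count by the
sample's total over *all* taxa in the table, not just the core. The
alternative reading (normalizing within the core) would make the
retained-read fraction meaningless and re-close the composition on a
subset; the full-total convention keeps core rows a sub-composition of
the whole and is what `retained_fraction` reports against.

**Association screen.** Spearman ρ via Pearson on midranks; two-sided
p from the t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df, the
standard large-sample approximation (|ρ| = 1 maps to p = 0). An exact
permutation p (full enumeration) is available for n ≤ 10 and serves as
the testing oracle. Constant taxa yield ρ = 0, p = 1 with a logged
warning rather than an error, since prevalence filtering does not
preclude constant columns in small tables. The edge threshold is a
fixed α = 10⁻⁵ — a Bonferroni-style guard for the ~10³ tests a
47-taxon core generates (0.05/1081 ≈ 4.6·10⁻⁵; the stricter round
value is the default and both are configurable). Two-sided throughout:
both signs are of scientific interest.

A node-wise adaptive-lasso partial-correlation estimator (two
BIC-selected lasso stages on rank-transformed data, AND rule across
the two directed regressions, sign from the coefficients) is provided
as an alternative `estimator="ggm"` mode. It estimates conditional
rather than marginal dependence; the thresholded Spearman network is
the default because the edge rule and the pair-count arithmetic of the
motivating analysis operate on the marginal correlation space.

**Topology.** Degree counts nonzero weights; strength sums |w|; the
hub core is the top ⌈0.10·N⌉ nodes by degree with deterministic
tie-breaking (strength, then node id) so hub sets are reproducible.
Transitivity is the global clustering coefficient
3·triangles/connected-triples of the binarized view, computed per sign
view with signs ignored inside the view. "Randomly reorganized
networks that maintain the links distribution" is implemented as
degree-preserving double-edge-swap rewiring (10·E successful swaps per
replicate, 1000 replicates), with the original multiset of signed
weights re-assigned to the rewired edges in shuffled order; graphs
with no valid swap (stars) are flagged and their replicates equal the
original. Group comparison permutes group labels over the pooled
samples and rebuilds both networks from scratch per permutation
(empirical two-sided p with +1 correction, Bonferroni over the
statistics tested). A subsample-based variant of the comparison is
deliberately not the default: permutation of labels is the standard
exchangeable null for a two-group contrast, and the subsampling
description it replaces conflates resampling with inference.
Isomorphism testing uses a degree-sequence pre-filter and exact
backtracking (VF2), with an optional timeout returning an inconclusive
result distinct from "not isomorphic".

**Cohesion.** Connectedness c+_i (c−_i) is the *mean* of taxon i's
strictly positive (negative) significant edge weights, 0 when it has
none; a sum variant exists behind `mode="sum"` for sensitivity
analysis. The mean keeps connectedness bounded in [−1, 1] and makes
cohesion comparable across nodes of different degree. Per sample,
C±_j = Σ_i a_ij·c±_i. The M-C ratio C+_j/|C−_j| is computed per
individual and then summarized (mean ± sd), matching the reported
per-individual dispersion convention; it is missing (NaN) exactly when
C−_j = 0. The null-model correction that some cohesion formulations
apply to the correlation matrix is intentionally not applied: the
implemented definition is the direct projection of the semi-weighted
matrix onto relative abundances. Group contrasts use two-sided
rank-sum tests, Bonferroni-corrected over the three metrics; coupling
is the squared Pearson correlation of C+ and C− within a group.

**Diversity.** Computed on raw counts (Chao1 needs
singletons/doubletons, which normalization destroys). Shannon in
log base 2 with equitability H/log₂(S) in the same base; Simpson as
1 − Σp²; Chao1 in the classic form S + F1²/(2F2), switching to the
bias-corrected S + F1(F1−1)/2 only when F2 = 0 to avoid the zero
division. Faith's PD is the total branch length of the union of
root-paths of observed tips (root-inclusive: PD of all taxa equals the
total tree length), implemented directly on the tree so multifurcating
(star) roots are accepted. No rarefaction is performed; a seeded
fixed-depth multinomial subsampler is provided for comparability
experiments. M-C/diversity correlations default to Pearson with
Spearman available — the upstream choice of coefficient is unstated,
so both are exposed and the default documented here.

**Stability.** Case-dropping subsampling without replacement
(fractions 1.0 → 0.5 in steps of 0.05, 25 iterations per fraction),
rebuilding the network on the full-data core taxa so strength vectors
stay comparable. At fraction 1.0 the subsample is the data itself and
the correlation is exactly 1 by construction. CS is the largest drop
fraction such that, at that drop and every smaller tested drop, the
subsample-vs-full strength correlation reaches 0.7 in ≥ 95 % of
iterations — the conventional constants of the case-dropping
centrality-stability bootstrap, which the cited protocol leaves
implicit. The per-fraction mean strength ratio (subsample total
strength / full total strength) is reported alongside, covering the
alternative "a 75 % subset retains x % of the strength" reading.
Plain per-node strength is used as the centrality; bridge variants
would require community assignments that are never defined upstream.

## The synthetic cohort: what it emulates, and what it does not

`coupled_cohort` generates the study conditions end to end: 64
active-like (ACT) and 45 sedentary-like (SED) individuals over a
shared 85-taxon pool; prevalence targets are set so that core
selection at 75 % yields 55 ACT core taxa, 52 SED core taxa and
exactly 47 in the overlap, with 25 noise taxa below the filter.
Counts come from a Gaussian copula: a latent normal with the planted
correlation matrix is pushed through per-taxon negative-binomial
quantile functions (means log-normal around 150 with σ = 0.5,
dispersion U(1.5, 4), per-sample log-normal depth factors with
CV 0.3). Prevalence targets above the NB's non-zero probability are
hit by truncating the zero quantile mass (so a target of 1.0 yields no
zeros at all); targets below it by independent Bernoulli masking,
which lets the prevalence filter be exercised independently of
abundance.

Planted structure per group:

- ACT-like: five mutualism blocks (6, 5, 5, 4, 4 taxa, pairwise
  ρ = +0.8) plus four independent *competition modules*, each a
  dedicated 3-taxon positive block with one competitor taxon
  anti-correlated at −0.85 with every member. Spreading competition
  over small independent factors — and giving the competitor taxa a
  3× abundance boost so C− variance is dominated by noise outside
  C+ — keeps positive and negative cohesion uncoupled, as in the real
  active group.
- SED-like: two mutualism blocks (5, 4 taxa, ρ = +0.8), each attacked
  by one competitor at −0.85. Because the attacked blocks also drive
  C+, the group's C− tracks its C+ across individuals: the coupling
  signature (R² typically 0.6–1.0) with fewer planted competitive
  edges overall.

Effect sizes are 0.8/0.85 rather than the 0.7 used in the dedicated
recovery benchmark because two attenuation channels sit between the
latent correlation and the measured one: the rank/copula transfer
(≈ 0.03) and compositional common-mode noise from dividing by the
sample total (≈ 0.1), and because n = 45 at α = 10⁻⁵ only detects
observed |ρ| ≳ 0.62. The planted pattern is repaired to positive
semi-definite by eigenvalue clipping and unit-diagonal rescaling
(tolerance 10⁻¹⁰); a pattern whose planted entries move by more than
0.1 under repair is rejected with the offending pairs named, rather
than silently distorted. Anti-block competitors are PSD-exact by
construction (the competitor loads −ρ_neg/√ρ_pos on the block factor).

What the generator does **not** emulate: taxonomic identity and
phylogeny (taxa are anonymous, so Faith PD on real trees is exercised
only through fixtures), sequencing error and chimeras, rarefaction,
overdispersion heavier than NB, and the absolute scale of the real
cohort's diversity or cohesion values. Passing tests therefore show
that the chain recovers planted interaction structure and group
contrasts under realistic count noise — not that any particular real
dataset would yield particular values.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: the
study-sized cohort (109 samples, 85 taxa) for the end-to-end
quantities; 25 replicates of a 24-taxon, n = 100 cohort at |ρ| = 0.7
for edge recovery; 100 noise cohorts (47 taxa, n = 50) for the null
false-edge rate; 200 simulations with 200 permutations each for the
type-I check of the group comparison; and 10 replicates of a 20-taxon,
n = 150 strong-signal cohort for CS. Null-ensemble and permutation
defaults in the library remain 1000; the smaller counts in tests are
test problem sizes, chosen so the whole suite stays interactive.

## Known limitations

- Compositional closure induces weak negative background correlation
  and a shared-denominator coupling between C+ and C−; the package
  measures it (it is visible as the small but nonzero ACT-like
  coupling R²) rather than removing it. Log-ratio (SparCC-style)
  estimators are out of scope by design.
- The fixed α = 10⁻⁵ with n = 45 implies a detection floor near
  |ρ| ≈ 0.6; weaker real interactions are invisible at this sample
  size, which is a property of the method, not of the implementation.
- The exact-permutation Spearman p is exponential in n and gated to
  n ≤ 10; it exists as an oracle, not a production path.
- `is_isomorphic` with a timeout cannot cancel the underlying search,
  only abandon it (daemon thread); for the N ≤ 60 networks in scope
  the exact test returns promptly.
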