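# micronet

Signed co-occurrence / competition network analysis for gut-microbiome
cohorts: from an OTU count table to core-taxon selection, a
significance-thresholded signed Spearman network per group, topology and
null-model calibration, per-sample community **cohesion** and the
**mutualism–competition (M-C) ratio**, the coupling between positive and
negative cohesion, alpha-diversity correlations, and subsampling
stability. A synthetic two-group cohort generator with planted ground
truth makes the whole chain testable without sequencing data.

## Who is this for

Microbiome researchers comparing the *interaction structure* of two
groups of individuals (e.g. active vs sedentary lifestyles, cases vs
controls) rather than just taxon abundances. The package asks: do the
groups differ in how taxa co-occur (mutualism) and co-exclude
(competition), and does the balance between the two track microbial
diversity?

## The method

For each group with samples *j = 1..n* and core taxa *i = 1..N*
(taxa present in ≥ 75 % of the group's samples):

1. **Association screen.** All N(N−1)/2 pairs are tested with
   Spearman's rank correlation ρ (two-sided p from
   t = ρ√((n−2)/(1−ρ²)) on n−2 df). With the 47-taxon shared core of
   the motivating cohort this is 46·(47/2) = 1081 tests; pairs are kept
   at the fixed Bonferroni-guard threshold p < 10⁻⁵.
2. **Semi-weighted network.** W\_ij = ρ\_ij if significant, else 0.
   Positive entries are mutualism (co-occurrence), negative entries
   competition (co-exclusion). Degree, strength, the hub core
   (top 10 % of nodes by degree), and transitivity are computed per
   sign view and calibrated against 1000 degree-preserving rewired
   networks; groups are compared with a label-permutation test.
3. **Cohesion.** Each taxon's positive/negative *connectedness*
   c±\_i is the mean of its significant edge weights of that sign;
   per sample, C±\_j = Σ\_i a\_ij · c±\_i with a\_ij the relative
   abundance. The **M-C ratio** is C+\_j / |C−\_j|, and the C+ vs C−
   coupling within a group is the squared Pearson correlation R².
4. **Diversity.** Observed species, Chao1, Shannon (log₂), Simpson,
   equitability and Faith's PD per sample, correlated with the M-C
   ratio within each group.
5. **Stability.** The group network is rebuilt on subsamples of
   individuals (fractions 1.0 → 0.5, 25 iterations each); the
   correlation-stability (CS) coefficient is the largest fraction of
   individuals that can be dropped while subsample node strength stays
   correlated ≥ 0.7 with the full-data strength in ≥ 95 % of
   iterations.

## Worked example

```python
from micronet import (
    CohortSpec, coupled_cohort, select_core, overlap_core,
    relative_abundance, spearman_matrix, threshold_network,
    split_signs, cohesion, coupling, mean_interactions,
)

table_act, table_sed, truth_act, truth_sed = coupled_cohort(CohortSpec(), seed=1)

core_act = select_core(table_act, "ACT", threshold=0.75)
core_sed = select_core(table_sed, "SED", threshold=0.75)
shared = overlap_core(core_act, core_sed)
print(f"core sizes: ACT={len(core_act)} SED={len(core_sed)} shared={len(shared)}")

for group, table in [("ACT", table_act), ("SED", table_sed)]:
    rel = relative_abundance(table, shared)
    net = threshold_network(spearman_matrix(rel), alpha=1e-5)
    pos, neg = split_signs(net)
    prof = cohesion(rel, net, table.group_labels)
    r2 = coupling(prof, group).r_squared
    print(
        f"{group}: {pos.n_edges:3d} mutualistic / {neg.n_edges:2d} competitive edges, "
        f"mean negative interactions {mean_interactions(neg):.2f}, "
        f"M-C ratio {prof.data.mc_ratio.mean():.2f} +/- {prof.data.mc_ratio.std():.2f}, "
        f"C+/C- coupling R^2 = {r2:.2f}"
    )
```

prints

```
core sizes: ACT=55 SED=52 shared=47
ACT:  52 mutualistic / 13 competitive edges, mean negative interactions 0.55, M-C ratio 1.54 +/- 0.31, C+/C- coupling R^2 = 0.02
SED:  13 mutualistic /  8 competitive edges, mean negative interactions 0.34, M-C ratio 0.76 +/- 0.18, C+/C- coupling R^2 = 0.58
```

Read: the active-like group's core carries more interactions of both
signs and a higher mutualism-to-competition balance, while in the
sedentary-like group positive and negative cohesion are tightly coupled
(R² = 0.58) — each individual's competitive load is predictable from
its mutualistic load, the signature of a less complex, less redundant
community. These are exactly the planted study conditions of the
generator, recovered by the analysis chain.

The same chain runs from the shell:

```bash
micronet simulate --seed 1 --out sim/
micronet run-all --table sim/counts.tsv --metadata sim/metadata.tsv \
    --seed 1 --out results/
```

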