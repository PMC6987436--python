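"""Synthetic OTU count tables with known interaction structure.

Counts are generated by a Gaussian copula: a latent multivariate normal
with a planted correlation matrix (positive blocks for mutualism,
negative pairs for competition, zeros elsewhere, repaired to positive
semi-definite) is pushed through per-taxon negative-binomial quantile
functions, so the *sign* of the planted rank correlation survives
exactly.  Per-taxon prevalence targets are hit by quantile truncation
(to raise prevalence) or independent Bernoulli masking (to lower it),
which lets the 75% core-prevalence filter be exercised independently of
abundance.  The two-group cohort generator emulates an active-vs-
sedentary study design: a 47-taxon shared core plus group-specific core
taxa and low-prevalence noise taxa.  The active-like group carries more
mutualism mass (several small blocks) and more competitive edges,
organized as independent competition modules whose abundant competitor
taxa keep negative cohesion decoupled from positive cohesion; the
sedentary-like group's competitors attack its own mutualism blocks, so
its negative cohesion tracks positive cohesion (the coupling signature)
while its overall interaction mass stays lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceTable

__all__ = [
    "PlantedStructure",
    "CohortSpec",
    "InfeasibleCorrelationError",
    "generate_truth",
    "sample_counts",
    "coupled_cohort",
]

PSD_TOL = 1e-10
#: Maximum allowed change of a planted entry under the PSD projection.
MAX_PROJECTION_SHIFT = 0.1


class InfeasibleCorrelationError(ValueError):
    """The requested correlation pattern cannot be repaired to PSD
    without distorting planted entries beyond tolerance."""


@dataclass
class PlantedStructure:
    """Ground truth emitted by the generator, used for recovery tests."""

    taxon_ids: list[str]
    latent_correlation: np.ndarray
    true_edges: set[tuple[str, str, str]]  # (taxon_i, taxon_j, '+'|'-'), i < j
    mean_abundance: np.ndarray
    dispersion: np.ndarray
    prevalence_targets: np.ndarray
    seed: int | None
    projection_shift: float = 0.0

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def __post_init__(self) -> None:
        eigs = np.linalg.eigvalsh(self.latent_correlation)
        if eigs.min() < -PSD_TOL:
            raise ValueError("latent correlation is not positive semi-definite")
        for a, b, s in self.true_edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            if s not in "+-":
                raise ValueError(f"bad edge sign {s!r}")

    def edges_of_sign(self, sign: str) -> set[tuple[str, str]]:
        return {(a, b) for a, b, s in self.true_edges if s == sign}

    def core_taxa_truth(self, threshold: float = 0.75) -> list[str]:
        """Taxa whose planted prevalence target reaches the threshold."""
        return [
            t
            for t, p in zip(self.taxon_ids, self.prevalence_targets)
            if p >= threshold
        ]


def _resolve_blocks(blocks, n_taxa: int) -> list[list[int]]:
    resolved: list[list[int]] = []
    cursor = 0
    for b in blocks:
        if np.isscalar(b):
            size = int(b)
            if size < 2:
                raise ValueError("block size must be >= 2")
            resolved.append(list(range(cursor, cursor + size)))
            cursor += size
        else:
            resolved.append([int(i) for i in b])
    flat = [i for blk in resolved for i in blk]
    if len(set(flat)) != len(flat):
        raise ValueError("blocks overlap")
    if flat and (max(flat) >= n_taxa or min(flat) < 0):
        raise ValueError("block indices exceed n_taxa")
    return resolved


def generate_truth(
    n_taxa: int,
    blocks=(),
    negative_pairs=(),
    effect_sizes: tuple[float, float] = (0.7, 0.6),
    seed: int | None = None,
    mean_abundance: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
    prevalence_targets: np.ndarray | None = None,
    taxon_prefix: str = "T",
    latent_extras=(),
) -> PlantedStructure:
    """Plant a block/pair correlation pattern and repair it to PSD.

    Parameters
    ----------
    blocks
        Mutualism blocks: each entry is either a block size (taxa are
        assigned consecutively) or an explicit list of taxon indices.
        All within-block pairs get correlation ``+effect_sizes[0]``.
    negative_pairs
        Competition: either explicit (i, j) index pairs, or an integer
        count of disjoint pairs drawn among the non-block taxa.
        Each pair gets correlation ``-effect_sizes[1]``.
    effect_sizes
        (positive, negative) correlation magnitudes, both in (0, 1).
    latent_extras
        Additional (i, j, rho) latent correlations *below* the edge
        effect size — structured background covariance that is not
        part of the planted edge set (and so does not enter
        ``true_edges``).

    The requested matrix is projected to the nearest PSD matrix by
    eigenvalue clipping at zero and rescaling to unit diagonal.  If the
    projection moves any planted entry by more than 0.1 the pattern is
    rejected with the offending pairs named.
    """
    rho_pos, rho_neg = effect_sizes
    if not (0 < rho_pos < 1 and 0 < rho_neg < 1):
        raise ValueError("effect sizes must be in (0, 1)")
    rng = np.random.default_rng(seed)
    block_idx = _resolve_blocks(blocks, n_taxa)
    in_block = {i for blk in block_idx for i in blk}
    if isinstance(negative_pairs, (int, np.integer)):
        pool = [i for i in range(n_taxa) if i not in in_block]
        if 2 * negative_pairs > len(pool):
            raise ValueError("not enough non-block taxa for the requested pairs")
        chosen = rng.choice(pool, size=2 * int(negative_pairs), replace=False)
        negative_pairs = [
            (int(chosen[2 * k]), int(chosen[2 * k + 1]))
            for k in range(int(negative_pairs))
        ]
    negative_pairs = [tuple(sorted((int(i), int(j)))) for i, j in negative_pairs]

    target = np.eye(n_taxa)
    planted: dict[tuple[int, int], float] = {}
    for blk in block_idx:
        for a_pos, i in enumerate(blk):
            for j in blk[a_pos + 1:]:
                key = tuple(sorted((i, j)))
                planted[key] = rho_pos
    for i, j in negative_pairs:
        if i == j:
            raise ValueError("self-pair in negative_pairs")
        key = (i, j)
        if key in planted:
            raise ValueError(f"pair {key} planted both positive and negative")
        planted[key] = -rho_neg
    min_effect = min(rho_pos, rho_neg)
    extras: dict[tuple[int, int], float] = {}
    for i, j, r in latent_extras:
        key = tuple(sorted((int(i), int(j))))
        if key[0] == key[1]:
            raise ValueError("self-pair in latent_extras")
        if key in planted:
            raise ValueError(f"pair {key} is both planted and extra")
        if abs(r) >= min_effect:
            raise ValueError(
                f"latent extra {key} at {r} reaches the edge effect size"
            )
        extras[key] = float(r)
    for (i, j), v in {**planted, **extras}.items():
        target[i, j] = target[j, i] = v

    # nearest-PSD projection: clip eigenvalues at 0, rescale to unit diagonal
    eigval, eigvec = np.linalg.eigh(target)
    repaired = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)

    shifts = {
        key: abs(repaired[key] - v) for key, v in planted.items()
    }
    bad = [key for key, s in shifts.items() if s > MAX_PROJECTION_SHIFT]
    if bad:
        raise InfeasibleCorrelationError(
            f"PSD projection distorts planted pairs beyond "
            f"{MAX_PROJECTION_SHIFT}: {sorted(bad)}"
        )

    width = max(3, len(str(n_taxa)))
    taxon_ids = [f"{taxon_prefix}{i + 1:0{width}d}" for i in range(n_taxa)]
    if mean_abundance is None:
        mean_abundance = np.exp(rng.normal(np.log(100.0), 0.5, size=n_taxa))
    if dispersion is None:
        dispersion = rng.uniform(0.8, 3.0, size=n_taxa)
    if prevalence_targets is None:
        prevalence_targets = np.ones(n_taxa)
    prevalence_targets = np.asarray(prevalence_targets, dtype=float)
    if np.any((prevalence_targets < 0) | (prevalence_targets > 1)):
        raise ValueError("prevalence targets must be in [0, 1]")

    true_edges = {
        (taxon_ids[i], taxon_ids[j], "+" if v > 0 else "-")
        for (i, j), v in planted.items()
    }
    return PlantedStructure(
        taxon_ids=taxon_ids,
        latent_correlation=repaired,
        true_edges=true_edges,
        mean_abundance=np.asarray(mean_abundance, dtype=float),
        dispersion=np.asarray(dispersion, dtype=float),
        prevalence_targets=prevalence_targets,
        seed=seed,
        projection_shift=max(shifts.values()) if shifts else 0.0,
    )


def sample_counts(
    truth: PlantedStructure,
    n_samples: int,
    depth_params: tuple[float, float] = (1.0, 0.3),
    seed: int | None = None,
    sample_prefix: str = "S",
    group: str | None = None,
) -> AbundanceTable:
    """Draw a taxa x samples count table from a planted structure.

    A latent Gaussian draw with the planted correlation is mapped to
    negative-binomial counts per taxon via quantile transformation
    (mean scaled by a per-sample log-normal depth factor, shape =
    ``dispersion``).  Prevalence targets above the marginal
    non-zero probability are met by truncating the zero mass of the
    quantile map; targets below it by independent Bernoulli masking.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    depth_mean, depth_cv = depth_params
    if depth_mean <= 0:
        raise ValueError("degenerate sequencing depth: mean factor must be > 0")
    rng = np.random.default_rng(seed)
    p_taxa = truth.n_taxa

    # latent Gaussian with the planted correlation
    eigval, eigvec = np.linalg.eigh(truth.latent_correlation)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((n_samples, p_taxa)) @ root.T
    u = stats.norm.cdf(z).T  # taxa x samples

    if depth_cv > 0:
        sigma = np.sqrt(np.log1p(depth_cv**2))
        factors = depth_mean * np.exp(
            rng.normal(-sigma**2 / 2.0, sigma, size=n_samples)
        )
    else:
        factors = np.full(n_samples, depth_mean)

    mu = truth.mean_abundance[:, None] * factors[None, :]
    k = truth.dispersion[:, None]
    nb_p = k / (k + mu)
    pi0 = nb_p**k  # P(count = 0) per cell
    target_zero = 1.0 - truth.prevalence_targets[:, None]

    # raise prevalence: remap u away from the zero mass
    shift = np.where(
        pi0 > target_zero,
        (pi0 - target_zero) / np.maximum(1.0 - target_zero, 1e-300),
        0.0,
    )
    shift = np.clip(shift, 0.0, 1.0 - 1e-12)
    u_adj = shift + u * (1.0 - shift)
    counts = stats.nbinom.ppf(np.clip(u_adj, 0.0, 1.0 - 1e-12), k, nb_p)

    # lower prevalence: independent per-cell Bernoulli masking
    mask_prob = np.where(
        pi0 < target_zero, (target_zero - pi0) / np.maximum(1.0 - pi0, 1e-300), 0.0
    )
    masked = rng.random(counts.shape) < mask_prob
    counts = np.where(masked, 0, counts).astype(np.int64)

    width = max(3, len(str(n_samples)))
    sample_ids = [f"{sample_prefix}{j + 1:0{width}d}" for j in range(n_samples)]
    frame = pd.DataFrame(counts, index=truth.taxon_ids, columns=sample_ids)
    labels = {s: group for s in sample_ids} if group is not None else {}
    return AbundanceTable(frame, labels)


@dataclass
class CohortSpec:
    """Study-design parameters of the two-group synthetic cohort.

    Defaults mirror the active/sedentary cohort layout: 64 and 45
    individuals, a 47-taxon shared core (55- and 52-taxon per-group
    cores), low-prevalence noise taxa making the 75% filter
    non-trivial, more mutualism block mass and more competitive pairs
    in the active-like group, and competitive pairs embedded in the
    sedentary-like group's mutualism blocks.
    """

    n_group_a: int = 64
    n_group_b: int = 45
    group_names: tuple[str, str] = ("ACT", "SED")
    n_shared_core: int = 47
    n_extra_core_a: int = 8
    n_extra_core_b: int = 5
    n_noise: int = 25
    rho_pos: float = 0.8
    #: negative effect size per group; the sedentary-like group gets a
    #: stronger one so its competitive edges stay detectable at n = 45
    #: under the fixed 1e-5 threshold.
    rho_neg_a: float = 0.85
    rho_neg_b: float = 0.85
    #: the active-like group spreads mutualism over many small blocks
    #: (modular structure); the sedentary-like group concentrates it in
    #: two large blocks.
    blocks_a: tuple[int, ...] = (6, 5, 5, 4, 4)
    blocks_b: tuple[int, ...] = (5, 4)
    #: planted negative edges per group as a fraction of half the core
    #: size; the active-like group competes more (paper-direction).
    competition_density_a: float = 0.50
    competition_density_b: float = 0.38
    #: size of each active-like competition module's positive block.
    competition_module_size: int = 3
    #: abundance multiplier for the active-like competitor taxa; large
    #: competitors give C- its own variance, decoupling it from C+.
    competitor_mean_boost: float = 3.0
    core_prevalence: float = 0.97
    extra_core_prevalence: float = 0.92
    off_group_prevalence: float = 0.35
    noise_prevalence: float = 0.45
    depth_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.n_group_a < 4 or self.n_group_b < 4:
            raise ValueError("group sizes must be >= 4")
        for rho in (self.rho_pos, self.rho_neg_a, self.rho_neg_b):
            if not 0 < rho < 1:
                raise ValueError("effect sizes must be in (0, 1)")
        for d in (self.competition_density_a, self.competition_density_b):
            if not 0 <= d <= 1:
                raise ValueError("competition densities must be in [0, 1]")
        if self.competition_density_b >= self.competition_density_a:
            raise ValueError(
                "group B (sedentary-like) must have lower competition density"
            )

    @property
    def n_taxa(self) -> int:
        return (
            self.n_shared_core + self.n_extra_core_a + self.n_extra_core_b
            + self.n_noise
        )

    def n_negative_edges(self, density: float) -> int:
        """Planted negative edges: density x core size / 2 (>= 1)."""
        return max(1, round(density * self.n_shared_core / 2.0))


def _competition_a(
    spec: CohortSpec,
) -> tuple[list[list[int]], list[tuple[int, int]], list[int]]:
    """Active-like competition: several small independent modules, each
    a dedicated positive block plus one competitor taxon anti-correlated
    with every block member.  Spreading competition over many small
    factors keeps C- variance diversified, so C+ and C- stay uncoupled.

    Returns (module_blocks, negative_pairs, competitor_indices); module
    blocks occupy taxa directly after the main blocks."""
    target_edges = spec.n_negative_edges(spec.competition_density_a)
    m = spec.competition_module_size
    n_modules = max(1, round(target_edges / m))
    cursor = sum(spec.blocks_a)
    module_blocks: list[list[int]] = []
    pairs: list[tuple[int, int]] = []
    competitors: list[int] = []
    for _ in range(n_modules):
        members = list(range(cursor, cursor + m))
        competitor = cursor + m
        cursor += m + 1
        module_blocks.append(members)
        competitors.append(competitor)
        pairs.extend((competitor, mem) for mem in members)
    if cursor > spec.n_shared_core:
        raise ValueError("not enough shared-core taxa for group A competition")
    return module_blocks, pairs, competitors


def _competition_b(spec: CohortSpec) -> tuple[list[tuple[int, int]], list[int]]:
    """Sedentary-like competition: one competitor taxon per mutualism
    block, anti-correlated with every member of its block.  Because the
    targeted blocks also drive positive cohesion, C- tracks C+ across
    individuals — the coupling signature of this group."""
    blocks = _resolve_blocks(spec.blocks_b, spec.n_taxa)
    cursor = sum(spec.blocks_b)
    pairs: list[tuple[int, int]] = []
    competitors: list[int] = []
    for block in blocks:
        competitor = cursor
        cursor += 1
        competitors.append(competitor)
        pairs.extend((competitor, mem) for mem in block)
    if cursor > spec.n_shared_core:
        raise ValueError("not enough shared-core taxa for group B competition")
    return pairs, competitors


def coupled_cohort(
    spec: CohortSpec | None = None, seed: int | None = None
) -> tuple[AbundanceTable, AbundanceTable, PlantedStructure, PlantedStructure]:
    """Generate the two-group cohort with shared taxa and group-specific
    interaction structure.

    Returns (table_a, table_b, truth_a, truth_b).  Both groups share
    the same taxon pool and marginal count parameters; prevalence
    targets make exactly ``n_shared_core`` taxa core in both groups,
    plus group-specific extra core taxa, with the remainder below the
    75% filter.  Group B has strictly fewer planted negative pairs than
    group A.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(seed)
    s_truth, s_a, s_b = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    n = spec.n_taxa
    shared = spec.n_shared_core
    extra_a = list(range(shared, shared + spec.n_extra_core_a))
    extra_b = list(
        range(shared + spec.n_extra_core_a,
              shared + spec.n_extra_core_a + spec.n_extra_core_b)
    )
    noise = list(range(shared + spec.n_extra_core_a + spec.n_extra_core_b, n))

    # shared marginals so both groups describe the same organisms
    marg_rng = np.random.default_rng(s_truth)
    means = np.exp(marg_rng.normal(np.log(150.0), 0.5, size=n))
    disp = marg_rng.uniform(1.5, 4.0, size=n)

    prev_a = np.full(n, spec.core_prevalence)
    prev_b = np.full(n, spec.core_prevalence)
    prev_a[extra_a] = spec.extra_core_prevalence
    prev_b[extra_a] = spec.off_group_prevalence
    prev_b[extra_b] = spec.extra_core_prevalence
    prev_a[extra_b] = spec.off_group_prevalence
    prev_a[noise] = spec.noise_prevalence
    prev_b[noise] = spec.noise_prevalence

    module_blocks, pairs_a, competitors_a = _competition_a(spec)
    pairs_b, _competitors_b = _competition_b(spec)
    means = means.copy()
    means[competitors_a] *= spec.competitor_mean_boost

    common = dict(n_taxa=n, mean_abundance=means, dispersion=disp)
    truth_a = generate_truth(
        blocks=list(spec.blocks_a) + module_blocks,
        negative_pairs=pairs_a,
        effect_sizes=(spec.rho_pos, spec.rho_neg_a),
        prevalence_targets=prev_a,
        seed=s_truth,
        **common,
    )
    truth_b = generate_truth(
        blocks=spec.blocks_b,
        negative_pairs=pairs_b,
        effect_sizes=(spec.rho_pos, spec.rho_neg_b),
        prevalence_targets=prev_b,
        seed=s_truth,
        **common,
    )
    if not len(truth_b.edges_of_sign("-")) < len(truth_a.edges_of_sign("-")):
        raise ValueError(
            "competition densities round to equal pair counts; "
            "group B must have strictly fewer negative pairs"
        )

    table_a = sample_counts(
        truth_a,
        spec.n_group_a,
        depth_params=(1.0, spec.depth_cv),
        seed=s_a,
        sample_prefix=f"{spec.group_names[0]}_",
        group=spec.group_names[0],
    )
    table_b = sample_counts(
        truth_b,
        spec.n_group_b,
        depth_params=(1.0, spec.depth_cv),
        seed=s_b,
        sample_prefix=f"{spec.group_names[1]}_",
        group=spec.group_names[1],
    )
    return table_a, table_b, truth_a, truth_b
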