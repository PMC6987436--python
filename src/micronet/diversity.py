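"""Alpha diversity and its relationship with the M-C ratio.

Indices per sample: observed species, Chao1 richness, Shannon entropy
(log base 2, matching the QIIME 1 convention), Simpson's index
(1 - sum p^2), equitability (Shannon / log2 richness), and Faith's
phylogenetic diversity when a rooted tree is supplied.  Diversity is
computed on raw counts — Chao1 needs singleton/doubleton counts, which
relative abundances destroy.  A seeded fixed-depth multinomial
subsampler is provided for comparability experiments; no rarefaction is
performed by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson

from .cohesion import CohesionProfile
from .core import AbundanceTable

__all__ = [
    "DiversityProfile",
    "CorrelationReport",
    "chao1",
    "faith_pd",
    "alpha_diversity",
    "subsample_counts",
    "correlate_mc_diversity",
]

INDEX_COLUMNS = [
    "observed_species",
    "chao1",
    "shannon",
    "simpson",
    "equitability",
    "faith_pd",
]


@dataclass
class DiversityProfile:
    """Per-sample alpha-diversity indices (faith_pd NaN without a tree)."""

    data: pd.DataFrame  # index: sample ids; columns: INDEX_COLUMNS (+ group)


@dataclass
class CorrelationReport:
    group: str
    method: str
    table: pd.DataFrame  # index: diversity index; columns: r, p_value
    n: int


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2).

    Falls back to the bias-corrected form S_obs + F1(F1-1)/2 when there
    are no doubletons, and equals S_obs when there are no singletons.
    """
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1**2 / (2.0 * f2)


def faith_pd(counts: np.ndarray, taxa: list[str], tree: TreeNode) -> float:
    """Faith's phylogenetic diversity, root-inclusive.

    Total branch length of the union of paths from every observed
    taxon's tip to the tree root.  With all taxa observed this equals
    the total branch length of the tree.
    """
    counts = np.asarray(counts)
    observed = [t for t, c in zip(taxa, counts) if c > 0]
    if not observed:
        return 0.0
    tips = {tip.name: tip for tip in tree.tips()}
    missing = [t for t in observed if t not in tips]
    if missing:
        raise ValueError(f"tree is missing observed taxa: {missing}")
    seen: set[int] = set()
    total = 0.0
    for name in observed:
        node = tips[name]
        while node.parent is not None:
            if id(node) in seen:
                break
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def _sample_indices(counts: np.ndarray, taxa: list[str], tree: TreeNode | None) -> dict:
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    p = counts[counts > 0] / total
    s_obs = int((counts > 0).sum())
    sh = float(_skbio_shannon(counts[counts > 0].astype(int), base=2))
    out = {
        "observed_species": s_obs,
        "chao1": chao1(counts),
        "shannon": sh,
        "simpson": float(_skbio_simpson(counts[counts > 0].astype(int))),
        "equitability": sh / np.log2(s_obs) if s_obs > 1 else np.nan,
        "faith_pd": faith_pd(counts, taxa, tree) if tree is not None else np.nan,
    }
    return out


def alpha_diversity(
    table: AbundanceTable, tree: TreeNode | None = None
) -> DiversityProfile:
    """Alpha-diversity indices for every sample of a count table."""
    taxa = table.taxon_ids
    rows = {}
    for s in table.sample_ids:
        rows[s] = _sample_indices(table.counts[s].to_numpy(), taxa, tree)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    df["group"] = [table.group_labels.get(s, "") for s in df.index]
    return DiversityProfile(df)


def subsample_counts(
    table: AbundanceTable, depth: int, seed: int | None = None
) -> AbundanceTable:
    """Seeded multinomial subsampling of every sample to a fixed depth.

    Samples with fewer than ``depth`` reads are dropped (with their
    labels), mirroring standard even-depth comparability protocols.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    cols = {}
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        if c.sum() < depth:
            continue
        picked = rng.choice(np.repeat(np.arange(c.size), c), size=depth, replace=False)
        cols[s] = np.bincount(picked, minlength=c.size)
    if not cols:
        raise ValueError("no sample reaches the requested depth")
    counts = pd.DataFrame(cols, index=table.counts.index)
    labels = {s: g for s, g in table.group_labels.items() if s in cols}
    return AbundanceTable(counts, labels)


def correlate_mc_diversity(
    cohesion_profile: CohesionProfile,
    diversity: DiversityProfile,
    group: str,
    method: str = "pearson",
    p_threshold: float | None = None,
) -> CorrelationReport:
    """Correlate the per-sample M-C ratio with each diversity index.

    ``method`` is "pearson" (default) or "spearman".  With
    ``p_threshold`` set, only indices whose two-sided p-value falls
    below it are reported (a reporting filter, not a correction).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    coh = cohesion_profile.for_group(group)["mc_ratio"].dropna()
    if coh.empty:
        raise ValueError(f"no samples with a defined M-C ratio in group {group!r}")
    div = diversity.data.loc[[s for s in coh.index if s in diversity.data.index]]
    common = div.index
    if len(common) < 5:
        raise ValueError("need at least 5 samples with a defined M-C ratio")
    x = coh.loc[common].to_numpy()
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = {}
    for col in INDEX_COLUMNS:
        y = div[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 5 or np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
            continue
        r, p = corr(x[ok], y[ok])
        if p_threshold is None or p < p_threshold:
            rows[col] = {"r": float(r), "p_value": float(p)}
    tab = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p_value"])
    tab.index.name = "index"
    return CorrelationReport(group=group, method=method, table=tab, n=len(common))
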