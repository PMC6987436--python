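"""Core-taxon selection and abundance normalization.

The analyses downstream (association networks, cohesion) operate on a
"core" microbiota: taxa present in at least a prevalence threshold
(default 75%) of each group's samples.  Core filtering avoids
zero-inflated correlation artifacts while retaining most of each
sample's reads.  Counts are converted to relative abundances by
dividing by the *full-table* sample total, so that core rows remain a
subset of a compositional whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "CoreSet",
    "prevalence",
    "select_core",
    "overlap_core",
    "relative_abundance",
    "retained_fraction",
]


@dataclass
class AbundanceTable:
    """A taxa x samples count matrix with group labels.

    Parameters
    ----------
    counts
        DataFrame with taxon ids as the index and sample ids as
        columns.  Entries must be non-negative integers.
    group_labels
        Mapping ``sample_id -> group name``.  May be empty when no
        group-wise operation is used.
    """

    counts: pd.DataFrame
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        samples = [s for s in self.sample_ids if self.group_labels.get(s) == group]
        if not samples:
            raise KeyError(f"unknown or empty group: {group!r}")
        return samples

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        labels = {s: self.group_labels[s] for s in sample_ids if s in self.group_labels}
        return AbundanceTable(self.counts[list(sample_ids)], labels)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.group_labels.get(s)
            if g is not None and g not in seen:
                seen.append(g)
        return seen


@dataclass
class CoreSet:
    """Result of prevalence-based core selection for one group."""

    group: str
    threshold: float
    core_taxa: list[str]
    prevalence: dict[str, float]

    def __len__(self) -> int:
        return len(self.core_taxa)


def prevalence(table: AbundanceTable, group: str) -> dict[str, float]:
    """Fraction of a group's samples in which each taxon is observed.

    A taxon counts as present in a sample when its count is strictly
    positive; no minimum-count floor is applied.
    """
    samples = table.samples_in_group(group)
    sub = table.counts[samples]
    frac = (sub.to_numpy() > 0).mean(axis=1)
    return dict(zip(table.taxon_ids, frac.tolist()))


def select_core(table: AbundanceTable, group: str, threshold: float = 0.75) -> CoreSet:
    """Select taxa present in at least ``threshold`` of the group's samples.

    The comparison is inclusive (prevalence >= threshold) and the input
    taxon order is preserved.  An empty core is returned (with a logged
    warning), not raised.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    prev = prevalence(table, group)
    core = [t for t in table.taxon_ids if prev[t] >= threshold]
    if not core:
        logger.warning(
            "core selection for group %r at threshold %.3f yielded no taxa",
            group,
            threshold,
        )
    return CoreSet(group=group, threshold=threshold, core_taxa=core, prevalence=prev)


def overlap_core(core_a: CoreSet, core_b: CoreSet) -> list[str]:
    """Taxa in both cores, in the order of ``core_a``."""
    in_b = set(core_b.core_taxa)
    return [t for t in core_a.core_taxa if t in in_b]


def relative_abundance(
    table: AbundanceTable, taxa_subset: list[str] | None = None
) -> pd.DataFrame:
    """Relative abundances of ``taxa_subset`` rows.

    Each entry is the taxon's count divided by the sample's total count
    over *all* taxa in the table, so subset rows generally do not sum
    to one per sample.
    """
    if taxa_subset is None:
        taxa_subset = table.taxon_ids
    if not list(taxa_subset):
        raise ValueError("taxa_subset must be non-empty")
    missing = [t for t in taxa_subset if t not in table.counts.index]
    if missing:
        raise KeyError(f"taxa not in table: {missing}")
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    return table.counts.loc[list(taxa_subset)].astype(float).div(totals, axis=1)


def retained_fraction(
    table: AbundanceTable, core_taxa: list[str]
) -> tuple[pd.Series, float]:
    """Per-sample fraction of reads captured by the core, and its mean."""
    if not list(core_taxa):
        raise ValueError("core_taxa must be non-empty")
    totals = table.counts.sum(axis=0).astype(float)
    core_totals = table.counts.loc[list(core_taxa)].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (core_totals / totals).fillna(0.0)
    return frac, float(frac.mean())
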