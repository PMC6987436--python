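"""Signed association networks among core taxa.

The primary estimator is the significance-thresholded Spearman rank
correlation: every taxon pair is tested (N(N-1)/2 tests for N taxa; 47
taxa give 1081 pairs) and only pairs whose two-sided p-value falls
below a fixed threshold (default 1e-5, a Bonferroni-style guard over
the ~1000 tests) contribute an edge.  The resulting symmetric
"semi-weighted" matrix carries the correlation coefficient for
significant pairs and zero elsewhere; positive entries are read as
co-occurrence (mutualism), negative entries as co-exclusion
(competition).

A node-wise adaptive-lasso partial-correlation estimator on
rank-transformed data is available as a clearly-labeled alternative
mode; it estimates conditional rather than marginal dependence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "SignedNetwork",
    "spearman_matrix",
    "threshold_network",
    "split_signs",
    "partial_correlation_network",
]

#: Fixed significance threshold used throughout the pipeline.
DEFAULT_ALPHA = 1e-5


@dataclass
class AssociationMatrix:
    """All-pairs Spearman correlations with two-sided p-values."""

    taxon_ids: list[str]
    rho: np.ndarray
    p_values: np.ndarray
    n_samples: int

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_tests(self) -> int:
        n = self.n_taxa
        return n * (n - 1) // 2

    def __post_init__(self) -> None:
        n = len(self.taxon_ids)
        if self.rho.shape != (n, n) or self.p_values.shape != (n, n):
            raise ValueError("matrix shapes do not match taxon count")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if np.nanmax(np.abs(self.rho)) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")


@dataclass
class SignedNetwork:
    """Semi-weighted matrix of significant signed associations.

    ``weights[i, j]`` is the Spearman rho of the pair when significant
    and 0 otherwise; the diagonal is zero.
    """

    taxon_ids: list[str]
    weights: np.ndarray
    alpha: float | None = None

    def __post_init__(self) -> None:
        n = len(self.taxon_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match taxon count")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edges(self) -> list[tuple[str, str, float]]:
        """Significant pairs as (taxon_a, taxon_b, weight), i < j order."""
        out = []
        iu = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(*iu):
            w = self.weights[i, j]
            if w != 0:
                out.append((self.taxon_ids[i], self.taxon_ids[j], float(w)))
        return out

    def edge_set(self, signed: bool = True) -> set[tuple]:
        if signed:
            return {(a, b, "+" if w > 0 else "-") for a, b, w in self.edges()}
        return {(a, b) for a, b, _ in self.edges()}


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for Spearman rho (midranks kept)."""
    n = rx.size
    rxc = rx - rx.mean()
    denom = np.sqrt((rxc**2).sum())
    hits = 0
    total = 0
    for perm in itertools.permutations(ry):
        ryp = np.asarray(perm, dtype=float)
        ryc = ryp - ryp.mean()
        d2 = np.sqrt((ryc**2).sum())
        r = float(rxc @ ryc / (denom * d2)) if denom > 0 and d2 > 0 else 0.0
        if abs(r) >= abs(observed) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def spearman_matrix(
    rel_abundance: pd.DataFrame, method: str = "t-approx"
) -> AssociationMatrix:
    """All-pairs Spearman correlation matrix over taxa (rows).

    Parameters
    ----------
    rel_abundance
        taxa x samples matrix (relative abundances, but any numeric
        values work since only ranks are used).
    method
        ``"t-approx"`` (default): two-sided p from the t statistic
        ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of
        freedom.  ``"exact"``: exhaustive permutation p-values;
        only permitted for n <= 10 samples.

    Constant taxa (zero rank variance) get rho 0 / p 1 for all their
    pairs, with a warning.
    """
    x = rel_abundance.to_numpy(dtype=float)
    n_taxa, n = x.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if method not in ("t-approx", "exact"):
        raise ValueError(f"unknown method: {method!r}")
    if method == "exact" and n > 10:
        raise ValueError("exact permutation p-values only supported for n <= 10")

    constant = x.std(axis=1) == 0
    if constant.any():
        names = [t for t, c in zip(rel_abundance.index, constant) if c]
        logger.warning("constant taxa (rho set to 0, p to 1): %s", names)

    # Spearman = Pearson on midranks.
    ranks = _rank_rows(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0

    if method == "exact":
        p = np.ones((n_taxa, n_taxa))
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                if constant[i] or constant[j]:
                    continue
                p[i, j] = p[j, i] = _exact_spearman_p(ranks[i], ranks[j], rho[i, j])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isnan(t)] = 0.0  # |rho| == 1 -> t infinite -> p = 0
        p[np.abs(rho) >= 1.0] = 0.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 1.0)
    p = (p + p.T) / 2.0
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    return AssociationMatrix(
        taxon_ids=list(rel_abundance.index), rho=rho, p_values=p, n_samples=n
    )


def threshold_network(
    assoc: AssociationMatrix, alpha: float = DEFAULT_ALPHA
) -> SignedNetwork:
    """Keep pairs with p < alpha; zero everything else ("semi-weighted")."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    keep = assoc.p_values < alpha
    weights = np.where(keep, assoc.rho, 0.0)
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0
    return SignedNetwork(taxon_ids=list(assoc.taxon_ids), weights=weights, alpha=alpha)


def split_signs(net: SignedNetwork) -> tuple[SignedNetwork, SignedNetwork]:
    """(mutualism view, competition view): w>0 edges and w<0 edges.

    The two views are disjoint and sum elementwise to the original.
    """
    pos = np.where(net.weights > 0, net.weights, 0.0)
    neg = np.where(net.weights < 0, net.weights, 0.0)
    return (
        SignedNetwork(list(net.taxon_ids), pos, alpha=net.alpha),
        SignedNetwork(list(net.taxon_ids), neg, alpha=net.alpha),
    )


def _adaptive_lasso_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-stage adaptive lasso with BIC-selected penalties."""
    from sklearn.linear_model import LassoLarsIC

    stage1 = LassoLarsIC(criterion="bic").fit(X, y)
    b1 = stage1.coef_
    w = np.abs(b1)
    if not np.any(w > 0):
        return np.zeros_like(b1)
    # Rescale columns by first-stage magnitude; a lasso on the rescaled
    # design is the adaptive lasso with weights 1/|b1|.
    Xw = X * w
    stage2 = LassoLarsIC(criterion="bic").fit(Xw, y)
    return stage2.coef_ * w


def partial_correlation_network(
    rel_abundance: pd.DataFrame, alpha: float | None = None
) -> SignedNetwork:
    """Sparse partial-correlation network via node-wise adaptive lasso.

    Each taxon's ranks are regressed on all others' ranks with a
    two-stage (adaptive) lasso penalty; an edge is kept only when both
    directed coefficients are nonzero (AND rule), with the edge sign
    taken from the coefficients and its weight set to the geometric
    mean of the two standardized coefficients' magnitudes.
    """
    x = rel_abundance.to_numpy(dtype=float)
    n_taxa, n = x.shape
    if n <= 5:
        raise ValueError("need more than 5 samples")
    ranks = _rank_rows(x)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("singular design: constant taxa after rank transform")
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]

    coef = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        others = [j for j in range(n_taxa) if j != i]
        beta = _adaptive_lasso_fit(z[i], z[others].T)
        coef[i, others] = beta

    weights = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            bij, bji = coef[i, j], coef[j, i]
            if bij != 0 and bji != 0 and np.sign(bij) == np.sign(bji):
                weights[i, j] = weights[j, i] = np.sign(bij) * np.sqrt(
                    abs(bij) * abs(bji)
                )
    return SignedNetwork(
        taxon_ids=list(rel_abundance.index), weights=weights, alpha=alpha
    )
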