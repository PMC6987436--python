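"""Community cohesion, the mutualism-competition (M-C) ratio, and
mutualism-competition coupling.

Cohesion projects the signed interaction network onto each sample's
relative abundances.  Every taxon gets a positive and a negative
*connectedness* (the mean of its significant positive / negative edge
weights); a sample's positive cohesion C+ is the abundance-weighted sum
of positive connectedness over taxa, and likewise C- for the negative
side.  The per-sample M-C ratio C+/|C-| summarizes the balance between
co-occurrence and co-exclusion structure an individual's community
engages; the coupling analysis asks whether C+ and C- covary across a
group's individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import SignedNetwork

__all__ = [
    "CohesionProfile",
    "CouplingResult",
    "connectedness",
    "cohesion",
    "mc_ratio",
    "coupling",
    "group_summary",
]


@dataclass
class CohesionProfile:
    """Per-sample C+, C-, and M-C ratio (NaN where C- is zero)."""

    data: pd.DataFrame  # index: sample ids; columns: group, c_plus, c_minus, mc_ratio

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def for_group(self, group: str) -> pd.DataFrame:
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise KeyError(f"unknown or empty group: {group!r}")
        return sub


@dataclass
class CouplingResult:
    group: str
    r_squared: float
    p_value: float
    p_adjusted: float
    n: int
    undefined: bool = False


def connectedness(net: SignedNetwork, mode: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon positive and negative connectedness.

    ``mode="mean"`` (default): the mean of the strictly positive
    (resp. strictly negative) weights in the taxon's row, 0 when the
    taxon has no edge of that sign — bounded in [-1, 1].
    ``mode="sum"`` sums instead of averaging (sensitivity variant).
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown connectedness mode: {mode!r}")
    w = net.weights
    pos_mask = w > 0
    neg_mask = w < 0
    pos_sum = np.where(pos_mask, w, 0.0).sum(axis=1)
    neg_sum = np.where(neg_mask, w, 0.0).sum(axis=1)
    if mode == "sum":
        return pos_sum, neg_sum
    pos_n = pos_mask.sum(axis=1)
    neg_n = neg_mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_plus = np.where(pos_n > 0, pos_sum / np.maximum(pos_n, 1), 0.0)
        c_minus = np.where(neg_n > 0, neg_sum / np.maximum(neg_n, 1), 0.0)
    return c_plus, c_minus


def cohesion(
    rel_abundance: pd.DataFrame,
    net: SignedNetwork,
    group_labels: dict[str, str] | None = None,
    mode: str = "mean",
) -> CohesionProfile:
    """Per-sample cohesion: C+_j = sum_i a_ij c+_i, C-_j = sum_i a_ij c-_i.

    ``rel_abundance`` is taxa x samples and must contain every network
    taxon as a row.
    """
    missing = [t for t in net.taxon_ids if t not in rel_abundance.index]
    if missing:
        raise KeyError(f"abundance matrix missing network taxa: {missing}")
    a = rel_abundance.loc[list(net.taxon_ids)].to_numpy(dtype=float)
    c_plus, c_minus = connectedness(net, mode=mode)
    cp = c_plus @ a
    cm = c_minus @ a
    samples = list(rel_abundance.columns)
    df = pd.DataFrame(
        {
            "group": [
                (group_labels or {}).get(s, "") for s in samples
            ],
            "c_plus": cp,
            "c_minus": cm,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    df["mc_ratio"] = mc_ratio(df["c_plus"], df["c_minus"])
    return CohesionProfile(df)


def mc_ratio(c_plus: pd.Series, c_minus: pd.Series) -> pd.Series:
    """Per-sample mutualism-competition ratio C+/|C-| (NaN when C- = 0)."""
    denom = c_minus.abs()
    out = c_plus / denom
    out[denom == 0] = np.nan
    return out


def coupling(
    profile: CohesionProfile, group: str, n_groups_tested: int = 1
) -> CouplingResult:
    """Squared Pearson correlation between per-sample C+ and C- in a group.

    The two-sided p-value is Bonferroni-adjusted over the number of
    groups tested.  Zero variance in either coordinate flags the result
    undefined.
    """
    sub = profile.for_group(group)
    if len(sub) < 4:
        raise ValueError("need at least 4 samples in the group")
    x = sub["c_plus"].to_numpy()
    y = sub["c_minus"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CouplingResult(group, float("nan"), float("nan"), float("nan"),
                              len(sub), undefined=True)
    r, p = stats.pearsonr(x, y)
    return CouplingResult(
        group=group,
        r_squared=float(r**2),
        p_value=float(p),
        p_adjusted=min(1.0, float(p) * n_groups_tested),
        n=len(sub),
    )


def group_summary(profile: CohesionProfile) -> pd.DataFrame:
    """Mean +/- sd of C+, C-, and the M-C ratio per group, with
    two-sided rank-sum tests between the two groups (Bonferroni over
    the three metrics)."""
    groups = [g for g in profile.data["group"].unique() if g != ""]
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    for g in groups:
        if (profile.data["group"] == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    metrics = ["c_plus", "c_minus", "mc_ratio"]
    rows = []
    for metric in metrics:
        a = profile.for_group(groups[0])[metric].dropna()
        b = profile.for_group(groups[1])[metric].dropna()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "metric": metric,
                f"mean_{groups[0]}": a.mean(),
                f"sd_{groups[0]}": a.std(ddof=1),
                f"mean_{groups[1]}": b.mean(),
                f"sd_{groups[1]}": b.std(ddof=1),
                "p_value": p,
                "p_adjusted": min(1.0, p * len(metrics)),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
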