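"""Seeded orchestration of the full analysis chain.

ingest/simulate -> per-group core selection -> overlap core ->
relative abundance -> signed network per group -> sign views, topology
and rewiring nulls -> per-sample cohesion, M-C ratio, coupling ->
alpha diversity and M-C/diversity correlations -> stability -> one
JSON report plus stage files.  Every stochastic stage derives its seed
from the single pipeline seed, so a run is fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .cohesion import CohesionProfile, cohesion, coupling, group_summary
from .core import (
    AbundanceTable,
    overlap_core,
    relative_abundance,
    retained_fraction,
    select_core,
)
from .diversity import alpha_diversity, correlate_mc_diversity
from .network import (
    DEFAULT_ALPHA,
    partial_correlation_network,
    spearman_matrix,
    split_signs,
    threshold_network,
)
from .stability import subsample_strengths
from .topology import rewire_null, summarize

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the printed defaults.

    75% core prevalence, significance threshold 1e-5, 1000 null
    replicates, 25 stability iterations per fraction, hub fraction 10%.
    """

    table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    core_threshold: float = 0.75
    alpha: float = DEFAULT_ALPHA
    estimator: str = "spearman"  # or "ggm"
    hub_fraction: float = 0.10
    null_replicates: int = 1000
    stability_iterations: int = 25
    stability_step: float = 0.05
    run_stability: bool = True
    correlation_method: str = "pearson"
    connectedness_mode: str = "mean"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.core_threshold <= 1:
            raise ValueError("core_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.estimator not in ("spearman", "ggm"):
            raise ValueError(f"unknown estimator: {self.estimator!r}")
        if not 0 < self.hub_fraction < 1:
            raise ValueError("hub_fraction must be in (0, 1)")
        if self.null_replicates < 0 or self.stability_iterations < 1:
            raise ValueError("replicate counts out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_all(
    config: PipelineConfig, table: AbundanceTable | None = None
) -> dict:
    """Run every stage for each group and return the report dict.

    ``table`` may be passed directly (e.g. a synthetic cohort);
    otherwise it is read from ``config.table``/``config.metadata``.
    With ``config.out_dir`` set, stage files (core lists, edge lists,
    GraphML, per-sample TSVs, report JSON) are written there.
    """
    rng = np.random.default_rng(config.seed)
    stage = "ingest"
    try:
        if table is None:
            if config.table is None:
                raise ValueError("no input table (config.table unset)")
            table = mio.read_abundance_tsv(config.table, metadata=config.metadata)
        groups = table.groups()
        if len(groups) != 2:
            raise ValueError(f"expected two groups, found {groups}")
        tree = None
        if config.tree:
            import skbio

            tree = skbio.TreeNode.read(config.tree)

        out = Path(config.out_dir) if config.out_dir else None
        if out:
            out.mkdir(parents=True, exist_ok=True)
            config.to_yaml(out / "config_resolved.yaml")
        logger.info("resolved config: %s", asdict(config))

        stage = "core_selection"
        cores = {g: select_core(table, g, config.core_threshold) for g in groups}
        shared = overlap_core(cores[groups[0]], cores[groups[1]])
        if not shared:
            raise ValueError("overlap core is empty")
        report: dict = {
            "groups": list(groups),
            "core_sizes": {g: len(cores[g]) for g in groups},
            "overlap_core_size": len(shared),
            "tested_pairs": len(shared) * (len(shared) - 1) // 2,
            "retained_fraction": {},
            "network": {},
            "topology": {},
            "cohesion": {},
            "diversity_correlation": {},
            "stability": {},
            "seed": config.seed,
        }

        stage = "normalization"
        rel = relative_abundance(table, shared)
        for g in groups:
            report["retained_fraction"][g] = retained_fraction(
                table.subset_samples(table.samples_in_group(g)),
                cores[g].core_taxa,
            )[1]

        stage = "network"
        nets = {}
        for g in groups:
            rel_g = rel[table.samples_in_group(g)]
            if config.estimator == "ggm":
                net = partial_correlation_network(rel_g, alpha=config.alpha)
            else:
                net = threshold_network(spearman_matrix(rel_g), alpha=config.alpha)
            nets[g] = net
            pos, neg = split_signs(net)
            report["network"][g] = {
                "edges": net.n_edges,
                "positive_edges": pos.n_edges,
                "negative_edges": neg.n_edges,
            }
            if out:
                mio.write_network_graphml(net, out / f"network_{g}.graphml")
                mio.write_edgelist(net, out / f"network_{g}_edges.tsv")

        stage = "topology"
        for g in groups:
            pos, neg = split_signs(nets[g])
            views = {"all": nets[g], "mutualism": pos, "competition": neg}
            report["topology"][g] = {}
            for name, view in views.items():
                summ = summarize(view, config.hub_fraction)
                entry = {
                    "mean_interactions": summ.mean_interactions,
                    "transitivity": summ.transitivity,
                    "hubs": summ.hub_set,
                }
                if config.null_replicates and view.n_edges >= 2:
                    seed_null = int(rng.integers(0, 2**31 - 1))
                    nulls = rewire_null(
                        view, n=config.null_replicates, seed=seed_null
                    )
                    entry["null"] = {
                        k: {
                            "observed": e.observed,
                            "z_score": e.z_score,
                            "p_value": e.p_value,
                        }
                        for k, e in nulls.items()
                    }
                report["topology"][g][name] = entry

        stage = "cohesion"
        # each sample's cohesion uses its own group's network
        frames = []
        for g in groups:
            rel_g = rel[table.samples_in_group(g)]
            prof_g = cohesion(
                rel_g, nets[g], table.group_labels, mode=config.connectedness_mode
            )
            frames.append(prof_g.data)
        profile = CohesionProfile(pd.concat(frames))
        couplings = {
            g: coupling(profile, g, n_groups_tested=len(groups)) for g in groups
        }
        summary = group_summary(profile)
        report["cohesion"] = {
            "per_group": {
                g: {
                    "c_plus_mean": float(profile.for_group(g)["c_plus"].mean()),
                    "c_plus_sd": float(profile.for_group(g)["c_plus"].std(ddof=1)),
                    "c_minus_mean": float(profile.for_group(g)["c_minus"].mean()),
                    "c_minus_sd": float(profile.for_group(g)["c_minus"].std(ddof=1)),
                    "mc_ratio_mean": float(profile.for_group(g)["mc_ratio"].mean()),
                    "mc_ratio_sd": float(profile.for_group(g)["mc_ratio"].std(ddof=1)),
                    "coupling_r_squared": couplings[g].r_squared,
                    "coupling_p_adjusted": couplings[g].p_adjusted,
                }
                for g in groups
            },
            "comparison_p_adjusted": {
                m: float(summary.loc[m, "p_adjusted"]) for m in summary.index
            },
        }
        if out:
            profile.data.to_csv(out / "cohesion.tsv", sep="\t")

        stage = "diversity"
        diversity = alpha_diversity(table, tree=tree)
        for g in groups:
            rep = correlate_mc_diversity(
                profile, diversity, g, method=config.correlation_method
            )
            report["diversity_correlation"][g] = {
                idx: {"r": float(row["r"]), "p_value": float(row["p_value"])}
                for idx, row in rep.table.iterrows()
            }
        if out:
            diversity.data.to_csv(out / "diversity.tsv", sep="\t")

        if config.run_stability:
            stage = "stability"
            for g in groups:
                seed_st = int(rng.integers(0, 2**31 - 1))
                rep = subsample_strengths(
                    table,
                    g,
                    iterations=config.stability_iterations,
                    seed=seed_st,
                    core_threshold=config.core_threshold,
                    alpha=config.alpha,
                    core_taxa=shared,
                )
                report["stability"][g] = {
                    "cs_coefficient": rep.cs,
                    "per_fraction_mean_correlation": {
                        f"{f:.2f}": float(v)
                        for f, v in rep.per_fraction()["mean_correlation"].items()
                    },
                    "per_fraction_mean_strength_ratio": {
                        f"{f:.2f}": float(v)
                        for f, v in rep.per_fraction()["mean_strength_ratio"].items()
                    },
                }
                if out:
                    rep.records.to_csv(
                        out / f"stability_{g}.tsv", sep="\t", index=False
                    )

        if out:
            mio.write_json_report(report, out / "report.json")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
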