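"""Reading and writing the pipeline's file formats.

Tables travel as TSV (taxa rows x sample columns, first column the
taxon id), metadata as a two-column TSV (sample_id, group), networks as
GraphML (via networkx, with ``weight`` and ``sign`` edge attributes)
and as sorted edge-list TSV, and ground truth / reports as JSON.  All
writers are deterministic given identical inputs; reports exclude
volatile fields like timestamps.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import AbundanceTable
from .network import SignedNetwork
from .synthetic import PlantedStructure

__all__ = [
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "write_network_graphml",
    "read_network_graphml",
    "write_edgelist",
    "write_truth_json",
    "write_json_report",
]


def read_abundance_tsv(
    path: str | Path,
    metadata: str | Path | None = None,
    orientation: str = "taxa-rows",
) -> AbundanceTable:
    """Read a count table; validates shape, ids and integrality.

    ``orientation`` is ``"taxa-rows"`` (default) or ``"samples-rows"``
    (transposed input).  Malformed files fail with the offending line
    number or id.
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header and at least one data row")
    header = rows[0]
    width = len(header)
    ids: list[str] = []
    data: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})"
            )
        ids.append(row[0])
        values = []
        for col, cell in zip(header[1:], row[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {col!r}"
                ) from None
            if v < 0 or v != int(v):
                raise ValueError(
                    f"{path}:{lineno}: count {cell!r} is not a non-negative integer"
                )
            values.append(int(v))
        data.append(values)
    frame = pd.DataFrame(data, index=ids, columns=header[1:], dtype=np.int64)
    if orientation == "samples-rows":
        frame = frame.T
    labels = read_metadata_tsv(metadata) if metadata is not None else {}
    return AbundanceTable(frame, labels)


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, group), with or without a header."""
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (lineno == 1 and row[0].lower() in ("sample_id", "sample")):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected sample_id<TAB>group")
            if row[0] in labels:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {row[0]!r}")
            labels[row[0]] = row[1]
    return labels


def write_metadata_tsv(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "group"])
        for sample, group in labels.items():
            writer.writerow([sample, group])


def write_network_graphml(net: SignedNetwork, path: str | Path) -> None:
    g = nx.Graph(alpha=float(net.alpha) if net.alpha is not None else -1.0)
    g.add_nodes_from(net.taxon_ids)
    for a, b, w in net.edges():
        g.add_edge(a, b, weight=float(w), sign="+" if w > 0 else "-")
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path) -> SignedNetwork:
    g = nx.read_graphml(str(path))
    taxa = list(g.nodes())
    idx = {t: i for i, t in enumerate(taxa)}
    weights = np.zeros((len(taxa), len(taxa)))
    for a, b, attrs in g.edges(data=True):
        weights[idx[a], idx[b]] = weights[idx[b], idx[a]] = attrs["weight"]
    alpha = g.graph.get("alpha", -1.0)
    return SignedNetwork(taxa, weights, alpha=None if alpha in (-1.0, None) else alpha)


def write_edgelist(net: SignedNetwork, path: str | Path) -> None:
    """Edge-list TSV sorted by (taxon_a, taxon_b) — deterministic."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon_a", "taxon_b", "weight", "sign"])
        for a, b, w in sorted(net.edges()):
            writer.writerow([a, b, repr(float(w)), "+" if w > 0 else "-"])


def write_truth_json(truth: PlantedStructure, path: str | Path) -> None:
    payload = {
        "taxon_ids": truth.taxon_ids,
        "true_edges": sorted(list(e) for e in truth.true_edges),
        "mean_abundance": truth.mean_abundance.tolist(),
        "dispersion": truth.dispersion.tolist(),
        "prevalence_targets": truth.prevalence_targets.tolist(),
        "seed": truth.seed,
        "projection_shift": truth.projection_shift,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        items = list(obj)
        if isinstance(obj, set):
            items = sorted(items, key=repr)
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    """Canonical JSON report: sorted keys, no volatile fields."""
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True, allow_nan=False)
        + "\n"
    )
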