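"""Readers and writers for the plain-text interchange formats.

Expression matrices are genes x samples TSV with a header row of sample ids;
target-site tables are long-format TSV (gene, mirna, site_count) of the
non-zero entries plus a one-id-per-line miRNA universe file; annotations,
APA calls and sample sheets are TSV; gene sets are GMT; networks are
edge-list TSV and GraphML.  All writers emit deterministic row order
(lexicographic ids) so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .backbone import TargetSiteTable
from .cerna import ExpressionMatrix
from .spectral import CalibrationResult
from .synthetic import (
    CONDITIONS,
    GroundTruth,
    SyntheticDataset,
    config_from_dict,
    config_to_dict,
)

__all__ = [
    "write_expression",
    "read_expression",
    "write_targets",
    "read_targets",
    "write_gene_list",
    "read_gene_list",
    "read_gmt",
    "write_gmt",
    "write_network_tsv",
    "read_network_tsv",
    "write_graphml",
    "write_calibration",
    "write_dataset",
    "read_dataset",
]


def write_expression(matrix: ExpressionMatrix, values_path: Path, labels_path: Path | None = None):
    df = matrix.values.sort_index()
    df.index.name = "gene"
    # %.17g is lossless for float64, so write + read round-trips exactly
    df.to_csv(values_path, sep="\t", float_format="%.17g")
    if labels_path is not None:
        labels = matrix.labels.copy()
        labels.index.name = "sample"
        labels.to_csv(labels_path, sep="\t")


def read_expression(values_path: Path, labels_path: Path | None = None) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0, float_precision="round_trip")
    values.index.name = None
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)
        labels.index.name = None
    return ExpressionMatrix(values, labels)


def write_targets(table: TargetSiteTable, long_path: Path, universe_path: Path):
    counts = table.counts.sort_index()
    rows = counts.stack()
    rows = rows[rows > 0].astype(int)
    out = rows.rename_axis(["gene", "mirna"]).rename("site_count").reset_index()
    out = out.sort_values(["gene", "mirna"], kind="mergesort")
    out.to_csv(long_path, sep="\t", index=False)
    Path(universe_path).write_text("".join(m + "\n" for m in table.universe))


def read_targets(long_path: Path, universe_path: Path) -> TargetSiteTable:
    universe = read_gene_list(universe_path)
    long = pd.read_csv(long_path, sep="\t")
    if long.empty:
        counts = pd.DataFrame(columns=universe, dtype=int)
    else:
        counts = (
            long.pivot(index="gene", columns="mirna", values="site_count")
            .reindex(columns=universe)
            .fillna(0)
            .astype(int)
        )
        counts.index.name = None
        counts.columns.name = None
    return TargetSiteTable(counts, universe=universe)


def write_gene_list(genes: Iterable[str], path: Path):
    Path(path).write_text("".join(g + "\n" for g in sorted(set(genes))))


def read_gene_list(path: Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_gmt(path: Path) -> dict[str, set[str]]:
    """GMT: one gene set per line, <name> <tab> <description> <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not fields[0]:
            continue
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(collection: Mapping[str, Iterable[str]], path: Path, description: str = "."):
    lines = [
        "\t".join([name, description] + sorted(set(collection[name]))) for name in sorted(collection)
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


def _edge_table(network: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v in sorted(tuple(sorted(e)) for e in network.edges):
        data = network.edges[u, v]
        rows.append((u, v, *(data.get(k, "") for k in ("r", "p", "q"))))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "q"])


def write_network_tsv(network: nx.Graph, path: Path):
    _edge_table(network).to_csv(path, sep="\t", index=False)


def read_network_tsv(path: Path) -> nx.Graph:
    net = nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        attrs = {
            k: float(getattr(row, k))
            for k in ("r", "p", "q")
            if k in df.columns and pd.notna(getattr(row, k))
        }
        net.add_edge(row.gene_a, row.gene_b, **attrs)
    return net


def write_graphml(network: nx.Graph, path: Path):
    # rebuild in sorted order so serialization is deterministic
    out = nx.Graph(**{k: v for k, v in network.graph.items() if v is not None})
    out.add_nodes_from(sorted(network.nodes))
    for u, v in sorted(tuple(sorted(e)) for e in network.edges):
        out.add_edge(u, v, **network.edges[u, v])
    nx.write_graphml(out, path)


def write_calibration(result: CalibrationResult, tsv_path: Path, json_path: Path):
    result.grid.to_csv(tsv_path, sep="\t", index=False)
    summary = {
        "selected_cutoff": result.selected_cutoff,
        "reference_clustering": result.reference_clustering,
    }
    Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


# -- synthetic dataset round trip -------------------------------------------


def write_dataset(dataset: SyntheticDataset, directory: Path) -> list[Path]:
    """Write every dataset component as TSV/JSON; returns the file list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    for group, state in CONDITIONS:
        path = directory / f"expression_{group}_{state}.tsv"
        write_expression(dataset.expression[(group, state)], path)
        written.append(path)

    targets_path = directory / "target_sites.tsv"
    universe_path = directory / "mirna_universe.txt"
    write_targets(dataset.targets, targets_path, universe_path)
    written += [targets_path, universe_path]

    ann_path = directory / "annotations.tsv"
    ann = dataset.annotations.astype(int)
    ann.index.name = "gene"
    ann.to_csv(ann_path, sep="\t")
    written.append(ann_path)

    apa_path = directory / "apa_calls.tsv"
    dataset.apa_calls.to_csv(apa_path, sep="\t", index=False)
    written.append(apa_path)

    samples_path = directory / "samples.tsv"
    samples = dataset.samples.copy()
    samples.index.name = "sample"
    samples.to_csv(samples_path, sep="\t")
    written.append(samples_path)

    truth_path = directory / "truth.json"
    truth = dataset.truth
    truth_path.write_text(
        json.dumps(
            {
                "us_genes": sorted(truth.us_genes),
                "partners": sorted(truth.partners),
                "cerna_pairs": sorted(list(p) for p in truth.cerna_pairs),
                "hk_genes": sorted(truth.hk_genes),
                "ta_genes": sorted(truth.ta_genes),
                "tf_genes": sorted(truth.tf_genes),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    written.append(truth_path)

    config_path = directory / "generator_config.json"
    if dataset.config is not None:
        config_path.write_text(json.dumps(config_to_dict(dataset.config), indent=2, sort_keys=True) + "\n")
        written.append(config_path)
    return written


def read_dataset(directory: Path) -> SyntheticDataset:
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col=0)
    samples.index.name = "sample"

    expression = {}
    for group, state in CONDITIONS:
        values = pd.read_csv(
            directory / f"expression_{group}_{state}.tsv",
            sep="\t",
            index_col=0,
            float_precision="round_trip",
        )
        values.index.name = None
        cols = list(values.columns)
        labels = samples.loc[cols].copy()
        labels.index.name = None
        expression[(group, state)] = ExpressionMatrix(values, labels)

    targets = read_targets(directory / "target_sites.tsv", directory / "mirna_universe.txt")
    annotations = pd.read_csv(directory / "annotations.tsv", sep="\t", index_col=0).astype(bool)
    annotations.index.name = "gene"
    apa_calls = pd.read_csv(directory / "apa_calls.tsv", sep="\t")
    if apa_calls.empty:
        apa_calls = pd.DataFrame(columns=["sample", "gene", "event"])

    raw = json.loads((directory / "truth.json").read_text())
    truth = GroundTruth(
        us_genes=set(raw["us_genes"]),
        partners=set(raw["partners"]),
        cerna_pairs={tuple(p) for p in raw["cerna_pairs"]},
        hk_genes=set(raw["hk_genes"]),
        ta_genes=set(raw["ta_genes"]),
        tf_genes=set(raw["tf_genes"]),
    )
    config = None
    cfg_path = directory / "generator_config.json"
    if cfg_path.exists():
        config = config_from_dict(json.loads(cfg_path.read_text()))
    return SyntheticDataset(
        expression=expression,
        targets=targets,
        annotations=annotations,
        apa_calls=apa_calls,
        samples=samples,
        truth=truth,
        config=config,
    )
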