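"""End-to-end orchestration.

Runs the full analysis in order: load or generate the dataset, filter to
expressed genes, build the target-share backbone, build the reference-group
normal network at the traditional cutoff, calibrate the other group's cutoff
by spectral similarity, build the four condition networks, then compute the
downstream comparison statistics and write every artifact with a JSON run
manifest.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .backbone import build_backbone
from .cerna import build_cerna_network, filter_expressed
from .comparison import (
    cerna_partners,
    classify_network_genes,
    degree_ratio,
    expression_variability,
    log2_fold_change,
    matched_null_similarity,
    overrepresentation,
    recurrent_apa,
    set_overlap_significance,
)
from .spectral import calibrate_cutoff
from .synthetic import GeneratorConfig, config_from_dict, config_to_dict, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "report"]

log = logging.getLogger("cernanet")

_GROUPS = ("A", "B")


@dataclass
class RunConfig:
    """Fully-serializable configuration of one pipeline run.

    Exactly one of ``generator`` (synthetic input) or ``input_dir`` (a
    directory written by :func:`cernanet.io.write_dataset`) must be set.
    """

    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    reference_group: str = "A"
    reference_cutoff: float = 0.6
    calibration_step: float = 0.01
    backbone_q: float = 0.05
    min_sites: int = 6
    recurrence_fraction: float = 0.2
    expr_min_value: float = 1.0
    expr_min_fraction: float = 0.8
    null_reps: int = 200
    gmt_path: Optional[str] = None
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("set exactly one of generator / input_dir")
        if self.reference_group not in _GROUPS:
            raise ValueError("reference_group must be 'A' or 'B'")
        if not 0 <= self.reference_cutoff <= 1:
            raise ValueError("reference_cutoff must be in [0, 1]")
        if not 0 < self.calibration_step <= 1:
            raise ValueError("calibration_step must be in (0, 1]")
        if not 0 < self.backbone_q <= 1:
            raise ValueError("backbone_q must be in (0, 1]")
        if self.min_sites < 0:
            raise ValueError("min_sites must be >= 0")
        if not 0 <= self.recurrence_fraction < 1:
            raise ValueError("recurrence_fraction must be in [0, 1)")
        if not 0 <= self.expr_min_fraction <= 1:
            raise ValueError("expr_min_fraction must be in [0, 1]")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = None if self.generator is None else config_to_dict(self.generator)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if d.get("generator") is not None:
            d["generator"] = config_from_dict(d["generator"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]  # keep below 2^31


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(manifest: dict, name: str):
    """Context-ish logger for one pipeline stage."""
    log.info("stage %s ...", name)
    manifest["stages"].append(name)
    return time.time()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole analysis; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_seed, null_seed = _child_seeds(config.seed, 2)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "child_seeds": {"generator": gen_seed, "null": null_seed},
        "stages": [],
        "results": {},
        "files": {},
        "degenerate": {},
    }
    files = manifest["files"]

    # -- input ---------------------------------------------------------------
    t0 = _stage(manifest, "input")
    if config.generator is not None:
        dataset = generate_dataset(dataclasses.replace(config.generator, seed=gen_seed))
        ds_dir = out / "dataset"
        for p in cio.write_dataset(dataset, ds_dir):
            files[str(p.relative_to(out))] = None
    else:
        dataset = cio.read_dataset(Path(config.input_dir))
    log.info("input: %d genes, %d samples (%.1fs)", dataset.targets.counts.shape[0],
             len(dataset.samples), time.time() - t0)

    # -- expression filter ---------------------------------------------------
    _stage(manifest, "filter_expressed")
    all_expr = dataset.all_expression()
    kept = filter_expressed(all_expr, config.expr_min_value, config.expr_min_fraction)
    kept_genes = set(kept.genes)
    manifest["results"]["n_genes_expressed"] = len(kept_genes)
    cond_expr = {
        cond: mat.subset_genes(kept_genes) for cond, mat in dataset.expression.items()
    }

    # -- backbone ------------------------------------------------------------
    _stage(manifest, "backbone")
    targets = dataset.targets.restrict_genes(kept_genes)
    backbone = build_backbone(targets, min_sites=config.min_sites, q_threshold=config.backbone_q)
    cio.write_network_tsv(backbone, out / "backbone_edges.tsv")
    files["backbone_edges.tsv"] = None
    manifest["results"]["backbone"] = {
        "n_nodes": backbone.number_of_nodes(),
        "n_edges": backbone.number_of_edges(),
    }

    # -- reference network + calibration -------------------------------------
    _stage(manifest, "calibrate")
    ref = config.reference_group
    other = "B" if ref == "A" else "A"
    ref_normal = cond_expr[(ref, "normal")]
    other_normal = cond_expr[(other, "normal")]
    ref_net = build_cerna_network(
        ref_normal, backbone, config.reference_cutoff, condition=f"{ref}_normal"
    )
    if ref_net.number_of_edges() == 0:
        raise RuntimeError("stage calibrate: reference network is empty")
    calib = calibrate_cutoff(
        ref_net, other_normal, backbone, step=config.calibration_step,
        condition=f"{other}_normal",
    )
    cio.write_calibration(calib, out / "calibration_grid.tsv", out / "calibration.json")
    files["calibration_grid.tsv"] = None
    files["calibration.json"] = None
    cutoffs = {ref: config.reference_cutoff, other: calib.selected_cutoff}
    manifest["results"]["calibrated_cutoff"] = calib.selected_cutoff
    manifest["results"]["reference_cutoff"] = config.reference_cutoff

    # -- four condition networks ---------------------------------------------
    _stage(manifest, "networks")
    networks = {}
    for group in _GROUPS:
        for state in ("normal", "tumor"):
            name = f"{group}_{state}"
            net = build_cerna_network(
                cond_expr[(group, state)], backbone, cutoffs[group], condition=name
            )
            networks[(group, state)] = net
            cio.write_network_tsv(net, out / f"network_{name}.tsv")
            cio.write_graphml(net, out / f"network_{name}.graphml")
            files[f"network_{name}.tsv"] = None
            files[f"network_{name}.graphml"] = None
    manifest["results"]["networks"] = {
        f"{g}_{s}": {
            "n_nodes": networks[(g, s)].number_of_nodes(),
            "n_edges": networks[(g, s)].number_of_edges(),
            "cutoff": cutoffs[g],
        }
        for g, s in networks
    }

    # -- recurrent APA + partners --------------------------------------------
    _stage(manifest, "apa_partners")
    us_genes, partners = {}, {}
    for group in _GROUPS:
        us = recurrent_apa(
            dataset.apa_calls, dataset.tumor_samples(group), "3US",
            config.recurrence_fraction,
        ) & kept_genes
        us_genes[group] = us
        partners[group] = cerna_partners(networks[(group, "normal")], us)
        cio.write_gene_list(us, out / f"recurrent_3US_{group}.txt")
        cio.write_gene_list(partners[group], out / f"3US_partners_{group}.txt")
        files[f"recurrent_3US_{group}.txt"] = None
        files[f"3US_partners_{group}.txt"] = None
    manifest["results"]["recurrent_3US"] = {g: len(us_genes[g]) for g in _GROUPS}
    manifest["results"]["3US_partners"] = {g: len(partners[g]) for g in _GROUPS}

    hk_all = set(dataset.annotations.index[dataset.annotations["HK"]])

    # -- HK sponge subnetwork vs matched nulls --------------------------------
    _stage(manifest, "hk_null_comparison")
    try:
        comp = matched_null_similarity(
            networks[(ref, "normal")], networks[(other, "normal")],
            hk_all, reps=config.null_reps, seed=null_seed,
        )
        manifest["results"]["hk_subnetwork"] = {
            "focal_p": comp.focal_p,
            "focal_statistic": comp.focal_statistic,
            "empirical_p": comp.empirical_p,
            "reps": config.null_reps,
        }
        pd.DataFrame({"null_p": comp.null_ps}).to_csv(
            out / "hk_null_pvalues.tsv", sep="\t", index=False
        )
        files["hk_null_pvalues.tsv"] = None
    except ValueError as exc:
        manifest["degenerate"]["hk_null_comparison"] = str(exc)

    # -- gene-class tables ----------------------------------------------------
    _stage(manifest, "gene_tables")
    for group in _GROUPS:
        normal_net = networks[(group, "normal")]
        tumor_net = networks[(group, "tumor")]
        nmat = cond_expr[(group, "normal")]
        tmat = cond_expr[(group, "tumor")]
        rows = []
        for g in sorted(normal_net.nodes):
            rows.append(
                (
                    g,
                    normal_net.degree(g),
                    degree_ratio(normal_net, tumor_net, g),
                    log2_fold_change(tmat.values.loc[g].to_numpy(), nmat.values.loc[g].to_numpy()),
                    g in hk_all,
                    g in us_genes[group],
                    g in partners[group],
                )
            )
        table = pd.DataFrame(
            rows,
            columns=["gene", "degree_normal", "degree_ratio", "log2_fc", "HK", "is_3US", "is_partner"],
        )
        table.to_csv(out / f"gene_stats_{group}.tsv", sep="\t", index=False)
        files[f"gene_stats_{group}.tsv"] = None

        classes = classify_network_genes(backbone, us_genes[group], dataset.annotations)
        classes.to_csv(out / f"gene_classes_{group}.tsv", sep="\t")
        files[f"gene_classes_{group}.tsv"] = None

    # -- HK overlap + variability ---------------------------------------------
    _stage(manifest, "hk_statistics")
    hk_in_net = {
        g: hk_all & set(networks[(g, "normal")].nodes) for g in _GROUPS
    }
    try:
        manifest["results"]["hk_overlap_p"] = set_overlap_significance(
            hk_in_net[ref], hk_in_net[other], set(backbone.nodes)
        )
    except ValueError as exc:
        manifest["degenerate"]["hk_overlap"] = str(exc)
    net_genes = set(networks[(ref, "normal")].nodes)
    hk_net = sorted(net_genes & hk_all)
    nonhk_net = sorted(net_genes - hk_all)
    if len(hk_net) >= 2 and len(nonhk_net) >= 2:
        try:
            _, _, var_p = expression_variability(cond_expr[(ref, "normal")], hk_net, nonhk_net)
            manifest["results"]["hk_variability_p"] = var_p
        except ValueError as exc:
            manifest["degenerate"]["hk_variability"] = str(exc)
    else:
        manifest["degenerate"]["hk_variability"] = "too few HK or non-HK network genes"

    # -- optional enrichment ---------------------------------------------------
    if config.gmt_path is not None:
        _stage(manifest, "enrichment")
        collection = cio.read_gmt(Path(config.gmt_path))
        enr = overrepresentation(partners[other], collection, kept_genes)
        enr.to_csv(out / "enrichment_partners.tsv", sep="\t", index=False)
        files["enrichment_partners.tsv"] = None

    # -- manifest --------------------------------------------------------------
    _stage(manifest, "manifest")
    for rel in sorted(files):
        files[rel] = _sha256(out / rel)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote %s", manifest_path)
    return manifest


def report(manifest_path: Path) -> str:
    """Human-readable summary of a completed run."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    m = json.loads(manifest_path.read_text())
    r = m["results"]
    lines = ["ceRNA pipeline run summary", "=" * 26, ""]
    lines.append(f"seed: {m['seed']}")
    lines.append(f"expressed genes: {r.get('n_genes_expressed')}")
    bb = r.get("backbone", {})
    lines.append(f"backbone: {bb.get('n_nodes')} genes, {bb.get('n_edges')} target-share edges")
    lines.append(
        f"cutoffs: reference {r.get('reference_cutoff')}, calibrated {r.get('calibrated_cutoff')}"
    )
    for name, info in sorted(r.get("networks", {}).items()):
        lines.append(
            f"network {name}: {info['n_nodes']} nodes, {info['n_edges']} edges"
            f" (cutoff {info['cutoff']})"
        )
    if "hk_subnetwork" in r:
        hk = r["hk_subnetwork"]
        lines.append(
            f"HK sponge subnetworks: similarity p {hk['focal_p']:.3g}, "
            f"empirical p vs {hk['reps']} matched nulls {hk['empirical_p']:.3g}"
        )
    if "hk_overlap_p" in r:
        lines.append(f"HK network-gene overlap p: {r['hk_overlap_p']:.3g}")
    if "hk_variability_p" in r:
        lines.append(f"HK vs non-HK expression-SD p: {r['hk_variability_p']:.3g}")
    for g in _GROUPS:
        lines.append(
            f"group {g}: {r.get('recurrent_3US', {}).get(g)} recurrent 3'US genes, "
            f"{r.get('3US_partners', {}).get(g)} ceRNA partners"
        )
    if m.get("degenerate"):
        lines.append("")
        lines.append("degenerate stages:")
        for k, v in sorted(m["degenerate"].items()):
            lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("result files:")
    for rel in sorted(m["files"]):
        lines.append(f"  {rel}  sha256={m['files'][rel]}")
    return "\n".join(lines) + "\n"
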