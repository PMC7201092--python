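"""Synthetic dataset generator.

Emulates the statistical structure the analysis assumes in paired
tumor/normal RNA-seq of two subtype groups of unequal size: block-correlated
expression driven by shared miRNA targeting, housekeeping (HK) genes acting
as stable high-site-count sponges, and planted 3'-UTR-shortening (3'US)
genes whose loss of target sites in tumor represses their ceRNA partners.

Generative model
----------------
miRNAs are partitioned into blocks and each gene targets a subset of one
block's miRNAs, so genes sharing a block share miRNAs and nothing else
overlaps.  Per sample, latent miRNA activities a_m ~ N(0, 1) repress their
targets linearly:

    x_gs = baseline_g - scale_g * sum_m site_{gm} * a_ms + eps_gs,  floored at 0

with scale_g setting the gene's miRNA-regulation strength — heterogeneous
across ordinary genes, so target-share pairs span weak to strong
co-expression, and fixed at a stable high value for HK sponges — and
eps ~ N(0, hk_noise_sd) for HK genes, N(0, noise_sd) otherwise.  Genes
sharing miRNAs are thereby positively co-expressed; HK genes have both lower
total variance and more reproducible correlations.  In tumor, planted 3'US
genes have their effective site counts zeroed (complete site loss) and every
non-3'US gene sharing a miRNA with a 3'US gene is shifted down by
``repression_effect`` on average, with per-sample variability
(``repression_sd``) reflecting variable APA penetrance across tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .backbone import TargetSiteTable
from .cerna import ExpressionMatrix

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticDataset", "generate_dataset", "CONDITIONS"]

CONDITIONS = (("A", "normal"), ("A", "tumor"), ("B", "normal"), ("B", "tumor"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic generator.

    ``samples_per_group`` follows the study design: (group A normal,
    group A tumor, group B normal, group B tumor); the default 77/77/20/20
    mirrors the two subtype groups of paired samples.  ``sponge_site_range``
    is the inclusive total-site-count interval for HK genes (sponges need
    >5 sites, hence a minimum of at least 6).
    """

    n_genes: int = 600
    n_mirnas: int = 60
    samples_per_group: tuple[int, int, int, int] = (77, 77, 20, 20)
    hk_fraction: float = 0.3
    sponge_site_range: tuple[int, int] = (8, 20)
    nonsponge_site_range: tuple[int, int] = (3, 10)
    n_3us_genes: int = 40
    us_block_fraction: float = 0.5
    repression_effect: float = 5.0
    repression_sd: float = 2.0
    noise_sd: float = 1.0
    hk_noise_sd: float = 0.4
    signal_sd: float = 2.0
    signal_strength_range: tuple[float, float] = (0.3, 0.85)
    hk_signal_sd: float = 1.2
    group_divergence: float = 0.0
    n_blocks: int = 8
    hk_dedicated_blocks: int = 0
    ta_fraction: float = 0.1
    tf_fraction: float = 0.1
    apa_call_rate: float = 0.6
    apa_background_rate: float = 0.01
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_mirnas <= 0:
            raise ValueError("n_genes and n_mirnas must be positive")
        if any(n <= 0 for n in self.samples_per_group) or len(self.samples_per_group) != 4:
            raise ValueError("samples_per_group must be four positive integers")
        if not 0 <= self.hk_fraction <= 1:
            raise ValueError("hk_fraction must be in [0, 1]")
        if self.sponge_site_range[0] < 6:
            raise ValueError("sponge_site_range minimum must be >= 6 (sponges need >5 sites)")
        if self.sponge_site_range[0] > self.sponge_site_range[1]:
            raise ValueError("invalid sponge_site_range")
        if self.n_3us_genes < 0 or self.n_3us_genes > self.n_genes:
            raise ValueError("n_3us_genes must be in [0, n_genes]")
        if not 0 < self.us_block_fraction <= 1:
            raise ValueError("us_block_fraction must be in (0, 1]")
        if self.repression_effect < 0:
            raise ValueError("repression_effect must be >= 0")
        if self.repression_sd < 0:
            raise ValueError("repression_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.hk_noise_sd < self.noise_sd:
            raise ValueError("hk_noise_sd must be strictly smaller than noise_sd")
        if self.n_blocks <= 0 or self.n_blocks > self.n_mirnas:
            raise ValueError("n_blocks must be in [1, n_mirnas]")
        if not 0 <= self.hk_dedicated_blocks < self.n_blocks:
            raise ValueError("hk_dedicated_blocks must leave at least one open block")
        lo, hi = self.signal_strength_range
        if not 0 < lo <= hi:
            raise ValueError("invalid signal_strength_range")
        if not 0 <= self.group_divergence <= 1:
            raise ValueError("group_divergence must be in [0, 1]")
        if self.hk_signal_sd <= 0 or self.signal_sd <= 0:
            raise ValueError("signal scales must be positive")


@dataclass
class GroundTruth:
    """Planted structure: the ledger downstream tests score against."""

    us_genes: set[str]
    partners: set[str]
    cerna_pairs: set[tuple[str, str]]
    hk_genes: set[str]
    ta_genes: set[str]
    tf_genes: set[str]


@dataclass
class SyntheticDataset:
    expression: dict[tuple[str, str], ExpressionMatrix]
    targets: TargetSiteTable
    annotations: pd.DataFrame  # index gene; bool columns HK, TA, TF
    apa_calls: pd.DataFrame  # tidy: sample, gene, event
    samples: pd.DataFrame  # index sample; columns group, state
    truth: GroundTruth
    config: GeneratorConfig = field(default=None)  # type: ignore[assignment]

    def condition(self, group: str, state: str) -> ExpressionMatrix:
        return self.expression[(group, state)]

    def all_expression(self) -> ExpressionMatrix:
        """All four conditions concatenated column-wise."""
        values = pd.concat([self.expression[c].values for c in CONDITIONS], axis=1)
        labels = pd.concat([self.expression[c].labels for c in CONDITIONS], axis=0)
        return ExpressionMatrix(values, labels)

    def tumor_samples(self, group: str) -> list[str]:
        sel = self.samples[(self.samples["group"] == group) & (self.samples["state"] == "tumor")]
        return list(sel.index)

    def equals(self, other: "SyntheticDataset") -> bool:
        if set(self.expression) != set(other.expression):
            return False
        for key in self.expression:
            if not self.expression[key].equals(other.expression[key]):
                return False
        return (
            self.targets.counts.equals(other.targets.counts)
            and self.targets.universe == other.targets.universe
            and self.annotations.equals(other.annotations)
            and self.apa_calls.equals(other.apa_calls)
            and self.samples.equals(other.samples)
            and self.truth == other.truth
        )


def _site_table(
    cfg: GeneratorConfig, rng: np.random.Generator, hk_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Block-structured gene x miRNA site counts, plus each gene's block."""
    block_of_mirna = np.sort(rng.permutation(np.arange(cfg.n_mirnas) % cfg.n_blocks))
    members = [np.flatnonzero(block_of_mirna == b) for b in range(cfg.n_blocks)]
    # optional HK-dedicated blocks sit at the end; HK genes then form their
    # own sponge community, sharing a full block's miRNAs with high counts
    n_open = cfg.n_blocks - cfg.hk_dedicated_blocks
    block_of_gene = rng.integers(0, n_open, size=cfg.n_genes)
    if cfg.hk_dedicated_blocks > 0:
        hk_idx = np.flatnonzero(hk_mask)
        block_of_gene[hk_idx] = n_open + rng.integers(
            0, cfg.hk_dedicated_blocks, size=len(hk_idx)
        )
    sites = np.zeros((cfg.n_genes, cfg.n_mirnas), dtype=int)
    for g in range(cfg.n_genes):
        lo, hi = cfg.sponge_site_range if hk_mask[g] else cfg.nonsponge_site_range
        total = int(rng.integers(lo, hi + 1))
        block = members[block_of_gene[g]]
        if hk_mask[g] and cfg.hk_dedicated_blocks > 0:
            # full-block support with evenly spread counts: near-parallel
            # site vectors, so the sponge community is a stable clique
            k = min(len(block), total)
            support = rng.choice(block, size=k, replace=False)
            counts = np.full(k, total // k)
            counts[: total % k] += 1
            sites[g, support] = counts
        else:
            k = int(rng.integers(2, len(block) + 1)) if len(block) >= 2 else len(block)
            k = min(k, total)
            support = rng.choice(block, size=k, replace=False)
            # at least one site per supported miRNA, remainder multinomial
            extra = rng.multinomial(total - k, np.full(k, 1.0 / k))
            sites[g, support] = 1 + extra
    return sites, block_of_gene


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset; identical config+seed is bit-identical."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(5, len(str(cfg.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    mirnas = [f"MIR{i:04d}" for i in range(cfg.n_mirnas)]

    # gene classes: HK first, TA/TF among the rest (disjoint), 3'US non-HK
    n_hk = int(round(cfg.hk_fraction * cfg.n_genes))
    perm = rng.permutation(cfg.n_genes)
    hk_idx = np.sort(perm[:n_hk])
    rest = perm[n_hk:]
    n_ta = min(int(round(cfg.ta_fraction * cfg.n_genes)), len(rest))
    n_tf = min(int(round(cfg.tf_fraction * cfg.n_genes)), max(0, len(rest) - n_ta))
    ta_idx = np.sort(rest[:n_ta])
    tf_idx = np.sort(rest[n_ta : n_ta + n_tf])
    hk_mask = np.zeros(cfg.n_genes, dtype=bool)
    hk_mask[hk_idx] = True

    sites, block_of_gene = _site_table(cfg, rng, hk_mask)
    presence = sites > 0

    # planted 3'US genes: non-HK genes concentrated in a subset of the miRNA
    # blocks, so that genes in the remaining blocks form the unconnected
    # contrast group downstream analyses compare against
    n_us_blocks = max(1, int(round(cfg.us_block_fraction * cfg.n_blocks)))
    rest_set = set(rest.tolist())
    us_pool = np.array(
        [g for g in range(cfg.n_genes) if g in rest_set and block_of_gene[g] < n_us_blocks],
        dtype=int,
    )
    if len(us_pool) < cfg.n_3us_genes:
        us_pool = rest if len(rest) >= cfg.n_3us_genes else np.arange(cfg.n_genes)
    us_idx = np.sort(rng.choice(us_pool, size=cfg.n_3us_genes, replace=False))
    us_mask = np.zeros(cfg.n_genes, dtype=bool)
    us_mask[us_idx] = True

    share = (presence.astype(np.int32) @ presence.T.astype(np.int32)) > 0  # share >=1 miRNA
    np.fill_diagonal(share, 0)
    partner_mask = (share[us_idx].sum(axis=0) > 0) & ~us_mask
    iu, ju = np.nonzero(np.triu(share, k=1))
    cerna_pairs = {(genes[i], genes[j]) for i, j in zip(iu, ju)}

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    noise_sd_g = np.where(hk_mask, cfg.hk_noise_sd, cfg.noise_sd)
    # per-gene miRNA-regulation strength: how much of a gene's variance the
    # shared miRNA activities explain.  Heterogeneous for ordinary genes (so
    # target-share pairs span weak to strong co-expression, the reservoir that
    # drives small-sample edge inflation); fixed and stable for HK sponges.
    lo, hi = cfg.signal_strength_range
    strength = cfg.signal_sd * rng.uniform(lo, hi, size=cfg.n_genes)
    strength[hk_mask] = cfg.hk_signal_sd
    # subtype divergence: a fraction of non-HK genes get independently
    # redrawn regulation strengths in group B, so non-HK crosstalk differs
    # between the groups while the HK sponge core stays synchronized
    strength_by_group = {"A": strength, "B": strength}
    if cfg.group_divergence > 0:
        diverged = strength.copy()
        redraw = (~hk_mask) & (rng.random(cfg.n_genes) < cfg.group_divergence)
        diverged[redraw] = cfg.signal_sd * rng.uniform(lo, hi, size=int(redraw.sum()))
        strength_by_group = {"A": strength, "B": diverged}

    def condition_matrix(group: str, state: str, n_samples: int) -> ExpressionMatrix:
        eff = sites.astype(float)
        if state == "tumor":
            eff = eff.copy()
            eff[us_idx] = 0.0
        norms = np.linalg.norm(eff, axis=1)
        s_g = strength_by_group[group]
        scale = np.divide(s_g, norms, out=np.zeros_like(norms), where=norms > 0)
        activity = rng.normal(size=(cfg.n_mirnas, n_samples))
        signal = -(eff @ activity) * scale[:, None]
        noise = rng.normal(size=(cfg.n_genes, n_samples)) * noise_sd_g[:, None]
        expr = baseline[:, None] + signal + noise
        if state == "tumor":
            # partner repression: mean shift -repression_effect with
            # sample-to-sample variability (APA penetrance differs across
            # tumors), which also attenuates partners' tumor co-expression
            n_partners = int(partner_mask.sum())
            rep = cfg.repression_effect + cfg.repression_sd * rng.normal(
                size=(n_partners, n_samples)
            )
            expr[partner_mask] -= rep
        expr = np.maximum(expr, 0.0)
        names = [f"{group}_{state}_{i:03d}" for i in range(n_samples)]
        values = pd.DataFrame(expr, index=genes, columns=names)
        labels = pd.DataFrame({"group": group, "state": state}, index=names)
        return ExpressionMatrix(values, labels)

    expression = {
        cond: condition_matrix(cond[0], cond[1], n)
        for cond, n in zip(CONDITIONS, cfg.samples_per_group)
    }

    # per-sample APA calls over tumor samples: planted 3'US genes are called
    # at apa_call_rate, everything else only as sparse background
    apa_rows = []
    for group in ("A", "B"):
        for sample in expression[(group, "tumor")].samples:
            called_us = us_idx[rng.random(len(us_idx)) < cfg.apa_call_rate]
            bg_pool = np.flatnonzero(~us_mask)
            bg_us = bg_pool[rng.random(len(bg_pool)) < cfg.apa_background_rate]
            ul = np.flatnonzero(rng.random(cfg.n_genes) < cfg.apa_background_rate)
            us_called = np.union1d(called_us, bg_us)
            for g in us_called:
                apa_rows.append((sample, genes[g], "3US"))
            for g in np.setdiff1d(ul, us_called):
                apa_rows.append((sample, genes[g], "3UL"))
    apa_calls = pd.DataFrame(apa_rows, columns=["sample", "gene", "event"])
    apa_calls = apa_calls.sort_values(["sample", "gene", "event"], kind="mergesort").reset_index(
        drop=True
    )

    annotations = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=["HK", "TA", "TF"])
    annotations.iloc[hk_idx, 0] = True
    annotations.iloc[ta_idx, 1] = True
    annotations.iloc[tf_idx, 2] = True

    samples = pd.concat([expression[c].labels for c in CONDITIONS], axis=0)
    samples.index.name = "sample"

    truth = GroundTruth(
        us_genes={genes[i] for i in us_idx},
        partners={genes[i] for i in np.flatnonzero(partner_mask)},
        cerna_pairs=cerna_pairs,
        hk_genes={genes[i] for i in hk_idx},
        ta_genes={genes[i] for i in ta_idx},
        tf_genes={genes[i] for i in tf_idx},
    )

    targets = TargetSiteTable(pd.DataFrame(sites, index=genes, columns=mirnas))
    return SyntheticDataset(
        expression=expression,
        targets=targets,
        annotations=annotations,
        apa_calls=apa_calls,
        samples=samples,
        truth=truth,
        config=cfg,
    )


def synchronized_sponge_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Conditions for the synchronized sponge-community comparison.

    A small housekeeping community shares a dedicated miRNA block with
    evenly spread high site counts (a stable near-clique conserved between
    the groups), while most other genes have their regulation strengths
    redrawn in group B (subtype-divergent non-HK crosstalk).  This is the
    planted structure behind the focal-vs-matched-null subnetwork test.
    """
    base = dict(
        n_genes=600,
        n_mirnas=64,
        n_blocks=8,
        hk_dedicated_blocks=1,
        samples_per_group=(75, 75, 75, 75),
        hk_fraction=0.05,
        sponge_site_range=(16, 24),
        signal_strength_range=(0.5, 0.95),
        hk_noise_sd=0.2,
        hk_signal_sd=1.5,
        group_divergence=0.9,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def config_to_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["samples_per_group"] = list(cfg.samples_per_group)
    d["sponge_site_range"] = list(cfg.sponge_site_range)
    d["nonsponge_site_range"] = list(cfg.nonsponge_site_range)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for key in (
        "samples_per_group",
        "sponge_site_range",
        "nonsponge_site_range",
        "signal_strength_range",
    ):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)
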