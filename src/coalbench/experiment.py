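"""Full factorial benchmark orchestration.

The design follows the study protocol: ``n_species_trees`` uniform-
speciation species trees of ``n_taxa`` taxa, each rescaled to every depth;
``n_loci_total`` coalescent gene trees per (tree, depth); one alignment per
gene tree; the loci partitioned into consecutive blocks of each block size
and analyzed three ways per block -- Bayesian MCMC on the concatenated
matrix, GLASS/STEM clustering on the block's gene trees, and exact MDC --
with Robinson-Foulds discord against the true species tree recorded per
analysis.  At full scale (50 trees, 540 loci, blocks of 3/9/27) this yields
180/60/20 matrices per tree-depth combination and 9,000/3,000/1,000
analyses per summary cell; ``scale_factor`` shrinks the design
proportionally for desk-scale reruns.

Seeding: a single ``root_seed`` plus deterministic spawn keys per
(iteration, species tree, depth, locus, stage), so any stage can be re-run
independently and identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from coalbench.discord import anova_table, mean_discord, robinson_foulds
from coalbench.inference import McmcConfig, consensus_allcompat, estimate_gene_tree_ml, run_concat_mcmc
from coalbench.seqsim import STUDY_MODEL, Alignment, SubstitutionModel, concatenate, simulate_alignment
from coalbench.speciestree import glass_species_tree, mdc_species_tree
from coalbench.treesim import MSCSimulator, simulate_species_tree, write_trees

__all__ = [
    "ExperimentConfig",
    "ConcatenatedMatrix",
    "ExperimentResult",
    "partition_loci",
    "design_counts",
    "run_experiment",
]

# spawn-key stage tags
_SPECIES, _GENETREE, _SEQ, _MCMC = 0, 1, 2, 3

METHODS = ("concatenation", "stem", "mdc")


def _lcm_all(values) -> int:
    out = 1
    for v in values:
        out = math.lcm(out, int(v))
    return out


@dataclass
class ExperimentConfig:
    """Benchmark design parameters (defaults = the full study design)."""

    n_species_trees: int = 50
    n_taxa: int = 8
    depths: tuple = (1.0, 10.0)
    n_loci_total: int = 540
    block_sizes: tuple = (3, 9, 27)
    seq_length: int = 1000
    model: SubstitutionModel = STUDY_MODEL
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    root_seed: int = 1
    output_dir: str | None = None
    n_iterations: int = 1
    coalescent_unit_in_N: float = 1.0
    use_true_gene_trees: bool = False
    scale_factor: int = 1

    def __post_init__(self):
        if isinstance(self.model, dict):
            self.model = SubstitutionModel(**self.model)
        if isinstance(self.mcmc, dict):
            self.mcmc = McmcConfig(**self.mcmc)
        self.depths = tuple(float(d) for d in self.depths)
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        for name in ("n_species_trees", "n_taxa", "n_loci_total", "seq_length",
                     "n_iterations", "scale_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(d <= 0 for d in self.depths):
            raise ValueError("depths must be positive")
        for b in self.block_sizes:
            if self.n_loci_total % b:
                raise ValueError(
                    f"n_loci_total={self.n_loci_total} not divisible by block size {b}"
                )

    # -- scaled design -----------------------------------------------------
    @property
    def eff_n_species_trees(self) -> int:
        return max(2, self.n_species_trees // self.scale_factor)

    @property
    def eff_n_loci_total(self) -> int:
        if self.scale_factor == 1:
            return self.n_loci_total
        step = _lcm_all(self.block_sizes)
        return max(step, step * round(self.n_loci_total / self.scale_factor / step))

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.md5(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def design_counts(cfg: ExperimentConfig) -> pd.DataFrame:
    """Design identities: matrices per cell and analyses per summary cell."""
    rows = []
    for b in cfg.block_sizes:
        rows.append(
            {
                "block_size": b,
                "matrices_per_tree_depth": cfg.n_loci_total // b,
                "analyses_per_summary_cell": cfg.n_species_trees * cfg.n_loci_total // b,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConcatenatedMatrix:
    """One concatenated block: alignment, 1-based partition table, provenance."""

    alignment: Alignment
    partition: list  # (locus name, start, end), 1-based inclusive, tiling [1, L]
    provenance: dict

    def __post_init__(self):
        pos = 0
        for _, start, end in self.partition:
            if start != pos + 1 or end < start:
                raise ValueError("partition spans must tile [1, L] without gaps")
            pos = end
        if pos != self.alignment.length:
            raise ValueError("partition does not cover the alignment")


def partition_loci(loci, block_size: int, provenance: dict | None = None) -> list:
    """Concatenate consecutive disjoint blocks of ``block_size`` loci.

    Returns ``len(loci) / block_size`` matrices (simulation order); raises
    for non-divisible input or taxon-set mismatches among loci.
    """
    loci = list(loci)
    if block_size < 1 or len(loci) % block_size:
        raise ValueError(
            f"number of loci ({len(loci)}) must be divisible by block size ({block_size})"
        )
    out = []
    for j in range(len(loci) // block_size):
        block = loci[j * block_size : (j + 1) * block_size]
        aln, partition = concatenate(block)
        prov = dict(provenance or {})
        prov.update(
            block_index=j,
            locus_ids=list(range(j * block_size, (j + 1) * block_size)),
            n_loci=block_size,
        )
        out.append(ConcatenatedMatrix(aln, partition, prov))
    return out


@dataclass
class ExperimentResult:
    records: pd.DataFrame          # one row per analysis
    summary: pd.DataFrame          # two-stage mean discord per cell
    anova: pd.DataFrame            # ANOVA report (per depth, per comparison)
    failures: list                 # per-cell failures, never silently dropped
    config: ExperimentConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "discord.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "mean_discord.tsv", sep="\t", index=False)
        self.anova.to_csv(out / "anova.tsv", sep="\t", index=False)
        if self.failures:
            with open(out / "failures.json", "w") as fh:
                json.dump(self.failures, fh, indent=2)


def _rng(cfg: ExperimentConfig, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.root_seed, spawn_key=key))


def _scale_tree(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


def _rescale_to_coalescent(tree: dendropy.Tree, subst_scale: float) -> dendropy.Tree:
    return _scale_tree(tree, 1.0 / subst_scale)


def simulate_replicate(cfg: ExperimentConfig, iteration: int, st_id: int):
    """Simulate one species tree (unit depth) shared by all depths."""
    rng = _rng(cfg, iteration, st_id, _SPECIES)
    return simulate_species_tree(cfg.n_taxa, 1.0, rng)


def _analyze_tree_depth(cfg, iteration, st_id, depth_idx, base_tree, log):
    """All analyses for one (species tree, depth): returns record rows."""
    depth = cfg.depths[depth_idx] * cfg.coalescent_unit_in_N
    species = _scale_tree(base_tree, depth)
    sim = MSCSimulator(species)
    n_loci = cfg.eff_n_loci_total

    gene_trees, alignments = [], []
    for locus in range(n_loci):
        gt = sim.simulate(_rng(cfg, iteration, st_id, depth_idx, locus, _GENETREE))
        gene_trees.append(gt)
        alignments.append(
            simulate_alignment(
                gt, cfg.seq_length, cfg.model, _rng(cfg, iteration, st_id, depth_idx, locus, _SEQ)
            )
        )

    if cfg.use_true_gene_trees:
        input_trees = gene_trees
    else:
        t0 = time.perf_counter()
        input_trees = [
            _rescale_to_coalescent(estimate_gene_tree_ml(aln, cfg.model), cfg.model.subst_scale)
            for aln in alignments
        ]
        log("gene_tree_ml", st_id=st_id, depth=depth, seconds=round(time.perf_counter() - t0, 2))

    rows, failures = [], []
    for block_size in cfg.block_sizes:
        matrices = partition_loci(
            alignments, block_size, provenance={"species_tree_id": st_id, "depth": depth}
        )
        for j, matrix in enumerate(matrices):
            block_trees = [input_trees[i] for i in matrix.provenance["locus_ids"]]
            base = dict(
                species_tree_id=st_id,
                depth=cfg.depths[depth_idx],
                n_loci=block_size,
                matrix_index=j,
                iteration=iteration,
            )
            t0 = time.perf_counter()
            try:
                sample = run_concat_mcmc(
                    matrix.alignment,
                    cfg.mcmc,
                    _rng(cfg, iteration, st_id, depth_idx, block_size, j, _MCMC),
                )
                cons = consensus_allcompat(sample)
                rows.append(
                    dict(
                        base,
                        method="concatenation",
                        rf=robinson_foulds(species, cons),
                        converged=sample.converged,
                    )
                )
            except Exception as exc:  # noqa: BLE001 -- surfaced, not dropped
                failures.append(dict(base, method="concatenation", error=repr(exc)))
            try:
                rows.append(
                    dict(
                        base,
                        method="stem",
                        rf=robinson_foulds(species, glass_species_tree(block_trees)),
                        converged=True,
                    )
                )
            except Exception as exc:
                failures.append(dict(base, method="stem", error=repr(exc)))
            try:
                rows.append(
                    dict(
                        base,
                        method="mdc",
                        rf=robinson_foulds(species, mdc_species_tree(block_trees).tree),
                        converged=True,
                    )
                )
            except Exception as exc:
                failures.append(dict(base, method="mdc", error=repr(exc)))
            log(
                "block_done",
                st_id=st_id,
                depth=depth,
                block_size=block_size,
                matrix_index=j,
                seconds=round(time.perf_counter() - t0, 2),
            )
    return rows, failures, species, gene_trees


def run_experiment(cfg: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run the full (possibly scaled) factorial design.

    Per-cell results are cached as TSV under ``output_dir/cells/<hash>``
    keyed by the config hash, so an interrupted run resumes; trees and
    tables are written under ``output_dir`` when one is given.  Identical
    config and root seed give byte-identical discord tables.
    """
    out = Path(cfg.output_dir) if cfg.output_dir else None
    cell_dir = out / "cells" / cfg.config_hash() if out else None
    if cell_dir:
        cell_dir.mkdir(parents=True, exist_ok=True)
    log_fh = open(out / "log.jsonl", "a") if out else None

    def log(event, **kw):
        if log_fh:
            log_fh.write(json.dumps({"event": event, **kw}) + "\n")
            log_fh.flush()
        if progress:
            print(f"[{event}] {kw}")

    all_rows, failures = [], []
    for iteration in range(cfg.n_iterations):
        for st_id in range(1, cfg.eff_n_species_trees + 1):
            base_tree = simulate_replicate(cfg, iteration, st_id)
            for depth_idx in range(len(cfg.depths)):
                cache = (
                    cell_dir / f"it{iteration}_st{st_id}_d{depth_idx}.tsv" if cell_dir else None
                )
                if cache and cache.exists():
                    cached = pd.read_csv(cache, sep="\t")
                    all_rows.extend(cached.to_dict("records"))
                    log("cell_cached", st_id=st_id, depth_idx=depth_idx)
                    continue
                rows, fails, species, gene_trees = _analyze_tree_depth(
                    cfg, iteration, st_id, depth_idx, base_tree, log
                )
                all_rows.extend(rows)
                failures.extend(fails)
                if cache:
                    pd.DataFrame(rows).to_csv(cache, sep="\t", index=False)
                if out:
                    tree_dir = out / f"species_tree_{st_id:03d}" / f"depth_{cfg.depths[depth_idx]:g}"
                    tree_dir.mkdir(parents=True, exist_ok=True)
                    write_trees([species], tree_dir / "species.nwk")
                    write_trees(gene_trees, tree_dir / "genetrees.nwk")

    records = pd.DataFrame(all_rows)
    summary = mean_discord(records)
    anova = anova_table(records)
    if log_fh:
        log_fh.close()
    result = ExperimentResult(records, summary, anova, failures, cfg)
    if out:
        result.write(out / "results")
    return result
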