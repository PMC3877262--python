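"""Matched two-condition synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the screen is designed to
detect: a cohort of matched mRNA/miRNA samples under two conditions in which
some protein complexes are *coherently regulated* — their member genes load
on a shared latent factor, and the miRNAs targeting them load on the same
factor with opposite sign (repressive action) — and a subset of these
modules loses that coupling in the second condition (the planted,
dysregulated modules).

Latent-factor (spiked-covariance) structure is the natural generative
counterpart of the spectral-entropy statistic: a coherent module produces a
mutual-information matrix dominated by one singular direction (low entropy),
decoupling spreads the spectral mass (high entropy), so planted modules show
exactly the between-condition entropy contrast the screen scores.

The miRNA→gene interaction network is homogeneous Bernoulli noise over all
pairs, so that under ``coupling = 0`` genes are fully exchangeable with the
size-matched random sets of the permutation null.  Planted *modulator
triplets* (miRNA x, target y, protein z) overwrite a spare gene's expression
with ``y = x * logistic(gain * z) + noise`` — the miRNA–target association
strength depends on the protein level — giving the downstream CMI screen a
known positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_model import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionSet,
    SampleGroups,
    write_expression,
    write_gmt,
    write_groups,
    write_interactions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "ModulatorTriplet",
    "CohortTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "write_cohort",
    "read_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    ``coupling`` is the latent-factor loading of module genes (and, with
    opposite sign, of their targeting miRNAs) relative to ``noise_sd``;
    planted modules carry it only in condition A and are decoupled (loading
    0) in condition B, non-planted modules carry it identically in both.
    ``background_edge_rate`` is the Bernoulli probability of each
    miRNA→gene interaction edge; ``edges_per_module`` is the minimum number
    of edges required into each module's member set (blocks are redrawn
    until satisfied, so every module has targeting miRNAs).
    """

    n_genes: int = 1500
    n_mirnas: int = 400
    n_samples_per_condition: int = 60
    n_modules: int = 40
    module_size_range: tuple = (5, 9)
    n_planted: int = 3
    coupling: float = 2.0
    noise_sd: float = 1.0
    edges_per_module: int = 2
    background_edge_rate: float = 0.0075
    n_modulator_triplets: int = 1
    modulator_gate_gain: float = 4.0
    modulator_noise_sd: float = 0.5
    condition_a: str = "normal"
    condition_b: str = "tumor"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_samples_per_condition", "n_modules",
                     "edges_per_module"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError("module_size_range must satisfy 2 <= lo <= hi")
        if not (0 <= self.n_planted <= self.n_modules):
            raise ValueError("n_planted must lie in [0, n_modules]")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 < self.background_edge_rate < 1):
            raise ValueError("background_edge_rate must lie in (0, 1)")
        if self.n_modulator_triplets < 0:
            raise ValueError("n_modulator_triplets must be >= 0")
        if self.condition_a == self.condition_b:
            raise ValueError("condition labels must differ")


@dataclass(frozen=True)
class ModulatorTriplet:
    mirna_id: str
    target_id: str
    protein_id: str
    set_id: str


@dataclass(frozen=True)
class CohortTruth:
    planted_modules: tuple
    modulator_triplets: tuple
    module_ids: tuple


@dataclass(frozen=True)
class SyntheticCohort:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    groups: SampleGroups
    interactions: InteractionSet
    gene_sets: GeneSetCollection
    truth: CohortTruth
    config: SimulationConfig


def simulate_modulator_triplet(
    n_samples: int,
    rng: np.random.Generator,
    gate_gain: float = 4.0,
    noise_sd: float = 0.5,
    modulated: bool = True,
):
    """One (miRNA x, target y, protein z) triplet with a protein-gated link.

    The target follows ``y = x * logistic(gain * z) + noise``: the strength
    of the miRNA–target association depends on the protein level, which is
    what the conditional-dependence screen is built to detect.  With
    ``modulated=False`` the protein is irrelevant (y depends on x only),
    giving the matched null fixture.
    """
    x = rng.standard_normal(n_samples)
    z = rng.standard_normal(n_samples)
    gate = 1.0 / (1.0 + np.exp(-gate_gain * z)) if modulated else 0.5
    y = x * gate + noise_sd * rng.standard_normal(n_samples)
    return x, y, z


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate one matched two-condition cohort; reproducible given the seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    n_module_genes = int(sizes.sum())
    if n_module_genes + config.n_modulator_triplets > config.n_genes:
        raise ValueError(
            f"infeasible sizes: {config.n_modules} modules of {lo}-{hi} genes plus "
            f"{config.n_modulator_triplets} modulator targets exceed n_genes={config.n_genes}"
        )

    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    mirna_ids = [f"mir{j:03d}" for j in range(config.n_mirnas)]
    module_ids = [f"M{k + 1:03d}" for k in range(config.n_modules)]
    n_s = config.n_samples_per_condition
    samples = {
        config.condition_a: [f"{config.condition_a}_{k:03d}" for k in range(n_s)],
        config.condition_b: [f"{config.condition_b}_{k:03d}" for k in range(n_s)],
    }

    # disjoint module gene blocks
    blocks, start = [], 0
    for size in sizes:
        blocks.append(np.arange(start, start + int(size)))
        start += int(size)
    planted_idx = np.sort(rng.choice(config.n_modules, size=config.n_planted,
                                     replace=False))
    planted = {int(i) for i in planted_idx}

    # homogeneous interaction network; module blocks redrawn until they have
    # the minimum number of incoming edges
    edge = rng.random((config.n_mirnas, config.n_genes)) < config.background_edge_rate
    redraws = 0
    for block in blocks:
        attempts = 0
        while edge[:, block].sum() < config.edges_per_module:
            edge[:, block] = (
                rng.random((config.n_mirnas, block.size)) < config.background_edge_rate
            )
            redraws += 1
            attempts += 1
            if attempts > 1000:
                raise RuntimeError(
                    "cannot satisfy edges_per_module; raise background_edge_rate"
                )
    if redraws:
        logger.info("redrew %d module edge blocks to satisfy edges_per_module", redraws)

    # expression: latent factor per (module, condition) with anti-correlated
    # miRNA loadings; planted modules decouple in condition B
    module_mirnas = [np.flatnonzero(edge[:, block].any(axis=1)) for block in blocks]
    gene_values = {}
    mirna_values = {}
    for c_index, condition in enumerate((config.condition_a, config.condition_b)):
        genes = config.noise_sd * rng.standard_normal((config.n_genes, n_s))
        mirnas = config.noise_sd * rng.standard_normal((config.n_mirnas, n_s))
        for k, block in enumerate(blocks):
            factor = rng.standard_normal(n_s)
            lam = config.coupling
            if k in planted and c_index == 1:
                lam = 0.0
            genes[block] += lam * factor
            mirnas[module_mirnas[k]] += -lam * factor
        gene_values[condition] = genes
        mirna_values[condition] = mirnas

    # planted modulator triplets on spare (non-module) genes
    triplets = []
    planted_gene_pool = (
        np.concatenate([blocks[i] for i in sorted(planted)])
        if planted else np.concatenate(blocks)
    )
    free_mirnas = np.flatnonzero(~edge.any(axis=1))
    for t in range(config.n_modulator_triplets):
        target = n_module_genes + t
        protein = int(rng.choice(planted_gene_pool))
        mirna = int(rng.choice(free_mirnas)) if free_mirnas.size else int(
            rng.integers(config.n_mirnas)
        )
        free_mirnas = free_mirnas[free_mirnas != mirna]
        for condition in (config.condition_a, config.condition_b):
            x = mirna_values[condition][mirna]
            z = gene_values[condition][protein]
            z_std = (z - z.mean()) / z.std()
            gate = 1.0 / (1.0 + np.exp(-config.modulator_gate_gain * z_std))
            gene_values[condition][target] = (
                x * gate + config.modulator_noise_sd * rng.standard_normal(n_s)
            )
        edge[mirna, target] = True
        set_id = ""
        for k, block in enumerate(blocks):
            if protein in block:
                set_id = module_ids[k]
                break
        triplets.append(ModulatorTriplet(mirna_ids[mirna], gene_ids[target],
                                         gene_ids[protein], set_id))

    all_samples = samples[config.condition_a] + samples[config.condition_b]
    mrna = ExpressionMatrix(
        gene_ids, all_samples,
        np.hstack([gene_values[config.condition_a], gene_values[config.condition_b]]),
    )
    mirna = ExpressionMatrix(
        mirna_ids, all_samples,
        np.hstack([mirna_values[config.condition_a], mirna_values[config.condition_b]]),
    )
    groups = SampleGroups({s: c for c in (config.condition_a, config.condition_b)
                           for s in samples[c]})
    pairs = frozenset(
        (mirna_ids[j], gene_ids[i]) for j, i in zip(*np.nonzero(edge))
    )
    gene_sets = GeneSetCollection([
        GeneSet(module_ids[k], f"synthetic module {k + 1}",
                tuple(gene_ids[i] for i in blocks[k]))
        for k in range(config.n_modules)
    ])
    truth = CohortTruth(
        planted_modules=tuple(module_ids[int(i)] for i in planted_idx),
        modulator_triplets=tuple(triplets),
        module_ids=tuple(module_ids),
    )
    logger.info("simulated cohort: %d genes, %d miRNAs, %d+%d samples, %d edges, "
                "%d planted modules, %d modulator triplets",
                config.n_genes, config.n_mirnas, n_s, n_s, len(pairs),
                config.n_planted, len(triplets))
    return SyntheticCohort(mrna, mirna, groups, InteractionSet(pairs),
                           gene_sets, truth, config)


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort in exactly the formats the readers consume.

    Returns a dict of logical name → written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": directory / "mrna.tsv",
        "mirna": directory / "mirna.tsv",
        "groups": directory / "groups.tsv",
        "interactions": directory / "interactions.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "truth": directory / "truth.tsv",
    }
    write_expression(cohort.mrna, paths["mrna"])
    write_expression(cohort.mirna, paths["mirna"])
    write_groups(cohort.groups, paths["groups"])
    write_interactions(cohort.interactions, paths["interactions"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tset_id\tmirna_id\ttarget_id\tprotein_id\n")
        for set_id in cohort.truth.planted_modules:
            fh.write(f"planted_module\t{set_id}\t\t\t\n")
        for tr in cohort.truth.modulator_triplets:
            fh.write(f"modulator\t{tr.set_id}\t{tr.mirna_id}\t{tr.target_id}\t{tr.protein_id}\n")
    return paths


def read_truth(path) -> CohortTruth:
    """Re-read a truth table written by :func:`write_cohort`."""
    planted, triplets = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("kind"):
            raise ValueError(f"{path}: not a truth table")
        for line in fh:
            kind, set_id, mirna_id, target_id, protein_id = line.rstrip("\n").split("\t")
            if kind == "planted_module":
                planted.append(set_id)
            elif kind == "modulator":
                triplets.append(ModulatorTriplet(mirna_id, target_id, protein_id, set_id))
            else:
                raise ValueError(f"{path}: unknown record kind {kind!r}")
    return CohortTruth(tuple(planted), tuple(triplets), ())
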