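"""Synthetic cohort, atlas and reference generators with planted ground truth.

Every pipeline input can be simulated here with a known, recoverable
structure: structural connectomes with a planted differential edge
component between two clinical groups, a regional expression atlas with
block-correlated gene modules whose latent factors track a regional trait
at a stated correlation, a cell-type expression reference with one module's
genes boosted in one cell type, and a two-group validation expression
dataset with planted per-gene effect sizes. Each generator is fully
determined by its spec and seed, and each returns the planted truth
alongside the data so downstream detectors can be scored against it.

The connectome generator uses a random geometric base topology
(distance-decaying weights on uniformly placed parcel centroids), which
gives the spatially structured sparsity that FA networks show and that
component-based inference is sensitive to. Group differences are additive
shifts on edge weights before clipping to [0, 1], preserving symmetry and
range. Phenotype scale scores are Gaussian fixtures whose group centers
follow typical clinic values for a depression cohort with and without
suicidal ideation/behavior; they are fixtures, not estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ctrlcircuit.io import (
    GROUP_LABELS,
    StructuralNetwork,
    validate_phenotypes,
    write_connectome,
)

__all__ = [
    "CohortSpec",
    "ExpressionSpec",
    "CellTypeSpec",
    "ConnectomeCohort",
    "ExpressionAtlasData",
    "ValidationDataset",
    "generate_connectome_cohort",
    "generate_expression_atlas",
    "generate_celltype_reference",
    "generate_validation_dataset",
]

# group centers for the phenotype fixtures: (mean, sd) per group
_SCALE_CENTERS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"HC": (34.2, 8.7), "MDDNSI": (31.1, 12.0), "MDDSI": (30.3, 11.7), "MDDSB": (30.1, 13.0)},
    "education": {"HC": (11.3, 3.6), "MDDNSI": (10.9, 2.7), "MDDSI": (11.0, 3.7), "MDDSB": (10.7, 3.3)},
    "HAMD17": {"HC": (1.5, 1.5), "MDDNSI": (19.0, 5.0), "MDDSI": (21.0, 5.0), "MDDSB": (14.5, 4.5)},
    "HAMA": {"HC": (1.2, 1.2), "MDDNSI": (16.0, 6.0), "MDDSI": (15.5, 4.5), "MDDSB": (14.5, 4.5)},
    "CTQ": {"HC": (34.0, 6.0), "MDDNSI": (39.0, 8.0), "MDDSI": (43.0, 11.0), "MDDSB": (39.0, 10.0)},
    "RSES": {"HC": (38.0, 8.0), "MDDNSI": (59.0, 9.0), "MDDSI": (62.0, 11.0), "MDDSB": (56.0, 9.0)},
    "MoCA": {"HC": (26.0, 2.0), "MDDNSI": (24.0, 2.5), "MDDSI": (25.0, 2.5), "MDDSB": (24.5, 2.5)},
    "ERQ_CR": {"HC": (34.0, 4.0), "MDDNSI": (28.0, 6.0), "MDDSI": (28.0, 7.0), "MDDSB": (27.0, 8.0)},
    "ERQ_ES": {"HC": (15.0, 5.0), "MDDNSI": (17.5, 5.5), "MDDSI": (16.0, 4.5), "MDDSB": (15.5, 6.5)},
    "RFQ_promote": {"HC": (20.4, 3.9), "MDDNSI": (17.2, 3.6), "MDDSI": (17.0, 3.5), "MDDSB": (18.8, 3.9)},
    "RFQ_prevent": {"HC": (20.5, 2.5), "MDDNSI": (18.7, 2.5), "MDDSI": (17.5, 2.0), "MDDSB": (18.6, 2.2)},
}
_SEX_P_FEMALE = {"HC": 22 / 37, "MDDNSI": 14 / 31, "MDDSI": 21 / 34, "MDDSB": 8 / 22}


@dataclass
class CohortSpec:
    """Conditions for a synthetic structural-connectome cohort."""

    n_per_group: dict[str, int]
    n_regions: int = 90
    planted_edges: list[tuple[int, int]] = field(default_factory=list)
    edge_effect: float = 0.0
    affected_group: str = "MDDSI"
    base_weight_range: tuple[float, float] = (0.2, 0.7)
    noise_sd: float = 0.1
    connection_radius: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 10:
            raise ValueError("n_regions must be at least 10")
        if self.edge_effect < 0:
            raise ValueError("edge_effect must be nonnegative")
        lo, hi = self.base_weight_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("base_weight_range must be within [0, 1]")
        unknown = set(self.n_per_group) - set(GROUP_LABELS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        for i, j in self.planted_edges:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions) or i == j:
                raise ValueError(f"planted edge ({i}, {j}) out of range")
        if self.planted_edges and not _edges_connected(self.planted_edges):
            raise ValueError("planted_edges must form a connected subgraph")


def _edges_connected(edges: list[tuple[int, int]]) -> bool:
    parent: dict[int, int] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        parent[find(i)] = find(j)
    roots = {find(v) for v in parent}
    return len(roots) == 1


@dataclass
class ConnectomeCohort:
    networks: list[StructuralNetwork]
    phenotypes: pd.DataFrame
    truth: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for net in self.networks:
            write_connectome(net, out / f"{net.subject_id}.tsv")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def generate_connectome_cohort(spec: CohortSpec) -> ConnectomeCohort:
    """Simulate FA-weighted connectomes with a planted differential component.

    A shared random geometric base topology (nodes uniform in the unit
    cube, edges within ``connection_radius``, weights decaying with
    distance within ``base_weight_range``) is perturbed per subject by
    Gaussian edge noise of scale ``noise_sd`` and clipped to [0, 1].
    Planted edges are forced into the topology at mid-range weight and
    attenuated by ``edge_effect * noise_sd`` in the affected group, i.e.
    ``edge_effect`` is the standardized mean difference at those edges.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    lo, hi = spec.base_weight_range

    pos = rng.uniform(size=(n, 3))
    dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    base = np.where(dist < spec.connection_radius,
                    hi - (hi - lo) * dist / spec.connection_radius, 0.0)
    np.fill_diagonal(base, 0.0)
    mid = (lo + hi) / 2.0
    for i, j in spec.planted_edges:
        base[i, j] = base[j, i] = mid

    labels = [f"R{idx:03d}" for idx in range(n)]
    shift = spec.edge_effect * spec.noise_sd

    networks: list[StructuralNetwork] = []
    rows = []
    sid = 0
    for group in GROUP_LABELS:
        for _ in range(spec.n_per_group.get(group, 0)):
            subject = f"sub-{sid:04d}"
            noise = rng.normal(0.0, spec.noise_sd, size=(n, n))
            noise = np.triu(noise, k=1)
            noise += noise.T
            A = np.where(base > 0, base + noise, 0.0)
            if group == spec.affected_group:
                for i, j in spec.planted_edges:
                    A[i, j] -= shift
                    A[j, i] -= shift
            A = np.clip(A, 0.0, 1.0)
            np.fill_diagonal(A, 0.0)
            networks.append(
                StructuralNetwork(subject_id=subject, region_labels=labels, A=A)
            )
            rows.append(_phenotype_row(subject, group, rng))
            sid += 1

    phenotypes = validate_phenotypes(pd.DataFrame(rows))
    truth = {
        "planted_edges": [list(e) for e in spec.planted_edges],
        "planted_nodes": sorted({v for e in spec.planted_edges for v in e}),
        "affected_group": spec.affected_group,
        "edge_effect": spec.edge_effect,
        "noise_sd": spec.noise_sd,
        "mean_shift": shift,
        "n_regions": n,
        "seed": spec.seed,
    }
    return ConnectomeCohort(networks=networks, phenotypes=phenotypes, truth=truth)


def _phenotype_row(subject: str, group: str, rng: np.random.Generator) -> dict:
    row = {
        "subject_id": subject,
        "group": group,
        "sex": "F" if rng.random() < _SEX_P_FEMALE[group] else "M",
        "medication_load": 0.0 if group == "HC" else float(np.round(rng.gamma(2.0, 1.0), 2)),
    }
    for scale, centers in _SCALE_CENTERS.items():
        mu, sd = centers[group]
        val = rng.normal(mu, sd)
        if scale == "age":
            val = max(18.0, val)
        row[scale] = float(np.round(max(val, 0.0), 2))
    return row


@dataclass
class ExpressionSpec:
    """Conditions for a synthetic regional expression atlas.

    ``modules`` lists ``(size, within_module_correlation,
    trait_correlation)`` triples; each module's genes share a latent
    regional factor, and that factor correlates with the regional trait at
    the stated value.
    """

    n_genes: int
    n_regions: int
    modules: list[tuple[int, float, float]] = field(default_factory=list)
    trait: np.ndarray | str = "generate"
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m[0] for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for size, w, tc in self.modules:
            if size < 2:
                raise ValueError("each module needs at least 2 genes")
            if not (-1 <= w <= 1 and -1 <= tc <= 1):
                raise ValueError("correlations must lie in [-1, 1]")
            if abs(tc) == 1 and w < 1:
                raise ValueError(
                    "trait_correlation of +/-1 is infeasible with within-module noise"
                )


@dataclass
class ExpressionAtlasData:
    expr: pd.DataFrame  # genes x regions
    trait: pd.Series  # per region
    truth: dict

    @property
    def module_labels(self) -> pd.Series:
        return pd.Series(self.truth["gene_modules"], name="module")

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.expr.to_csv(out / "expression_atlas.tsv", sep="\t", float_format="%.8g")
        self.trait.to_frame("trait").to_csv(out / "trait.tsv", sep="\t")
        with open(out / "expression_truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_expression_atlas(spec: ExpressionSpec) -> ExpressionAtlasData:
    """Simulate a genes x regions atlas with planted coexpression modules.

    A gene in module m with within-correlation w is
    ``sqrt(w) * f_m + sqrt(1-w) * noise`` so any two module genes correlate
    at w in expectation. The module factor is ``tc * trait +
    sqrt(1-tc^2) * noise`` with the noise orthogonalized against the trait
    in-sample, so the factor's *empirical* correlation with the trait is
    exactly tc and the planted value is recoverable without sampling bias;
    the module eigengene then correlates with the trait near tc. Background
    genes are independent noise, labeled "none".
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.n_regions
    regions = [f"L_{idx:03d}" for idx in range(r)]

    if isinstance(spec.trait, str):
        trait = rng.normal(size=r)
    else:
        trait = np.asarray(spec.trait, dtype=float)
        if trait.shape != (r,):
            raise ValueError("trait length must equal n_regions")
    trait_z = _standardize(trait)

    expr = np.empty((spec.n_genes, r))
    gene_modules = {}
    gene_ids = [f"G{idx:05d}" for idx in range(spec.n_genes)]
    pos = 0
    factors = []
    for m, (size, w, tc) in enumerate(spec.modules):
        eta = rng.normal(size=r)
        eta = eta - (eta @ trait_z) / (trait_z @ trait_z) * trait_z
        if eta.std() > 0:
            eta = _standardize(eta)
        f = tc * trait_z + np.sqrt(max(0.0, 1 - tc**2)) * eta
        f = _standardize(f)
        factors.append(f)
        for _ in range(size):
            g = np.sqrt(max(w, 0.0)) * f + np.sqrt(max(0.0, 1 - max(w, 0.0))) * rng.normal(size=r)
            expr[pos] = g
            gene_modules[gene_ids[pos]] = m
            pos += 1
    for idx in range(pos, spec.n_genes):
        expr[idx] = rng.normal(size=r)
        gene_modules[gene_ids[idx]] = "none"

    df = pd.DataFrame(expr, index=gene_ids, columns=regions)
    truth = {
        "gene_modules": gene_modules,
        "module_specs": [list(m) for m in spec.modules],
        "n_background": spec.n_genes - pos,
        "seed": spec.seed,
    }
    return ExpressionAtlasData(
        expr=df, trait=pd.Series(trait, index=regions, name="trait"), truth=truth
    )


@dataclass
class CellTypeSpec:
    """Conditions for a synthetic cell-type mean-expression reference."""

    cell_type_names: list[str]
    enriched_module: int | None = None
    enrichment_fold: float = 1.0
    target_cell_type: str | None = None
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.cell_type_names)) != len(self.cell_type_names):
            raise ValueError("cell type names must be unique")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.target_cell_type is None and self.cell_type_names:
            self.target_cell_type = self.cell_type_names[0]
        if self.target_cell_type not in self.cell_type_names:
            raise ValueError(f"unknown target cell type {self.target_cell_type!r}")


def generate_celltype_reference(
    module_labels: pd.Series, spec: CellTypeSpec
) -> tuple[pd.DataFrame, dict]:
    """Simulate a genes x cell-types mean-expression reference.

    Each gene gets a lognormal baseline shared across cell types times mild
    multiplicative gamma noise (mean 1, cv ``noise_cv``), so specificity is
    uniform in expectation. Genes of the enriched module are multiplied by
    ``enrichment_fold`` in the target cell type; with C cell types their
    expected specificity there is close to fold / (fold + C - 1).
    """
    if module_labels.empty:
        raise ValueError("empty gene list")
    if spec.enriched_module is not None:
        present = {m for m in module_labels if m != "none"}
        if spec.enriched_module not in present:
            raise ValueError(f"unknown module index {spec.enriched_module}")
    rng = np.random.default_rng(spec.seed)
    genes = list(module_labels.index)
    C = len(spec.cell_type_names)
    baseline = rng.lognormal(mean=1.0, sigma=0.5, size=len(genes))
    shape = 1.0 / spec.noise_cv**2
    noise = rng.gamma(shape, 1.0 / shape, size=(len(genes), C))
    vals = baseline[:, None] * noise
    if spec.enriched_module is not None and spec.enrichment_fold > 1:
        tgt = spec.cell_type_names.index(spec.target_cell_type)
        mask = (module_labels == spec.enriched_module).to_numpy()
        vals[mask, tgt] *= spec.enrichment_fold
    ref = pd.DataFrame(vals, index=genes, columns=spec.cell_type_names)
    truth = {
        "enriched_module": spec.enriched_module,
        "target_cell_type": spec.target_cell_type,
        "enrichment_fold": spec.enrichment_fold,
        "seed": spec.seed,
    }
    return ref, truth


@dataclass
class ValidationDataset:
    data: pd.DataFrame  # samples x (group + genes)
    truth: dict


def generate_validation_dataset(
    genes,
    n_per_group: int,
    de_genes,
    effect_sizes,
    seed: int = 0,
    group_names: tuple[str, str] = ("control", "case"),
) -> ValidationDataset:
    """Two-group expression table with planted per-gene effect sizes.

    Expression is unit-variance Gaussian; each differential gene's case
    group is shifted by its (standardized) effect size. Non-listed genes
    are null.
    """
    genes = list(genes)
    de_genes = list(de_genes)
    effect_sizes = list(effect_sizes)
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    if len(de_genes) != len(effect_sizes):
        raise ValueError(
            f"{len(de_genes)} de_genes but {len(effect_sizes)} effect sizes"
        )
    unknown = set(de_genes) - set(genes)
    if unknown:
        raise ValueError(f"de_genes not in gene panel: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_group, len(genes)))
    shift = dict(zip(de_genes, effect_sizes))
    for j, g in enumerate(genes):
        if g in shift:
            X[n_per_group:, j] += shift[g]
    df = pd.DataFrame(X, columns=genes)
    df.insert(0, "group", [group_names[0]] * n_per_group + [group_names[1]] * n_per_group)
    truth = {"de_genes": de_genes, "effect_sizes": effect_sizes, "seed": seed}
    return ValidationDataset(data=df, truth=truth)
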