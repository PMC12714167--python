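"""End-to-end orchestration of the synthetic-to-report analysis run.

``run_all`` executes: simulate -> controllability -> NBS (SI and SB
contrasts) -> regional trait construction -> expression atlas with planted
modules -> coexpression module detection -> module-trait association and
hub screening -> pathway ORA + cell-type enrichment -> validation DEG
overlap and ROC. Results land in a machine-readable JSON report plus a
short human-readable summary.

Seeding: the single config seed fans out to per-stage seeds by a fixed
counter scheme (``stage_seed = seed * 100 + stage_index``), so any stage
can be re-run reproducibly on its own.

The SI contrast compares patients with vs without suicidal ideation
(MDDSI vs MDDNSI); the SB contrast merges the two non-behavior patient
groups (MDDNSB = MDDNSI u MDDSI) against MDDSB. Healthy controls enter
the controllability group comparison but not the circuit contrasts. The
regional trait for module-trait analysis is, per region, the summed |t| of
significant differential edges incident to it (zero elsewhere), restricted
to the modelled left hemisphere — the first half of the parcellation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ctrlcircuit import nbs as nbs_mod
from ctrlcircuit import stats as stats_mod
from ctrlcircuit import wgcna
from ctrlcircuit.controllability import cohort_controllability, compare_anc
from ctrlcircuit.enrichment import ewce_bootstrap, ora, specificity
from ctrlcircuit.io import COVARIATE_COLUMNS, SCALE_COLUMNS, GeneSetCollection
from ctrlcircuit.synthetic import (
    CellTypeSpec,
    CohortSpec,
    ExpressionSpec,
    generate_celltype_reference,
    generate_connectome_cohort,
    generate_expression_atlas,
    generate_validation_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]

_STAGES = ("cohort", "expression", "celltype", "validation", "nbs", "ewce")


@dataclass
class NbsSettings:
    primary_p: float = 0.001
    n_perm: int = 5000


@dataclass
class WgcnaSettings:
    min_module_size: int = 100
    target_r2: float = 0.85
    mm_threshold: float = 0.8
    gs_threshold: float = 0.5
    merge_eigengene_dissim: float = 0.25


@dataclass
class EnrichmentSettings:
    p_threshold: float = 0.01
    min_overlap: int = 3
    min_enrichment: float = 1.0
    n_boot: int = 10000
    top_n: int = 5


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; see the demo config for typical values."""

    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 20, "MDDNSI": 20, "MDDSI": 20, "MDDSB": 20}
    )
    n_regions: int = 90
    planted_edges: list[tuple[int, int]] = field(default_factory=list)
    edge_effect: float = 0.0
    affected_group: str = "MDDSI"
    noise_sd: float = 0.1
    n_genes: int = 800
    modules: list[tuple[int, float, float]] = field(default_factory=list)
    cell_types: list[str] = field(
        default_factory=lambda: ["GABA", "Glut", "Astro", "Oligo", "Micro", "Endo"]
    )
    enriched_module: int | None = None
    enrichment_fold: float = 1.0
    n_validation_per_group: int = 30
    validation_effect: float = 0.0
    nbs: NbsSettings = field(default_factory=NbsSettings)
    wgcna: WgcnaSettings = field(default_factory=WgcnaSettings)
    enrichment: EnrichmentSettings = field(default_factory=EnrichmentSettings)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 100 + _STAGES.index(stage)) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("nbs", NbsSettings), ("wgcna", WgcnaSettings),
                         ("enrichment", EnrichmentSettings)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "planted_edges" in raw:
            raw["planted_edges"] = [tuple(e) for e in raw["planted_edges"]]
        if "modules" in raw:
            raw["modules"] = [tuple(m) for m in raw["modules"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _patient_subset(networks, phenotypes, groups_a, groups_b):
    by_id = {n.subject_id: n for n in networks}
    sel = phenotypes[phenotypes["group"].isin(groups_a + groups_b)]
    nets = [by_id[s] for s in sel["subject_id"]]
    labels = np.where(sel["group"].isin(groups_a), "a", "b")
    return nets, labels, sel


def _nbs_trait(result: nbs_mod.NBSResult, n_regions: int, left_regions: int) -> np.ndarray:
    """Per-region summed |t| over significant-component edges incident to it."""
    trait = np.zeros(n_regions)
    for comp in result.significant:
        for i, j in comp.edges:
            t = abs(result.tstats[i, j])
            trait[i] += t
            trait[j] += t
    return trait[:left_regions]


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write ``report.json`` and ``summary.txt``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_seed": config.seed}

    # --- simulate ---------------------------------------------------------
    cohort = generate_connectome_cohort(
        CohortSpec(
            n_per_group=config.n_per_group,
            n_regions=config.n_regions,
            planted_edges=config.planted_edges,
            edge_effect=config.edge_effect,
            affected_group=config.affected_group,
            noise_sd=config.noise_sd,
            seed=config.stage_seed("cohort"),
        )
    )
    cohort.save(out / "cohort")
    report["n_subjects"] = len(cohort.networks)

    # --- controllability --------------------------------------------------
    anc = cohort_controllability(cohort.networks)
    anc.to_csv(out / "anc.csv")
    anc_stats = compare_anc(anc, cohort.phenotypes)
    anc_stats.drop(columns=["significant"]).to_csv(out / "anc_group_stats.csv")
    report["anc"] = {
        "mean": float(anc.to_numpy().mean()),
        "n_regions_significant": int(anc_stats["significant"].sum()),
    }

    # --- NBS: SI and SB circuit contrasts ---------------------------------
    nbs_results = {}
    for name, ga, gb in (
        ("SI", ["MDDNSI"], ["MDDSI"]),
        ("SB", ["MDDNSI", "MDDSI"], ["MDDSB"]),
    ):
        nets, labels, _ = _patient_subset(cohort.networks, cohort.phenotypes, ga, gb)
        res = nbs_mod.permutation_fwer(
            nets, labels,
            primary_p=config.nbs.primary_p,
            n_perm=config.nbs.n_perm,
            seed=config.stage_seed("nbs") + (0 if name == "SI" else 1),
        )
        nbs_results[name] = res
        report[f"nbs_{name}"] = {
            "n_components": len(res.components),
            "n_significant": len(res.significant),
            "components": [
                {"size": c.size, "fwer_p": c.fwer_p, "nodes": c.nodes,
                 "mean_t": c.mean_t}
                for c in res.components
            ],
        }

    # behavioral partial correlations of significant SI/SB component strength
    for name, res in nbs_results.items():
        if not res.significant:
            continue
        comp = res.significant[0]
        pheno = cohort.phenotypes
        strengths = [
            nbs_mod.component_mean_strength(n, comp) for n in cohort.networks
        ]
        behav = nbs_mod.behavior_partial_correlation(
            strengths,
            pheno[list(SCALE_COLUMNS)],
            pheno[list(COVARIATE_COLUMNS)].assign(
                sex=(pheno["sex"] == "F").astype(float)
            ),
        )
        behav.to_csv(out / f"behavior_{name}.csv")
        report[f"behavior_{name}"] = {
            "n_significant_scales": int((behav["p_bonferroni"] < 0.05).sum())
        }

    # --- regional trait (left hemisphere = first half of parcellation) ----
    left = config.n_regions // 2
    trait_vec = _nbs_trait(nbs_results["SI"], config.n_regions, left)
    trait_source = "nbs_si_component"
    if np.ptp(trait_vec) == 0:
        trait_vec = "generate"  # null run: no differential circuit exists
        trait_source = "generated"
    report["trait_source"] = trait_source

    # --- expression atlas with planted modules ----------------------------
    atlas = generate_expression_atlas(
        ExpressionSpec(
            n_genes=config.n_genes,
            n_regions=left,
            modules=config.modules,
            trait=trait_vec,
            seed=config.stage_seed("expression"),
        )
    )
    atlas.save(out / "expression")

    # --- coexpression modules ---------------------------------------------
    beta, power_table = wgcna.select_soft_power(
        atlas.expr, target_r2=config.wgcna.target_r2
    )
    power_table.to_csv(out / "soft_power.csv", index=False)
    adj = wgcna.adjacency(atlas.expr, beta)
    dissim = 1.0 - np.asarray(wgcna.tom(adj))
    modules = wgcna.detect_modules(
        atlas.expr, dissim,
        min_module_size=config.wgcna.min_module_size,
        merge_eigengene_dissim=config.wgcna.merge_eigengene_dissim,
    )
    modules.labels.to_frame("module").to_csv(out / "module_labels.tsv", sep="\t")
    report["wgcna"] = {
        "soft_power": int(beta),
        "n_modules": len(modules.module_colors),
        "module_sizes": {c: int(n) for c, n in modules.sizes.items()},
    }

    # --- module-trait association and hub screen --------------------------
    hub_list: list[str] = []
    trait_series = atlas.trait
    if modules.module_colors and trait_series.std() > 0:
        mt = wgcna.module_trait(modules.eigengenes, trait_series)
        mt.to_csv(out / "module_trait.csv", index=False)
        sig = mt[mt["p_adj"] < 0.05]
        report["module_trait"] = {
            "n_significant": int(len(sig)),
            "rows": mt.to_dict("records"),
        }
        hubs = wgcna.hub_genes(
            atlas.expr, modules, trait_series,
            mm_threshold=config.wgcna.mm_threshold,
            gs_threshold=config.wgcna.gs_threshold,
        )
        hubs.to_csv(out / "hub_genes.tsv", sep="\t")
        sig_modules = set(sig["module"])
        hub_list = list(hubs.index[hubs["hub"] & hubs["module"].isin(sig_modules)])
        report["n_hub_genes"] = len(hub_list)
    else:
        report["module_trait"] = {"n_significant": 0, "rows": []}
        report["n_hub_genes"] = 0

    # --- pathway over-representation --------------------------------------
    gene_sets = _synthetic_gene_sets(atlas, config)
    if hub_list:
        ora_table = ora(
            hub_list, gene_sets, universe=list(atlas.expr.index),
            p_threshold=config.enrichment.p_threshold,
            min_overlap=config.enrichment.min_overlap,
            min_enrichment=config.enrichment.min_enrichment,
            top_n=config.enrichment.top_n,
        )
        ora_table.to_csv(out / "ora.csv", index=False)
        report["ora"] = {"n_selected": int(ora_table["selected"].sum())
                         if not ora_table.empty else 0}
    else:
        report["ora"] = {"n_selected": 0}

    # --- cell-type enrichment ---------------------------------------------
    ref, ct_truth = generate_celltype_reference(
        atlas.module_labels,
        CellTypeSpec(
            cell_type_names=config.cell_types,
            enriched_module=config.enriched_module,
            enrichment_fold=config.enrichment_fold,
            target_cell_type=config.cell_types[0],
            seed=config.stage_seed("celltype"),
        ),
    )
    target = hub_list if hub_list else []
    if target:
        spec_matrix = specificity(ref)
        ew = ewce_bootstrap(
            target, spec_matrix,
            n_boot=config.enrichment.n_boot,
            seed=config.stage_seed("ewce"),
        )
        ew.table.to_csv(out / "ewce.csv")
        enriched = ew.table.index[ew.table["p_adj"] < 0.05]
        report["ewce"] = {
            "n_enriched_cell_types": int(len(enriched)),
            "enriched": list(enriched),
        }
    else:
        report["ewce"] = {"n_enriched_cell_types": 0, "enriched": []}

    # --- validation dataset: DEG overlap + ROC ----------------------------
    module_genes = [g for g, m in atlas.module_labels.items() if m == 0]
    de_genes = module_genes[: max(1, len(module_genes) // 3)] if (
        config.validation_effect > 0 and module_genes
    ) else []
    val = generate_validation_dataset(
        list(atlas.expr.index),
        config.n_validation_per_group,
        de_genes,
        [config.validation_effect] * len(de_genes),
        seed=config.stage_seed("validation"),
    )
    if hub_list:
        overlap = stats_mod.deg_overlap(hub_list, val.data)
        report["validation"] = {
            "n_degs": len(overlap["degs"]),
            "n_overlap": len(overlap["overlap"]),
            "overlap_genes": sorted(overlap["overlap"])[:20],
        }
        if overlap["overlap"]:
            best = min(overlap["overlap"], key=lambda g: overlap["p_values"][g])
            roc = stats_mod.roc_auc(
                val.data[best], val.data["group"], positive_label="case", name=best
            )
            report["validation"]["top_gene"] = best
            report["validation"]["top_gene_auc"] = roc.auc
    else:
        report["validation"] = {"n_degs": 0, "n_overlap": 0, "overlap_genes": []}

    # --- report ------------------------------------------------------------
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    _write_summary(report, out / "summary.txt")
    return report


def _synthetic_gene_sets(atlas, config: PipelineConfig) -> GeneSetCollection:
    """Gene sets for ORA: one per planted module plus size-matched random sets."""
    rng = np.random.default_rng(config.stage_seed("expression") + 7)
    sets, desc = {}, {}
    genes = list(atlas.expr.index)
    for m, _spec in enumerate(config.modules):
        members = [g for g, lab in atlas.module_labels.items() if lab == m]
        if members:
            sets[f"planted_module_{m}"] = set(members)
            desc[f"planted_module_{m}"] = "genes of one planted coexpression module"
    for i in range(5):
        size = int(rng.integers(30, 120))
        sets[f"random_set_{i}"] = set(rng.choice(genes, size=size, replace=False))
        desc[f"random_set_{i}"] = "size-matched random gene set"
    return GeneSetCollection(sets=sets, descriptions=desc)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_summary(report: dict, path: Path) -> None:
    lines = [
        f"seed {report['config_seed']}: {report['n_subjects']} subjects",
        f"mean ANC {report['anc']['mean']:.4f}; "
        f"{report['anc']['n_regions_significant']} regions differ across groups",
    ]
    for name in ("SI", "SB"):
        r = report[f"nbs_{name}"]
        lines.append(
            f"NBS {name} contrast: {r['n_significant']} significant component(s) "
            f"of {r['n_components']} found"
        )
    lines.append(
        f"coexpression: {report['wgcna']['n_modules']} modules "
        f"(soft power {report['wgcna']['soft_power']}); "
        f"{report['module_trait']['n_significant']} trait-associated; "
        f"{report['n_hub_genes']} hub genes"
    )
    lines.append(
        f"ORA: {report['ora']['n_selected']} terms pass filters; "
        f"EWCE: {report['ewce']['n_enriched_cell_types']} enriched cell type(s)"
    )
    v = report["validation"]
    lines.append(
        f"validation: {v['n_degs']} DEGs, {v['n_overlap']} overlap hub genes"
        + (f"; top gene {v['top_gene']} AUC {v['top_gene_auc']:.2f}"
           if "top_gene" in v else "")
    )
    path.write_text("\n".join(lines) + "\n")
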