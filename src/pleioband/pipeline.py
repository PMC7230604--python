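"""End-to-end orchestration: catalog -> regions -> clusters -> downstream.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives
the stages in order; each stage's outputs are persisted as TSV in the run
directory together with a JSON report and a manifest (inputs, parameters,
seed), so every reported number is reproducible from the intermediates.
Later stages (enrichment, similarity, variant ranking, expression) run only
when their inputs are configured.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .catalog import (
    TraitQuery,
    UNASSIGNED,
    assign_phenotype_groups,
    filter_significant,
    parse_catalog,
    write_associations,
)
from .enrich import enrich_terms, read_annotations, write_enrichment
from .expression import (
    compare_all,
    rank_mean_expression,
    read_expression,
    write_comparisons,
    write_ranking,
)
from .ontosim import (
    compute_ic,
    pairwise_entity_similarity,
    read_ontology,
    similarity_partner_counts,
    write_similarity_matrix,
)
from .refdata import DIABETES, TRAIT_VOCABULARY
from .regions import (
    band_position_warnings,
    collect_genes,
    extract_snp_clusters,
    regions_per_phenotype,
    select_shared_regions,
    venn_partition,
    write_cluster_table,
    write_shared_region_report,
)
from .variants import (
    count_snps_per_gene,
    median_threshold,
    read_intervals,
    select_candidate_genes,
    write_counts,
)

logger = logging.getLogger("pleioband")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        text = f"[{stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)


@dataclass
class RunConfig:
    """Validated run parameters; mirror of the CLI flags."""

    catalog: str = ""
    phenotypes: dict[str, list[str]] = field(
        default_factory=lambda: {g: list(t) for g, t in TRAIT_VOCABULARY.items()}
    )
    match_mode: str = "exact"
    alpha: float = 0.05
    min_phenotypes: int = 4
    required_group: str | None = DIABETES
    alias_map: dict[str, str] | None = None
    # optional downstream inputs
    annotations: str | None = None
    universe: str | None = None
    enrichment_method: str = "hypergeometric"
    ontology_edges: str | None = None
    ontology_annotations: str | None = None
    similarity_combiner: str = "best-match-average"
    similarity_threshold: float = 0.5
    min_partners: int = 5
    vcfs: dict[str, str] | None = None
    intervals: str | None = None
    exclusion_max: int = 1
    expression_matrix: str | None = None
    expression_groups: str | None = None
    marker_gene: str = "KCNJ11"
    normality_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping at the top level")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def queries(self) -> list[TraitQuery]:
        return [
            TraitQuery(name, tuple(terms), self.match_mode)
            for name, terms in self.phenotypes.items()
        ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the configured stages and return the report dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": []}
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {},
    }

    # --- catalog stage ------------------------------------------------------
    if not config.catalog:
        raise PipelineError("catalog", "no catalog path configured",
                            "set 'catalog' in the config")
    catalog_path = Path(config.catalog)
    if not catalog_path.exists():
        raise PipelineError("catalog", f"catalog file not found: {catalog_path}")
    manifest["inputs"]["catalog"] = {"path": str(catalog_path), "sha256": _sha256(catalog_path)}
    parsed = parse_catalog(catalog_path)
    logger.info("catalog: %d associations parsed, %d rows skipped",
                len(parsed), parsed.n_skipped)
    grouped = assign_phenotype_groups(parsed.associations, config.queries())
    n_assigned = sum(len(v) for k, v in grouped.items() if k != UNASSIGNED)
    if n_assigned == 0:
        raise PipelineError("regions", "no assigned associations",
                            "check the phenotype trait terms against the catalog traits")
    filtered_by_group = {}
    n_missing_p = 0
    for group, assocs in grouped.items():
        if group == UNASSIGNED:
            continue
        res = filter_significant(assocs, config.alpha)
        filtered_by_group[group] = res.associations
        n_missing_p += res.n_missing_p
    all_filtered = [a for assocs in filtered_by_group.values() for a in assocs]
    report["stages"].append("catalog")
    report["catalog"] = {
        "n_parsed": len(parsed),
        "n_skipped": parsed.n_skipped,
        "n_assigned": n_assigned,
        "n_unassigned": len(grouped[UNASSIGNED]),
        "n_missing_p": n_missing_p,
        "alpha": config.alpha,
    }

    # --- region intersection ------------------------------------------------
    region_sets = regions_per_phenotype(filtered_by_group)
    partition = venn_partition(region_sets)
    shared = select_shared_regions(partition, config.min_phenotypes, config.required_group)
    clusters = extract_snp_clusters(shared, all_filtered)
    genes = collect_genes(clusters, config.alias_map)
    n_snps = len({snp for cl in clusters for snp in cl.snps})
    warnings = band_position_warnings(all_filtered)
    logger.info("regions: %d shared regions, %d SNPs, %d genes (min_phenotypes=%d)",
                len(shared), n_snps, len(genes), config.min_phenotypes)
    write_shared_region_report(partition, clusters, outdir / "shared_regions.tsv")
    write_cluster_table(clusters, outdir / "snp_clusters.tsv")
    (outdir / "genes.txt").write_text("".join(f"{g}\n" for g in genes))
    write_associations(all_filtered, outdir / "associations_filtered.tsv")
    report["stages"].append("regions")
    report["regions"] = {
        "n_regions_per_group": {rs.group_name: len(rs.regions) for rs in region_sets},
        "n_cells": len(partition.cells),
        "n_shared_regions": len(shared),
        "shared_regions": sorted(shared),
        "n_snps": n_snps,
        "n_genes": len(genes),
        "genes": genes,
        "band_position_warnings": warnings,
    }

    # --- enrichment (optional) ----------------------------------------------
    if config.annotations and config.universe:
        universe = {
            line.strip()
            for line in Path(config.universe).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
        annotations = read_annotations(config.annotations)
        query = {snp for cl in clusters for snp in cl.snps} & universe
        results = enrich_terms(query, annotations, universe, config.enrichment_method)
        write_enrichment(results, outdir / "enrichment.tsv")
        n_sig = sum(1 for r in results if r.fdr < 0.05)
        logger.info("enrichment: %d terms tested, %d with FDR<0.05", len(results), n_sig)
        report["stages"].append("enrichment")
        report["enrichment"] = {
            "method": config.enrichment_method,
            "n_terms": len(results),
            "n_fdr_lt_0.05": n_sig,
        }
    else:
        report.setdefault("skipped", []).append("enrichment")

    # --- similarity (optional) ----------------------------------------------
    if config.ontology_edges and config.ontology_annotations:
        dag = read_ontology(config.ontology_edges, config.ontology_annotations)
        ic = compute_ic(dag)
        matrix = pairwise_entity_similarity(dag, ic, combine=config.similarity_combiner)
        counts, qualifying = similarity_partner_counts(
            matrix, config.similarity_threshold, config.min_partners
        )
        write_similarity_matrix(matrix, outdir / "similarity.tsv")
        logger.info("similarity: %d entities, %d with >=%d partners above %.2f",
                    len(matrix.entities), len(qualifying), config.min_partners,
                    config.similarity_threshold)
        report["stages"].append("similarity")
        report["similarity"] = {
            "combiner": config.similarity_combiner,
            "threshold": config.similarity_threshold,
            "min_partners": config.min_partners,
            "n_entities": len(matrix.entities),
            "n_qualifying": len(qualifying),
            "partner_counts": counts,
        }
    else:
        report.setdefault("skipped", []).append("similarity")

    # --- variant ranking (optional) -----------------------------------------
    if config.vcfs and config.intervals:
        intervals = read_intervals(config.intervals)
        counts = count_snps_per_gene(config.vcfs, intervals)
        threshold = median_threshold(counts, config.exclusion_max)
        candidates = select_candidate_genes(counts, threshold)
        write_counts(counts, outdir / "variant_counts.tsv")
        (outdir / "candidate_genes.txt").write_text("".join(f"{g}\n" for g in candidates))
        logger.info("variants: median threshold %.1f, %d candidate genes",
                    threshold, len(candidates))
        report["stages"].append("variants")
        report["variants"] = {
            "median_threshold": threshold,
            "exclusion_max": config.exclusion_max,
            "candidates": candidates,
        }
    else:
        report.setdefault("skipped", []).append("variants")

    # --- expression (optional) ----------------------------------------------
    if config.expression_matrix and config.expression_groups:
        matrix = read_expression(config.expression_matrix, config.expression_groups)
        candidates = report.get("variants", {}).get("candidates")
        genes_to_test = [g for g in (candidates or matrix.genes) if g in matrix.values.index]
        results = compare_all(matrix, genes_to_test, config.normality_alpha)
        ranking = rank_mean_expression(matrix, genes_to_test, config.marker_gene)
        write_comparisons(results, outdir / "expression_comparison.tsv")
        write_ranking(ranking, outdir / "expression_ranking.tsv")
        logger.info("expression: %d genes compared, marker %s",
                    len(results), config.marker_gene)
        report["stages"].append("expression")
        report["expression"] = {
            "n_genes": len(results),
            "marker": config.marker_gene,
            "comparisons": {
                r.gene: {"test": r.test_used, "p": r.p_value, "direction": r.direction}
                for r in results
            },
            "ranking": [r.gene for r in ranking],
        }
    else:
        report.setdefault("skipped", []).append("expression")

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
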