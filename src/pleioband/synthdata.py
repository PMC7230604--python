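"""Synthetic inputs and bundled fixtures for every pipeline stage.

Two kinds of generator live here:

* ``fixture_*`` functions materialize the bundled UAEDIAB reference tables
  (:mod:`pleioband.refdata`) into the exact file dialects the pipeline
  consumes — a miniature association catalog realizing the published
  region-phenotype memberships, and the two-patient SNV count table.
* ``simulate_*`` functions draw parameterized random inputs with a planted
  ground truth (region memberships, term ICs and entity similarities,
  per-gene SNV counts, expression group shifts) so each stage can be tested
  against an independent oracle.

Every generator is deterministic given its seed, and every emitted file
carries a generator-version + seed comment header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import DEFAULT_DIALECT, TraitQuery
from .expression import ExpressionMatrix
from .refdata import (
    PATIENT_GENE_SNV_COUNTS,
    REGION_CELLS,
    SHARED_REGION_SNPS,
    SHARED_REGIONS,
    TRAIT_VOCABULARY,
    region_memberships,
)
from .variants import GeneInterval

_BASES = "ACGT"


def _header_comment(seed: int | None) -> str:
    return f"# pleioband-synthdata v{__version__} seed={seed}"


@dataclass
class SimConfig:
    """Knobs for the random generators; defaults mirror the study conditions
    (two sequenced patients, 63 nondiabetic vs 12 diabetic islet donors)."""

    seed: int = 0
    # catalog simulation
    n_decoy_associations: int = 10
    n_phenotypes: int = 5
    planted_regions_per_k: Mapping[int, int] = field(
        default_factory=lambda: {1: 4, 2: 3, 3: 2, 4: 3, 5: 1}
    )
    # ontology simulation
    n_terms: int = 15
    branching: int = 2
    annotation_rate: float = 0.25
    n_entities: int = 8
    # vcf simulation
    planted_counts: Mapping[str, Mapping[str, int]] | None = None  # None -> patient table
    interval_length: int = 5000
    n_decoy_snvs: int = 3
    n_decoy_indels: int = 2
    n_decoy_filtered: int = 2
    # expression simulation
    n_nd: int = 63
    n_t2d: int = 12
    n_background_genes: int = 20
    planted_log2_effects: Mapping[str, float] | None = None  # None -> HSD17B12 down
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "n_decoy_associations", "n_phenotypes", "n_terms", "n_entities",
            "interval_length", "n_decoy_snvs", "n_decoy_indels",
            "n_decoy_filtered", "n_nd", "n_t2d", "n_background_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# --------------------------------------------------------------------------
# fixture catalog (bundled reference tables)
# --------------------------------------------------------------------------

_DECOY_TRAITS = ("Height", "Eye color", "Hair color", "Freckles", "Handedness")
_DECOY_BANDS = ("21q21.1", "20p11.21", "19p12", "18q23", "Xp22.31", "4q13.2",
                "5p15.33", "10q11.22", "22q11.21", "2q37.3")


def _band_chromosome(band: str) -> str:
    for i, ch in enumerate(band):
        if ch in "pq":
            return band[:i]
    return band


def fixture_catalog(n_decoys: int = 0, seed: int = 0) -> pd.DataFrame:
    """Mini association catalog realizing the bundled reference tables.

    Emits (a) the 46 shared-region SNP rows with trait strings covering each
    region's full phenotype combination; (b) one association per
    region-phenotype membership for every other region, so the published
    Venn partition is reconstructable; (c) ``n_decoys`` rows in regions
    outside the reference table whose traits match no phenotype group.

    Regions whose phenotype combination is larger than their SNP count get
    extra rows reusing an existing rsID with a different trait (one row per
    SNP-trait association, as in the real catalog), so the distinct-SNP
    count is preserved.
    """
    rng = np.random.default_rng(seed)
    memberships = region_memberships()
    rows: list[dict[str, str]] = []

    def add_row(snp, mapped, band, chrom, pos, reported, trait, p):
        rows.append(
            {
                DEFAULT_DIALECT["snp"]: snp,
                DEFAULT_DIALECT["region"]: band,
                DEFAULT_DIALECT["chromosome"]: chrom,
                DEFAULT_DIALECT["position"]: str(pos) if pos is not None else "",
                DEFAULT_DIALECT["mapped_gene"]: mapped,
                DEFAULT_DIALECT["reported_gene"]: reported,
                DEFAULT_DIALECT["trait"]: trait,
                DEFAULT_DIALECT["p_value"]: p,
            }
        )

    # (a) shared-region SNP rows
    by_region: dict[str, list[tuple[str, str, str, str, str]]] = {}
    for rec in SHARED_REGION_SNPS:
        by_region.setdefault(rec[2], []).append(rec)
    for region in SHARED_REGIONS:
        phens = sorted(memberships[region])
        recs = by_region[region]
        for i, (snp, mapped, band, loc, reported) in enumerate(recs):
            phen = phens[i % len(phens)]
            term = TRAIT_VOCABULARY[phen][i % len(TRAIT_VOCABULARY[phen])]
            chrom, pos = loc.split(":")
            add_row(snp, mapped, band, chrom, int(pos), reported, term, "2e-8")
        # phenotypes not yet covered in this region: extra SNP-trait rows
        covered = {phens[i % len(phens)] for i in range(len(recs))}
        for j, phen in enumerate(p for p in phens if p not in covered):
            snp, mapped, band, loc, reported = recs[j % len(recs)]
            chrom, pos = loc.split(":")
            add_row(snp, mapped, band, chrom, int(pos), reported,
                    TRAIT_VOCABULARY[phen][0], "3e-8")

    # (b) one association per remaining region-phenotype membership
    counter = 0
    for region in sorted(memberships, key=str):
        if region in SHARED_REGIONS:
            continue
        chrom = _band_chromosome(region)
        for k, phen in enumerate(sorted(memberships[region])):
            counter += 1
            term = TRAIT_VOCABULARY[phen][counter % len(TRAIT_VOCABULARY[phen])]
            add_row(
                f"rs99{counter:06d}", f"GENE{counter:04d}", region, chrom,
                1_000_000 + counter * 1_000, f"GENE{counter:04d}", term, "1e-9",
            )

    # (c) decoys: regions outside the reference table, non-matching traits,
    # and a mix of significant / non-significant / missing p-values
    for d in range(n_decoys):
        band = _DECOY_BANDS[d % len(_DECOY_BANDS)]
        trait = _DECOY_TRAITS[d % len(_DECOY_TRAITS)]
        p = ("4e-8", "0.5", "")[d % 3]
        pos = int(rng.integers(1_000_000, 9_000_000))
        add_row(f"rs88{d:06d}", f"DECOY{d:03d}", band, _band_chromosome(band),
                pos, f"DECOY{d:03d}", trait, p)

    return pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values()))


def write_catalog(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a catalog table with the generator-version + seed header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def fixture_queries() -> list[TraitQuery]:
    """Exact-match trait queries for the five phenotype groups."""
    return [TraitQuery(g, terms) for g, terms in TRAIT_VOCABULARY.items()]


def fixture_patient_counts() -> dict[str, dict[str, int]]:
    """The bundled two-patient per-gene SNV count table."""
    return {s: dict(g) for s, g in PATIENT_GENE_SNV_COUNTS.items()}


# --------------------------------------------------------------------------
# simulated catalog with planted region memberships
# --------------------------------------------------------------------------

def simulate_catalog(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, frozenset[str]], list[TraitQuery]]:
    """Catalog with a known number of regions shared by exactly k phenotypes.

    Returns the catalog table, the truth map region -> phenotype set, and
    exact-match queries for the synthetic phenotype names.
    """
    rng = np.random.default_rng(config.seed)
    phenotypes = [f"phen{i + 1}" for i in range(config.n_phenotypes)]
    queries = [TraitQuery(p, (f"{p} trait",)) for p in phenotypes]
    truth: dict[str, frozenset[str]] = {}
    rows = []
    counter = 0
    for k, n_regions in sorted(config.planted_regions_per_k.items()):
        if k > config.n_phenotypes:
            raise ValueError(f"cannot share a region among {k} of {config.n_phenotypes} phenotypes")
        for _ in range(n_regions):
            counter += 1
            chrom = str(1 + counter % 22)
            band = f"{chrom}q{10 + counter}.{k}"
            chosen = sorted(rng.choice(phenotypes, size=k, replace=False))
            truth[band] = frozenset(chosen)
            for phen in chosen:
                counter += 1
                rows.append(
                    {
                        DEFAULT_DIALECT["snp"]: f"rs77{counter:06d}",
                        DEFAULT_DIALECT["region"]: band,
                        DEFAULT_DIALECT["chromosome"]: chrom,
                        DEFAULT_DIALECT["position"]: str(500_000 + counter * 750),
                        DEFAULT_DIALECT["mapped_gene"]: f"SIMG{counter:04d}",
                        DEFAULT_DIALECT["reported_gene"]: f"SIMG{counter:04d}",
                        DEFAULT_DIALECT["trait"]: f"{phen} trait",
                        DEFAULT_DIALECT["p_value"]: "5e-9",
                    }
                )
    for d in range(config.n_decoy_associations):
        counter += 1
        rows.append(
            {
                DEFAULT_DIALECT["snp"]: f"rs66{counter:06d}",
                DEFAULT_DIALECT["region"]: _DECOY_BANDS[d % len(_DECOY_BANDS)],
                DEFAULT_DIALECT["chromosome"]: _band_chromosome(_DECOY_BANDS[d % len(_DECOY_BANDS)]),
                DEFAULT_DIALECT["position"]: str(200_000 + counter * 310),
                DEFAULT_DIALECT["mapped_gene"]: f"DEC{counter:04d}",
                DEFAULT_DIALECT["reported_gene"]: f"DEC{counter:04d}",
                DEFAULT_DIALECT["trait"]: _DECOY_TRAITS[d % len(_DECOY_TRAITS)],
                DEFAULT_DIALECT["p_value"]: "1e-8",
            }
        )
    df = pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values()))
    return df, truth, queries


# --------------------------------------------------------------------------
# simulated ontology with enumeration-based truth
# --------------------------------------------------------------------------

def _closure(term: str, parents: Mapping[str, tuple[str, ...]]) -> set[str]:
    """Ancestor closure (term included) by plain recursion — oracle path."""
    out = {term}
    for p in parents.get(term, ()):
        out |= _closure(p, parents)
    return out


def _oracle_entity_sim(
    prof1: Sequence[str],
    prof2: Sequence[str],
    parents: Mapping[str, tuple[str, ...]],
    ic: Mapping[str, float],
    combine: str,
) -> float:
    """Straightforward enumeration of the best-match combiners."""
    def tsim(a: str, b: str) -> float:
        common = _closure(a, parents) & _closure(b, parents)
        mica = max((ic[c] for c in common if math.isfinite(ic[c])), default=0.0)
        if not (math.isfinite(ic[a]) and math.isfinite(ic[b])):
            return 0.0
        denom = ic[a] + ic[b]
        return 2.0 * mica / denom if denom > 0 else 0.0

    best = []
    for a in prof1:
        best.append(max(tsim(a, b) for b in prof2))
    for b in prof2:
        best.append(max(tsim(a, b) for a in prof1))
    if combine == "maximum":
        return max(max(tsim(a, b) for b in prof2) for a in prof1)
    if combine == "complete":
        return min(best)
    return sum(best) / len(best)


def simulate_ontology(
    config: SimConfig,
) -> tuple[
    list[tuple[str, str]],
    dict[str, frozenset[str]],
    dict[str, float],
    dict[tuple[str, str, str], float],
]:
    """Random rooted DAG + annotations + brute-force truth.

    Returns (edges, annotations, truth_ic, truth_sims) where truth values
    come from an independent closure-enumeration oracle, not from
    :mod:`pleioband.ontosim`.
    """
    if config.n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = np.random.default_rng(config.seed)
    terms = [f"T{i:03d}" for i in range(config.n_terms)]
    parents: dict[str, tuple[str, ...]] = {terms[0]: ()}
    edges: list[tuple[str, str]] = []
    for i in range(1, config.n_terms):
        n_par = int(rng.integers(1, max(2, config.branching + 1)))
        pool = terms[:i]
        chosen = rng.choice(pool, size=min(n_par, len(pool)), replace=False)
        parents[terms[i]] = tuple(sorted(chosen))
        for p in parents[terms[i]]:
            edges.append((terms[i], p))

    entities = [f"E{i:02d}" for i in range(config.n_entities)]
    annotations: dict[str, frozenset[str]] = {}
    non_root = terms[1:]
    for e in entities:
        mask = rng.random(len(non_root)) < config.annotation_rate
        chosen = [t for t, m in zip(non_root, mask) if m]
        if not chosen:
            chosen = [non_root[int(rng.integers(len(non_root)))]]
        annotations[e] = frozenset(chosen)

    # enumeration truth: propagated counts -> IC -> pairwise similarities
    closures = {e: set().union(*(_closure(t, parents) for t in ts))
                for e, ts in annotations.items()}
    total = len(entities)
    truth_ic: dict[str, float] = {}
    for t in terms:
        count = sum(1 for e in entities if t in closures[e])
        truth_ic[t] = -math.log10(count / total) if count else math.inf

    truth_sims: dict[tuple[str, str, str], float] = {}
    for combine in ("best-match-average", "maximum", "complete"):
        for i, e1 in enumerate(entities):
            for e2 in entities[i:]:
                truth_sims[(e1, e2, combine)] = _oracle_entity_sim(
                    sorted(annotations[e1]), sorted(annotations[e2]),
                    parents, truth_ic, combine,
                )
    return edges, annotations, truth_ic, truth_sims


def write_ontology(
    edges: Sequence[tuple[str, str]],
    annotations: Mapping[str, frozenset[str]],
    edges_path: str | Path,
    annotations_path: str | Path,
    seed: int | None = None,
) -> None:
    with open(edges_path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("child\tparent\n")
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")
    with open(annotations_path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("entity\tterm\n")
        for entity in sorted(annotations):
            for term in sorted(annotations[entity]):
                fh.write(f"{entity}\t{term}\n")


# --------------------------------------------------------------------------
# simulated VCFs with planted per-gene SNV counts
# --------------------------------------------------------------------------

def simulate_vcf(
    config: SimConfig, outdir: str | Path
) -> tuple[dict[str, Path], list[GeneInterval], dict[str, dict[str, int]]]:
    """Write per-sample VCF 4.2 files with planted SNVs inside gene intervals.

    Decoy indels (inside intervals), decoy SNVs (outside any interval) and
    filter-failing SNVs are planted too; none of them should be counted
    under the default SNV-only / PASS-only rules. Returns (vcf paths,
    intervals, truth counts).
    """
    rng = np.random.default_rng(config.seed)
    planted = config.planted_counts or PATIENT_GENE_SNV_COUNTS
    planted = {s: dict(g) for s, g in planted.items()}
    genes = sorted({g for per_gene in planted.values() for g in per_gene})

    intervals: list[GeneInterval] = []
    for i, gene in enumerate(genes):
        chrom = str(1 + i % 22)
        start = 1_000_000 + (i // 22) * 10 * config.interval_length + 1
        intervals.append(GeneInterval(gene, chrom, start, start + config.interval_length - 1))
    iv_by_gene = {iv.gene: iv for iv in intervals}

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = sorted({iv.chromosome for iv in intervals}, key=lambda c: int(c))

    paths: dict[str, Path] = {}
    for sample, per_gene in planted.items():
        records: list[tuple[str, int, str, str, str]] = []
        for gene in genes:
            iv = iv_by_gene[gene]
            count = per_gene.get(gene, 0)
            if count > config.interval_length:
                raise ValueError(f"{gene}: planted count exceeds interval length")
            step = max(1, config.interval_length // (count + 1))
            for k in range(count):
                pos = iv.start + k * step  # first SNV exactly at the interval start
                ref, alt = rng.choice(list(_BASES), size=2, replace=False)
                records.append((iv.chromosome, pos, ref, alt, "PASS"))
        for d in range(config.n_decoy_indels):
            iv = intervals[d % len(intervals)]
            pos = iv.start + config.interval_length // 2 + 7 * d + 1
            records.append((iv.chromosome, pos, "AT", "A", "PASS"))
        max_end = {c: max(iv.end for iv in intervals if iv.chromosome == c) for c in chroms}
        for d in range(config.n_decoy_snvs):
            iv = intervals[d % len(intervals)]
            pos = max_end[iv.chromosome] + 10_000 + d  # beyond every interval on the chromosome
            records.append((iv.chromosome, pos, "G", "C", "PASS"))
        for d in range(config.n_decoy_filtered):
            iv = intervals[d % len(intervals)]
            pos = iv.start + config.interval_length // 3 + 11 * d + 1
            records.append((iv.chromosome, pos, "C", "T", "q10"))
        records.sort(key=lambda r: (int(r[0]), r[1]))

        safe = sample.replace(" ", "_")
        path = outdir / f"{safe}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=pleioband-synthdata v{__version__} seed={config.seed}\n")
            fh.write('##FILTER=<ID=q10,Description="Low quality">\n')
            for chrom in chroms:
                fh.write(f"##contig=<ID={chrom},length=250000000>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom, pos, ref, alt, filt in records:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t.\n")
        paths[sample] = path

    return paths, intervals, planted


def write_intervals(
    intervals: Sequence[GeneInterval], path: str | Path, seed: int | None = None
) -> None:
    """1-based inclusive interval TSV."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("gene\tchromosome\tstart\tend\n")
        for iv in intervals:
            fh.write(f"{iv.gene}\t{iv.chromosome}\t{iv.start}\t{iv.end}\n")


# --------------------------------------------------------------------------
# simulated islet expression matrix
# --------------------------------------------------------------------------

#: Planted base log2-FPKM means for the candidate genes and the beta-cell
#: marker, ordered high (ASAH1, HSD17B12) over the marker over low (FES, LRP4).
DEFAULT_BASE_MEANS: dict[str, float] = {
    "ASAH1": 8.5,
    "HSD17B12": 8.0,
    "KCNJ11": 6.0,
    "FES": 4.0,
    "LRP4": 3.5,
}


def simulate_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Log-normal FPKM matrix with planted group shifts.

    Default shape mirrors the islet cohort (63 nondiabetic vs 12 diabetic
    donors). The default planted effect moves HSD17B12 down by one log2 unit
    in the T2D group; all other genes are null. Returns the matrix and the
    truth map gene -> planted log2 effect (T2D minus ND).
    """
    if config.n_nd < 2 or config.n_t2d < 2:
        raise ValueError("both groups need at least 2 samples")
    rng = np.random.default_rng(config.seed)
    effects = dict(config.planted_log2_effects or {"HSD17B12": -1.0})
    base = dict(DEFAULT_BASE_MEANS)
    for i in range(config.n_background_genes):
        base[f"BG{i:03d}"] = float(rng.uniform(2.0, 7.0))
    for gene in effects:
        if gene not in base:
            base[gene] = float(rng.uniform(3.0, 8.0))

    samples = [f"ND{i + 1:02d}" for i in range(config.n_nd)] + [
        f"T2D{i + 1:02d}" for i in range(config.n_t2d)
    ]
    group = {s: ("ND" if s.startswith("ND") else "T2D") for s in samples}
    genes = sorted(base)
    log2 = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        shift = effects.get(gene, 0.0)
        mus = [base[gene] + (shift if group[s] == "T2D" else 0.0) for s in samples]
        log2[gi] = np.asarray(mus) + rng.normal(0.0, config.noise_sd, size=len(samples))
    values = pd.DataFrame(2.0 ** log2, index=pd.Index(genes, name="gene"), columns=samples)
    truth = {g: effects.get(g, 0.0) for g in genes}
    return ExpressionMatrix(values=values, group=group), truth


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    groups_path: str | Path,
    seed: int | None = None,
) -> None:
    with open(matrix_path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        matrix.values.to_csv(fh, sep="\t")
    with open(groups_path, "w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("sample\tgroup\n")
        for s in matrix.samples:
            fh.write(f"{s}\t{matrix.group[s]}\n")
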