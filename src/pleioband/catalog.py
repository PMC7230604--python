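"""GWAS-catalog association parsing and phenotype-group assignment.

Reads NHGRI-EBI-style association download tables (TSV, one header row),
normalizes each row into :class:`CatalogAssociation` records (splitting
multi-SNP rows), assigns associations to configured phenotype groups by
trait string, and applies the significance filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .refdata import PHENOTYPE_GROUPS, TRAIT_VOCABULARY

#: Reserved key under which non-matching associations are returned.
UNASSIGNED = "unassigned"

#: Default column-name map following the NHGRI-EBI association download.
DEFAULT_DIALECT: dict[str, str] = {
    "snp": "SNPS",
    "region": "REGION",
    "chromosome": "CHR_ID",
    "position": "CHR_POS",
    "mapped_gene": "MAPPED_GENE",
    "reported_gene": "REPORTED GENE(S)",
    "trait": "DISEASE/TRAIT",
    "p_value": "P-VALUE",
}

_RSID_RE = re.compile(r"^rs\d+$")
_NOT_REPORTED_RE = re.compile(r"^not\s+reported$", re.IGNORECASE)
# Multi-SNP field separators: ";", ",", and the " x " haplotype notation.
_SNP_SPLIT_RE = re.compile(r";|,|\s+x\s+")


@dataclass(frozen=True)
class TraitQuery:
    """A phenotype group defined by a list of trait strings."""

    group_name: str
    trait_terms: tuple[str, ...]
    match_mode: str = "exact"  # "exact" (case-insensitive) or "substring"

    def __post_init__(self) -> None:
        if not self.group_name:
            raise ValueError("group_name must be nonempty")
        if not self.trait_terms:
            raise ValueError(f"group {self.group_name!r}: trait_terms must be nonempty")
        norm = [_norm_trait(t) for t in self.trait_terms]
        if len(set(norm)) != len(norm):
            raise ValueError(f"group {self.group_name!r}: duplicate trait terms")
        if self.match_mode not in ("exact", "substring"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    def matches(self, trait: str) -> bool:
        t = _norm_trait(trait)
        if self.match_mode == "exact":
            return any(t == _norm_trait(term) for term in self.trait_terms)
        return any(_norm_trait(term) in t for term in self.trait_terms)


@dataclass(frozen=True)
class CatalogAssociation:
    """One SNP-trait association (one SNP per record after row splitting)."""

    snp_id: str
    chromosome: str
    position: int | None
    cytoband: str
    mapped_genes: tuple[str, ...]
    reported_genes: tuple[str, ...]  # sentinel "Not Reported" already removed
    trait: str
    p_value: float | None
    source_row: int

    @property
    def has_standard_id(self) -> bool:
        return bool(_RSID_RE.match(self.snp_id))


@dataclass
class ParseResult:
    associations: list[CatalogAssociation]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.associations)

    def __len__(self) -> int:
        return len(self.associations)


@dataclass
class FilterResult:
    associations: list[CatalogAssociation]
    n_missing_p: int = 0

    def __iter__(self):
        return iter(self.associations)

    def __len__(self) -> int:
        return len(self.associations)


def _norm_trait(s: str) -> str:
    return " ".join(s.split()).casefold()


def split_gene_cell(cell: str) -> tuple[str, ...]:
    """Split a catalog gene cell on ';' and ','; drop the Not-Reported sentinel."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    out = []
    for token in re.split(r"[;,]", str(cell)):
        token = token.strip()
        if token and not _NOT_REPORTED_RE.match(token):
            out.append(token)
    return tuple(out)


def default_queries() -> list[TraitQuery]:
    """The five UAEDIAB phenotype groups with their verbatim trait terms."""
    return [TraitQuery(g, TRAIT_VOCABULARY[g]) for g in PHENOTYPE_GROUPS]


def parse_catalog(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> ParseResult:
    """Parse an association table into one record per single SNP.

    Rows whose SNP field lists several SNPs are split into one record each,
    duplicating the row's other fields. Rows with an empty SNP or region
    field are skipped and counted in ``n_skipped``.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read catalog file {path}: {exc}") from exc
    missing = [col for col in dialect.values() if col not in df.columns]
    if missing:
        raise ValueError(
            f"catalog {path} is missing required column(s): {', '.join(missing)}"
        )

    records: list[CatalogAssociation] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        snp_field = row[dialect["snp"]].strip()
        cytoband = row[dialect["region"]].strip()
        if not snp_field or not cytoband:
            n_skipped += 1
            continue
        pos_raw = row[dialect["position"]].strip()
        try:
            position = int(pos_raw) if pos_raw else None
        except ValueError:
            position = None
        if position is not None and position <= 0:
            n_skipped += 1
            continue
        p_raw = row[dialect["p_value"]].strip()
        try:
            p_value = float(p_raw) if p_raw else None
        except ValueError:
            p_value = None
        if p_value is not None and not (0.0 <= p_value <= 1.0):
            n_skipped += 1
            continue
        snps = [s.strip() for s in _SNP_SPLIT_RE.split(snp_field) if s.strip()]
        for snp in snps:
            records.append(
                CatalogAssociation(
                    snp_id=snp,
                    chromosome=row[dialect["chromosome"]].strip(),
                    position=position,
                    cytoband=cytoband,
                    mapped_genes=split_gene_cell(row[dialect["mapped_gene"]]),
                    reported_genes=split_gene_cell(row[dialect["reported_gene"]]),
                    trait=row[dialect["trait"]].strip(),
                    p_value=p_value,
                    source_row=i,
                )
            )
    return ParseResult(records, n_skipped)


def assign_phenotype_groups(
    associations: Iterable[CatalogAssociation], queries: list[TraitQuery]
) -> dict[str, list[CatalogAssociation]]:
    """Assign each association to every matching phenotype group.

    Associations matching no query land under the reserved ``"unassigned"``
    key. An association may appear under several groups.
    """
    if not queries:
        raise ValueError("queries must be nonempty")
    names = [q.group_name for q in queries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names in queries")
    if UNASSIGNED in names:
        raise ValueError(f"{UNASSIGNED!r} is a reserved group name")
    grouped: dict[str, list[CatalogAssociation]] = {n: [] for n in names}
    grouped[UNASSIGNED] = []
    for assoc in associations:
        hit = False
        for q in queries:
            if q.matches(assoc.trait):
                grouped[q.group_name].append(assoc)
                hit = True
        if not hit:
            grouped[UNASSIGNED].append(assoc)
    return grouped


def filter_significant(
    associations: Iterable[CatalogAssociation], alpha: float = 0.05
) -> FilterResult:
    """Keep associations with reported p-value strictly below ``alpha``.

    Records with a missing p-value are dropped and counted in
    ``n_missing_p`` (a warning tally, not an error).
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    kept: list[CatalogAssociation] = []
    n_missing = 0
    for assoc in associations:
        if assoc.p_value is None:
            n_missing += 1
        elif assoc.p_value < alpha:
            kept.append(assoc)
    return FilterResult(kept, n_missing)


def write_associations(associations: Iterable[CatalogAssociation], path: str | Path) -> None:
    """Write normalized associations as TSV with a fixed column order."""
    rows = [
        {
            "snp_id": a.snp_id,
            "chromosome": a.chromosome,
            "position": a.position if a.position is not None else "",
            "cytoband": a.cytoband,
            "mapped_genes": ";".join(a.mapped_genes),
            "reported_genes": ";".join(a.reported_genes),
            "trait": a.trait,
            "p_value": a.p_value if a.p_value is not None else "",
            "source_row": a.source_row,
        }
        for a in associations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chromosome", "position", "cytoband", "mapped_genes",
            "reported_genes", "trait", "p_value", "source_row",
        ],
    ).to_csv(path, sep="\t", index=False)
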