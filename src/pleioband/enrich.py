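"""Annotation-term over-representation testing for SNP sets.

One-sided enrichment of a query SNP set against annotation term sets within
an explicit background universe, with hypergeometric (default), binomial or
Fisher's-exact p-values, a finite-population z-score, and Benjamini-Hochberg
FDR across all tested terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

METHODS = ("hypergeometric", "binomial", "fisher")


@dataclass(frozen=True)
class AnnotationSet:
    term_id: str
    term_name: str
    annotated: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap_ids: frozenset[str]
    x: int  # overlap count
    n: int  # query size
    K: int  # term size
    N: int  # universe size
    expected: float
    z_score: float
    p_value: float
    fdr: float
    degenerate: bool = False


def _tail_p(x: int, n: int, K: int, N: int, method: str) -> float:
    """Upper-tail P(X >= x) under the chosen null."""
    if method == "hypergeometric":
        return float(stats.hypergeom.sf(x - 1, N, K, n))
    if method == "binomial":
        return float(stats.binom.sf(x - 1, n, K / N))
    if method == "fisher":
        table = [[x, n - x], [K - x, N - K - (n - x)]]
        return float(stats.fisher_exact(table, alternative="greater")[1])
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _z_score(x: int, n: int, K: int, N: int) -> tuple[float, bool]:
    """Finite-population (hypergeometric) z-score; degenerate variance -> 0."""
    expected = n * K / N
    var = expected * (N - K) / N * (N - n) / (N - 1) if N > 1 else 0.0
    if var <= 0.0:
        return 0.0, True
    return (x - expected) / math.sqrt(var), False


def enrich_terms(
    query: Iterable[str],
    annotations: Sequence[AnnotationSet],
    universe: Iterable[str],
    method: str = "hypergeometric",
) -> list[EnrichmentResult]:
    """Test each annotation term for over-representation in the query set.

    Results are sorted by p-value ascending (ties by term id); the FDR
    column is the BH adjustment across all terms tested in this call.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    universe = frozenset(universe)
    query = frozenset(query)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 entities")
    stray = query - universe
    if stray:
        raise ValueError(f"query IDs outside the universe: {sorted(stray)}")
    N, n = len(universe), len(query)

    raw = []
    for ann in annotations:
        stray = ann.annotated - universe
        if stray:
            raise ValueError(
                f"term {ann.term_id}: annotated IDs outside the universe: {sorted(stray)}"
            )
        K = len(ann.annotated)
        overlap = query & ann.annotated
        x = len(overlap)
        z, degenerate = _z_score(x, n, K, N)
        p = 1.0 if degenerate and K in (0, N) else _tail_p(x, n, K, N, method)
        raw.append((ann, overlap, x, K, z, min(p, 1.0), degenerate))

    fdrs = bh_fdr([r[5] for r in raw]) if raw else []
    results = [
        EnrichmentResult(
            term_id=ann.term_id,
            term_name=ann.term_name,
            overlap_ids=frozenset(overlap),
            x=x,
            n=n,
            K=K,
            N=N,
            expected=n * K / N,
            z_score=z,
            p_value=p,
            fdr=fdr,
            degenerate=degenerate,
        )
        for (ann, overlap, x, K, z, p, degenerate), fdr in zip(raw, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def read_annotations(
    path: str | Path, term_names: dict[str, str] | None = None
) -> list[AnnotationSet]:
    """Read a two-column (term_id, entity_id) TSV into annotation sets."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (term_id, entity_id)")
    term_col, ent_col = df.columns[:2]
    out = []
    for term_id, sub in df.groupby(term_col, sort=True):
        out.append(
            AnnotationSet(
                term_id=str(term_id),
                term_name=(term_names or {}).get(str(term_id), str(term_id)),
                annotated=frozenset(sub[ent_col].astype(str)),
            )
        )
    return out


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "n_overlap": r.x,
            "overlap_ids": ";".join(sorted(r.overlap_ids)),
            "n_query": r.n,
            "n_term": r.K,
            "n_universe": r.N,
            "expected": r.expected,
            "z_score": r.z_score,
            "p_value": r.p_value,
            "fdr": r.fdr,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "n_overlap", "overlap_ids", "n_query",
            "n_term", "n_universe", "expected", "z_score", "p_value", "fdr",
        ],
    ).to_csv(path, sep="\t", index=False)
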