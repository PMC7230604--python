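"""Information-content semantic similarity over an annotation ontology DAG.

Entities (SNPs or genes) carry direct term annotations; annotations are
propagated to all ancestors (true-path rule). A term's information content
is IC(t) = -log10(fraction of annotated entities at or below t); term-pair
similarity is Lin-normalized at the most informative common ancestor (MICA),
and entity-pair similarity combines the cross-profile term matrix with a
best-match combiner (average, maximum, or complete). The partner-count
summary reports, per entity, how many other entities score above a
threshold ("socialiser"-style relatedness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

COMBINERS = ("best-match-average", "maximum", "complete")


@dataclass
class OntologyDAG:
    """Rooted is-a DAG with entity->terms direct annotations."""

    terms: frozenset[str]
    edges: tuple[tuple[str, str], ...]  # (child, parent)
    direct_annotations: dict[str, frozenset[str]]

    graph: nx.DiGraph = field(init=False, repr=False)
    root: str = field(init=False)
    _ancestors: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child}, {parent}) references unknown term")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a unique root, found {sorted(roots)}")
        self.root = roots[0]
        # ancestor closure including the term itself (edges point child->parent,
        # so ancestors are graph descendants)
        closure: dict[str, frozenset[str]] = {}
        for term in g.nodes:
            closure[term] = frozenset(nx.descendants(g, term)) | {term}
        for term, anc in closure.items():
            if self.root not in anc:
                raise ValueError(f"term {term} cannot reach the root {self.root}")
        for entity, terms in self.direct_annotations.items():
            unknown = terms - self.terms
            if unknown:
                raise ValueError(f"entity {entity} annotated to unknown terms {sorted(unknown)}")
            if not terms:
                raise ValueError(f"entity {entity} has an empty annotation set")
        self.graph = g
        self._ancestors = closure

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of a term, including the term itself."""
        try:
            return self._ancestors[term]
        except KeyError:
            raise ValueError(f"unknown term {term!r}") from None

    def annotation_closure(self, entity: str) -> frozenset[str]:
        """All terms annotating an entity after true-path propagation."""
        try:
            direct = self.direct_annotations[entity]
        except KeyError:
            raise ValueError(f"entity {entity!r} has no annotations") from None
        out: set[str] = set()
        for t in direct:
            out.update(self.ancestors(t))
        return frozenset(out)


@dataclass(frozen=True)
class TermIC:
    """Per-term information content: -log10(annotation frequency)."""

    ic: dict[str, float]

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise ValueError(f"unknown term {term!r}") from None


@dataclass
class SimilarityMatrix:
    entities: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.entities)
        if self.scores.shape != (n, n):
            raise ValueError("scores shape does not match entity count")

    def score(self, e1: str, e2: str) -> float:
        return float(self.scores[self.entities.index(e1), self.entities.index(e2)])


def compute_ic(dag: OntologyDAG) -> TermIC:
    """Propagate annotations to ancestors and derive -log10 frequencies.

    Terms annotating no entity (even after propagation) get IC = +inf: they
    carry no annotation evidence, and any similarity through them is 0.
    """
    if not dag.direct_annotations:
        raise ValueError("ontology has no annotated entities")
    counts: dict[str, int] = {t: 0 for t in dag.terms}
    for entity in dag.direct_annotations:
        for term in dag.annotation_closure(entity):
            counts[term] += 1
    total = len(dag.direct_annotations)
    ic = {
        t: (-math.log10(c / total) if c > 0 else math.inf)
        for t, c in counts.items()
    }
    return TermIC(ic)


def term_similarity(
    t1: str,
    t2: str,
    dag: OntologyDAG,
    ic: TermIC,
    normalize: bool = True,
) -> float:
    """Lin-normalized MICA similarity (raw Resnik IC with normalize=False).

    MICA is the common ancestor (the terms included) of maximal IC;
    score = 2*IC(MICA) / (IC(t1) + IC(t2)), defined as 0 when the
    denominator is 0 (both terms at root-level information).
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    mica_ic = max((ic[c] for c in common if math.isfinite(ic[c])), default=0.0)
    if not normalize:
        return mica_ic
    ic1, ic2 = ic[t1], ic[t2]
    if not (math.isfinite(ic1) and math.isfinite(ic2)):
        return 0.0
    denom = ic1 + ic2
    if denom <= 0.0:
        return 0.0
    return min(1.0, 2.0 * mica_ic / denom)


def entity_similarity(
    e1: str,
    e2: str,
    dag: OntologyDAG,
    ic: TermIC,
    combine: str = "best-match-average",
) -> float:
    """Profile similarity between two annotated entities in [0, 1].

    From the pairwise term-similarity matrix between the two direct
    annotation profiles, the directional best matches (each term's best
    partner in the other profile) are combined:

    * ``best-match-average`` — mean of all directional best matches;
    * ``maximum`` — matrix maximum;
    * ``complete`` — minimum of the directional best matches (the most
      conservative summary: every term must have a good match).
    """
    if combine not in COMBINERS:
        raise ValueError(f"unknown combiner {combine!r}; expected one of {COMBINERS}")
    p1 = sorted(dag.direct_annotations.get(e1, frozenset()))
    p2 = sorted(dag.direct_annotations.get(e2, frozenset()))
    if not p1:
        raise ValueError(f"entity {e1!r} has no annotations")
    if not p2:
        raise ValueError(f"entity {e2!r} has no annotations")
    m = np.array([[term_similarity(a, b, dag, ic) for b in p2] for a in p1])
    best_rows = m.max(axis=1)  # best match of each term of e1 in e2's profile
    best_cols = m.max(axis=0)
    best = np.concatenate([best_rows, best_cols])
    if combine == "maximum":
        return float(m.max())
    if combine == "complete":
        return float(best.min())
    return float(best.mean())


def pairwise_entity_similarity(
    dag: OntologyDAG,
    ic: TermIC,
    entities: Sequence[str] | None = None,
    combine: str = "best-match-average",
) -> SimilarityMatrix:
    """Symmetric entity-by-entity similarity matrix (diagonal from self-pairs)."""
    if entities is None:
        entities = sorted(dag.direct_annotations)
    n = len(entities)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = entity_similarity(entities[i], entities[j], dag, ic, combine)
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(list(entities), scores)


def similarity_partner_counts(
    matrix: SimilarityMatrix,
    threshold: float = 0.5,
    min_partners: int = 5,
) -> tuple[dict[str, int], list[str]]:
    """Count, per entity, the OTHER entities scoring strictly above threshold.

    Returns the counts and the qualifying subset (count >= min_partners),
    order-stable with the matrix's entity order.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if min_partners < 0:
        raise ValueError("min_partners must be >= 0")
    counts: dict[str, int] = {}
    n = len(matrix.entities)
    for i, e in enumerate(matrix.entities):
        counts[e] = int(
            sum(1 for j in range(n) if j != i and matrix.scores[i, j] > threshold)
        )
    qualifying = [e for e in matrix.entities if counts[e] >= min_partners]
    return counts, qualifying


def read_ontology(
    edges_path: str | Path, annotations_path: str | Path
) -> OntologyDAG:
    """Build a DAG from an edge-list TSV (child, parent) and an annotation TSV
    (entity, term)."""
    edf = pd.read_csv(edges_path, sep="\t", dtype=str, comment="#")
    adf = pd.read_csv(annotations_path, sep="\t", dtype=str, comment="#")
    edges = tuple((str(c), str(p)) for c, p in edf.iloc[:, :2].itertuples(index=False))
    terms = frozenset(t for e in edges for t in e)
    annotations: dict[str, set[str]] = {}
    for entity, term in adf.iloc[:, :2].itertuples(index=False):
        annotations.setdefault(str(entity), set()).add(str(term))
    return OntologyDAG(
        terms=terms,
        edges=edges,
        direct_annotations={e: frozenset(t) for e, t in annotations.items()},
    )


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.scores, index=matrix.entities, columns=matrix.entities
    ).to_csv(path, sep="\t", index_label="entity")
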