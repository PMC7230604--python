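"""Two-group islet expression comparison with a normality gate, and
mean-expression ranking of candidate genes against a marker gene.

Per gene, the nondiabetic (ND) and diabetic (T2D) sample groups are compared
by Student's t-test when both groups pass the D'Agostino-Pearson normality
test (and are large enough for it to be meaningful), otherwise by the
Mann-Whitney U test. Values are analyzed on log2(FPKM + 1) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_fdr

GROUPS = ("ND", "T2D")

#: Minimum per-group size for the D'Agostino-Pearson gate to be applied;
#: below this, the nonparametric branch is forced (the test needs enough
#: observations for its skewness/kurtosis components).
MIN_N_NORMALITY = 8


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an ND/T2D sample grouping."""

    values: pd.DataFrame  # genes as index, samples as columns
    group: dict[str, str]  # sample -> "ND" | "T2D"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        missing = [s for s in self.values.columns if s not in self.group]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = {g for g in self.group.values()} - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == group]


@dataclass(frozen=True)
class ComparisonResult:
    gene: str
    test_used: str  # "t-test" | "mann-whitney"
    statistic: float
    p_value: float
    group_means: dict[str, float]
    log2_scale: bool

    @property
    def direction(self) -> str:
        """Sign of the T2D-vs-ND shift in group means."""
        diff = self.group_means["T2D"] - self.group_means["ND"]
        if diff > 0:
            return "up"
        if diff < 0:
            return "down"
        return "none"


def compare_expression(
    matrix: ExpressionMatrix,
    gene: str,
    alpha_normality: float = 0.05,
    log_transform: bool = True,
) -> ComparisonResult:
    """Normality-gated two-sided comparison of ND vs T2D for one gene.

    Both groups need >= 2 samples. The gate runs only when both groups have
    at least :data:`MIN_N_NORMALITY` samples; smaller groups are compared
    nonparametrically.
    """
    if gene not in matrix.values.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    arrays = {}
    for grp in GROUPS:
        samples = matrix.group_samples(grp)
        if len(samples) < 2:
            raise ValueError(f"group {grp} has fewer than 2 samples")
        vals = matrix.values.loc[gene, samples].to_numpy(dtype=float)
        arrays[grp] = np.log2(vals + 1.0) if log_transform else vals
    nd, t2d = arrays["ND"], arrays["T2D"]

    use_t = False
    if min(len(nd), len(t2d)) >= MIN_N_NORMALITY:
        normal = []
        for vals in (nd, t2d):
            if np.ptp(vals) == 0:  # constant group: normality test undefined
                normal.append(False)
                continue
            normal.append(stats.normaltest(vals).pvalue > alpha_normality)
        use_t = all(normal)

    if use_t:
        res = stats.ttest_ind(nd, t2d, equal_var=True)
        test_used = "t-test"
    else:
        res = stats.mannwhitneyu(nd, t2d, alternative="two-sided")
        test_used = "mann-whitney"
    return ComparisonResult(
        gene=gene,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means={"ND": float(nd.mean()), "T2D": float(t2d.mean())},
        log2_scale=log_transform,
    )


def compare_all(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    alpha_normality: float = 0.05,
    log_transform: bool = True,
    adjust_fdr: bool = False,
) -> list[ComparisonResult]:
    """Run :func:`compare_expression` over several genes.

    No multiple-testing correction by default; ``adjust_fdr=True`` replaces
    the p-values with their BH adjustment across the tested genes.
    """
    genes = list(genes) if genes is not None else matrix.genes
    results = [
        compare_expression(matrix, g, alpha_normality, log_transform) for g in genes
    ]
    if adjust_fdr:
        adj = bh_fdr([r.p_value for r in results])
        results = [
            ComparisonResult(r.gene, r.test_used, r.statistic, q, r.group_means, r.log2_scale)
            for r, q in zip(results, adj)
        ]
    return results


@dataclass(frozen=True)
class RankedGene:
    gene: str
    mean_nd: float
    is_marker: bool


def rank_mean_expression(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    marker: str,
) -> list[RankedGene]:
    """Rank genes (plus the reference marker) by mean ND expression.

    Means are computed on the raw input scale over nondiabetic samples only;
    descending order, ties broken alphabetically. The marker gene is flagged
    so it can serve as an expression yardstick.
    """
    wanted = list(dict.fromkeys([*genes, marker]))
    missing = [g for g in wanted if g not in matrix.values.index]
    if missing:
        raise ValueError(f"genes missing from expression matrix: {missing}")
    nd_samples = matrix.group_samples("ND")
    means = {
        g: float(matrix.values.loc[g, nd_samples].to_numpy(dtype=float).mean())
        for g in wanted
    }
    ordered = sorted(wanted, key=lambda g: (-means[g], g))
    return [RankedGene(g, means[g], g == marker) for g in ordered]


def read_expression(
    matrix_path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    """Read a gene x sample TSV and a two-column (sample, group) map."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str, comment="#")
    group = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    return ExpressionMatrix(values=values, group=group)


def write_comparisons(results: Sequence[ComparisonResult], path: str | Path) -> None:
    rows = [
        {
            "gene": r.gene,
            "test_used": r.test_used,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "mean_ND": r.group_means["ND"],
            "mean_T2D": r.group_means["T2D"],
            "direction_T2D_vs_ND": r.direction,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ranking(ranking: Sequence[RankedGene], path: str | Path) -> None:
    rows = [
        {"gene": r.gene, "mean_ND": r.mean_nd, "is_marker": r.is_marker}
        for r in ranking
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
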