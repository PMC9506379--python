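"""CRISPR dependency (CERES) thresholding and subtype-level summaries.

CERES scores estimate how much a cell line depends on a gene for survival:
0 means no dependency, while a score near −1 matches the median of
pan-essential genes.  A gene is *called* essential in a line when its
score is strictly below −1, and subtype-level dependency is the fraction
of that subtype's lines with an essential call.  Distributional
comparisons between subtypes use rank statistics (Mann-Whitney pairwise,
Kruskal-Wallis overall), and the expression-dependency relationship is a
Spearman correlation over the shared cell lines.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from subtypescreen.enrichment import nejm_stars

ESSENTIAL_THRESHOLD = -1.0  # strict '<': a score of exactly -1 is not essential


@dataclass
class DependencyMatrix:
    """Genes × cell lines of CERES scores with per-line subtype labels."""

    ceres: pd.DataFrame
    subtype_of: pd.Series

    def __post_init__(self) -> None:
        unlabeled = [c for c in self.ceres.columns if c not in self.subtype_of.index]
        if unlabeled:
            raise ValueError(f"cell lines without a subtype label: {unlabeled}")

    def gene_row(self, gene: str) -> pd.Series:
        if gene not in self.ceres.index:
            raise KeyError(f"gene {gene!r} not in the dependency matrix")
        return self.ceres.loc[gene]


def essential_calls(matrix: DependencyMatrix, threshold: float = ESSENTIAL_THRESHOLD) -> pd.DataFrame:
    """Boolean essentiality calls (score < threshold); missing stays missing."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    calls = matrix.ceres < threshold
    return calls.where(matrix.ceres.notna(), other=pd.NA)


def subtype_dependency_fraction(
    matrix: DependencyMatrix, gene: str, threshold: float = ESSENTIAL_THRESHOLD
) -> pd.DataFrame:
    """Per-subtype fraction of cell lines in which ``gene`` is essential.

    Denominators count non-missing lines only and are reported alongside;
    a subtype with no non-missing line gets a missing fraction.
    """
    row = matrix.gene_row(gene)
    labels = matrix.subtype_of.reindex(row.index)
    rows = []
    for subtype in sorted(labels.dropna().unique()):
        vals = row[labels == subtype]
        n = int(vals.notna().sum())
        k = int((vals < threshold).sum())
        frac = k / n if n else np.nan
        rows.append((subtype, frac, k, n))
    return pd.DataFrame(rows, columns=["subtype", "fraction", "n_essential", "n_lines"])


def _rank_pair_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_dependency(matrix: DependencyMatrix, gene: str) -> dict:
    """Rank-based subtype comparison of one gene's dependency scores.

    Returns the overall Kruskal-Wallis H and p plus a pairwise
    Mann-Whitney table with NEJM stars.  All-tied data gives H = 0, p = 1.
    """
    row = matrix.gene_row(gene)
    labels = matrix.subtype_of.reindex(row.index)
    groups = {
        s: row[labels == s].dropna().to_numpy()
        for s in sorted(labels.dropna().unique())
    }
    small = [s for s, v in groups.items() if v.size < 2]
    if small:
        raise ValueError(f"subtypes with fewer than 2 scored lines: {small}")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        h, p_overall = 0.0, 1.0
    else:
        h, p_overall = stats.kruskal(*groups.values())
    rows = []
    for a, b in itertools.combinations(groups, 2):
        u, p = _rank_pair_test(groups[a], groups[b])
        rows.append((a, b, u, p, nejm_stars(p)))
    pairwise = pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "u", "p", "stars"])
    return {"H": float(h), "p": float(p_overall), "pairwise": pairwise}


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact permutation p for small panels (n <= 8)."""
    n = x.size
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        return float("nan"), float("nan")
    if n <= 8:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        perms = np.array(list(itertools.permutations(ry)))
        null = np.array([stats.pearsonr(rx, p).statistic for p in perms])
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return float(rho), p


def expression_vs_dependency(
    expression: pd.DataFrame, matrix: DependencyMatrix, gene: str
) -> pd.DataFrame:
    """Spearman correlation between a gene's expression and its dependency.

    Pairs cell lines by id intersection; reports rho and p per subtype and
    pooled.  Subtypes with fewer than 3 shared lines are reported as
    skipped (missing rho).
    """
    if expression.columns.duplicated().any() or matrix.ceres.columns.duplicated().any():
        raise ValueError("duplicate cell-line ids")
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} not in the expression matrix")
    dep = matrix.gene_row(gene)
    shared = expression.columns.intersection(dep.index)
    paired = pd.DataFrame(
        {"expression": expression.loc[gene, shared], "dependency": dep[shared]}
    ).dropna()
    if len(paired) < 3:
        raise ValueError("fewer than 3 shared cell lines with both values")
    labels = matrix.subtype_of.reindex(paired.index)
    rows = []
    for subtype in sorted(labels.dropna().unique()):
        sub = paired[labels == subtype]
        if len(sub) < 3:
            rows.append((subtype, len(sub), np.nan, np.nan, "skipped: <3 lines"))
            continue
        rho, p = _spearman(sub["expression"].to_numpy(), sub["dependency"].to_numpy())
        rows.append((subtype, len(sub), rho, p, ""))
    rho, p = _spearman(paired["expression"].to_numpy(), paired["dependency"].to_numpy())
    rows.append(("pooled", len(paired), rho, p, ""))
    return pd.DataFrame(rows, columns=["subtype", "n", "rho", "p", "note"])
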