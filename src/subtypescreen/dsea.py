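"""Drug-set enrichment analysis over subtype contrasts.

Drugs are ranked by their differential mean response (subtype mean minus
rest mean) for a one-vs-rest contrast, best-to-worst: drugs the contrast
subtype *resists* (positive delta) head the list and drugs it is
*sensitive* to (negative delta) sit at the bottom.  A drug set whose
members concentrate at the bottom of that ranking is negatively enriched —
the screen's signal of subtype-specific sensitivity — so a "sensitive"
call is a negative NES passing the FDR threshold.  Both response modes
share the convention: lower AUC and lower fraction-viable both mean more
sensitive.

Single-drug lead hits are the most-negative-delta drugs with Welch t
p-values annotated at the NEJM significance thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from subtypescreen.enrichment import (
    EnrichmentResult,
    RankedList,
    enrichment_score,
    nejm_stars,
    normalize_and_fdr,
    permutation_null,
    welch_t,
)
from subtypescreen.io_formats import SetCollection

MAX_MISSING_FRACTION = 0.5  # drop a drug from a contrast above this, per group


@dataclass
class DrugResponseMatrix:
    """Drugs × cell lines with a response mode and per-line subtype labels."""

    values: pd.DataFrame  # drugs × cell lines, NaN = missing
    mode: str  # 'auc' or 'viability'
    subtype_of: pd.Series  # cell line -> subtype

    def __post_init__(self) -> None:
        if self.mode not in ("auc", "viability"):
            raise ValueError(f"mode must be 'auc' or 'viability', got {self.mode!r}")
        unlabeled = [c for c in self.values.columns if c not in self.subtype_of.index]
        if unlabeled:
            raise ValueError(f"cell lines without a subtype label: {unlabeled}")

    def contrast_columns(self, contrast_subtype: str) -> tuple[pd.Index, pd.Index]:
        labels = self.subtype_of.reindex(self.values.columns)
        mask = labels == contrast_subtype
        if mask.sum() == 0:
            raise ValueError(f"contrast subtype {contrast_subtype!r} has no cell lines")
        return self.values.columns[mask], self.values.columns[~mask]


def contrast_deltas(
    matrix: DrugResponseMatrix, contrast_subtype: str
) -> tuple[pd.Series, list[str]]:
    """Per-drug delta = mean(contrast lines) − mean(rest lines).

    Drugs with more than 50% missing values in either group are dropped
    and returned in the drop log.
    """
    in_cols, out_cols = matrix.contrast_columns(contrast_subtype)
    if len(in_cols) < 2 or len(out_cols) < 2:
        raise ValueError("need at least 2 cell lines on each side of the contrast")
    a = matrix.values[in_cols]
    b = matrix.values[out_cols]
    ok = (a.isna().mean(axis=1) <= MAX_MISSING_FRACTION) & (
        b.isna().mean(axis=1) <= MAX_MISSING_FRACTION
    )
    dropped = list(matrix.values.index[~ok])
    delta = (a.mean(axis=1) - b.mean(axis=1))[ok]
    return delta, dropped


def rank_drugs(matrix: DrugResponseMatrix, contrast_subtype: str) -> RankedList:
    """Rank drugs best-to-worst by delta (descending; ties by drug id).

    The most subtype-sensitizing drugs (most negative delta) land at the
    bottom of the list, where a sensitive drug set shows negative
    enrichment.
    """
    delta, _ = contrast_deltas(matrix, contrast_subtype)
    order = np.lexsort((delta.index.to_numpy(), -delta.to_numpy()))
    ordered = delta.iloc[order]
    return RankedList(list(ordered.index), ordered.to_numpy())


def run_dsea(
    matrix: DrugResponseMatrix,
    sets: SetCollection,
    contrast_subtype: str,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    min_set_size: int = 3,
    max_set_size: int | None = None,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Drug-set enrichment for one subtype contrast.

    Returns results sorted by NES ascending (most sensitive first) with
    p and FDR q from a random set-membership permutation null.  Sets are
    filtered to ``min_set_size <= overlap <= max_set_size`` (default N/2)
    after intersecting with the ranked drugs; an empty survivor list
    returns an empty result.
    """
    ranking = rank_drugs(matrix, contrast_subtype)
    universe = set(ranking.item_ids)
    n = len(ranking)
    max_size = max_set_size if max_set_size is not None else n // 2
    surviving: dict[str, set[str]] = {}
    for name in sets.names:
        overlap = set(sets.members[name]) & universe
        if min_set_size <= len(overlap) <= max_size:
            surviving[name] = overlap
    if not surviving:
        return []
    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    observed, nulls = [], {}
    for name, overlap in surviving.items():
        es, _, edge = enrichment_score(ranking, overlap, weight_exponent)
        observed.append(EnrichmentResult(name, es, len(overlap), edge))
        size = len(overlap)
        if size not in null_by_size:
            null_by_size[size] = permutation_null(
                ranking, size, n_permutations, weight_exponent, rng
            )
        nulls[name] = null_by_size[size]
    observed = normalize_and_fdr(observed, nulls)
    observed.sort(key=lambda r: (r.nes, r.set_name))
    return observed


def dsea_results_to_frame(
    results: list[EnrichmentResult], q_threshold: float = 0.25
) -> pd.DataFrame:
    """Tabulate enrichment results; ``sensitive`` marks nes < 0 at q below threshold."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "n_overlap": [r.n_overlap for r in results],
            "sensitive": [(r.nes < 0) and (r.fdr_q < q_threshold) for r in results],
            "leading_edge": ["|".join(r.leading_edge) for r in results],
            "flag": [r.flag for r in results],
        }
    )


def call_single_drug_hits(
    matrix: DrugResponseMatrix, contrast_subtype: str, top_k: int = 10
) -> pd.DataFrame:
    """Top-k most subtype-sensitizing single drugs with Welch t statistics.

    Ordered by (delta, p, drug id); stars follow the NEJM thresholds.
    Drugs failing the missing-value policy, or with fewer than two
    non-missing values in either group, are excluded.
    """
    delta, dropped = contrast_deltas(matrix, contrast_subtype)
    in_cols, out_cols = matrix.contrast_columns(contrast_subtype)
    rows = []
    for drug in delta.index:
        a = matrix.values.loc[drug, in_cols].dropna().to_numpy()
        b = matrix.values.loc[drug, out_cols].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            dropped.append(drug)
            continue
        t, df, p = welch_t(a, b)
        rows.append((drug, contrast_subtype, float(delta[drug]), t, p, nejm_stars(p)))
    hits = pd.DataFrame(
        rows, columns=["drug_id", "contrast_subtype", "delta", "t", "p", "stars"]
    )
    hits = hits.sort_values(["delta", "p", "drug_id"]).reset_index(drop=True)
    hits.attrs["dropped"] = dropped
    if top_k > len(hits):
        return hits
    return hits.head(top_k)


def zscore_by_drug(matrix: DrugResponseMatrix) -> tuple[DrugResponseMatrix, list[str]]:
    """Z-score each drug's responses across cell lines (sample sd).

    Missing values are ignored; zero-variance drugs become all-zero rows
    and are returned in the flag list.  Idempotent up to floating
    tolerance.
    """
    values = matrix.values
    counts = values.notna().sum(axis=1)
    if (counts < 2).any():
        bad = list(values.index[counts < 2])
        raise ValueError(f"drugs with fewer than 2 non-missing values: {bad}")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flagged = list(values.index[sd == 0])
    z = values.sub(mean, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z.loc[flagged] = z.loc[flagged].where(values.loc[flagged].isna(), 0.0)
    return DrugResponseMatrix(z, matrix.mode, matrix.subtype_of), flagged
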