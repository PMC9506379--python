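"""Consensus molecular subtyping of bladder-cancer cell lines.

Four published taxonomies (MDA, Lund, TCGA, Consensus) each assign a cell
line a subtype from their own vocabulary.  This module harmonizes those
calls onto a common four-label space (basal, luminal, mesenchymal-like,
neuronal) and assigns the *predominant* subtype when at least three of the
four harmonized calls agree.  Cell lines without such a majority can still
be designated mesenchymal-like through a signature-score fallback: pure
cultured cell lines lack the stromal-infiltration markers the TCGA and
Consensus mesenchymal-like subtypes rely on, so intrinsically mesenchymal
lines tend to scatter across taxonomies (often into the rare neuronal
label) while scoring high on an EMT/mesenchymal gene signature.

The harmonization vocabulary and the default mesenchymal signature ship as
editable data files, not code constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from subtypescreen.enrichment import RankedList, enrichment_score

HARMONIZED_LABELS = ("basal", "luminal", "mesenchymal-like", "neuronal")
TAXONOMIES = ("MDA", "Lund", "TCGA", "Consensus")


@dataclass
class ConsensusAssignment:
    sample_id: str
    harmonized_labels: dict[str, str]  # taxonomy -> harmonized label
    n_concordant: int
    predominant: str  # basal | luminal | mesenchymal-like | unassigned
    fallback_used: bool = False
    mesenchymal_score: float = np.nan


def _data_path(name: str):
    return resources.files("subtypescreen.data") / name


def load_harmonization(path=None) -> dict[tuple[str, str], str]:
    """Load the (taxonomy, raw_label) -> harmonized label table."""
    src = path if path is not None else _data_path("harmonization.tsv")
    table = pd.read_csv(src, sep="\t")
    out = {}
    for _, row in table.iterrows():
        if row["harmonized"] not in HARMONIZED_LABELS:
            raise ValueError(f"unknown harmonized label {row['harmonized']!r}")
        out[(row["taxonomy"], row["raw_label"])] = row["harmonized"]
    return out


def load_mesenchymal_signature(path=None) -> list[str]:
    """Load the default (editable) mesenchymal/EMT marker gene list."""
    src = path if path is not None else _data_path("mesenchymal_signature.txt")
    with open(src, "rt", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def harmonize_label(taxonomy: str, raw_label: str, table=None) -> str:
    """Map one taxonomy's raw label onto the harmonized four-label space."""
    table = table if table is not None else load_harmonization()
    key = (taxonomy, raw_label.strip())
    if key not in table:
        accepted = sorted(lbl for tax, lbl in table if tax == taxonomy)
        if not accepted:
            raise KeyError(f"unknown taxonomy {taxonomy!r}; known: {TAXONOMIES}")
        raise KeyError(
            f"unknown label {raw_label!r} for taxonomy {taxonomy}; accepted: {accepted}"
        )
    return table[key]


def assign_consensus(
    sample_id: str,
    calls: dict[str, str],
    mesenchymal_score: float = np.nan,
    score_threshold: float = 0.0,
    table=None,
) -> ConsensusAssignment:
    """Assign the predominant subtype from one call per taxonomy.

    ``calls`` maps each of the four taxonomies to its raw label.  A modal
    harmonized label with multiplicity >= 3 wins (except neuronal, which is
    never a final cell-line assignment here — misclassification of
    mesenchymal lines into the rare neuronal subtype is the known failure
    mode).  Otherwise a mesenchymal signature score above ``score_threshold``
    triggers the mesenchymal-like fallback; otherwise unassigned.
    Invariant to the ordering of the calls.
    """
    missing = [t for t in TAXONOMIES if t not in calls]
    if missing or set(calls) - set(TAXONOMIES):
        raise ValueError(
            f"need exactly one call per taxonomy {TAXONOMIES}; "
            f"missing {missing}, extraneous {sorted(set(calls) - set(TAXONOMIES))}"
        )
    table = table if table is not None else load_harmonization()
    harmonized = {tax: harmonize_label(tax, calls[tax], table) for tax in TAXONOMIES}
    counts = pd.Series(list(harmonized.values())).value_counts()
    modal_label, n_concordant = counts.index[0], int(counts.iloc[0])
    if n_concordant >= 3 and modal_label != "neuronal":
        return ConsensusAssignment(sample_id, harmonized, n_concordant, modal_label)
    if np.isfinite(mesenchymal_score) and mesenchymal_score > score_threshold:
        return ConsensusAssignment(
            sample_id, harmonized, n_concordant, "mesenchymal-like",
            fallback_used=True, mesenchymal_score=float(mesenchymal_score),
        )
    return ConsensusAssignment(
        sample_id, harmonized, n_concordant, "unassigned",
        mesenchymal_score=float(mesenchymal_score),
    )


def centroid_classify(expression: pd.DataFrame, signatures: dict[str, list[str]]) -> pd.Series:
    """Nearest-centroid style classification from label signatures.

    Expression is genes × samples.  Each gene is z-scored across samples;
    each sample receives the label whose signature-gene mean z-score is
    largest.  Ties break to the lexicographically first label.
    """
    present = {
        label: [g for g in genes if g in expression.index]
        for label, genes in signatures.items()
    }
    empty = [label for label, genes in present.items() if not genes]
    if empty:
        raise ValueError(f"no signature gene present in the matrix for label(s): {empty}")
    sd = expression.std(axis=1, ddof=1)
    z = expression.sub(expression.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    scores = pd.DataFrame(
        {label: z.loc[genes].mean(axis=0) for label, genes in present.items()}
    )
    ordered = scores[sorted(scores.columns)]  # lexicographic tie-break via first-max
    return ordered.idxmax(axis=1).rename("label")


def signature_score(
    expression_column: pd.Series, signature, weight_exponent: float = 0.25
) -> float:
    """Single-sample signature enrichment score (ssGSEA-style).

    Genes are ranked by expression within the sample (descending); the
    score is the weighted-KS enrichment of the signature in that ranking
    with absolute-rank weights ``rank^exponent`` — a function of ranks
    only, hence invariant to monotone shifts of the expression values.
    """
    overlap = [g for g in signature if g in expression_column.index]
    if len(overlap) < 2:
        raise ValueError("need at least 2 signature genes present in the sample")
    if len(overlap) >= expression_column.size:
        raise ValueError("signature must be smaller than the gene universe")
    order = expression_column.sort_values(ascending=False, kind="mergesort")
    n = order.size
    ranks_desc = np.arange(n, 0, -1, dtype=float)  # N..1, top gene heaviest
    ranking = RankedList(list(order.index), ranks_desc)
    es, _, _ = enrichment_score(ranking, overlap, weight_exponent)
    return es


def mesenchymal_scores(
    expression: pd.DataFrame, signature=None, weight_exponent: float = 0.25
) -> pd.Series:
    """Per-sample mesenchymal signature scores, z-normalized across samples.

    The default fallback criterion is a z-normalized score > 0, i.e. the
    sample is more mesenchymal than the panel average — a scale-free
    relative criterion.
    """
    signature = signature if signature is not None else load_mesenchymal_signature()
    raw = expression.apply(lambda col: signature_score(col, signature, weight_exponent), axis=0)
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return raw * 0.0
    return (raw - raw.mean()) / sd


def assignments_to_frame(assignments: list[ConsensusAssignment]) -> pd.DataFrame:
    """Tabulate assignments for TSV output."""
    rows = []
    for a in assignments:
        row = {"sample_id": a.sample_id}
        row.update({f"label_{tax}": a.harmonized_labels[tax] for tax in TAXONOMIES})
        row.update(
            n_concordant=a.n_concordant,
            predominant=a.predominant,
            fallback_used=a.fallback_used,
            mesenchymal_score=a.mesenchymal_score,
        )
        rows.append(row)
    return pd.DataFrame(rows)
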