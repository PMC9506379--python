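"""Weighted Kolmogorov-Smirnov enrichment statistic, permutation null, NES and FDR.

The shared statistical core for drug-set enrichment, single-sample signature
scoring and regulon activity.  A *ranked list* holds items ordered
best-to-worst by a numeric metric (non-increasing).  The enrichment score of
a member set is the extremum of a running sum that is incremented at member
positions by the normalized metric weight ``|m|^exponent`` and decremented
at non-member positions by the constant ``1/(N - n_hit)`` — the classic
GSEA statistic.  Significance comes from a random set-membership
permutation null; normalized scores (NES) divide the score by the mean
magnitude of same-sign null scores, and the false-discovery rate follows
the GSEA two-fraction convention on pooled null NES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "normalize_and_fdr",
    "welch_t",
    "nejm_stars",
]


def nejm_stars(p: float) -> str:
    """Significance annotation at the NEJM thresholds 0.033 / 0.002 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.002:
        return "**"
    if p < 0.033:
        return "*"
    return "ns"


@dataclass
class RankedList:
    """Items ordered best-to-worst by a non-increasing metric."""

    item_ids: list[str]
    metric_values: np.ndarray

    def __post_init__(self) -> None:
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if len(self.item_ids) != len(self.metric_values):
            raise ValueError("item_ids and metric_values lengths differ")
        if len(self.item_ids) < 2:
            raise ValueError("ranked list needs at least 2 items")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids in ranking")
        if np.any(np.diff(self.metric_values) > 1e-12):
            raise ValueError("metric_values must be non-increasing (best-to-worst)")

    def __len__(self) -> int:
        return len(self.item_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    n_overlap: int
    leading_edge: list[str] = field(default_factory=list)
    nes: float = np.nan
    p_value: float = np.nan
    fdr_q: float = np.nan
    flag: str = ""


def _hit_increments(metric: np.ndarray, hit_mask: np.ndarray, exponent: float) -> np.ndarray:
    """Per-position running-sum increments for one member set.

    Falls back to exponent 0 when every hit weight is zero, so a set sitting
    entirely on zero-metric items still has a defined score.
    """
    n = metric.size
    n_hit = int(hit_mask.sum())
    weights = np.abs(metric) ** exponent if exponent != 0 else np.ones(n)
    hit_total = weights[hit_mask].sum()
    if hit_total == 0.0:
        weights = np.ones(n)
        hit_total = float(n_hit)
    steps = np.where(hit_mask, weights / hit_total, -1.0 / (n - n_hit))
    return steps


def enrichment_score(
    ranking: RankedList, members, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score of ``members`` in ``ranking``.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` is the
    full profile over positions and the leading edge contains the member
    items at or before the extremum (positive es) or at or after it
    (negative es).
    """
    members = set(members)
    ids = ranking.item_ids
    hit_mask = np.fromiter((i in members for i in ids), dtype=bool, count=len(ids))
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("no overlap between member set and ranking")
    if n_hit == len(ids):
        raise ValueError("member set covers the whole ranking; miss decrement undefined")
    running = np.cumsum(_hit_increments(ranking.metric_values, hit_mask, weight_exponent))
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        edge = [ids[i] for i in range(peak + 1) if hit_mask[i]]
    else:
        edge = [ids[i] for i in range(peak, len(ids)) if hit_mask[i]]
    return es, running, edge


def _es_batch(metric: np.ndarray, hit_masks: np.ndarray, exponent: float) -> np.ndarray:
    """Enrichment scores for many member sets at once (rows of ``hit_masks``)."""
    n = metric.size
    n_hit = hit_masks.sum(axis=1)
    weights = np.abs(metric) ** exponent if exponent != 0 else np.ones(n)
    hit_totals = hit_masks @ weights
    flat = hit_totals == 0.0  # all-zero hit weights -> unweighted fallback
    steps = np.where(
        hit_masks,
        np.where(flat[:, None], 1.0 / np.maximum(n_hit, 1)[:, None], weights[None, :] / np.where(hit_totals, hit_totals, 1.0)[:, None]),
        -1.0 / (n - n_hit)[:, None],
    )
    running = np.cumsum(steps, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), peaks]


def permutation_null(
    ranking: RankedList,
    set_size: int,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null enrichment scores of random member sets of the given size."""
    n = len(ranking)
    if set_size >= n:
        raise ValueError(f"set_size {set_size} must be smaller than the ranking ({n})")
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hit_masks = np.zeros((n_permutations, n), dtype=bool)
    for row in hit_masks:
        row[rng.choice(n, size=set_size, replace=False)] = True
    return _es_batch(ranking.metric_values, hit_masks, weight_exponent)


def _same_sign_p(es: float, nulls: np.ndarray) -> tuple[float, float, str]:
    """Empirical p and same-sign null mean magnitude with add-one correction."""
    if es == 0.0:
        return 1.0, np.nan, ""
    same = nulls[nulls > 0] if es > 0 else nulls[nulls < 0]
    if same.size == 0:
        return 1.0 / (nulls.size + 1), np.nan, "no-same-sign-nulls"
    p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
    return float(p), float(np.mean(np.abs(same))), ""


def _normalize(values: np.ndarray, pos_mean: float, neg_mean: float) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    pos, neg = values > 0, values < 0
    if pos_mean and np.isfinite(pos_mean):
        out[pos] = values[pos] / pos_mean
    if neg_mean and np.isfinite(neg_mean):
        out[neg] = values[neg] / neg_mean
    return out


def normalize_and_fdr(
    observed: list[EnrichmentResult], nulls: dict[str, np.ndarray]
) -> list[EnrichmentResult]:
    """Fill nes, p and fdr_q on observed results from per-set null samples.

    NES divides each score (observed and null) by the mean magnitude of
    same-sign nulls of its own set; p is the same-sign empirical tail
    fraction with add-one correction; q follows the GSEA convention — for
    each observed NES the fraction of pooled null NES at least as extreme
    (same sign) over the fraction of observed NES at least as extreme,
    clipped to [0, 1] and monotonized within each sign.
    """
    eps = 1e-12
    pooled_null_nes = []
    for res in observed:
        null = np.asarray(nulls[res.set_name], dtype=float)
        if null.size < 100:
            raise ValueError(f"set {res.set_name!r}: need >= 100 null values, got {null.size}")
        pos = null[null > 0]
        neg = null[null < 0]
        pos_mean = float(np.mean(pos)) if pos.size else np.nan
        neg_mean = float(np.mean(np.abs(neg))) if neg.size else np.nan
        res.p_value, _, flag = _same_sign_p(res.es, null)
        if res.es == 0.0:
            res.nes = 0.0
        elif res.es > 0:
            res.nes = res.es / pos_mean if np.isfinite(pos_mean) else res.es / eps
        else:
            res.nes = res.es / neg_mean if np.isfinite(neg_mean) else res.es / eps
        if flag:
            res.flag = flag
        pooled_null_nes.append(_normalize(null, pos_mean, neg_mean))
    pooled = np.concatenate(pooled_null_nes)
    obs_nes = np.array([r.nes for r in observed])
    for sign in (1, -1):
        idx = np.where(np.sign(obs_nes) == sign)[0]
        if idx.size == 0:
            continue
        pool_same = pooled[np.sign(pooled) == sign]
        raw = np.empty(idx.size)
        for k, i in enumerate(idx):
            mag = abs(obs_nes[i])
            null_frac = (
                np.mean(np.abs(pool_same) >= mag) if pool_same.size else 0.0
            )
            obs_frac = np.mean(np.abs(obs_nes[idx]) >= mag)
            raw[k] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 0.0
        # monotonize: a more extreme NES never gets a larger q (BH-style)
        order = np.argsort(-np.abs(obs_nes[idx]))
        mono = np.minimum.accumulate(raw[order][::-1])[::-1]
        for pos, loc in enumerate(order):
            observed[idx[loc]].fdr_q = float(mono[pos])
    for r in observed:
        if r.nes == 0.0:
            r.fdr_q = 1.0
    return observed


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Unpaired two-tailed Welch t-test: returns (t, df, two-sided p).

    Zero-variance contracts: both groups constant and equal means gives
    ``(0, df, 1)``; zero pooled standard error with unequal means gives the
    smallest representable positive p and an infinite statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        sign = -1.0 if a.mean() < b.mean() else 1.0
        return sign * np.inf, float(na + nb - 2), float(np.finfo(float).tiny)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
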