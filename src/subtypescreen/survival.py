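"""Biomarker survival stratification and subtype differential expression.

A continuous biomarker (log2 expression of a candidate gene) is
dichotomized at the cutoff maximizing Youden's index J = sensitivity +
specificity − 1 on a ROC of the marker against the overall-survival event
flag.  The resulting high/low groups are compared by Kaplan-Meier
estimation and the log-rank test (hypergeometric variance, no continuity
correction).  Differential marker expression between molecular subtypes
uses the Kruskal-Wallis test with a pairwise rank-sum table.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from subtypescreen.enrichment import nejm_stars

REQUIRED_COLUMNS = ("time_months", "event", "marker")


@dataclass
class KmEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # months; NaN when survival never reaches 0.5


@dataclass
class YoudenCutoff:
    cutoff: float
    sensitivity: float
    specificity: float
    j: float
    uninformative: bool = False


def filter_cohort(
    raw: pd.DataFrame, required: tuple[str, ...] = REQUIRED_COLUMNS
) -> tuple[pd.DataFrame, int]:
    """Drop patients with incomplete annotation; report the exclusion count."""
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks required column(s): {missing_cols}")
    keep = raw[list(required)].notna().all(axis=1)
    filtered = raw[keep].reset_index(drop=True)
    return filtered, int((~keep).sum())


def youden_cutoff(marker, event, j_floor: float = 0.05) -> YoudenCutoff:
    """ROC-derived optimal dichotomization cutoff by Youden's index.

    Scans every distinct marker value as a threshold with the high group
    defined inclusively (marker >= cutoff); sensitivity is the event rate
    captured by the high group.  Ties on J break toward the larger cutoff
    (the smaller high group).  A maximum J below ``j_floor`` flags the
    marker as uninformative.
    """
    marker = np.asarray(marker, dtype=float)
    event = np.asarray(event, dtype=int)
    if marker.size != event.size:
        raise ValueError("marker and event lengths differ")
    n_pos, n_neg = int(event.sum()), int((1 - event).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both event classes must be present for ROC analysis")
    best = None
    for c in np.unique(marker):
        high = marker >= c
        sens = (event[high] == 1).sum() / n_pos
        spec = (event[~high] == 0).sum() / n_neg
        j = sens + spec - 1.0
        # >= keeps the larger cutoff on J ties (unique() scans ascending)
        if best is None or j >= best.j:
            best = YoudenCutoff(float(c), float(sens), float(spec), float(j))
    best.uninformative = best.j < j_floor
    return best


def km_fit(time, event) -> KmEstimate:
    """Product-limit survival estimate with right censoring.

    The median is the smallest time at which survival drops to 0.5 or
    below; NaN when the curve never reaches 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_["KM_estimate"]
    median = kmf.median_survival_time_
    return KmEstimate(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        at_risk=kmf.event_table["at_risk"].to_numpy(),
        median=float(median) if np.isfinite(median) else float("nan"),
    )


def logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi_square, p)."""
    if (np.sum(event_a) + np.sum(event_b)) == 0:
        raise ValueError("log-rank needs at least one event overall")
    res = _lifelines_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def stratify_by_marker(cohort: pd.DataFrame) -> dict:
    """Full stratification: Youden cutoff, group KM fits, log-rank comparison.

    Expects a filtered cohort with ``time_months``, ``event`` and
    ``marker`` columns.  The high group includes the cutoff.
    """
    cut = youden_cutoff(cohort["marker"], cohort["event"])
    high = cohort["marker"] >= cut.cutoff
    km_high = km_fit(cohort.loc[high, "time_months"], cohort.loc[high, "event"])
    km_low = km_fit(cohort.loc[~high, "time_months"], cohort.loc[~high, "event"])
    chi2, p = logrank(
        cohort.loc[high, "time_months"], cohort.loc[high, "event"],
        cohort.loc[~high, "time_months"], cohort.loc[~high, "event"],
    )
    return {
        "cutoff": cut,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "km_high": km_high,
        "km_low": km_low,
        "median_high": km_high.median,
        "median_low": km_low.median,
        "chi_square": chi2,
        "p": p,
    }


def marker_correlations(
    expression: pd.DataFrame, marker_gene: str, partner_genes
) -> pd.DataFrame:
    """Spearman correlation of a marker gene against partner genes."""
    if marker_gene not in expression.index:
        raise KeyError(f"marker gene {marker_gene!r} absent from the expression matrix")
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expression.loc[marker_gene]
    rows = []
    for partner in partner_genes:
        if partner not in expression.index:
            raise KeyError(f"partner gene {partner!r} absent from the expression matrix")
        rho, p = stats.spearmanr(x, expression.loc[partner])
        rows.append((marker_gene, partner, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["marker", "partner", "rho", "p"])


def subtype_differential_expression(
    expression: pd.DataFrame, gene: str, subtype_of: pd.Series
) -> dict:
    """Kruskal-Wallis test of one gene across subtypes with a pairwise table."""
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    values = expression.loc[gene]
    labels = subtype_of.reindex(values.index)
    groups = {
        s: values[labels == s].dropna().to_numpy()
        for s in sorted(labels.dropna().unique())
    }
    groups = {s: v for s, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 subtypes with at least 2 samples each")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        h, p_overall = 0.0, 1.0
    else:
        h, p_overall = stats.kruskal(*groups.values())
    rows = []
    for a, b in itertools.combinations(groups, 2):
        if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
            u, p = len(groups[a]) * len(groups[b]) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append((a, b, u, p, nejm_stars(p)))
    pairwise = pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "u", "p", "stars"])
    return {"H": float(h), "p": float(p_overall), "pairwise": pairwise}
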