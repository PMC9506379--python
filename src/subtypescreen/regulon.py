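"""Regulon-activity scoring on a subtype differential-expression contrast.

A *regulon* is a transcriptional regulator together with its signed,
weighted target set (mode +1 for activated targets, −1 for repressed;
weight in (0, 1] for interaction confidence).  Regulator activity in a
subtype contrast is inferred from where its targets fall in the
differential-expression signature: each gene's contrast statistic is
quantile-transformed to a normal score, and the activity raw score is the
weight-normalized mean of mode-adjusted target scores.  Significance and
a normalized score come from a target-resampling null (random same-size
target sets carrying the same modes and weights).  Positive normalized
activity reads as "activated" in the contrast subtype, negative as
"inactivated".

This is a deliberately simplified single-tail-per-mode statistic: no
pleiotropy or shadow correction, and targets with unknown mode are
dropped rather than split into a two-tail term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from subtypescreen.enrichment import welch_t

MIN_REGULON_SIZE = 10


@dataclass
class Regulon:
    regulator: str
    targets: list[str]
    modes: np.ndarray  # per-target sign in {+1, -1}
    weights: np.ndarray  # per-target confidence in (0, 1]

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.regulator}: duplicate targets")
        if not (len(self.targets) == self.modes.size == self.weights.size):
            raise ValueError(f"regulon {self.regulator}: field lengths differ")
        if not np.all(np.isin(self.modes, (-1.0, 1.0))):
            raise ValueError(f"regulon {self.regulator}: modes must be +1 or -1")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError(f"regulon {self.regulator}: weights must lie in (0, 1]")


@dataclass
class ActivityResult:
    regulator: str
    raw_score: float
    nes: float
    p: float
    direction: str  # 'activated' | 'inactivated'
    n_targets_used: int


def read_regulons(source) -> dict[str, Regulon]:
    """Load a regulon network table (regulator, target, mode, weight)."""
    table = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    out = {}
    for reg, block in table.groupby("regulator", sort=True):
        out[str(reg)] = Regulon(
            regulator=str(reg),
            targets=[str(t) for t in block["target"]],
            modes=block["mode"].to_numpy(),
            weights=block["weight"].to_numpy(),
        )
    return out


def contrast_signature(
    expression: pd.DataFrame, subtype_of: pd.Series, contrast_subtype: str
) -> pd.Series:
    """Per-gene Welch t statistic, contrast subtype vs all other lines."""
    labels = subtype_of.reindex(expression.columns)
    in_cols = expression.columns[labels == contrast_subtype]
    out_cols = expression.columns[(labels != contrast_subtype) & labels.notna()]
    if len(in_cols) < 2 or len(out_cols) < 2:
        raise ValueError("need at least 2 cell lines on each side of the contrast")
    sig = pd.Series(
        [welch_t(expression.loc[g, in_cols], expression.loc[g, out_cols])[0]
         for g in expression.index],
        index=expression.index, name="t",
    )
    return sig


def _quantile_scores(signature: pd.Series) -> pd.Series:
    """Normal scores of the signature ranks (average-rank ties)."""
    ranks = stats.rankdata(signature.to_numpy())
    return pd.Series(stats.norm.ppf(ranks / (signature.size + 1)), index=signature.index)


def regulon_activity(
    signature: pd.Series,
    regulon: Regulon,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    min_overlap: int = MIN_REGULON_SIZE,
) -> ActivityResult | None:
    """Regulator activity in a signed differential-expression signature.

    Raw score: weighted mean of mode-adjusted normal-quantile signature
    scores over the targets present in the signature universe.  NES is the
    raw score standardized against random same-size target draws with the
    same weights and modes; p is the two-sided empirical tail with add-one
    correction.  Returns None (skip) when the target overlap is below
    ``min_overlap``.
    """
    present = np.array([t in signature.index for t in regulon.targets])
    if present.sum() < min_overlap:
        return None
    targets = [t for t, keep in zip(regulon.targets, present) if keep]
    modes = regulon.modes[present]
    weights = regulon.weights[present]
    z = _quantile_scores(signature)
    w_sum = weights.sum()
    raw = float(np.sum(weights * modes * z.loc[targets].to_numpy()) / w_sum)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = z.to_numpy()
    idx = np.array(
        [rng.choice(universe.size, size=len(targets), replace=False)
         for _ in range(n_permutations)]
    )
    null = (universe[idx] * (weights * modes)).sum(axis=1) / w_sum
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    nes = (raw - mu) / sd if sd > 0 else 0.0
    p = (1.0 + np.sum(np.abs(null - mu) >= abs(raw - mu))) / (n_permutations + 1.0)
    return ActivityResult(
        regulator=regulon.regulator,
        raw_score=raw,
        nes=float(nes),
        p=float(p),
        direction="activated" if nes > 0 else "inactivated",
        n_targets_used=len(targets),
    )


def score_regulons(
    signature: pd.Series,
    regulons: dict[str, Regulon],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every regulon against one signature; table sorted by NES."""
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(regulons):
        res = regulon_activity(signature, regulons[name], n_permutations, rng)
        if res is None:
            continue
        rows.append(
            (res.regulator, res.raw_score, res.nes, res.p, res.direction, res.n_targets_used)
        )
    frame = pd.DataFrame(
        rows, columns=["regulator", "raw_score", "nes", "p", "direction", "n_targets"]
    )
    return frame.sort_values("nes", ascending=False).reset_index(drop=True)
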