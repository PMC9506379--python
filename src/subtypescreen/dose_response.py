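"""Dilution-curve analytics: AUC, 4PL fitting, plate QC, viability gating.

Covers both screen designs without special-casing: an 8-step 4-fold
dilution ladder starting at 10 µM (pooled-screen style) and an 8-step
2-fold ladder starting at 40 µM (hit-validation style) differ only in log
spacing.  Drug sensitivity is summarized as the normalized area under the
response-vs-log-concentration curve (lower AUC = more sensitive), and hit
validation fits a four-parameter logistic (4PL) model

    response = bottom + (top - bottom) / (1 + (conc / ic50)^hill)

by bounded multi-start least squares.  Plate quality uses the Z'-factor,
z' = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|, with z' > 0.5 the
conventional acceptability bar.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from subtypescreen.enrichment import nejm_stars, welch_t

RESPONSE_CAP = 1.2  # fraction-of-control cap applied before AUC integration


def ccle_ladder(start_um: float = 10.0, steps: int = 8, fold: float = 4.0) -> np.ndarray:
    """Descending molar concentration ladder, 4-fold dilutions from 10 µM."""
    return start_um * 1e-6 / fold ** np.arange(steps)


def inhouse_ladder(start_um: float = 40.0, steps: int = 8, fold: float = 2.0) -> np.ndarray:
    """Descending molar concentration ladder, 2-fold dilutions from 40 µM."""
    return start_um * 1e-6 / fold ** np.arange(steps)


@dataclass
class DilutionSeries:
    """One replicate's dose-response measurements, concentrations descending."""

    concentrations: np.ndarray  # molar, strictly positive, strictly descending
    responses: np.ndarray  # fraction of control, >= 0
    drug_id: str = ""
    cell_line_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.size != self.responses.size:
            raise ValueError("concentrations and responses lengths differ")
        if self.concentrations.size < 4:
            raise ValueError("need at least 4 concentration points")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) >= 0):
            raise ValueError("concentrations must be strictly descending")
        if np.any(self.responses < 0):
            raise ValueError("responses must be >= 0")


@dataclass
class FittedCurve:
    top: float
    bottom: float
    ic50: float  # molar
    hill: float
    rss: float
    converged: bool
    extrapolated: bool = False
    drug_id: str = ""
    cell_line_id: str = ""


@dataclass
class PlateQc:
    z_prime: float
    positive_mean: float
    positive_sd: float
    negative_mean: float
    negative_sd: float


def auc_from_series(series: DilutionSeries) -> float:
    """Normalized area under response vs log10(concentration).

    Trapezoidal area divided by the area of a constant response of 1 over
    the same log range; responses are capped at 1.2 first.  Depends only
    on log-spacing ratios, hence invariant to the concentration unit.
    """
    logc = np.log10(series.concentrations[::-1])  # ascending
    resp = np.minimum(series.responses[::-1], RESPONSE_CAP)
    span = logc[-1] - logc[0]
    if span <= 0:
        raise ValueError("degenerate concentration range")
    return float(np.trapezoid(resp, logc) / span)


def _four_pl(logc: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_4pl(series: DilutionSeries, replicates: list[DilutionSeries] | None = None) -> FittedCurve:
    """Fit the 4PL model to a series (optionally pooled with replicates).

    Bounded least squares with multi-start initialization: the IC50 start
    walks every tested concentration and the Hill start takes both signs,
    making the fit deterministic and robust to curves that rise with
    concentration (inverse responses).  IC50 is absolute (the response
    midpoint between top and bottom).  Zero response variance yields a
    flat curve with ``converged=False``.
    """
    pool = [series] + list(replicates or [])
    logc = np.concatenate([np.log10(s.concentrations) for s in pool])
    resp = np.concatenate([s.responses for s in pool])
    if np.unique(logc).size < 4:
        raise ValueError("need at least 4 distinct concentrations pooled across replicates")
    if np.ptp(resp) == 0.0:
        flat = float(resp[0])
        return FittedCurve(
            top=flat, bottom=flat, ic50=float(10 ** np.median(logc)), hill=1.0,
            rss=0.0, converged=False,
            drug_id=series.drug_id, cell_line_id=series.cell_line_id,
        )
    lo = np.array([0.5, -0.1, logc.min() - 2.0, -10.0])
    hi = np.array([1.5, 0.8, logc.max() + 2.0, 10.0])

    def residuals(theta):
        return _four_pl(logc, *theta) - resp

    best = None
    top0 = float(np.clip(resp.max(), 0.5, 1.5))
    bot0 = float(np.clip(resp.min(), -0.1, 0.8))
    for x50, h0 in itertools.product(np.unique(logc), (1.0, -1.0)):
        x0 = np.clip([top0, bot0, x50, h0], lo, hi)
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if best is None or sol.cost < best.cost:
            best = sol
    top, bottom, log_ic50, hill = best.x
    if bottom > top:  # canonical orientation: report top >= bottom, flip hill
        top, bottom, hill = bottom, top, -hill
    ic50 = float(10 ** log_ic50)
    cmin, cmax = 10 ** logc.min(), 10 ** logc.max()
    return FittedCurve(
        top=float(top), bottom=float(bottom), ic50=ic50, hill=float(hill),
        rss=float(2 * best.cost), converged=bool(best.success),
        extrapolated=not (cmin / 100 <= ic50 <= cmax * 100),
        drug_id=series.drug_id, cell_line_id=series.cell_line_id,
    )


def compare_ic50(curves_by_subtype: dict[str, list[FittedCurve]]) -> pd.DataFrame:
    """Pairwise subtype comparison of log10(IC50) by Welch t with NEJM stars.

    Non-converged curves are excluded; a pair where either subtype has
    fewer than 2 converged curves is skipped with a warning row.
    """
    usable = {
        s: np.log10([c.ic50 for c in curves if c.converged])
        for s, curves in curves_by_subtype.items()
    }
    if sum(len(v) >= 2 for v in usable.values()) < 2:
        raise ValueError("need >= 2 subtypes with >= 2 converged curves each")
    rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        if len(usable[a]) < 2 or len(usable[b]) < 2:
            rows.append((a, b, np.nan, np.nan, "skipped: insufficient converged curves"))
            continue
        t, _, p = welch_t(usable[a], usable[b])
        rows.append((a, b, t, p, nejm_stars(p)))
    return pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "t", "p", "stars"])


def z_prime(positive, negative) -> PlateQc:
    """Z'-factor plate quality from positive/negative control signals."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 values per control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValueError("control means are equal; Z' undefined")
    sd_p, sd_n = pos.std(ddof=1), neg.std(ddof=1)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return PlateQc(float(z), float(mu_p), float(sd_p), float(mu_n), float(sd_n))


def gate_viability(cell_table: pd.DataFrame, vehicle_wells) -> pd.Series:
    """Fraction-viable per well from per-cell dead-dye intensities.

    ``cell_table`` has one row per detected cell with columns ``well`` and
    ``dead_signal``.  Cells with intensity above the dead gate —
    vehicle-control mean + 3 sd — are considered dead; the per-well
    fraction is viable cells over the mean viable count across vehicle
    wells.
    """
    vehicle_wells = list(vehicle_wells)
    if not vehicle_wells:
        raise ValueError("no vehicle-control wells given")
    missing = set(vehicle_wells) - set(cell_table["well"])
    if missing:
        raise ValueError(f"vehicle wells absent from the plate table: {sorted(missing)}")
    vehicle = cell_table[cell_table["well"].isin(vehicle_wells)]["dead_signal"]
    gate = vehicle.mean() + 3.0 * vehicle.std(ddof=1)
    alive = cell_table[cell_table["dead_signal"] <= gate]
    viable_counts = alive.groupby("well").size().reindex(
        cell_table["well"].unique(), fill_value=0
    )
    denom = viable_counts[vehicle_wells].mean()
    if denom == 0:
        raise ValueError("no viable cells in vehicle-control wells")
    return (viable_counts / denom).rename("fraction_viable")
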