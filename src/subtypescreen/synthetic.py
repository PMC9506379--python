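"""Synthetic fixtures with the statistical structure the analysis assumes.

Generates log2 expression matrices with planted subtype signatures, drug
response screens (AUC or fraction-viable) with planted subtype-specific
sensitivity shifts, CRISPR dependency matrices with planted essential
genes, and survival cohorts with a marker-dependent exponential hazard —
so every downstream stage is testable without any external download.

All generators are pure functions of ``(config, seed)``.  The global seed
is split into fixed per-stage substreams, so changing e.g. ``cohort_size``
never perturbs the expression draw.  Planted-truth tables fully describe
every injected effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from subtypescreen.io_formats import SetCollection

SUBTYPES = ("basal", "luminal", "mesenchymal-like")

# fixed substream keys: generators must not share or reorder streams
_STREAMS = {"expression": 1, "drug": 2, "dependency": 3, "cohort": 4, "regulon": 5}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror the screening design the analysis targets: three cell
    lines per molecular subtype, compact drug sets of ten compounds, a
    0.4 response-unit planted sensitivity shift over measurement noise of
    0.1, CERES-scale essentiality shifts, and a ~400-patient cohort with a
    0.7 log-hazard marker effect under 30% censoring.
    """

    n_genes: int = 1000
    n_lines_per_subtype: int = 3
    signature_size: int = 50
    signature_effect: float = 3.0  # log2 units
    drug_count: int = 100
    set_count: int = 10
    set_size_range: tuple[int, int] = (10, 10)
    planted_sets: dict[str, str] = field(default_factory=dict)  # set name -> subtype
    planted_sensitivity: float = 0.4  # response units, applied downward
    noise_sd: float = 0.1
    essential_gene_effect: float = 1.2  # CERES units, applied downward
    n_essential_genes: int = 5
    essential_target_subtype: str = "mesenchymal-like"
    cohort_size: int = 400
    marker_log_hazard: float = 0.7
    censoring_rate: float = 0.3
    baseline_median_months: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_lines_per_subtype, self.signature_size,
            self.drug_count, self.set_count, self.cohort_size,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("set_size_range must be a valid count interval")
        if self.signature_size * len(SUBTYPES) > self.n_genes:
            raise ValueError("signature_size x 3 exceeds n_genes")
        if not self.planted_sets:
            self.planted_sets = {"SET01": "mesenchymal-like"}

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STREAMS[stage]]))

    def to_dict(self) -> dict:
        return asdict(self)


def _line_ids_and_labels(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    ids, labels = [], []
    for subtype in SUBTYPES:
        tag = subtype.split("-")[0][:3].upper()
        for i in range(config.n_lines_per_subtype):
            ids.append(f"{tag}{i + 1:02d}")
            labels.append(subtype)
    return ids, pd.Series(labels, index=ids, name="subtype")


def signature_genes(config: SimulationConfig) -> dict[str, list[str]]:
    """The planted signature gene blocks, one disjoint block per subtype."""
    out = {}
    for k, subtype in enumerate(SUBTYPES):
        start = k * config.signature_size
        out[subtype] = [f"G{g + 1:05d}" for g in range(start, start + config.signature_size)]
    return out


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Log2 expression (genes × cell lines) with planted subtype signatures.

    Background is Normal(5, 1) log2 units; each subtype's signature block
    is shifted up by ``signature_effect`` in that subtype's lines.  Returns
    the matrix and the true subtype label per line.
    """
    rng = config.rng("expression")
    ids, labels = _line_ids_and_labels(config)
    genes = [f"G{g + 1:05d}" for g in range(config.n_genes)]
    values = rng.normal(5.0, 1.0, size=(config.n_genes, len(ids)))
    expr = pd.DataFrame(values, index=genes, columns=ids)
    for subtype, block in signature_genes(config).items():
        cols = labels.index[labels == subtype]
        expr.loc[block, cols] += config.signature_effect
    return expr, labels


def _partition_sets(config: SimulationConfig, rng: np.random.Generator) -> SetCollection:
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.set_count)
    if sizes.sum() > config.drug_count:
        raise ValueError(
            f"set sizes total {sizes.sum()} but only {config.drug_count} drugs available"
        )
    drugs = [f"drug{d + 1:04d}" for d in range(config.drug_count)]
    order = rng.permutation(config.drug_count)
    names, members = [], {}
    cursor = 0
    for s, size in enumerate(sizes):
        name = f"SET{s + 1:02d}"
        names.append(name)
        members[name] = sorted(drugs[i] for i in order[cursor:cursor + size])
        cursor += size
    return SetCollection(names, members)


def simulate_drug_response(
    config: SimulationConfig, labels: pd.Series, mode: str = "viability"
) -> tuple[pd.DataFrame, SetCollection, pd.DataFrame]:
    """Drug response screen (drugs × cell lines) with planted sensitivity.

    In ``auc`` mode the baseline is Normal(0.9, noise_sd) truncated to
    [0, 1.2]; in ``viability`` mode Normal(0.95, noise_sd) truncated to
    [0, 1.1].  Drugs belonging to a planted (set, subtype) pair are shifted
    *down* by ``planted_sensitivity`` in that subtype's lines before
    truncation — lower values mean more sensitive in both modes.  Returns
    the matrix, the drug-set collection, and the planted-truth table.
    """
    if mode not in ("auc", "viability"):
        raise ValueError(f"mode must be 'auc' or 'viability', got {mode!r}")
    rng = config.rng("drug")
    sets = _partition_sets(config, rng)
    for set_name, subtype in config.planted_sets.items():
        if set_name not in sets.members:
            raise ValueError(f"planted set {set_name!r} not among generated sets")
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown planted subtype {subtype!r}")
    baseline, upper = (0.9, 1.2) if mode == "auc" else (0.95, 1.1)
    drugs = [f"drug{d + 1:04d}" for d in range(config.drug_count)]
    values = rng.normal(baseline, config.noise_sd, size=(config.drug_count, labels.size))
    resp = pd.DataFrame(values, index=drugs, columns=labels.index)
    truth_rows = []
    for set_name, subtype in config.planted_sets.items():
        cols = labels.index[labels == subtype]
        for drug in sets.members[set_name]:
            resp.loc[drug, cols] -= config.planted_sensitivity
            truth_rows.append((drug, set_name, subtype, config.planted_sensitivity))
    resp = resp.clip(lower=0.0, upper=upper)
    truth = pd.DataFrame(truth_rows, columns=["drug_id", "set_name", "subtype", "shift"])
    return resp, sets, truth


def simulate_dependency(
    config: SimulationConfig, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CERES-scale dependency matrix with planted subtype-specific essentiality.

    Background Normal(0, 0.2); the first ``n_essential_genes`` genes are
    shifted by −``essential_gene_effect`` in ``essential_target_subtype``
    lines.  Returns the matrix and the planted-truth table.
    """
    rng = config.rng("dependency")
    genes = [f"G{g + 1:05d}" for g in range(config.n_genes)]
    ceres = pd.DataFrame(
        rng.normal(0.0, 0.2, size=(config.n_genes, labels.size)),
        index=genes, columns=labels.index,
    )
    planted = genes[: config.n_essential_genes]
    cols = labels.index[labels == config.essential_target_subtype]
    ceres.loc[planted, cols] -= config.essential_gene_effect
    truth = pd.DataFrame(
        {"gene_id": planted,
         "subtype": config.essential_target_subtype,
         "shift": -config.essential_gene_effect}
    )
    return ceres, truth


def _calibrate_uniform_censoring(lam_low: float, lam_high: float, rate: float) -> float:
    """Upper bound of Uniform(0, c) censoring giving the target censored fraction.

    For C ~ Uniform(0, c) and T an equal mixture of two exponentials,
    P(censored) = E[S_T(C)] = mean over rates of (1 - exp(-lam c))/(lam c),
    which decreases monotonically in c; solved by bisection.
    """
    from scipy.optimize import brentq

    def censored_fraction(c: float) -> float:
        return 0.5 * sum(
            (1.0 - np.exp(-lam * c)) / (lam * c) for lam in (lam_low, lam_high)
        )

    return float(brentq(lambda c: censored_fraction(c) - rate, 1e-9, 1e9, xtol=1e-10))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Survival cohort with a marker-dependent exponential hazard.

    Marker ~ Normal(0, 1); event times are exponential with hazard
    ``lambda0 * exp(marker_log_hazard)`` for marker-positive patients and
    ``lambda0`` otherwise, where ``lambda0`` fixes the baseline median at
    ``baseline_median_months``.  Censoring times are independent
    Uniform(0, c_max), with ``c_max`` calibrated so the expected censored
    fraction equals ``censoring_rate`` — like administrative follow-up,
    this leaves short survivors more likely to have an observed event.
    """
    rng = config.rng("cohort")
    n = config.cohort_size
    marker = rng.normal(0.0, 1.0, size=n)
    lam0 = np.log(2.0) / config.baseline_median_months
    hazard = lam0 * np.exp(config.marker_log_hazard * (marker > 0))
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        c_max = _calibrate_uniform_censoring(
            lam0, lam0 * np.exp(config.marker_log_hazard), config.censoring_rate
        )
        censor_time = rng.uniform(0.0, c_max, size=n)
    else:
        censor_time = np.full(n, np.inf)
    censored = censor_time < event_time
    time = np.minimum(event_time, censor_time)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "time_months": time,
            "event": (~censored).astype(int),
            "marker": marker,
        }
    )


def simulate_regulons(
    config: SimulationConfig,
    n_regulons: int = 20,
    targets_per_regulon: int = 20,
    planted_regulator: str = "TF_PLANTED",
    planted_subtype: str = "mesenchymal-like",
) -> pd.DataFrame:
    """Synthetic regulon network (regulator, target, mode, weight) for tests.

    Random regulators draw targets uniformly from the gene universe with
    random signs; the planted regulator's positive-mode targets are that
    subtype's signature genes, so its activity should track the planted
    expression contrast.
    """
    rng = config.rng("regulon")
    genes = [f"G{g + 1:05d}" for g in range(config.n_genes)]
    rows = []
    for r in range(n_regulons):
        reg = f"TF{r + 1:03d}"
        targets = rng.choice(config.n_genes, size=targets_per_regulon, replace=False)
        modes = rng.choice([-1, 1], size=targets_per_regulon)
        weights = rng.uniform(0.5, 1.0, size=targets_per_regulon)
        rows += [(reg, genes[t], int(m), float(w)) for t, m, w in zip(targets, modes, weights)]
    sig = signature_genes(config)[planted_subtype][:targets_per_regulon]
    rows += [(planted_regulator, g, 1, 1.0) for g in sig]
    return pd.DataFrame(rows, columns=["regulator", "target", "mode", "weight"])
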