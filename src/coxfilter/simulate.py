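"""Two-subtype synthetic cohorts with known per-gene prognostic structure.

The generator inverts the screening model: each sample's hazard is

    lambda(t) = lambda0(t) * exp(b1*I(c2) + b2*X + b3*I(c2)*X)

so a gene is prognostic for subtype c1 when b2 != 0 and for subtype c2
when b2 + b3 != 0.  Genes are planted in four classes (``null``,
``c1_only``, ``c2_only``, ``shared``) in configured proportions, with
independent exponential right-censoring.

Two simulation designs are provided:

* :func:`generate_cohort` — one shared survival outcome driven by a small
  set of "driver" genes (default one).  Per-gene marginal fits on such a
  cohort are approximations when several drivers act at once.
* :func:`generate_matched_cohort` — one survival realisation per gene,
  each driven by that gene alone, so every per-gene fit is exactly
  correctly specified.  This is the design used by calibration, recovery
  and classification studies.

Expression is i.i.d. Normal per gene on the log2(FPKM+1) scale; a raw-FPKM
emission mode (2^X - 1, floored at 0) exists solely to exercise the
preprocessing filters.  The baseline hazard is exponential by default
(Weibull shape configurable).  The generator centers expression at
``expr_mean`` inside the linear predictor: a location shift only rescales
the baseline hazard, leaving the coefficients and partial likelihood
unchanged, but keeps the event fraction at its configured level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import ConfigError, ExpressionMatrix, LOG2P1, RAW

CLASS_ORDER = ("null", "c1_only", "c2_only", "shared")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-subtype cohort.

    ``beta2_effect`` is the log-hazard per expression unit for genes
    prognostic in subtype c1; ``beta3_effect`` is the c2 contrast
    (b2 + b3) for genes prognostic in subtype c2.  Rates are events per
    day; ``censor_rate = 0`` disables censoring.  ``mode`` selects the
    shared-outcome cohort design (``"cohort"``, with ``n_drivers`` active
    genes) or the per-gene matched design (``"matched"``).
    """

    n_c1: int = 81
    n_c2: int = 83
    n_genes: int = 200
    frac_null: float = 0.7
    frac_c1_only: float = 0.1
    frac_c2_only: float = 0.1
    frac_shared: float = 0.1
    beta1: float = 0.0
    beta2_effect: float = 1.0
    beta3_effect: float = 1.0
    baseline_rate: float = 0.001
    censor_rate: float = 0.0015
    weibull_shape: float = 1.0
    admin_cutoff: Optional[float] = None
    expr_mean: float = 3.0
    expr_sd: float = 1.0
    emit: str = "log2"  # or "fpkm"
    mode: str = "matched"  # or "cohort"
    n_drivers: int = 1
    seed: int = 0

    @property
    def fractions(self):
        return (self.frac_null, self.frac_c1_only, self.frac_c2_only, self.frac_shared)

    def validate(self) -> "SimulationConfig":
        if min(self.n_c1, self.n_c2, self.n_genes) < 1:
            raise ConfigError("n_c1, n_c2 and n_genes must all be >= 1")
        if any(f < 0 for f in self.fractions):
            raise ConfigError("class fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ConfigError(
                f"class fractions must sum to 1, got {sum(self.fractions)!r}"
            )
        if self.baseline_rate <= 0 or self.weibull_shape <= 0:
            raise ConfigError("baseline_rate and weibull_shape must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0 (0 disables censoring)")
        if self.expr_sd < 0:
            raise ConfigError("expr_sd must be >= 0")
        if self.emit not in ("log2", "fpkm"):
            raise ConfigError(f"unknown emit mode {self.emit!r}")
        if self.mode not in ("matched", "cohort"):
            raise ConfigError(f"unknown simulation mode {self.mode!r}")
        if self.n_drivers < 0:
            raise ConfigError("n_drivers must be >= 0")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GeneTruth:
    """Planted per-gene effect class and generative coefficients.

    ``driver`` marks whether the gene actually entered the simulated
    hazard (always true in matched mode; only for the selected drivers in
    cohort mode — non-driver signal genes are relabelled ``null``).
    """

    gene_id: str
    class_label: str
    true_beta1: float
    true_beta2: float
    true_beta3: float
    driver: bool = True

    def __post_init__(self):
        b2, b3 = self.true_beta2, self.true_beta3
        ok = {
            "null": b2 == 0 and b2 + b3 == 0,
            "c1_only": b2 != 0 and b2 + b3 == 0,
            "c2_only": b2 == 0 and b3 != 0,
            "shared": b2 != 0 and b2 + b3 != 0,
        }
        if self.class_label not in ok:
            raise ConfigError(f"unknown class label {self.class_label!r}")
        if not ok[self.class_label]:
            raise ConfigError(
                f"coefficients (b2={b2}, b3={b3}) inconsistent with "
                f"class {self.class_label!r}"
            )


def class_coefficients(class_label: str, config: SimulationConfig):
    """(b2, b3) implied by a class label under the configured effect sizes."""
    b2e, b3e = config.beta2_effect, config.beta3_effect
    table = {
        "null": (0.0, 0.0),
        "c1_only": (b2e, -b2e),       # c2 contrast b2+b3 = 0
        "c2_only": (0.0, b3e),        # c2 contrast = beta3_effect
        "shared": (b2e, b3e - b2e),   # c2 contrast = beta3_effect
    }
    return table[class_label]


def assign_gene_classes(n_genes: int, fractions, rng: np.random.Generator):
    """Apportion ``n_genes`` into the four classes by largest remainder.

    Counts are exact largest-remainder apportionment (ties broken by class
    order null, c1_only, c2_only, shared); the returned label order is
    shuffled by ``rng``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (4,) or np.any(fractions < 0):
        raise ConfigError("fractions must be four non-negative numbers")
    if abs(fractions.sum() - 1.0) > 1e-12:
        raise ConfigError("fractions must sum to 1")
    quota = n_genes * fractions
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n_genes - counts.sum()
    # stable sort descending on remainder => ties resolved by class order
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    labels = np.repeat(CLASS_ORDER, counts)
    rng.shuffle(labels)
    return list(labels)


def simulate_survival(
    linear_predictor,
    baseline_rate: float,
    censor_rate: float,
    rng: np.random.Generator,
    weibull_shape: float = 1.0,
    admin_cutoff: Optional[float] = None,
):
    """Draw (time, event) per sample under a proportional-hazards model.

    Event times follow cumulative hazard ``(baseline_rate * t)**shape *
    exp(lp)`` (exponential when shape is 1); censoring is an independent
    Exponential(censor_rate), optionally truncated at an administrative
    cutoff.  Returns ``(min(T, C), 1 if T <= C else 0)`` arrays.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    if baseline_rate <= 0 or weibull_shape <= 0:
        raise ValueError("baseline_rate and weibull_shape must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    e = rng.exponential(size=lp.shape)
    t_event = (e * np.exp(-lp)) ** (1.0 / weibull_shape) / baseline_rate
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=lp.shape)
    else:
        t_cens = np.full(lp.shape, np.inf)
    if admin_cutoff is not None:
        t_cens = np.minimum(t_cens, admin_cutoff)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _base_cohort(config: SimulationConfig, rng: np.random.Generator):
    """Sample ids, subtype labels/indicator, expression, class labels."""
    n = config.n_c1 + config.n_c2
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    subtype = np.array(["c1"] * config.n_c1 + ["c2"] * config.n_c2)
    i_c2 = (subtype == "c2").astype(float)
    classes = assign_gene_classes(config.n_genes, config.fractions, rng)
    x = rng.normal(config.expr_mean, config.expr_sd, size=(config.n_genes, n))
    return sample_ids, subtype, i_c2, classes, x


def _emit_matrix(x: np.ndarray, config: SimulationConfig, sample_ids):
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    if config.emit == "fpkm":
        values = np.maximum(2.0 ** x - 1.0, 0.0)
        tag = RAW
    else:
        values = x
        tag = LOG2P1
    return ExpressionMatrix(gene_ids, sample_ids, values, tag)


def _gene_lp(x_row, i_c2, b2, b3, config):
    xc = x_row - config.expr_mean
    return b2 * xc + b3 * i_c2 * xc


def generate_cohort(config: SimulationConfig):
    """Shared-outcome cohort: one clinical table for all genes.

    Up to ``config.n_drivers`` genes are drawn (rng) from the planted
    signal genes and entered jointly into the hazard; remaining signal
    genes have no effect on the outcome and are therefore relabelled
    ``null`` in the returned truth.

    Returns ``(ExpressionMatrix, clinical DataFrame, list[GeneTruth])``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_ids, subtype, i_c2, classes, x = _base_cohort(config, rng)
    matrix = _emit_matrix(x, config, sample_ids)

    signal = [g for g, c in enumerate(classes) if c != "null"]
    k = min(config.n_drivers, len(signal))
    drivers = set(rng.choice(signal, size=k, replace=False)) if k else set()

    lp = config.beta1 * i_c2
    truths = []
    for g, cls in enumerate(classes):
        if cls != "null" and g not in drivers:
            cls = "null"
        b2, b3 = class_coefficients(cls, config)
        if g in drivers:
            lp = lp + _gene_lp(x[g], i_c2, b2, b3, config)
        truths.append(
            GeneTruth(matrix.feature_ids[g], cls, config.beta1, b2, b3,
                      driver=g in drivers)
        )
    time, event = simulate_survival(
        lp, config.baseline_rate, config.censor_rate, rng,
        config.weibull_shape, config.admin_cutoff,
    )
    clinical = pd.DataFrame(
        {"sample_id": sample_ids, "os_time": time, "os_event": event,
         "subtype": subtype}
    )
    return matrix, clinical, truths


def generate_matched_cohort(config: SimulationConfig):
    """Per-gene matched design: one survival realisation per gene.

    Every gene is the sole driver of its own outcome, so the per-gene
    screening model is exactly correctly specified for each gene.

    Returns ``(ExpressionMatrix, subtype array, times, events, truths)``
    where ``times`` and ``events`` are (n_genes, n_samples) arrays.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_ids, subtype, i_c2, classes, x = _base_cohort(config, rng)
    matrix = _emit_matrix(x, config, sample_ids)

    n = len(sample_ids)
    times = np.empty((config.n_genes, n))
    events = np.empty((config.n_genes, n), dtype=int)
    truths = []
    for g, cls in enumerate(classes):
        b2, b3 = class_coefficients(cls, config)
        lp = config.beta1 * i_c2 + _gene_lp(x[g], i_c2, b2, b3, config)
        times[g], events[g] = simulate_survival(
            lp, config.baseline_rate, config.censor_rate, rng,
            config.weibull_shape, config.admin_cutoff,
        )
        truths.append(
            GeneTruth(matrix.feature_ids[g], cls, config.beta1, b2, b3)
        )
    return matrix, subtype, times, events, truths


def truths_to_frame(truths) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "class_label": [t.class_label for t in truths],
            "true_beta1": [t.true_beta1 for t in truths],
            "true_beta2": [t.true_beta2 for t in truths],
            "true_beta3": [t.true_beta3 for t in truths],
            "driver": [int(t.driver) for t in truths],
        }
    )


def write_truth_tsv(truths, path) -> None:
    truths_to_frame(truths).to_csv(path, sep="\t", index=False,
                                   float_format="%.10g")
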