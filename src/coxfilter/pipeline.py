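"""Reproducible pipeline: simulate -> preprocess -> screen -> evaluate.

A single YAML config drives all stages; in synthetic mode the run ends
with a recovery report scoring the screen against the simulator's planted
truth.  Identical config + seed reproduces byte-identical output tables;
a manifest (config hash, seed, library versions) records provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ConfigError,
    DataError,
    ExpressionMatrix,
    LOG2P1,
    RAW,
    read_clinical_tsv,
    write_clinical_tsv,
)
from .evaluate import evaluate_signature, wilcoxon_test
from .preprocess import prepare
from .screening import ScreenResult, screen_genes, screen_genes_matched
from .simulate import (
    GeneTruth,
    SimulationConfig,
    generate_cohort,
    generate_matched_cohort,
    truths_to_frame,
    write_truth_tsv,
)

log = logging.getLogger("coxfilter")


@dataclass
class RecoveryReport:
    """Screen performance against the simulator's planted truth.

    Each of the two screened sets is scored against its generative truth:
    ``set_c1`` against {true b2 != 0}, ``set_c2`` against
    {true b2 + b3 != 0}.  The confusion table crosses assigned labels with
    planted classes.  Empirical FDR is None (reported as NA) when a set is
    empty.  Unfit genes are excluded from the counts and reported
    separately.
    """

    per_set: dict           # {"c1": {tp, fp, fn, tn, fdr, sensitivity}, "c2": ...}
    sensitivity_by_class: dict
    confusion: pd.DataFrame
    n_genes: int
    n_unfit: int

    def to_dict(self) -> dict:
        return {
            "per_set": self.per_set,
            "sensitivity_by_class": self.sensitivity_by_class,
            "confusion": self.confusion.to_dict(),
            "n_genes": self.n_genes,
            "n_unfit": self.n_unfit,
        }


def _set_scores(selected: set, positives: set, universe: list) -> dict:
    tp = len(selected & positives)
    fp = len(selected - positives)
    fn = len(positives - selected)
    tn = len(universe) - tp - fp - fn
    n_sel = tp + fp
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "fdr": (fp / n_sel) if n_sel else None,
        "sensitivity": (tp / len(positives)) if positives else None,
    }


def score_recovery(screen: ScreenResult, truths: list) -> RecoveryReport:
    """Score a screen's sets and labels against planted gene classes."""
    truth_by_id = {t.gene_id: t for t in truths}
    table = screen.table
    # screened genes may be a subset of the truth (low-expression filtering)
    if not set(table["gene_id"]) <= set(truth_by_id):
        raise DataError("screen contains gene ids absent from the truth")
    fitted = table[table["label"] != "unfit"]
    universe = list(fitted["gene_id"])
    pos_c1 = {g for g in universe if truth_by_id[g].true_beta2 != 0}
    pos_c2 = {
        g for g in universe
        if truth_by_id[g].true_beta2 + truth_by_id[g].true_beta3 != 0
    }
    per_set = {
        "c1": _set_scores(screen.set_c1 & set(universe), pos_c1, universe),
        "c2": _set_scores(screen.set_c2 & set(universe), pos_c2, universe),
    }
    classes = ("null", "c1_only", "c2_only", "shared")
    labels = ("c1_specific", "c2_specific", "shared", "none")
    confusion = pd.DataFrame(0, index=labels, columns=classes)
    sens = {}
    expected = {"c1_only": "c1_specific", "c2_only": "c2_specific",
                "shared": "shared"}
    for _, row in fitted.iterrows():
        cls = truth_by_id[row["gene_id"]].class_label
        confusion.loc[row["label"], cls] += 1
    for cls, lab in expected.items():
        total = int(confusion[cls].sum())
        sens[cls] = (int(confusion.loc[lab, cls]) / total) if total else None
    return RecoveryReport(
        per_set, sens, confusion,
        n_genes=len(table), n_unfit=int((table["label"] == "unfit").sum()),
    )


# ---------------------------------------------------------------------------
# config

@dataclass
class PipelineConfig:
    """Full-run configuration (see README for the YAML layout)."""

    mode: str = "synthetic"                      # or "tsv"
    simulation: Optional[SimulationConfig] = None
    expr_path: Optional[str] = None
    clinical_path: Optional[str] = None
    expr_scale: str = RAW
    fpkm_threshold: float = 4.0
    require: tuple = ("os_time", "os_event", "subtype")
    alpha: float = 0.05
    ties_method: str = "efron"
    adjust_family: str = "separate"
    top_k: int = 10
    split: str = "none"                          # or "holdout"
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("synthetic", "tsv"):
            raise ConfigError(f"unknown pipeline mode {self.mode!r}")
        if self.mode == "tsv" and not (self.expr_path and self.clinical_path):
            raise ConfigError("tsv mode requires expr_path and clinical_path")
        if not 0 <= self.alpha <= 1:
            raise ConfigError("alpha must lie in [0, 1]")
        if self.split not in ("none", "holdout"):
            raise ConfigError(f"unknown split mode {self.split!r}")
        if self.mode == "synthetic":
            (self.simulation or SimulationConfig()).validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"simulation"}
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            cfg = dataclasses.replace(cfg, simulation=SimulationConfig(**sim))
        if "require" in raw:
            cfg = dataclasses.replace(cfg, require=tuple(raw["require"]))
        return cfg.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["require"] = list(self.require)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def run_pipeline(config: PipelineConfig, out_dir, seed: Optional[int] = None):
    """Execute all stages and write every table under ``out_dir``.

    Returns a dict of in-memory stage results.  ``seed`` overrides the
    config seed (both the pipeline's and the simulation's).
    """
    config.validate()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
        if config.simulation is not None:
            config = dataclasses.replace(
                config, simulation=dataclasses.replace(
                    config.simulation, seed=seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    truths = None
    matched = None

    if config.mode == "synthetic":
        sim = config.simulation or SimulationConfig(seed=config.seed)
        sim.validate()
        if sim.mode == "matched":
            if sim.emit != "log2":
                raise ConfigError(
                    "matched-mode pipeline requires emit='log2': feature "
                    "filtering would break the per-gene survival panel")
            matrix, subtype, times, events, truths = generate_matched_cohort(sim)
            matched = (subtype, times, events)
            clinical = pd.DataFrame({
                "sample_id": matrix.sample_ids, "subtype": subtype})
            pd.DataFrame(times, index=matrix.feature_ids,
                         columns=matrix.sample_ids).to_csv(
                out / "survival_times.tsv", sep="\t", float_format="%.10g")
            pd.DataFrame(events, index=matrix.feature_ids,
                         columns=matrix.sample_ids).to_csv(
                out / "survival_events.tsv", sep="\t")
        else:
            matrix, clinical, truths = generate_cohort(sim)
        matrix.write_tsv(out / "expression.tsv")
        if matched is None:
            write_clinical_tsv(clinical, out / "clinical.tsv")
        else:
            clinical.to_csv(out / "samples.tsv", sep="\t", index=False)
        write_truth_tsv(truths, out / "truth.tsv")
        log.info("simulate: %d genes x %d samples (mode=%s)",
                 matrix.n_features, matrix.n_samples, sim.mode)
    else:
        matrix = ExpressionMatrix.read_tsv(config.expr_path, config.expr_scale)
        clinical = read_clinical_tsv(config.clinical_path)
        log.info("load: %d genes x %d samples", matrix.n_features,
                 matrix.n_samples)

    n_before = (matrix.n_features, matrix.n_samples)
    if matrix.scale_tag == RAW or config.mode == "tsv":
        matrix, clinical = prepare(
            matrix, clinical, config.fpkm_threshold, config.require)
    log.info("preprocess: %d->%d genes, %d->%d samples",
             n_before[0], matrix.n_features, n_before[1], matrix.n_samples)
    matrix.write_tsv(out / "expression_prepared.tsv")

    if matched is not None:
        subtype, times, events = matched
        screen = screen_genes_matched(
            matrix, subtype, times, events, alpha=config.alpha,
            ties_method=config.ties_method, adjust_family=config.adjust_family)
    else:
        screen = screen_genes(
            matrix, clinical, alpha=config.alpha,
            ties_method=config.ties_method, adjust_family=config.adjust_family)
    screen.write_tsv(out / "screen_results.tsv")
    log.info("screen: |set_c1|=%d |set_c2|=%d overlap=%d unfit=%d",
             len(screen.set_c1), len(screen.set_c2), len(screen.overlap),
             int((screen.table["label"] == "unfit").sum()))
    results["screen"] = screen

    if truths is not None:
        report = score_recovery(screen, truths)
        with open(out / "recovery_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True,
                      default=_json_default)
        report.confusion.to_csv(out / "confusion.tsv", sep="\t")
        results["recovery"] = report
        log.info("recovery: FDR c1=%s c2=%s", report.per_set["c1"]["fdr"],
                 report.per_set["c2"]["fdr"])

    # signature evaluation on the top genes of the shared-outcome cohort
    if matched is None:
        hits = screen.table[screen.table["label"].isin(
            ("c1_specific", "c2_specific", "shared"))].copy()
        if len(hits):
            hits["best_padj"] = hits[["padj_c1", "padj_c2"]].min(axis=1)
            genes = list(hits.sort_values(
                ["best_padj", "gene_id"]).head(config.top_k)["gene_id"])
            train_ids = None
            if config.split == "holdout":
                rng = np.random.default_rng(config.seed)
                ids = np.array(matrix.sample_ids)
                train_ids = set(rng.choice(
                    ids, size=len(ids) // 2, replace=False))
            ev = evaluate_signature(matrix, clinical, genes,
                                    config.ties_method, train_ids)
            n_eval = len(ev.scores)
            eval_ids = (matrix.sample_ids if train_ids is None else
                        [s for s in matrix.sample_ids if s not in train_ids])
            pd.DataFrame({
                "sample_id": eval_ids, "score": ev.scores, "group": ev.groups,
            }).to_csv(out / "risk_scores.tsv", sep="\t", index=False,
                      float_format="%.10g")
            for lev, curve in ev.km.items():
                curve.to_frame().to_csv(out / f"km_{lev}.tsv", sep="\t",
                                        index=False, float_format="%.10g")
            sub = clinical["subtype"].to_numpy()
            wilcoxon_rows = []
            for gid in genes:
                stat, p = wilcoxon_test(matrix.row(gid)[sub == sub[0]],
                                        matrix.row(gid)[sub != sub[0]])
                wilcoxon_rows.append({"gene_id": gid, "U": stat, "p": p})
            summary = pd.DataFrame({
                "test": ["logrank_high_vs_low"], "statistic": [ev.logrank_chi2],
                "p": [ev.logrank_p], "n": [n_eval],
            })
            summary.to_csv(out / "tests_summary.tsv", sep="\t", index=False,
                           float_format="%.10g")
            pd.DataFrame(wilcoxon_rows).to_csv(
                out / "wilcoxon_subtype.tsv", sep="\t", index=False,
                float_format="%.10g")
            results["signature"] = ev
            log.info("evaluate: %d signature genes, log-rank p=%.3g",
                     len(genes), ev.logrank_p)
        else:
            log.info("evaluate: no significant genes; skipped")

    import coxfilter
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "coxfilter": coxfilter.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
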