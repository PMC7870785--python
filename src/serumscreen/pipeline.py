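"""End-to-end screening pipeline: simulate -> MoM -> risk -> evaluate.

Orchestrates the library modules into one reproducible run that writes
plain-text reports: the cohort table, per-subject MoM and risk tables,
a group-summary report (medians, log10 MoM means/SDs, correlations), a
diagnostic-performance report per trisomy (AUC, Youden cutoff,
sensitivity/specificity, predictive values, likelihood ratios, detection
rate at the target false-positive rate), logistic-regression odds
ratios, and ROC point files for plotting.  Every report row carries a
hash of the configuration so outputs are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SimulationConfig, default_config, generate_cohort
from .metrics import (
    detection_rate_at_fpr,
    logistic_fit,
    roc_curve,
    youden_cutoff,
)
from .mom import MedianNormalizer
from .params import MARKERS
from .risk import DEFAULT_PRIORS, PriorModel, score_cohort
from .stats import group_summary_table, summarize_group

logger = logging.getLogger("serumscreen")

COHORT_COLUMNS = [
    "subject_id", "group", "age", "weight", "gestational_week",
    "afp", "free_bhcg", "ue3", "shla_g",
]
VALID_GROUPS = ("control", "T21", "T18")
_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    simulation: SimulationConfig
    weight_model: str = "identity"
    priors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIORS)
    )
    use_correlations: bool = False
    risk_threshold: float = 0.01
    target_fpr: float = 0.05
    output_dir: str | Path = "screening_run"

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fpr < 1.0:
            raise ValueError("target_fpr must be in (0, 1)")

    def hash(self) -> str:
        payload = {
            "group_sizes": self.simulation.group_sizes,
            "seed": self.simulation.seed,
            "weight_model": self.weight_model,
            "priors": self.priors,
            "use_correlations": self.use_correlations,
            "risk_threshold": self.risk_threshold,
            "target_fpr": self.target_fpr,
            "params": {
                g: p.to_dict() for g, p in self.simulation.group_params.items()
            },
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return digest[:12]


def default_pipeline_config(
    seed: int = 0, output_dir: str | Path = "screening_run"
) -> PipelineConfig:
    return PipelineConfig(simulation=default_config(seed), output_dir=output_dir)


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; numeric formatting is stable for round-trips."""
    records[COHORT_COLUMNS].to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors carry the offending line."""
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        if row.group not in VALID_GROUPS:
            raise ValueError(
                f"{path}: line {i}: unknown group label {row.group!r}"
            )
        if not 15 <= int(row.gestational_week) <= 19:
            raise ValueError(
                f"{path}: line {i}: gestational_week outside 15-19"
            )
        for marker in MARKERS:
            value = getattr(row, marker)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{path}: line {i}: non-positive {marker} level {value!r}"
                )
    frame["gestational_week"] = frame["gestational_week"].astype(int)
    return frame


def _mom_long_table(cohort: pd.DataFrame, mom: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for marker in MARKERS:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"].to_numpy(),
                    "marker": marker,
                    "mom": mom[f"{marker}_mom"].to_numpy(),
                    "log10_mom": mom[f"{marker}_log10_mom"].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _evaluate_trisomy(
    trisomy: str,
    cohort: pd.DataFrame,
    mom: pd.DataFrame,
    risks: pd.DataFrame,
    target_fpr: float,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-marker and risk-score diagnostic metrics for one trisomy."""
    mask = cohort["group"].isin(["control", trisomy]).to_numpy()
    labels = (cohort.loc[mask, "group"] == trisomy).astype(int).to_numpy()
    rows = []
    roc_points: dict[str, pd.DataFrame] = {}
    scored = risks[risks["trisomy"] == trisomy].set_index("subject_id")
    posterior = scored.loc[
        cohort.loc[mask, "subject_id"], "posterior"
    ].to_numpy()
    score_sets = {
        f"{marker}_mom": mom.loc[mask, f"{marker}_mom"].to_numpy()
        for marker in MARKERS
    }
    score_sets["risk_posterior"] = posterior
    for name, scores in score_sets.items():
        roc = roc_curve(
            scores, labels,
            direction="higher_is_positive" if name == "risk_posterior" else "auto",
        )
        best = youden_cutoff(roc)
        dr, dr_cut = detection_rate_at_fpr(
            scores, labels, target_fpr, direction=roc.direction
        )
        rows.append(
            {
                "trisomy": trisomy,
                "score": name,
                "direction": roc.direction,
                "cutoff": best.cutoff,
                "auc": roc.auc,
                "auc_se": roc.se,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "p_value": roc.p_value,
                "sensitivity": best.sensitivity,
                "specificity": best.specificity,
                "ppv": best.ppv,
                "npv": best.npv,
                "plr": best.plr,
                "nlr": best.nlr,
                f"detection_rate_at_fpr_{target_fpr:g}": dr,
                "detection_cutoff": dr_cut,
            }
        )
        roc_points[name] = roc.points
    return pd.DataFrame(rows), roc_points


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full pipeline and write all reports under ``output_dir``.

    Returns a mapping of artifact names to paths.  Reruns with the same
    configuration are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    artifacts: dict[str, Path] = {}
    log_lines = [
        f"config_hash={cfg_hash}",
        f"seed={config.simulation.seed}",
        f"group_sizes={json.dumps(config.simulation.group_sizes, sort_keys=True)}",
        f"weight_model={config.weight_model}",
        f"use_correlations={config.use_correlations}",
        f"priors={json.dumps(config.priors, sort_keys=True)}",
        f"risk_threshold={config.risk_threshold:g}",
        f"target_fpr={config.target_fpr:g}",
    ]

    cohort = generate_cohort(config.simulation)
    artifacts["cohort"] = out / "cohort.csv"
    write_cohort_csv(cohort, artifacts["cohort"])

    normalizer = MedianNormalizer(weight_model=config.weight_model).fit(cohort)
    mom = normalizer.transform(cohort)
    artifacts["mom"] = out / "mom.csv"
    _mom_long_table(cohort, mom).to_csv(
        artifacts["mom"], index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )

    summary = group_summary_table(cohort, mom)
    summary["config_hash"] = cfg_hash
    artifacts["group_summary"] = out / "group_summary.csv"
    summary.to_csv(
        artifacts["group_summary"], float_format=_FLOAT_FMT, lineterminator="\n"
    )

    counts = cohort["group"].value_counts()
    present = [
        t for t in ("T21", "T18") if counts.get(t, 0) >= 2
    ]
    for t in ("T21", "T18"):
        if t not in present:
            msg = f"group {t} absent or too small; its evaluation is skipped"
            logger.info(msg)
            log_lines.append(f"notice={msg}")
    if counts.get("control", 0) < 2:
        raise ValueError("pipeline needs at least 2 control subjects")

    params_by_group = {
        g: summarize_group(
            mom.loc[(cohort["group"] == g).to_numpy()], g
        )
        for g in ["control", *present]
    }
    priors = {
        t: PriorModel(flat_prior=config.priors.get(t, DEFAULT_PRIORS[t]))
        for t in present
    }
    if present:
        risks = score_cohort(
            cohort,
            normalizer.median_curve_,
            params_by_group,
            priors,
            threshold=config.risk_threshold,
            use_correlations=config.use_correlations,
            trisomies=tuple(present),
        )
        risks["config_hash"] = cfg_hash
        artifacts["risk"] = out / "risk.csv"
        risks.to_csv(
            artifacts["risk"], index=False, float_format=_FLOAT_FMT,
            lineterminator="\n",
        )

        eval_rows = []
        for trisomy in present:
            table, roc_points = _evaluate_trisomy(
                trisomy, cohort, mom, risks, config.target_fpr
            )
            eval_rows.append(table)
            for name, points in roc_points.items():
                key = f"roc_{trisomy}_{name}"
                artifacts[key] = out / f"{key}.csv"
                points.to_csv(
                    artifacts[key], index=False, float_format=_FLOAT_FMT,
                    lineterminator="\n",
                )
        evaluation = pd.concat(eval_rows, ignore_index=True)
        evaluation["config_hash"] = cfg_hash
        artifacts["evaluation"] = out / "evaluation.csv"
        evaluation.to_csv(
            artifacts["evaluation"], index=False, float_format=_FLOAT_FMT,
            lineterminator="\n",
        )

        logistic_rows = []
        for trisomy in present:
            mask = cohort["group"].isin(["control", trisomy]).to_numpy()
            covs = pd.DataFrame(
                {
                    "age": cohort.loc[mask, "age"].to_numpy(),
                    "weight": cohort.loc[mask, "weight"].to_numpy(),
                    **{
                        f"{m}_mom": mom.loc[mask, f"{m}_mom"].to_numpy()
                        for m in MARKERS
                    },
                }
            )
            outcome = (cohort.loc[mask, "group"] == trisomy).astype(int)
            fit = logistic_fit(covs, outcome.to_numpy())
            tab = fit.table.copy()
            tab.insert(0, "trisomy", trisomy)
            tab["converged"] = fit.converged
            logistic_rows.append(tab)
        logistic = pd.concat(logistic_rows)
        logistic["config_hash"] = cfg_hash
        artifacts["logistic"] = out / "logistic.csv"
        logistic.to_csv(
            artifacts["logistic"], float_format=_FLOAT_FMT, lineterminator="\n"
        )

    artifacts["run_log"] = out / "run_log.txt"
    artifacts["run_log"].write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return artifacts
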