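"""Report assembly: group contrasts, AUC table, cut-off metrics, correlations.

`evaluate_scores` turns a long-format score table into the four result tables;
`run_report` is the end-to-end path from typed cohort records to files on
disk.  Output is deterministic given the cohort and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .diagnostics import (
    confusion_at_cutoff,
    empirical_roc,
    group_summary,
    pearson_correlation,
)
from .errors import DegenerateDataError, MsofaError
from .io import provenance_line, score_cohort
from .types import CohortRecord, Instrument, Timepoint

__all__ = ["RunConfig", "evaluate_scores", "run_report"]

log = logging.getLogger("msofa")


@dataclass
class RunConfig:
    """Options shared by the evaluate/report pipeline."""

    out_dir: Path
    instruments: Sequence[Instrument] = (Instrument.SOFA, Instrument.MSOFA)
    timepoints: Sequence[Timepoint] = (Timepoint.T0, Timepoint.T24, Timepoint.T48)
    cutoff: Optional[float] = None  # override; default is the Youden cut-off
    seed: int = 0
    verbose: bool = False

    def config_items(self) -> dict:
        return {
            "instruments": ",".join(Instrument(i).value for i in self.instruments),
            "timepoints": ",".join(Timepoint(t).value for t in self.timepoints),
            "cutoff": self.cutoff,
        }


def evaluate_scores(scores: pd.DataFrame, config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Compute the evaluation tables from a long score table.

    Expects columns patient_id, timepoint, instrument, total, outcome.  Raises
    on a single-class cohort before producing any table, so no partial results
    escape.
    """
    required = {"patient_id", "timepoint", "instrument", "total", "outcome"}
    missing = required - set(scores.columns)
    if missing:
        raise MsofaError(f"score table missing column(s): {', '.join(sorted(missing))}")
    if scores["outcome"].nunique() < 2:
        raise DegenerateDataError(
            "cohort contains a single outcome class; ROC evaluation is undefined"
        )

    instruments = [Instrument(i).value for i in config.instruments]
    timepoints = [Timepoint(t).value for t in config.timepoints]

    group_rows, auc_rows, cut_rows, corr_rows = [], [], [], []
    for tp in timepoints:
        for inst in instruments:
            sub = scores[(scores.timepoint == tp) & (scores.instrument == inst)]
            if sub.empty:
                continue
            totals = sub["total"].to_numpy(float)
            outcomes = sub["outcome"].tolist()
            gs = group_summary(totals, outcomes)
            group_rows.append(
                {
                    "instrument": inst, "timepoint": tp,
                    "n_deceased": gs.n_deceased, "n_survived": gs.n_survived,
                    "mean_deceased": round(gs.mean_deceased, 4),
                    "sd_deceased": round(gs.sd_deceased, 4),
                    "mean_survived": round(gs.mean_survived, 4),
                    "sd_survived": round(gs.sd_survived, 4),
                    "p_value": float(f"{gs.p_value:.3e}"),
                }
            )
            roc = empirical_roc(totals, outcomes)
            auc_rows.append(
                {
                    "instrument": inst, "timepoint": tp,
                    "auc": round(roc.auc, 4), "auc_se": round(roc.auc_se, 4),
                    "ci95_low": round(roc.ci95[0], 4), "ci95_high": round(roc.ci95[1], 4),
                }
            )
            cutoff = config.cutoff if config.cutoff is not None else roc.chosen_cutoff
            cm = confusion_at_cutoff(totals, outcomes, cutoff)
            cut_rows.append(
                {
                    "instrument": inst, "timepoint": tp, "cutoff": cutoff,
                    "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                    "sensitivity": round(cm.sensitivity, 4),
                    "specificity": round(cm.specificity, 4),
                    "ppv": round(cm.ppv, 4), "npv": round(cm.npv, 4),
                    "youden_j": round(cm.youden_j, 4),
                    "dor": (round(cm.diagnostic_odds_ratio, 4)
                            if math.isfinite(cm.diagnostic_odds_ratio)
                            else cm.diagnostic_odds_ratio),
                }
            )
        if {"sofa", "msofa"} <= set(instruments):
            wide = scores[scores.timepoint == tp].pivot_table(
                index="patient_id", columns="instrument", values="total"
            )
            if {"sofa", "msofa"} <= set(wide.columns) and len(wide) >= 3:
                r, p = pearson_correlation(wide["sofa"].to_numpy(), wide["msofa"].to_numpy())
                corr_rows.append(
                    {"timepoint": tp, "r": round(r, 4), "p_value": float(f"{p:.3e}")}
                )

    return {
        "group_summary": pd.DataFrame(group_rows),
        "auc_table": pd.DataFrame(auc_rows),
        "cutoff_report": pd.DataFrame(cut_rows),
        "correlations": pd.DataFrame(corr_rows),
    }


def _pretty_text(tables: Dict[str, pd.DataFrame], header: str) -> str:
    lines = [header, ""]
    titles = {
        "group_summary": "Score totals by outcome group (mean ± SD, Welch t)",
        "auc_table": "Discrimination: AUC with 95% CI",
        "cutoff_report": "Operating cut-offs and diagnostic metrics",
        "correlations": "SOFA-MSOFA Pearson correlation by timepoint",
    }
    for key, title in titles.items():
        df = tables[key]
        lines += [title, "-" * len(title), df.to_string(index=False) if not df.empty else "(empty)", ""]
    return "\n".join(lines) + "\n"


def write_tables(tables: Dict[str, pd.DataFrame], config: RunConfig) -> Dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = provenance_line(config.seed, config.config_items())
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        with p.open("w", newline="") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, index=False)
        paths[name] = p
    text_path = out / "report.txt"
    text_path.write_text(_pretty_text(tables, header))
    paths["report"] = text_path
    return paths


def run_report(records: Sequence[CohortRecord], config: RunConfig) -> Dict[str, Path]:
    """Score the cohort with both instruments and write all report files."""
    log.info("scoring %d records", len(records))
    scores = score_cohort(records, config.instruments)
    tables = evaluate_scores(scores, config)
    log.info("writing report to %s", config.out_dir)
    return write_tables(tables, config)
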