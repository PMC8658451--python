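"""End-to-end orchestration: study in, Tables-shaped CSVs out.

The full analysis mirrors the schematic: average reference -> per-band
zero-phase filtering -> per-epoch Hilbert-phase PLI -> per-epoch Kruskal
MST and metrics -> epoch-averaged subject x condition x band summaries ->
2x2 mixed ANOVAs with BH-FDR across the metric family, per-condition
follow-up contrasts, and PLI ~ relative-power regressions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import band_mean_pli
from .core import CONDITIONS, DEFAULT_BANDS, BandSpec, StudyDesign
from .mst import subject_band_metrics
from .preprocess import TOTAL_POWER_RANGE, average_reference, bandpass, relative_power
from .stats import (
    bh_fdr,
    mixed_anova_2x2,
    per_condition_group_test,
    regress_pli_on_power,
    stepwise_regression,
)

__all__ = ["AnalysisConfig", "AnalysisResults", "run_full_analysis", "export_tables"]

log = logging.getLogger("eegmst.pipeline")

#: MST metrics entering the statistical family by default.
DEFAULT_STAT_METRICS = (
    "degree_max_norm",
    "leaf_fraction",
    "diameter_norm",
    "eccentricity_mean_norm",
    "bc_max",
    "tree_hierarchy",
    "degree_correlation",
    "kappa",
    "mst_mean",
)


@dataclass
class AnalysisConfig:
    """Validated configuration of a full analysis run.

    ``stat_bands`` restricts the statistical family (delta is computed and
    reported but excluded from inference by default); ``fdr_q`` lists the
    FDR levels to flag (lenient 0.10 and strict 0.05). The config hash and
    seed are embedded in every output CSV for provenance.
    """

    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    total_power_range: tuple[float, float] = TOTAL_POWER_RANGE
    stat_bands: tuple[str, ...] = ("theta", "alpha", "beta")
    metrics: tuple[str, ...] = DEFAULT_STAT_METRICS
    fdr_q: tuple[float, ...] = (0.10, 0.05)
    alpha: float = 0.05
    seed: int = 0
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        names = {b.name for b in self.bands}
        missing = set(self.stat_bands) - names
        if missing:
            raise ValueError(f"stat_bands not among analyzed bands: {sorted(missing)}")
        if any(not (0 < q < 1) for q in self.fdr_q):
            raise ValueError("FDR q levels must lie in (0, 1)")

    def hash(self) -> str:
        payload = json.dumps(
            {
                "bands": [(b.name, b.lo, b.hi) for b in self.bands],
                "total": self.total_power_range,
                "stat_bands": self.stat_bands,
                "metrics": self.metrics,
                "fdr_q": self.fdr_q,
                "alpha": self.alpha,
                "seed": self.seed,
            },
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisResults:
    """Bundle of per-subject summaries and group-level tables."""

    subject_table: pd.DataFrame
    omnibus: pd.DataFrame
    followups: pd.DataFrame
    regressions: pd.DataFrame
    stepwise: pd.DataFrame | None = None
    errors: dict = field(default_factory=dict)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def _subject_rows(design: StudyDesign, config: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    cache_path = None
    if config.cache_dir:
        cache_path = Path(config.cache_dir) / f"subject_table_{config.hash()}.csv"
        if cache_path.exists():
            log.info("loading cached subject table %s", cache_path)
            return pd.read_csv(cache_path, comment="#"), {}

    rows, errors = [], {}
    for (sid, condition), rec in sorted(design.recordings.items()):
        t0 = time.perf_counter()
        try:
            ref = average_reference(rec)
            for band in config.bands:
                power = relative_power(ref, band, *config.total_power_range)
                rec_band = bandpass(ref, band)
                metrics = subject_band_metrics(rec_band)
                row = {
                    "subject": sid,
                    "group": rec.group,
                    "condition": condition,
                    "band": band.name,
                    "n_epochs": rec.n_epochs,
                    "relative_power": power.relative_power,
                    "pli": band_mean_pli(rec_band),
                }
                row.update({k: metrics[k] for k in metrics})
                rows.append(row)
        except Exception as exc:  # keep going; report per subject
            errors[(sid, condition)] = str(exc)
            log.warning("subject %s/%s failed: %s", sid, condition, exc)
            continue
        log.info(
            "processed %s/%s (%d epochs) in %.2fs",
            sid, condition, rec.n_epochs, time.perf_counter() - t0,
        )
    table = pd.DataFrame(rows)
    if cache_path is not None and len(table):
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(cache_path, index=False)
    return table, errors


def _measure_columns(config: AnalysisConfig) -> list[str]:
    return ["pli", "relative_power", *config.metrics]


def run_full_analysis(
    design: StudyDesign,
    config: AnalysisConfig | None = None,
    behavior: pd.DataFrame | None = None,
) -> AnalysisResults:
    """Run the whole pipeline on a study.

    Per subject x condition x band: relative power, mean total PLI and
    epoch-averaged MST metrics. Group level, per band x measure within
    ``config.stat_bands``: the 2x2 mixed ANOVA (condition, group,
    interaction) with BH-FDR flags across the measure family of each band,
    per-condition follow-up group contrasts, and the PLI ~ relative power
    regression per band x condition.

    ``behavior`` (optional): per-subject outcomes (index = subject id);
    each outcome is regressed on the subjects' EEG measures by stepwise
    selection, separately per group, yielding the stepwise table.

    Deterministic given the design and config.
    """
    config = config or AnalysisConfig()
    subject_table, errors = _subject_rows(design, config)
    if subject_table.empty:
        raise ValueError("no recordings could be analyzed")

    measures = _measure_columns(config)
    omnibus_rows, follow_rows, regress_rows = [], [], []
    for band in config.stat_bands:
        sub = subject_table[subject_table["band"] == band]
        for measure in measures:
            data = sub[["subject", "group", "condition", measure]].dropna()
            piv = data.pivot_table(index="subject", columns="condition", values=measure)
            complete = piv.dropna()
            if complete.shape[0] < 4 or len(data["group"].unique()) < 2:
                continue
            try:
                res = mixed_anova_2x2(
                    data, dv=measure, subject="subject",
                    within="condition", between="group",
                )
            except ValueError:
                continue
            by = {r.effect: r for r in res}
            cond_means = data.groupby("condition")[measure].mean()
            direction = ""
            if {"baseline", "task"} <= set(cond_means.index):
                direction = "up" if cond_means["task"] > cond_means["baseline"] else "down"
            omnibus_rows.append(
                {
                    "band": band,
                    "measure": measure,
                    "task_direction": direction,
                    "F_condition": by["condition"].F,
                    "p_condition": by["condition"].p,
                    "peta2_condition": by["condition"].partial_eta_sq,
                    "F_interaction": by["condition x group"].F,
                    "p_interaction": by["condition x group"].p,
                    "peta2_interaction": by["condition x group"].partial_eta_sq,
                    "F_group": by["group"].F,
                    "p_group": by["group"].p,
                    "peta2_group": by["group"].partial_eta_sq,
                }
            )
            for condition in CONDITIONS:
                d = data[data["condition"] == condition]
                if d["subject"].duplicated().any() or len(d) < 4:
                    continue
                try:
                    ct = per_condition_group_test(d[measure].to_numpy(), d["group"].to_numpy())
                except ValueError:
                    continue
                gm = d.groupby("group")[measure].mean()
                rel = ""
                if {"dyslexic", "typical"} <= set(gm.index):
                    rel = "<" if gm["dyslexic"] < gm["typical"] else ">"
                follow_rows.append(
                    {
                        "band": band,
                        "measure": measure,
                        "condition": condition,
                        "F": ct.F,
                        "p": ct.p,
                        "peta2": ct.partial_eta_sq,
                        "dys_vs_typ": rel,
                    }
                )
        # PLI ~ relative power regression per condition
        for condition in CONDITIONS:
            d = sub[sub["condition"] == condition]
            if len(d) >= 3 and d["relative_power"].std() > 0:
                r, r2, p = regress_pli_on_power(
                    d["pli"].to_numpy(), d["relative_power"].to_numpy()
                )
                regress_rows.append(
                    {"band": band, "condition": condition, "R": r, "R2": r2, "p": p}
                )

    omnibus = pd.DataFrame(omnibus_rows)
    if len(omnibus):
        for effect in ("condition", "interaction", "group"):
            for q in config.fdr_q:
                col = f"fdr_{effect}_q{q:g}"
                omnibus[col] = False
                for band in config.stat_bands:
                    mask = omnibus["band"] == band
                    if mask.any():
                        omnibus.loc[mask, col] = bh_fdr(
                            omnibus.loc[mask, f"p_{effect}"].to_numpy(), q=q
                        )
    followups = pd.DataFrame(follow_rows)
    regressions = pd.DataFrame(regress_rows)

    stepwise_df = None
    if behavior is not None:
        stepwise_df = _stepwise_tables(subject_table, behavior, config)

    return AnalysisResults(
        subject_table=subject_table,
        omnibus=omnibus,
        followups=followups,
        regressions=regressions,
        stepwise=stepwise_df,
        errors=errors,
        config=config,
    )


def _stepwise_tables(
    subject_table: pd.DataFrame, behavior: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Stepwise regression of each behavioral outcome on EEG measures, per group."""
    feats = subject_table[subject_table["band"].isin(config.stat_bands)].pivot_table(
        index="subject",
        columns=["band", "condition"],
        values=["pli", "relative_power"],
    )
    feats.columns = ["_".join(c) for c in feats.columns]
    groups = subject_table.drop_duplicates("subject").set_index("subject")["group"]
    rows = []
    for outcome in behavior.columns:
        for group in sorted(groups.unique()):
            sids = [s for s in feats.index if groups[s] == group and s in behavior.index]
            if len(sids) < 5:
                continue
            X = feats.loc[sids].dropna(axis=1)
            y = behavior.loc[sids, outcome].to_numpy(dtype=float)
            model = stepwise_regression(y, X)
            for i, step in enumerate(model.steps, start=1):
                rows.append(
                    {
                        "outcome": outcome,
                        "group": group,
                        "model": i,
                        "action": step.action,
                        "predictor": step.predictor,
                        "adj_R2": step.adj_r2,
                        "delta_R2": step.delta_r2,
                        "F_change": step.f_change,
                        "p_change": step.p_change,
                        "se_estimate": model.se_estimate,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "outcome", "group", "model", "action", "predictor",
            "adj_R2", "delta_R2", "F_change", "p_change", "se_estimate",
        ],
    )


def export_tables(results: AnalysisResults, outdir: str | Path) -> dict[str, Path]:
    """Write the result bundle as CSVs with a provenance header line.

    Emits the per-subject summary, the omnibus (condition/interaction/
    group) table, the per-condition follow-ups, the PLI ~ power
    regressions, and — when behavioral outcomes were supplied — the
    stepwise table. Empty results yield headers-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = f"# eegmst config_hash={results.config.hash()} seed={results.config.seed}\n"
    tables = {
        "subject_metrics": results.subject_table,
        "omnibus": results.omnibus,
        "followups": results.followups,
        "regressions": results.regressions,
    }
    if results.stepwise is not None:
        tables["stepwise"] = results.stepwise
    written = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(provenance)
            df.to_csv(fh, index=False)
        written[name] = path
    return written
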