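"""Ensemble experiments: many paired simulations, summarised.

Treatment effects are quantified as *paired* relative differences: each
treatment trajectory is compared against the unperturbed control of the
very same network, and the per-pair relative differences are averaged (the
mean of per-pair ratios, which generally differs from the ratio of ensemble
means).  Ensemble means carry normal-approximation 95% confidence
intervals.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .colony_graph import ModelParams
from .measures import MeasureRecord
from .perturbation import run_experiment

ID_COLUMNS = ["network", "arm", "t"]
MEASURE_NAMES = [f.name for f in dc_fields(MeasureRecord)
                 if f.name not in ID_COLUMNS]


def records_to_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        rows.extend(rec.to_dict() for rec in res.records)
    return pd.DataFrame(rows)


def run_ensemble(params: ModelParams, n_networks: int, master_seed: int,
                 workers: int = 1, *, fast: bool = False,
                 return_results: bool = False):
    """Run ``n_networks`` independent paired experiments.

    Seeds are derived hierarchically from ``(master_seed, network index)``,
    so the output is identical for any worker count.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    results = Parallel(n_jobs=workers)(
        delayed(run_experiment)(params, master_seed, network=i, fast=fast)
        for i in range(n_networks))
    frame = records_to_frame(results)
    return (frame, results) if return_results else frame


def to_long(records: pd.DataFrame) -> pd.DataFrame:
    """Wide measure records -> long format keyed by (network, arm, t,
    measure)."""
    measures = [c for c in records.columns
                if c in MEASURE_NAMES]
    return records.melt(id_vars=ID_COLUMNS, value_vars=measures,
                        var_name="measure", value_name="value")


def paired_relative_difference(records: pd.DataFrame) -> pd.DataFrame:
    """Relative difference of each treatment row vs the matched control.

    rel = (x_treat - x_control) / x_control for the same (network, t,
    measure); control rows get 0; pairs with a zero control value are
    missing (NaN).  Input may be wide records or long format.
    """
    long = records if "measure" in records.columns else to_long(records)
    ctrl = long[long["arm"] == "control"] \
        .rename(columns={"value": "control_value"}) \
        .drop(columns=["arm"])
    merged = long.merge(ctrl, on=["network", "t", "measure"], how="left")
    denom = merged["control_value"].where(merged["control_value"] != 0)
    rel = (merged["value"] - merged["control_value"]) / denom
    rel[merged["arm"] == "control"] = 0.0
    out = merged[ID_COLUMNS + ["measure"]].copy()
    out["rel_diff"] = rel
    return out


def aggregate(records: pd.DataFrame,
              value_col: str | None = None) -> pd.DataFrame:
    """Ensemble mean with normal-approximation 95% CI per (arm, t, measure).

    Accepts wide records, long values, or paired relative differences
    (``value_col`` defaults to whichever of ``value``/``rel_diff`` is
    present).  Missing values are dropped with ``n`` adjusted.
    """
    long = records if "measure" in records.columns else to_long(records)
    if value_col is None:
        value_col = "rel_diff" if "rel_diff" in long.columns else "value"
    g = long.groupby(["arm", "t", "measure"])[value_col]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    half = 1.96 * out["sd"] / np.sqrt(out["n"].clip(lower=1))
    out["ci_low"] = out["mean"] - half
    out["ci_high"] = out["mean"] + half
    return out.drop(columns=["sd"])


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Full summary table: ensemble means with CIs joined with the mean
    paired relative differences vs control (in %) and their CIs."""
    means = aggregate(records)
    rel = aggregate(paired_relative_difference(records))
    rel = rel.rename(columns={"mean": "rel_diff_pct",
                              "ci_low": "rel_ci_low_pct",
                              "ci_high": "rel_ci_high_pct"}) \
             .drop(columns=["n"])
    for c in ("rel_diff_pct", "rel_ci_low_pct", "rel_ci_high_pct"):
        rel[c] = 100.0 * rel[c]
    return means.merge(rel, on=["arm", "t", "measure"], how="left")
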