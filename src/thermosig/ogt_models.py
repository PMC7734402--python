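"""Linear models linking composition metrics to optimum growth temperature.

Metrics (16S G+C, CvP, IVYWREL, genome size ...) are regressed on OGT by
ordinary least squares in the ``metric_on_ogt`` orientation (metric on the
y axis, OGT on x, as such comparisons are conventionally plotted).  A
species whose lifestyle changed recently can retain the proteome of its
ancestral thermal class: its point then falls far off the fitted line, and
the signed residual (observed metric minus the value the line predicts at
the species' OGT) quantifies that vestige.

Literature regression lines from larger surveys can be supplied through a
flat key=value config file and used for prediction/residual scoring
alongside lines refitted from any species table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LinearModel:
    metric_name: str
    slope: float
    intercept: float
    orientation: str = "metric_on_ogt"  # or "ogt_on_metric"
    r: Optional[float] = None
    n: Optional[int] = None
    source: str = "fitted"  # or "literature"

    def __post_init__(self):
        if self.orientation not in ("metric_on_ogt", "ogt_on_metric"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.r is not None and not np.isnan(self.r)
                and not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"r out of [-1, 1]: {self.r}")


def fit_linear_model(x, y, metric_name: str = "metric",
                     orientation: str = "metric_on_ogt") -> LinearModel:
    """Ordinary least squares of y on x with Pearson r.

    In the default orientation x is OGT (degrees C) and y the metric.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope undefined")
    res = stats.linregress(x, y)
    return LinearModel(metric_name, res.slope, res.intercept,
                       orientation=orientation, r=res.rvalue, n=int(x.size))


def predict_metric(model: LinearModel, ogt: float) -> float:
    """Metric value the line predicts at a given OGT."""
    if model.orientation == "metric_on_ogt":
        return model.intercept + model.slope * ogt
    if model.slope == 0:
        raise ValueError("slope 0: ogt_on_metric line not invertible for metric")
    return (ogt - model.intercept) / model.slope


def predict_ogt(model: LinearModel, metric_value: float) -> float:
    """OGT (degrees C) the line predicts for a metric value."""
    if model.orientation == "ogt_on_metric":
        return model.intercept + model.slope * metric_value
    if model.slope == 0:
        raise ValueError("slope 0: metric_on_ogt line not invertible for OGT")
    return (metric_value - model.intercept) / model.slope


def ogt_residual(model: LinearModel, metric_value: float,
                 ogt_observed: float) -> float:
    """Observed metric minus the line's prediction at the observed OGT.

    Positive: the species' metric is higher than its growth temperature
    predicts (e.g. a still-thermophilic proteome in a mesophile).
    """
    return metric_value - predict_metric(model, ogt_observed)


def correlate_metric_ogt(table: pd.DataFrame, metric_name: str,
                         method: str = "pearson",
                         ogt_column: str = "ogt_c"):
    """Correlation of one metric with OGT over pairwise-complete rows.

    Returns (coefficient, two-sided p, n_used).
    """
    sub = table[[ogt_column, metric_name]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"only {n} complete rows for {metric_name}; need >= 3")
    if method == "pearson":
        r, p = stats.pearsonr(sub[ogt_column], sub[metric_name])
    elif method == "spearman":
        r, p = stats.spearmanr(sub[ogt_column], sub[metric_name])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# model config (flat key=value): lines transcribed from external surveys


def read_model_config(path) -> dict[str, LinearModel]:
    """Read literature regression lines from a flat key=value file.

    Keys look like ``<metric>.slope``, ``<metric>.intercept`` and optionally
    ``<metric>.orientation`` / ``<metric>.n`` / ``<metric>.r``.  Metrics with
    a missing slope or intercept are ignored (the shipped template leaves
    them blank for the user to transcribe from the cited surveys).
    """
    raw: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = (s.strip() for s in line.split("=", 1))
            if "." not in key or not value:
                continue
            metric, attr = key.rsplit(".", 1)
            raw.setdefault(metric, {})[attr] = value
    models = {}
    for metric, attrs in raw.items():
        if "slope" not in attrs or "intercept" not in attrs:
            continue
        models[metric] = LinearModel(
            metric,
            float(attrs["slope"]),
            float(attrs["intercept"]),
            orientation=attrs.get("orientation", "metric_on_ogt"),
            r=float(attrs["r"]) if "r" in attrs else None,
            n=int(attrs["n"]) if "n" in attrs else None,
            source="literature",
        )
    return models


def residual_table(table: pd.DataFrame, models: dict[str, LinearModel],
                   ogt_column: str = "ogt_c",
                   id_column: str = "species_id") -> pd.DataFrame:
    """Per-species signed residuals against each model's line."""
    rows = []
    for _, row in table.iterrows():
        if pd.isna(row[ogt_column]):
            continue
        entry = {id_column: row[id_column], ogt_column: row[ogt_column]}
        for metric, model in models.items():
            if metric in row and not pd.isna(row[metric]):
                entry[f"{metric}_residual"] = ogt_residual(
                    model, row[metric], row[ogt_column]
                )
        rows.append(entry)
    return pd.DataFrame(rows)


def fit_all_metrics(table: pd.DataFrame, metrics, ogt_column: str = "ogt_c",
                    min_rows: int = 3) -> dict[str, LinearModel]:
    """Fit one metric_on_ogt line per metric over pairwise-complete rows.

    Metrics that are constant or have too few complete rows are skipped.
    """
    models = {}
    for metric in metrics:
        if metric not in table.columns:
            continue
        sub = table[[ogt_column, metric]].dropna()
        if len(sub) < min_rows or np.ptp(sub[ogt_column].to_numpy()) == 0:
            continue
        if np.ptp(sub[metric].to_numpy()) == 0:
            continue
        models[metric] = fit_linear_model(
            sub[ogt_column], sub[metric], metric_name=metric
        )
    return models
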