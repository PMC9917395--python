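"""CSV/YAML/JSON artifact reading and writing."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dditraj.errors import ValidationError
from dditraj.gbtm import GbtmFit
from dditraj.synthetic import CohortBundle, SimConfig

logger = logging.getLogger(__name__)


def read_long_measurements(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long measurement CSV; return (clean rows, error report).

    Requires columns patient_id, day (or timestamp), value.  Rows whose
    value or day fails to parse as a number are collected into the error
    report with a reason rather than silently dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise ValidationError("measurement file lacks column 'patient_id'")
    time_col = "day" if "day" in df.columns else (
        "timestamp" if "timestamp" in df.columns else None)
    if time_col is None:
        raise ValidationError("measurement file needs a 'day' or 'timestamp' column")
    if "value" not in df.columns:
        raise ValidationError("measurement file lacks column 'value'")
    if len(df) == 0:
        logger.warning("measurement file %s is empty", path)
        return df.assign(value=pd.Series(dtype=float)), df.copy()

    value = pd.to_numeric(df["value"], errors="coerce")
    if time_col == "day":
        timeval = pd.to_numeric(df["day"], errors="coerce")
    else:
        timeval = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = value.isna() | timeval.isna()
    errors = df[bad].copy()
    if len(errors):
        errors["reason"] = np.where(value[bad].isna(),
                                    "unparseable value", "unparseable time")
        logger.warning("%d malformed measurement rows routed to error report",
                       len(errors))
    clean = df[~bad].copy()
    clean["value"] = value[~bad]
    clean[time_col] = timeval[~bad]
    return clean, errors


def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Write a cohort bundle as CSVs plus its config as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    meas = bundle.measurements.copy()
    meas["value"] = meas["value"].round(2)
    pid = bundle.covariates["patient_id"].to_numpy()
    artifacts = {
        "measurements.csv": meas,
        "covariates.csv": bundle.covariates,
        "labels.csv": pd.DataFrame(
            {"patient_id": pid, "group": bundle.true_labels.to_numpy()}),
        "outcomes.csv": pd.DataFrame(
            {"patient_id": pid, "death": bundle.outcomes.to_numpy()}),
    }
    for name, df in artifacts.items():
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = str(p)
    if bundle.config is not None:
        p = out / "sim_config.yaml"
        cfg = json.loads(json.dumps(dataclasses.asdict(bundle.config)))
        with open(p, "w") as fh:
            yaml.safe_dump(cfg, fh)
        paths["sim_config.yaml"] = str(p)
    return paths


def fit_to_dict(fit: GbtmFit) -> dict:
    """JSON-serialisable summary of a fitted trajectory model."""
    return {
        "n_groups": fit.spec.n_groups,
        "poly_orders": list(fit.spec.poly_orders),
        "censor": [fit.spec.censor_lo, fit.spec.censor_hi],
        "time_scale": fit.spec.time_scale,
        "beta_scaled": [b.tolist() for b in fit.params.beta],
        "beta_per_day": [b.tolist() for b in
                         fit.params.beta_per_day(fit.spec.time_scale)],
        "sigma": fit.params.sigma,
        "pi": fit.params.pi.tolist(),
        "loglik": fit.loglik,
        "bic": fit.bic,
        "entropy": fit.entropy,
        "appa": [None if np.isnan(v) else float(v) for v in fit.appa],
        "group_props": fit.group_props.tolist(),
        "n_params": fit.n_params,
        "converged": fit.converged,
        "n_starts": fit.n_starts,
        "n_iter": fit.n_iter,
        "seed": fit.seed,
        "warnings": fit.warnings,
    }


def write_fit(fit: GbtmFit, out_dir) -> dict[str, str]:
    """Write fit.json and posterior.csv for a fitted model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit_path = out / "fit.json"
    with open(fit_path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=2)
    post = pd.DataFrame(fit.posterior,
                        columns=[f"p_group_{g + 1}"
                                 for g in range(fit.spec.n_groups)])
    post.insert(0, "patient_id",
                fit.ids if fit.ids is not None else np.arange(len(post)))
    post["assigned_group"] = fit.assignment + 1
    post_path = out / "posterior.csv"
    post.to_csv(post_path, index=False)
    return {"fit.json": str(fit_path), "posterior.csv": str(post_path)}


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
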