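"""Readers and writers for the pipeline's plain-text formats.

Time series are TSV (frames as rows, one column per node, header row of
node labels); motion is whitespace-delimited 6-column text (tx ty tz rx
ry rz, one row per frame); phenotypes are CSV; fitted models are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ROITimeSeries
from .model import BrainAgeModel

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_motion",
    "write_motion",
    "read_phenotype",
    "save_model",
    "load_model",
    "write_cohort",
    "DAYS_PER_MONTH",
]

#: mean Gregorian month length, used to convert day counts to months
DAYS_PER_MONTH = 30.4375

MODEL_SCHEMA = "fcbrainage-model"
MODEL_SCHEMA_VERSION = 1

EXPECTED_N_NODES = 100  # the reference cortical parcellation size


def read_timeseries(
    path,
    tr_seconds: float = 2.2,
    subject_id: str = "",
    session: str = "",
    run: str = "",
) -> ROITimeSeries:
    """Read a frames x nodes TSV with a header row of node labels."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty time-series file") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed TSV ({exc})") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    bad = [c for c in df.columns
           if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[coerced.isna()].tolist()
            if rows:
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r}, "
                    f"data row {rows[0]}"
                )
        raise ValueError(f"{path}: non-numeric column(s) {bad}")
    if df.shape[1] != EXPECTED_N_NODES:
        warnings.warn(
            f"{path}: {df.shape[1]} nodes (expected "
            f"{EXPECTED_N_NODES}-node parcellation); proceeding",
            stacklevel=2,
        )
    values = df.to_numpy(dtype=float)
    col_mean = values.mean(axis=0)
    col_sd = values.std(axis=0)
    if np.any(np.abs(col_mean) > 0.5 * np.maximum(col_sd, 1e-12)):
        warnings.warn(
            f"{path}: node time series have nonzero mean; input is "
            "expected to be nuisance-regressed/demeaned upstream",
            stacklevel=2,
        )
    return ROITimeSeries(
        values=values,
        tr_seconds=tr_seconds,
        node_labels=tuple(str(c) for c in df.columns),
        subject_id=subject_id,
        session=session,
        run=run,
    )


def write_timeseries(ts: ROITimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.node_labels)).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_motion(path) -> np.ndarray:
    """Whitespace-delimited 6-column motion table."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(
            f"{path}: motion file must have 6 columns, got {arr.shape[1]}"
        )
    return arr


def write_motion(motion: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.6f")


REQUIRED_PHENO_COLUMNS = (
    "subject_id", "age_t0", "sex", "scan_date_t0", "scan_date_t18",
)


def read_phenotype(path, require_followup: bool = True) -> pd.DataFrame:
    """Phenotype CSV -> typed table with dt_months from ISO-8601 dates."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in df.columns]
    if require_followup is False:
        missing = [c for c in missing if c != "scan_date_t18"]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id: {dup!r}")
    df = df.copy()
    df["age_t0"] = pd.to_numeric(df["age_t0"], errors="raise")
    for col in ("scan_date_t0", "scan_date_t18"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
    if "scan_date_t18" in df.columns:
        days = (df["scan_date_t18"] - df["scan_date_t0"]).dt.days
        if (days <= 0).any():
            bad = df.loc[days <= 0, "subject_id"].iloc[0]
            raise ValueError(
                f"scan_date_t18 not after scan_date_t0 for {bad!r}"
            )
        df["dt_months"] = days / DAYS_PER_MONTH
    return df


def save_model(model: BrainAgeModel, path) -> None:
    """Persist a model as JSON for bit-exact reload."""
    payload = {
        "schema": MODEL_SCHEMA,
        "schema_version": MODEL_SCHEMA_VERSION,
        "weights": [float(w) for w in model.weights],
        "intercept": model.intercept,
        "c_param": model.c_param,
        "epsilon": model.epsilon,
        "edge_index": [list(e) for e in model.edge_index],
        "n_train": model.n_train,
        "age_range": list(model.age_range),
        "seed": model.seed,
        "standardize": model.standardize,
        "feature_mean": (
            None if model.feature_mean is None
            else [float(v) for v in model.feature_mean]
        ),
        "feature_sd": (
            None if model.feature_sd is None
            else [float(v) for v in model.feature_sd]
        ),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> BrainAgeModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupted model file ({exc})") from None
    if not isinstance(payload, dict) or payload.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"{path}: not a {MODEL_SCHEMA} file")
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported schema version "
            f"{payload.get('schema_version')!r}"
        )
    required = {"weights", "intercept", "c_param", "epsilon", "edge_index"}
    if not required <= payload.keys():
        raise ValueError(f"{path}: model file missing keys "
                         f"{sorted(required - payload.keys())}")
    return BrainAgeModel(
        weights=np.asarray(payload["weights"], dtype=float),
        intercept=float(payload["intercept"]),
        c_param=float(payload["c_param"]),
        epsilon=float(payload["epsilon"]),
        edge_index=tuple(tuple(e) for e in payload["edge_index"]),
        n_train=int(payload.get("n_train", 0)),
        age_range=tuple(payload.get("age_range", (float("nan"),) * 2)),
        seed=payload.get("seed"),
        standardize=bool(payload.get("standardize", False)),
        feature_mean=(
            None if payload.get("feature_mean") is None
            else np.asarray(payload["feature_mean"], dtype=float)
        ),
        feature_sd=(
            None if payload.get("feature_sd") is None
            else np.asarray(payload["feature_sd"], dtype=float)
        ),
    )


def write_cohort(cohort, outdir) -> None:
    """Write a synthetic cohort to disk in the pipeline's file layout.

    One TSV per run per subject, one motion file per run, a phenotype CSV
    (with synthetic ISO-8601 scan dates reproducing each dt), and a JSON
    sidecar with the generator parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "timeseries").mkdir(exist_ok=True)
    (outdir / "motion").mkdir(exist_ok=True)
    rows = []
    t0 = pd.Timestamp("2017-06-01")
    for subj in cohort.subjects:
        sessions = [("T0", subj.runs_t0, subj.motion_t0)]
        if subj.runs_t18 is not None:
            sessions.append(("T18", subj.runs_t18, subj.motion_t18))
        for ses, runs, motions in sessions:
            for i, (ts, mot) in enumerate(zip(runs, motions)):
                stem = f"{subj.subject_id}_{ses}_run-{i + 1}"
                write_timeseries(ts, outdir / "timeseries" / f"{stem}.tsv")
                write_motion(mot, outdir / "motion" / f"{stem}.txt")
        row = {
            "subject_id": subj.subject_id,
            "age_t0": subj.chronological_age_t0,
            "sex": subj.sex,
            "scan_date_t0": t0.date().isoformat(),
        }
        if subj.dt_months is not None:
            t18 = t0 + pd.Timedelta(days=round(subj.dt_months
                                               * DAYS_PER_MONTH))
            row["scan_date_t18"] = t18.date().isoformat()
            row["weight_change_pct"] = subj.weight_change_pct
            row.update(subj.clinical_deltas)
            row.update(subj.ffq_items)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "phenotype.csv", index=False)
    params = dict(cohort.params)
    (outdir / "generator_params.json").write_text(
        json.dumps(params, indent=2, default=float)
    )
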