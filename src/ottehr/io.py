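"""Delimited-text readers/writers, config loading, and run manifests.

The on-disk dialect is two CSV tables joined on ``admission_id``:

* admissions — ``admission_id``, a group column, and either an
  ``outcome_hours`` column or ISO-8601 ``admit_time``/``discharge_time``
  timestamps (duration is then discharge minus admission, in hours);
* diagnoses — ``admission_id``, ``code`` (one row per diagnosis).

A single shared code vocabulary (all codes in the diagnoses table,
sorted) is used for every group read from one table pair, so groups
extracted from the same database land in the shared-space scenario.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embedding import Cohort
from .ot import OTConfig
from .pipeline import ExperimentConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_cohorts",
    "write_cohort_tables",
    "write_reports",
    "load_experiment_config",
    "file_digest",
]


def file_digest(path) -> str:
    """SHA-256 hex digest of a file."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _durations_hours(adm: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Outcome vector and a keep-mask; timestamps parsed as ISO-8601."""
    if "outcome_hours" in adm.columns:
        vals = pd.to_numeric(adm["outcome_hours"], errors="coerce")
        return vals, vals.notna()
    if {"admit_time", "discharge_time"} <= set(adm.columns):
        t0 = pd.to_datetime(adm["admit_time"], errors="coerce")
        t1 = pd.to_datetime(adm["discharge_time"], errors="coerce")
        keep = t0.notna() & t1.notna()
        hours = (t1 - t0).dt.total_seconds() / 3600.0
        return hours, keep
    raise ValueError(
        "admissions table needs an 'outcome_hours' column or "
        "'admit_time'/'discharge_time' timestamps"
    )


def read_cohorts(
    admissions_path, diagnoses_path, group_column: str = "group"
) -> list[Cohort]:
    """Read the two tables and return one Cohort per distinct group.

    Admissions without any diagnosis row get an all-zero indicator row
    (logged); rows with unparseable outcomes/timestamps are skipped with
    a logged count.  Group order follows first appearance in the file.
    """
    adm = pd.read_csv(admissions_path, dtype={"admission_id": str})
    dx = pd.read_csv(diagnoses_path, dtype={"admission_id": str, "code": str})
    for col in ("admission_id", group_column):
        if col not in adm.columns:
            raise ValueError(f"admissions table is missing column {col!r}")
    for col in ("admission_id", "code"):
        if col not in dx.columns:
            raise ValueError(f"diagnoses table is missing column {col!r}")

    outcomes, keep = _durations_hours(adm)
    n_bad = int((~keep).sum())
    if n_bad:
        logger.warning("skipped %d admissions with unparseable outcomes", n_bad)
    adm = adm.loc[keep].copy()
    adm["__outcome"] = outcomes[keep]

    vocab = sorted(dx["code"].unique())
    code_idx = {c: i for i, c in enumerate(vocab)}
    codes_by_adm = dx.groupby("admission_id")["code"].agg(list)

    cohorts = []
    for group, sub in adm.groupby(group_column, sort=False):
        X = np.zeros((len(sub), len(vocab)), dtype=np.uint8)
        n_empty = 0
        for i, adm_id in enumerate(sub["admission_id"]):
            codes = codes_by_adm.get(adm_id)
            if codes is None:
                n_empty += 1
                continue
            X[i, [code_idx[c] for c in codes]] = 1
        if n_empty:
            logger.info(
                "group %s: %d admissions with no diagnoses (all-zero rows)",
                group, n_empty,
            )
        cohorts.append(Cohort(X, sub["__outcome"].to_numpy(), str(group), vocab))
    return cohorts


def write_cohort_tables(cohorts: list[Cohort], out_dir) -> dict[str, Path]:
    """Write cohorts as admissions/diagnoses CSVs the reader consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adm_rows, dx_rows = [], []
    for cohort in cohorts:
        for i in range(cohort.n_admissions):
            adm_id = f"{cohort.group}-{i:06d}"
            adm_rows.append({
                "admission_id": adm_id,
                "group": cohort.group,
                "outcome_hours": cohort.outcomes[i],
            })
            for j in np.nonzero(cohort.features[i])[0]:
                dx_rows.append({
                    "admission_id": adm_id,
                    "code": cohort.code_vocabulary[j],
                })
    paths = {
        "admissions": out_dir / "admissions.csv",
        "diagnoses": out_dir / "diagnoses.csv",
    }
    pd.DataFrame(adm_rows).to_csv(paths["admissions"], index=False)
    pd.DataFrame(dx_rows).to_csv(paths["diagnoses"], index=False)
    return paths


def load_experiment_config(
    path=None, seed: int | None = None
) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file mirroring its fields.

    The optional ``ot`` sub-mapping mirrors the OT hyperparameters
    field-for-field; a ``seed`` argument overrides the file's value.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    ot_data = data.pop("ot", {}) or {}
    config = ExperimentConfig(ot=OTConfig(**ot_data), **data)
    if seed is not None:
        config.seed = seed
    return config


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_reports(
    out_dir,
    tables: dict[str, pd.DataFrame],
    config: ExperimentConfig | None = None,
    inputs: dict[str, str] | None = None,
    extra: dict | None = None,
) -> list[Path]:
    """Write report tables plus a manifest sufficient to re-run bit-identically.

    Each table lands as ``<name>.csv``; the manifest records the config
    snapshot, seeds, package version, input-file digests, and the output
    file list with their digests.  The manifest contains no timestamps
    or absolute paths, so a re-run with the same inputs reproduces every
    byte.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)

    manifest = {
        "package_version": __version__,
        "config": _jsonable(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "inputs": {
            name: file_digest(p) for name, p in (inputs or {}).items()
        },
        "outputs": {p.name: file_digest(p) for p in written},
        "extra": _jsonable(extra) if extra else {},
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(manifest_path)
    return written
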