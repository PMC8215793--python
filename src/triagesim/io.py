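"""Configuration parsing, cohort CSV round-tripping, seeds and run logging.

The cohort CSV dialect is fixed so round-trip tests can be byte-exact:
comma-separated, header ``age,sbp,rr,gcs,major_trauma``, UTF-8, LF line
endings, missing vitals encoded as an empty field.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .cohort import COHORT_COLUMNS, CohortSpec
from .exceptions import ConfigError


class CohortFromSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    spec: CohortSpec


class CohortFromCsv(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    csv: str


class ExperimentConfig(BaseModel):
    """Validated experiment configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    cohorts: list[Union[CohortFromSpec, CohortFromCsv]] = Field(min_length=1)
    epp_levels: list[int] = [10, 25, 100, 1000]
    repetitions: int = Field(default=1000, ge=1)
    bootstrap_reps: int = Field(default=1000, ge=1)
    search_budget: int = Field(default=30, ge=1)
    cv_folds: int = Field(default=5, ge=2)
    master_seed: int = Field(default=0, ge=0)
    shrink_mode: Literal["default", "literal"] = "default"


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML/JSON experiment config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML/JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ExperimentConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid config\n  " + "\n  ".join(lines)) from exc


# ---------------------------------------------------------------------------
# Cohort CSV


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, lineterminator="\n", na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read the cohort dialect with row-addressed errors; empty field = missing."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ConfigError(f"{path}: missing columns {missing_cols}")
    out = {}
    for col in COHORT_COLUMNS:
        s = raw[col].str.strip()
        blank = s == ""
        if col in ("age", "major_trauma") and blank.any():
            row = int(np.flatnonzero(blank.to_numpy())[0])
            raise ConfigError(f"{path}: row {row + 2}: column {col!r} may not be empty")
        numeric = pd.to_numeric(s.where(~blank), errors="coerce")
        bad = (~blank) & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ConfigError(
                f"{path}: row {row + 2}: non-numeric value {s.iloc[row]!r} in column {col!r}"
            )
        if col in ("age", "major_trauma"):
            out[col] = numeric.astype(np.int64)
        else:
            out[col] = numeric.astype("Int64")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Seeds, manifest, logging


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Named child streams of a single master seed (documented splitting scheme)."""
    return list(np.random.SeedSequence(master_seed).spawn(n))


def config_hash(config: ExperimentConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_manifest(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Provenance manifest sufficient to re-execute the run bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "master_seed": config.master_seed,
        "config": config.model_dump(),
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


class JsonlLogger:
    """Minimal JSON-lines run log: level, module, event, payload."""

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path is not None else None
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("", encoding="utf-8")

    def log(self, level: str, module: str, event: str, **payload) -> None:
        if self.path is None:
            return
        entry = {"level": level, "module": module, "event": event, "payload": payload}
        with self.path.open("a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry) + "\n")
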