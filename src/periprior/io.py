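"""Trial-table CSV schema, JSON artifacts and run configuration.

Trial tables are UTF-8 comma-separated files with a mandatory header, "."
decimals and the literal ``NA`` for missing values.  Leading ``#`` comment
lines carry provenance (config hash, master seed) and are ignored by the
reader.  All positions are absolute mm azimuth; model-space centering is
performed downstream, never in files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitConfig
from .model import EvalGrid, ParameterError
from .simulate import CohortDesign, ConditionParams, GenerativeParams, default_generative_params

__all__ = [
    "TRIAL_COLUMNS",
    "SchemaError",
    "read_trials",
    "write_trials",
    "write_json",
    "read_json",
    "RunConfig",
]

TRIAL_COLUMNS = (
    "participant_id", "visibility", "block_type", "reach_target",
    "m_v_mm", "m_p_mm", "disparity_mm", "response_mm",
    "trial_index", "block_index",
)

_ENUMS = {
    "visibility": {"visible", "invisible"},
    "block_type": {"uni_visual", "uni_proprio", "multi"},
    "reach_target": {"visual", "proprioceptive", "NA"},
}


class SchemaError(ValueError):
    """A file violates the trial-table schema; messages carry row numbers."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Unknown columns are a hard error; rows whose response is NA are rejected
    with a warning; a disparity inconsistent with the targets by more than
    1e-6 mm is a row-level error.  Returns typed columns with ``NaN`` for NA.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    unknown = set(df.columns) - set(TRIAL_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown columns {sorted(unknown)} in {path}")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)} in {path}")
    if df.empty:
        return df.reindex(columns=list(TRIAL_COLUMNS))
    for col, allowed in _ENUMS.items():
        vals = df[col].astype(str).where(df[col].notna(), "NA")
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, counting the header
            raise SchemaError(
                f"{path}: invalid {col}={df[col][bad].iloc[0]!r} at row {row}")
    for col in ("m_v_mm", "m_p_mm", "disparity_mm", "response_mm"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: non-numeric {col}: {exc}")
    for col in ("trial_index", "block_index"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise", downcast=None).astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: non-integer {col}: {exc}")
        if (df[col] < 0).any():
            raise SchemaError(f"{path}: negative {col}")
    both = df["m_v_mm"].notna() & df["m_p_mm"].notna() & df["disparity_mm"].notna()
    mism = both & ((df["m_p_mm"] - df["m_v_mm"] - df["disparity_mm"]).abs() > 1e-6)
    if mism.any():
        row = int(df.index[mism][0]) + 2
        raise SchemaError(
            f"{path}: disparity_mm inconsistent with m_p_mm - m_v_mm at row {row}")
    na_resp = df["response_mm"].isna()
    if na_resp.any():
        rows = [int(i) + 2 for i in df.index[na_resp][:5]]
        warnings.warn(f"{path}: rejecting {int(na_resp.sum())} rows with NA "
                      f"response (first at rows {rows})")
        df = df[~na_resp].reset_index(drop=True)
    return df


def write_trials(df: pd.DataFrame, path, config_hash: str | None = None,
                 master_seed: int | None = None) -> None:
    """Write a trial table; provenance goes into leading comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        if master_seed is not None:
            fh.write(f"# master_seed={master_seed}\n")
        df.reindex(columns=list(TRIAL_COLUMNS)).to_csv(
            fh, index=False, na_rep="NA")


def write_json(payload, path, config_hash: str | None = None,
               master_seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"config_hash": config_hash, "master_seed": master_seed,
           "payload": payload}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for simulation and fitting."""

    grid_lo: float = -300.0
    grid_hi: float = 300.0
    grid_step: float = 0.5
    area_A: float = 600.0 ** 2
    n_starts_stage1: int = 500
    n_carry_stage2: int = 50
    tol_stage1: float = 100.0
    tol_stage2: float = 1e-4
    lam_bounds: tuple[float, float] = (0.01, 0.99)
    master_seed: int = 0
    n_participants: int = 20
    proprio_sd_swapped: bool = False
    motor_sd: float = 0.0
    generative_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        EvalGrid(self.grid_lo, self.grid_hi, self.grid_step)  # validates
        if self.area_A <= 0:
            raise ParameterError("area_A must be > 0")
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if self.motor_sd < 0:
            raise ParameterError("motor_sd must be >= 0")
        FitConfig(n_starts_stage1=self.n_starts_stage1,
                  n_carry_stage2=self.n_carry_stage2,
                  tol_stage1=self.tol_stage1, tol_stage2=self.tol_stage2,
                  lam_bounds=tuple(self.lam_bounds))  # validates

    # -- derived objects ---------------------------------------------------
    def grid(self) -> EvalGrid:
        return EvalGrid(self.grid_lo, self.grid_hi, self.grid_step)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            n_starts_stage1=self.n_starts_stage1,
            n_carry_stage2=self.n_carry_stage2,
            tol_stage1=self.tol_stage1, tol_stage2=self.tol_stage2,
            lam_bounds=tuple(self.lam_bounds), master_seed=self.master_seed,
            area_A=self.area_A, grid=self.grid())

    def design(self) -> CohortDesign:
        return CohortDesign(n_participants=self.n_participants)

    def generative_params(self) -> GenerativeParams:
        params = default_generative_params(self.proprio_sd_swapped)
        params = replace(params, motor_sd=self.motor_sd)
        for key, values in self.generative_overrides.items():
            if key not in ("visible", "invisible", "visible_sd", "invisible_sd"):
                raise ParameterError(f"unknown generative override {key!r}")
            cond: ConditionParams = getattr(params, key)
            unknown = set(values) - set(vars(cond))
            if unknown:
                raise ParameterError(f"unknown fields {sorted(unknown)} in "
                                     f"generative override {key!r}")
            params = replace(params, **{key: replace(cond, **values)})
        return params

    # -- serialization -----------------------------------------------------
    @property
    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc["lam_bounds"] = list(doc["lam_bounds"])
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(doc, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "lam_bounds" in doc:
            doc["lam_bounds"] = tuple(doc["lam_bounds"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["lam_bounds"] = list(doc["lam_bounds"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True),
                              encoding="utf-8")
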