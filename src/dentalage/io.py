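"""CSV readers/writers and run configuration.

All tables are plain CSV: datasets are small (order 10^3 rows) and human
inspection matters in forensic contexts.  Every reader validates against the
core type invariants and names the offending CSV line in its error message;
every writer round-trips losslessly through its reader.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .core import (
    STAGES,
    TOOTH_IDS,
    Atlas,
    Dataset,
    Estimate,
    ScoringTable,
    Sex,
    SubjectRecord,
    ValidationError,
)

STAGE_COLUMNS = [f"s{t}" for t in TOOTH_IDS]
DATASET_COLUMNS = ["subject_id", "sex", "ca_years"] + STAGE_COLUMNS + ["observer_id"]
ESTIMATE_COLUMNS = ["subject_id", "method", "da_years", "error_years"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_dataset(path: str | Path) -> Dataset:
    """Read a subject dataset CSV, validating each row.

    Columns: subject_id, sex (M/F), ca_years, s31..s37 (stage letters, N
    allowed), observer_id (optional, default obs1).  Ages are normalised to
    two decimals on ingestion.  Errors cite the CSV line (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DATASET_COLUMNS[:-1], path)
    if "observer_id" not in df.columns:
        df["observer_id"] = "obs1"
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            ca = round(float(row["ca_years"]), 2)
        except ValueError:
            raise ValidationError(
                f"{path}, line {line}: non-parsable age {row['ca_years']!r} "
                "in column ca_years"
            ) from None
        stages = {}
        for tooth in TOOTH_IDS:
            code = row[f"s{tooth}"].strip()
            if code not in STAGES:
                raise ValidationError(
                    f"{path}, line {line}: invalid stage {code!r} in column s{tooth}"
                )
            stages[tooth] = code
        try:
            records.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    sex=Sex.parse(row["sex"]),
                    ca_years=ca,
                    stages=stages,
                    observer_id=row["observer_id"] or "obs1",
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {line}: {exc}") from None
    try:
        return Dataset(records, provenance={"source": str(path)})
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    df = dataset.to_frame()
    df["ca_years"] = df["ca_years"].map(lambda x: f"{x:.2f}")
    df.to_csv(path, index=False)


def read_scoring_table(path: str | Path) -> ScoringTable:
    """Read a scoring-table CSV (columns sex, fdi, stage, score_years)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["sex", "fdi", "stage", "score_years"], path)
    try:
        return ScoringTable.from_frame(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_scoring_table(table: ScoringTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_atlas(path: str | Path) -> Atlas:
    """Read an atlas CSV (columns ref_age, s31..s37)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["ref_age"] + STAGE_COLUMNS, path)
    try:
        return Atlas.from_frame(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, index=False)


def read_estimates(path: str | Path) -> list[Estimate]:
    """Read a long-format estimates CSV (one row per subject per method)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ESTIMATE_COLUMNS, path)
    try:
        return [
            Estimate(
                subject_id=str(row["subject_id"]),
                method=str(row["method"]),
                da_years=float(row["da_years"]),
                error_years=float(row["error_years"]),
            )
            for _, row in df.iterrows()
        ]
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_estimates(estimates: Iterable[Estimate], path: str | Path) -> None:
    from .estimators import estimates_to_frame

    estimates_to_frame(estimates).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Flat, typed configuration for the shell pipeline.

    Unknown keys in a config file are rejected; command-line flags override
    file values and the resolved merge is written beside each run's outputs.
    """

    seed: int = 0
    n: int = 831
    p_female: float = 0.574
    age_min: float = 10.0
    age_max: float = 16.99
    sigma_subject: float = 0.6
    sigma_tooth: float = 0.4
    sex_gap: float = 0.16
    methods: tuple[str, ...] = ("quick", "willems", "atlas")
    minuend: float = 16.0
    scoring_table: str = "model"  # path to CSV, or "model" for model-derived
    atlas: str = "model"  # path to CSV, or "model" for model-derived
    atlas_step: float = 0.5
    atlas_age_min: float = 9.0
    atlas_age_max: float = 17.0
    grouping: str = "overall"
    stratify_by: tuple[str, ...] = ("method", "bracket", "sex")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a key-value mapping")
        unknown = sorted(set(raw) - set(cls.field_names()))
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {unknown}")
        for key in ("methods", "stratify_by"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        unknown = sorted(set(clean) - set(self.field_names()))
        if unknown:
            raise ValidationError(f"unknown config override(s) {unknown}")
        merged = asdict(self)
        merged.update(clean)
        for key in ("methods", "stratify_by"):
            if isinstance(merged[key], list):
                merged[key] = tuple(merged[key])
        return RunConfig(**merged)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        for key in ("methods", "stratify_by"):
            payload[key] = list(payload[key])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
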