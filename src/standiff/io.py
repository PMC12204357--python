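"""Shared readers/writers and run configuration.

All region-indexed tables are CSV with a ``subject_id`` column and one
column per region; columns are always re-indexed to the connectome's
canonical label order by name, never by position.  Output CSVs carry a
header comment with the package version, a config hash, and the RNG seed
so any artifact can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

logger = logging.getLogger(__name__)


def read_region_table(
    path: str | Path, region_labels: list[str]
) -> pd.DataFrame:
    """Read a subjects-x-regions CSV and re-index columns to canonical order."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise ValueError("region table must have a subject_id column")
    df = df.set_index("subject_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids: {dups}")
    missing = [r for r in region_labels if r not in df.columns]
    if missing:
        raise ValueError(f"missing region columns: {missing}")
    unknown = [c for c in df.columns if c not in region_labels]
    if unknown:
        raise ValueError(f"unknown region columns: {unknown}")
    return df[region_labels].astype(float)


def read_biomarker_table(path: str | Path) -> pd.DataFrame:
    """Biomarker CSV: subject_id, diagnosis, age, then named biomarkers."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("subject_id", "diagnosis", "age"):
        if col not in df.columns:
            raise ValueError(f"biomarker table missing column {col!r}")
    return df.set_index("subject_id")


def read_longitudinal_table(
    path: str | Path, region_labels: list[str]
):
    """Longitudinal CSV: subject_id, delta_years, then region columns."""
    from .prediction import LongitudinalRecord

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("subject_id", "delta_years"):
        if col not in df.columns:
            raise ValueError(f"longitudinal table missing column {col!r}")
    missing = [r for r in region_labels if r not in df.columns]
    if missing:
        raise ValueError(f"missing region columns: {missing}")
    records = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("delta_years")
        visits = [
            (float(row["delta_years"]), row[region_labels].to_numpy(dtype=float))
            for _, row in grp.iterrows()
        ]
        records.append(
            LongitudinalRecord(subject_id=str(sid), baseline_stage=0.0, visits=visits)
        )
    return records


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index_label: str | None = "subject_id",
) -> None:
    """Write a CSV with a provenance header comment; 17 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# standiff {__version__} config={cfg_hash} seed={seed}\n")
        df.to_csv(fh, float_format="%.17g", index_label=index_label)


@dataclass
class RunConfig:
    """Full-pipeline configuration; CLI flags override file values."""

    connectome: str = ""
    tau: str = ""
    biomarkers: str = ""
    longitudinal: str | None = None
    mask: str | None = None
    out_dir: str = "stand_out"
    rng_seed: int = 0
    n_mcmc_iter: int = 20_000
    threshold_grid: list = field(
        default_factory=lambda: [[1.0, 2.0, 3.0]]
    )  # each entry: per-biomarker triple, broadcast across biomarkers
    decreasing_biomarkers: list = field(default_factory=list)
    lam: float = 0.03
    strategy: str = "subject_both"
    k_grid: list = field(default_factory=lambda: list(range(1, 7)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("connectome", "tau", "biomarkers"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} missing: {p}")
        for name in ("longitudinal", "mask"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} missing: {p}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
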