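"""NIfTI and table I/O, validation, and run manifests.

NIfTI-1 is the only volume dialect; subject collections are stored as 4-D
stacks in float32.  Tables are CSV (inputs) / TSV (results); model results
and manifests are JSON.  Every pipeline stage appends one manifest record to
``manifests.jsonl`` in its run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .containers import BrainMask, CohortVolumes


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3-D or 4-D volume as float32 NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine).  Gzipped or plain."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def check_grid(data: np.ndarray, affine: np.ndarray, mask: BrainMask) -> None:
    """Hard error when a volume's grid or affine disagrees with the mask."""
    shape = data.shape[-3:] if data.ndim == 4 else data.shape
    if tuple(shape) != tuple(mask.data.shape):
        raise ValueError(
            f"grid mismatch: volume {tuple(shape)} vs mask {tuple(mask.data.shape)}"
        )
    if not np.allclose(affine, mask.affine):
        raise ValueError(
            f"affine mismatch:\nvolume:\n{affine}\nmask:\n{mask.affine}"
        )


def write_cohort(cohort: CohortVolumes, path: str | Path) -> Path:
    """4-D stack with subjects on the last axis (NIfTI convention)."""
    return write_volume(np.moveaxis(cohort.data, 0, -1), cohort.affine, path)


def read_cohort(path: str | Path, subject_ids: list[str]) -> CohortVolumes:
    data, affine = read_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D stack, got shape {data.shape}")
    data = np.moveaxis(data, -1, 0)
    return CohortVolumes(data, affine, list(subject_ids))


REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "group", "age", "gender", "education", "tiv")
KNOWN_GROUPS = ("DD", "ODD")


def read_phenotype(path: str | Path, require_interval: bool = False) -> pd.DataFrame:
    """Load and validate a phenotype table.

    Requires subject id, group, age, gender, education, and TIV columns;
    duplicate ids and unknown group labels are rejected with the offending
    rows listed.
    """
    df = pd.read_csv(path)
    return validate_phenotype(df, require_interval=require_interval)


def validate_phenotype(df: pd.DataFrame, require_interval: bool = False) -> pd.DataFrame:
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if require_interval and "interval_years" not in df.columns:
        missing.append("interval_years")
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject ids: {sorted(dup.unique())}")
    bad = df.loc[~df["group"].isin(KNOWN_GROUPS)]
    if len(bad):
        raise ValueError(
            f"unknown group labels in rows {bad.index.tolist()}: "
            f"{sorted(bad['group'].unique())} (expected {list(KNOWN_GROUPS)})"
        )
    if "interval_years" in df.columns:
        nonpos = df.loc[df["interval_years"].notna() & (df["interval_years"] <= 0)]
        if len(nonpos):
            raise ValueError(f"non-positive follow-up intervals in rows {nonpos.index.tolist()}")
    return df


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """One record per stage invocation, appended to ``manifests.jsonl``."""

    stage: str
    config_hash: str
    seed: int
    inputs: list[str]
    outputs: list[str]
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0
    warnings: list[str] = dataclasses.field(default_factory=list)
    status: str = "ok"

    def write(self, run_dir: str | Path) -> Path:
        path = Path(run_dir) / "manifests.jsonl"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "a") as fh:
            fh.write(json.dumps(dataclasses.asdict(self)) + "\n")
        return path


class stage_manifest:
    """Context manager recording a stage run (timing, warnings, failure)."""

    def __init__(self, run_dir: str | Path, stage: str, config: dict, seed: int,
                 inputs: list[str] | None = None):
        self.run_dir = Path(run_dir)
        self.manifest = RunManifest(
            stage=stage, config_hash=config_hash(config), seed=seed,
            inputs=[str(p) for p in (inputs or [])], outputs=[],
        )

    def add_output(self, path: str | Path) -> None:
        self.manifest.outputs.append(str(path))

    def __enter__(self) -> "stage_manifest":
        self.manifest.started = time.time()
        return self

    def __exit__(self, exc_type, exc, tb) -> bool:
        self.manifest.finished = time.time()
        if exc_type is not None:
            self.manifest.status = f"failed: {exc_type.__name__}: {exc}"
        self.manifest.write(self.run_dir)
        return False
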