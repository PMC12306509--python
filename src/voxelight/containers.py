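"""Shared in-memory containers for volumetric cohort data.

Volumes live on a common 3-D grid with a shared affine.  A cohort is a stack
of per-subject gray-matter maps; masking flattens it to the subjects x voxels
matrix every statistical stage works on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def default_affine(voxel_size_mm: float) -> np.ndarray:
    """Isotropic scanner-style affine with the origin at the grid corner."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


@dataclass
class BrainMask:
    """Boolean in-brain volume with provenance of how it was built."""

    data: np.ndarray  # bool, 3-D
    affine: np.ndarray
    threshold: float | None = None
    n_subjects_averaged: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if not self.data.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates of in-mask voxels."""
        return np.argwhere(self.data)


@dataclass
class CohortVolumes:
    """Stack of per-subject 3-D volumes on a common grid.

    ``data`` is (n_subjects, nx, ny, nz); ``subject_ids`` aligns rows with the
    phenotype table.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("cohort volumes must be 4-D (subjects first)")
        if self.subject_ids and len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length does not match volume count")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def masked_matrix(self, mask: BrainMask) -> np.ndarray:
        """Subjects x in-mask-voxels matrix."""
        if mask.data.shape != self.grid_dims:
            raise ValueError(
                f"mask grid {mask.data.shape} does not match volume grid {self.grid_dims}"
            )
        return self.data[:, mask.data]

    def select(self, subject_ids: list[str]) -> "CohortVolumes":
        """Subset and reorder rows to the given subject ids."""
        pos = {sid: i for i, sid in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise KeyError(f"subjects not in cohort: {missing[:5]}")
        rows = [pos[s] for s in subject_ids]
        return CohortVolumes(self.data[rows], self.affine, list(subject_ids))


def unmask(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Scatter a per-in-mask-voxel vector back into a full 3-D volume."""
    out = np.full(mask.data.shape, fill, dtype=float)
    out[mask.data] = values
    return out
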