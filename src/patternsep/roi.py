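"""ROI mask handling and voxel-pattern extraction.

Masks are boolean 3-D volumes with a voxel-to-world affine, read and written
as NIfTI.  Pattern extraction uses a fixed ascending flat-index (C-order)
voxel scan order, recorded via :func:`scan_order_hash` so any downstream
result can be traced to an exact voxel ordering.  Masks and data must share
grid shape and affine exactly; resampling is deliberately unsupported.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .exceptions import EmptyMaskError, InvalidParameterError, ShapeError
from .simulate import TrialPatternSet


@dataclass
class ROIMask:
    name: str
    grid: np.ndarray  # 3-D bool
    affine: np.ndarray  # 4x4

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ShapeError("mask grid must be 3-D")
        if self.affine.shape != (4, 4):
            raise ShapeError("affine must be 4x4")
        if not self.grid.any():
            raise EmptyMaskError(f"mask {self.name!r} contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Ascending C-order flat indices of in-mask voxels (the scan order)."""
        return np.flatnonzero(self.grid.ravel(order="C"))


def read_mask(path, name: str | None = None) -> ROIMask:
    """Load a NIfTI volume as an ROI mask (nonzero voxels -> True)."""
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj) != 0
    if grid.ndim == 4 and grid.shape[3] == 1:
        grid = grid[..., 0]
    return ROIMask(name=name or str(path), grid=grid, affine=img.affine)


def write_mask(mask: ROIMask, path) -> None:
    """Write an ROI mask as uint8 NIfTI."""
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def scan_order_hash(mask: ROIMask) -> str:
    """SHA-256 of the voxel scan order, for the run manifest."""
    return hashlib.sha256(mask.flat_indices.astype(np.int64).tobytes()).hexdigest()


def _data_and_affine(tmaps):
    if isinstance(tmaps, nib.spatialimages.SpatialImage):
        return np.asanyarray(tmaps.dataobj), tmaps.affine
    return np.asarray(tmaps, dtype=np.float64), None


def extract_patterns(
    tmaps,
    mask: ROIMask,
    labels,
    accurate=None,
    *,
    participant_id: int = 0,
) -> TrialPatternSet:
    """Extract a trials x voxels matrix from 4-D trial volumes.

    ``tmaps`` is a 4-D array or NIfTI image with one volume per trial; the
    output columns follow the mask's fixed scan order.  If ``tmaps`` is an
    image, its affine must match the mask's exactly.
    """
    data, affine = _data_and_affine(tmaps)
    if data.ndim != 4:
        raise ShapeError("trial volumes must be 4-D (x, y, z, trial)")
    if data.shape[:3] != mask.grid.shape:
        raise ShapeError(
            f"data grid {data.shape[:3]} does not match mask grid "
            f"{mask.grid.shape}"
        )
    if affine is not None and not np.allclose(affine, mask.affine):
        raise ShapeError("data affine does not match mask affine exactly")
    n_trials = data.shape[3]
    flat = data.reshape(-1, n_trials, order="C")
    patterns = flat[mask.flat_indices].T  # trials x voxels
    if accurate is None:
        accurate = np.ones(n_trials, dtype=bool)
    return TrialPatternSet(
        participant_id=participant_id,
        roi_name=mask.name,
        patterns=patterns,
        labels=list(labels),
        accurate=accurate,
    )


def embed_patterns(patterns: np.ndarray, mask: ROIMask) -> np.ndarray:
    """Inverse of extraction: place trials x voxels back into a 4-D volume.

    Out-of-mask voxels are zero; ``extract`` after ``embed`` is the identity
    on the masked voxels.
    """
    patterns = np.asarray(patterns, dtype=np.float64)
    if patterns.ndim != 2 or patterns.shape[1] != mask.n_voxels:
        raise ShapeError("patterns must be trials x mask-voxel-count")
    n_trials = patterns.shape[0]
    flat = np.zeros((mask.grid.size, n_trials))
    flat[mask.flat_indices] = patterns.T
    return flat.reshape(mask.grid.shape + (n_trials,))


def subsample_voxels(patterns: TrialPatternSet, k: int,
                     seed: int = 0) -> TrialPatternSet:
    """Keep ``k`` voxel columns sampled without replacement (voxel-count
    control).  Selected columns are kept in ascending scan order, so
    ``k == n_voxels`` returns the identical pattern set.  Deterministic
    given ``seed``.
    """
    n = patterns.n_voxels
    if not (1 <= k <= n):
        raise InvalidParameterError(
            f"k must be in [1, {n}], got {k}"
        )
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(n, size=k, replace=False))
    return TrialPatternSet(
        participant_id=patterns.participant_id,
        roi_name=patterns.roi_name,
        patterns=patterns.patterns[:, cols],
        labels=list(patterns.labels),
        accurate=patterns.accurate.copy(),
    )
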