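"""Volume container and file I/O (NIfTI-1 volumes, text centerlines).

All world coordinates are millimetres in RAS orientation (x to the subject's
right, y anterior, z superior).  Volumes loaded from disk are reoriented to
the closest canonical (RAS) axis order before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

T1_LIKE = "t1_like"
T2_LIKE = "t2_like"
POLARITIES = (T1_LIKE, T2_LIKE)


@dataclass
class Volume:
    """A 3-D scalar image with a voxel-to-world (mm) affine.

    Parameters
    ----------
    data : ndarray
        3-D array indexed ``[i, j, k]`` in RAS axis order.
    affine : ndarray
        4x4 homogeneous voxel-to-mm transform.
    polarity : str, optional
        Contrast tag, ``"t1_like"`` or ``"t2_like"``.
    """

    data: np.ndarray
    affine: np.ndarray
    polarity: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.polarity is not None and self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to mm coordinates."""
        voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
        return voxels @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of mm coordinates to fractional voxel indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]


def load_volume(path: str | Path, polarity: str | None = None) -> Volume:
    """Load a NIfTI volume, reoriented to canonical RAS axis order."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data=data, affine=img.affine, polarity=polarity)


def save_volume(volume: Volume, path: str | Path, dtype=None) -> None:
    data = volume.data if dtype is None else volume.data.astype(dtype)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


def read_centerline_text(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited x y z (mm) point list, rostral first."""
    pts = np.loadtxt(str(path), ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError(f"expected 3 columns (x y z mm) in {path}, got {pts.shape[1]}")
    return pts


def write_centerline_text(points: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(points, dtype=float), fmt="%.4f")
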