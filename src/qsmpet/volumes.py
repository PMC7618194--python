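"""Voxel-lattice containers shared across the voxelwise, kinetic and IO layers.

Conventions: lattice indices are 0-based internally; reporting-space
coordinates are millimetres, obtained from ``origin + index * voxel_size``
(scaling-plus-translation affines only). Subject-stacked data put the subject
axis first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledVolume", "VolumeStack", "mm_coordinates"]


@dataclass
class LabeledVolume:
    """A single 3D volume with geometry, an analysis mask and optional labels.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (ppb for susceptibility, min^-1 for Ki maps).
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    origin : tuple of float
        mm coordinate of lattice index (0, 0, 0).
    mask : bool ndarray or None
        In-analysis lattice sites; must match ``data.shape``.
    labels : int ndarray or None
        Region id per site (0 = background).
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    mask: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.data.shape:
                raise ValueError("label shape does not match data shape")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class VolumeStack:
    """Subject-stacked volumes sharing one lattice, mask and geometry.

    ``data`` has shape (n_subjects, nx, ny, nz).  ``matrix()`` exposes the
    masked data as an (n_subjects, n_mask_voxels) array in a fixed voxel
    order (C order over the lattice), which is the layout every statistical
    routine consumes.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    labels: np.ndarray | None = None
    mask_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (subject, x, y, z)")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError(
                f"stack lattice {self.data.shape[1:]} does not match mask {self.mask.shape}"
            )
        self.mask_index = np.flatnonzero(self.mask.ravel())

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def matrix(self) -> np.ndarray:
        """Masked data as (n_subjects, n_voxels), float64."""
        flat = self.data.reshape(self.n_subjects, -1)
        return np.asarray(flat[:, self.mask_index], dtype=float)

    def with_matrix(self, y: np.ndarray) -> "VolumeStack":
        """Rebuild a stack from an (n_subjects, n_voxels) masked matrix."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_subjects, self.n_voxels):
            raise ValueError("matrix shape does not match stack")
        flat = np.full((self.n_subjects, self.mask.size), np.nan)
        flat[:, self.mask_index] = y
        return VolumeStack(
            flat.reshape(self.data.shape), self.mask, self.voxel_size, self.origin, self.labels
        )

    def unmask(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-voxel values back onto the 3D lattice."""
        values = np.asarray(values, dtype=float)
        flat = np.full(self.mask.size, fill, dtype=float)
        flat[self.mask_index] = values
        return flat.reshape(self.mask.shape)


def mm_coordinates(index_xyz: np.ndarray, voxel_size, origin) -> np.ndarray:
    """Map 0-based lattice indices to mm reporting-space coordinates."""
    return np.asarray(index_xyz, dtype=float) * np.asarray(voxel_size) + np.asarray(origin)
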