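"""Geometric volume containers for CT series.

A :class:`CTVolume` couples a 3-D Hounsfield-unit array with a
:class:`VolumeGeometry` that maps voxel indices to patient-space
millimetres in the LPS (left-posterior-superior) convention used by
DICOM. Array axes follow the geometry axes: axis 0 runs along the
in-plane row direction (increasing column index), axis 1 along the
in-plane column direction (increasing row index), and axis 2 along the
slice normal, so ``spacing[2]`` is the inter-slice spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGeometry", "CTVolume"]

#: Default tolerance on direction-cosine orthonormality checks.
ORTHO_TOL = 1e-6


@dataclass
class VolumeGeometry:
    """Voxel-to-world mapping of a regularly sampled 3-D image.

    Parameters
    ----------
    origin : (3,) array-like
        Patient-space position (mm, LPS) of the *center* of voxel
        ``(0, 0, 0)``.
    spacing : (3,) array-like
        Per-axis voxel size in mm; the third component is the
        inter-slice spacing.
    direction : (3, 3) array-like
        Orthonormal matrix whose columns are the direction cosines of
        the three voxel axes; column 2 is the slice normal.
    size : (3,) tuple of int
        Voxel counts per axis.
    """

    origin: np.ndarray
    spacing: np.ndarray
    direction: np.ndarray
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        self.size = tuple(int(n) for n in self.size)
        self.validate()

    def validate(self, tol: float = 1e-4) -> None:
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise ValueError(f"size must be >= 1 per axis, got {self.size}")
        gram = self.direction.T @ self.direction
        if not np.allclose(gram, np.eye(3), atol=tol):
            raise ValueError("direction columns must be orthonormal")

    @property
    def slice_normal(self) -> np.ndarray:
        """Unit normal of the slice plane (third direction column)."""
        return self.direction[:, 2]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices to patient-space mm.

        ``idx`` has shape (..., 3); returns the same shape. Voxel
        centers, not corners: index (0,0,0) maps exactly to ``origin``.
        """
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_world` (continuous indices)."""
        pts = np.asarray(pts, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing

    def same_grid(self, other: "VolumeGeometry", tol: float = 1e-6) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class CTVolume:
    """A 3-D Hounsfield-unit image with its geometry.

    ``slice_thickness`` carries the reconstructed slab width (the DICOM
    SliceThickness tag), which is distinct from the inter-slice spacing
    stored in ``geometry.spacing[2]``.
    """

    intensities: np.ndarray
    geometry: VolumeGeometry
    slice_thickness: float | None = None
    series_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.geometry.size:
            raise ValueError(
                f"array shape {self.intensities.shape} != geometry size "
                f"{self.geometry.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def copy_with(self, intensities: np.ndarray) -> "CTVolume":
        """New volume sharing this geometry with replaced intensities."""
        return CTVolume(
            intensities=np.asarray(intensities, dtype=float),
            geometry=self.geometry,
            slice_thickness=self.slice_thickness,
            series_id=self.series_id,
            metadata=dict(self.metadata),
        )


def canonical_axial_direction() -> np.ndarray:
    """Direction cosines of an untilted axial series (identity)."""
    return np.eye(3)


def canonical_coronal_direction() -> np.ndarray:
    """Direction cosines of an untilted coronal series.

    Rows run left-right (+x), columns run superior-to-inferior (-z),
    and the slice normal points anterior-to-posterior (+y).
    """
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, -1.0, 0.0],
        ]
    )
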