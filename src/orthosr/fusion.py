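"""Two-series fusion: build the LR volume on the thin-axial grid.

The two thick series (axial and coronal) are registered purely through
their DICOM world coordinates: every voxel center of the target
(thin-axial) grid is mapped to patient space and then to continuous
indices of each source, sampled by trilinear interpolation, and the two
values are averaged. Because the axial stack is sharp in-plane and the
coronal stack is sharp along z, their average carries more detail than
either thick stack alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .admission import check_orthogonality
from .geometry import CTVolume, VolumeGeometry

__all__ = ["FusionResult", "resample_to_grid", "fuse"]

FILL_HU = -1000.0


@dataclass
class FusionResult:
    """Fused LR volume plus per-voxel provenance.

    ``coverage_mask`` is True where *both* sources covered the voxel;
    ``n_sources`` counts covering sources (0, 1 or 2) per voxel.
    """

    lr: CTVolume
    coverage_mask: np.ndarray
    n_sources: np.ndarray
    provenance: tuple[str | None, str | None]


def resample_to_grid(
    src: CTVolume, target: VolumeGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly resample ``src`` onto ``target`` voxel centers.

    Returns ``(values, covered)`` where ``covered`` is False wherever a
    target voxel center falls outside the source voxel-center extent
    (there the value is the −1000 HU fill).
    """
    if abs(np.linalg.det(src.geometry.direction)) < 1e-9:
        raise ValueError("source direction matrix is singular")
    idx = np.indices(target.size, dtype=float).reshape(3, -1).T
    world = target.index_to_world(idx)
    src_idx = src.geometry.world_to_index(world)  # (n, 3) continuous

    size = np.asarray(src.geometry.size)
    covered = np.all((src_idx >= 0.0) & (src_idx <= size - 1), axis=1)
    values = map_coordinates(
        src.intensities, src_idx.T, order=1, mode="constant", cval=FILL_HU
    )
    values[~covered] = FILL_HU
    return values.reshape(target.size), covered.reshape(target.size)


def fuse(
    thick_axial: CTVolume,
    thick_coronal: CTVolume,
    target: VolumeGeometry,
    ortho_tol: float = 1e-3,
) -> FusionResult:
    """Average the two resampled thick series on the target grid.

    Voxels covered by both sources get the mean of the two trilinear
    values; voxels covered by one source keep that single value; voxels
    covered by neither are filled with −1000 HU (air). A pair whose
    slice planes are not mutually orthogonal is rejected, mirroring the
    admission rule applied to the clinical material.
    """
    if not check_orthogonality(thick_axial.geometry, thick_coronal.geometry, ortho_tol):
        raise ValueError(
            "thick axial and coronal series are not right orthogonal; pair rejected"
        )
    va, ca = resample_to_grid(thick_axial, target)
    vc, cc = resample_to_grid(thick_coronal, target)

    n_sources = ca.astype(np.int8) + cc.astype(np.int8)
    out = np.full(target.size, FILL_HU)
    both = ca & cc
    out[both] = 0.5 * (va[both] + vc[both])
    only_a = ca & ~cc
    out[only_a] = va[only_a]
    only_c = cc & ~ca
    out[only_c] = vc[only_c]

    lr = CTVolume(
        out,
        target,
        slice_thickness=target.spacing[2],
        series_id="fused-lr",
        metadata={"sources": (thick_axial.series_id, thick_coronal.series_id)},
    )
    return FusionResult(
        lr=lr,
        coverage_mask=both,
        n_sources=n_sources,
        provenance=(thick_axial.series_id, thick_coronal.series_id),
    )
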