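"""Seeded synthetic chest-like CT phantoms.

Emulates the study material: for each case a thin-slice axial volume
(the high-resolution ground truth) plus two thick series derived from
it by block averaging — a 5 mm axial stack and a 5 mm coronal stack.
The phantom is deliberately simple anatomy: an ellipsoidal soft-tissue
body (≈40 HU) in ambient air (−1000 HU), two low-density lung fields
(≈−800 HU) containing bright tubular vessels (≈0 HU) and ground-glass-
like nodules (≈−400 HU), with additive Gaussian noise confined to the
body so that the surrounding air stays exactly blank, as it nearly does
in clinical scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CTVolume, VolumeGeometry, canonical_coronal_direction

__all__ = ["PhantomSpec", "make_phantom_hr", "degrade_to_thick", "make_triplet"]

HU_AIR = -1000.0
HU_BODY = 40.0
HU_LUNG = -800.0
HU_VESSEL = 0.0
HU_NODULE = -400.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Sizes and spacings are in voxels and mm on the thin (1 mm) grid;
    ``body_axes`` / ``lung_axes`` are ellipsoid semi-axes in mm and
    ``lung_offsets`` the two lung centers relative to the body center.
    """

    size: tuple[int, int, int] = (96, 96, 60)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_axes: tuple[float, float, float] | None = None
    lung_axes: tuple[float, float, float] | None = None
    lung_offsets: tuple[tuple[float, float, float], ...] | None = None
    n_vessels: int = 8
    n_nodules: int = 3
    noise_sd: float = 15.0
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # default anatomy scales with the physical extent so that the
        # lungs never touch the volume border at any grid size
        ex, ey, ez = (n * s for n, s in zip(self.size, self.spacing))
        if self.body_axes is None:
            self.body_axes = (0.42 * ex, 0.33 * ey, 0.45 * ez)
        if self.lung_axes is None:
            self.lung_axes = (0.14 * ex, 0.20 * ey, 0.30 * ez)
        if self.lung_offsets is None:
            self.lung_offsets = ((-0.19 * ex, -0.02 * ey, 0.0), (0.19 * ex, -0.02 * ey, 0.0))


def _ellipsoid_mask(grid: tuple[np.ndarray, ...], center, axes) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    ax, ay, az = axes
    return (
        ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    ) <= 1.0


def make_phantom_hr(spec: PhantomSpec) -> CTVolume:
    """Generate the thin-slice (HR) phantom volume.

    Deterministic given ``spec.seed``. Raises if a lung ellipsoid is
    not contained in the body ellipsoid.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.size
    sx, sy, sz = spec.spacing
    # voxel-center coordinates in mm, relative to the volume center
    x = (np.arange(nx) - (nx - 1) / 2.0)[:, None, None] * sx
    y = (np.arange(ny) - (ny - 1) / 2.0)[None, :, None] * sy
    z = (np.arange(nz) - (nz - 1) / 2.0)[None, None, :] * sz
    grid = (x, y, z)

    body = _ellipsoid_mask(grid, (0, 0, 0), spec.body_axes)
    hu = np.full(spec.size, HU_AIR)
    hu[body] = HU_BODY

    lung_mask = np.zeros(spec.size, dtype=bool)
    lung_centers = []
    for off in spec.lung_offsets:
        lung = _ellipsoid_mask(grid, off, spec.lung_axes)
        if np.any(lung & ~body):
            raise ValueError("lung ellipsoid exceeds the body ellipsoid")
        lung_mask |= lung
        lung_centers.append(np.asarray(off, dtype=float))
    hu[lung_mask] = HU_LUNG

    # tubular vessels: random segments through a lung, ~1.5 mm radius
    pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)  # (nx,ny,nz,3)
    for _ in range(spec.n_vessels):
        c = lung_centers[rng.integers(len(lung_centers))]
        start = c + (rng.random(3) - 0.5) * np.asarray(spec.lung_axes)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        half_len = rng.uniform(8.0, 16.0)
        radius = rng.uniform(1.0, 2.0)
        rel = pts - start
        t = np.clip(rel @ direction, -half_len, half_len)
        dist = np.linalg.norm(rel - t[..., None] * direction, axis=-1)
        hu[(dist <= radius) & lung_mask] = HU_VESSEL

    # ground-glass-like nodules: small spheres inside a lung
    for _ in range(spec.n_nodules):
        c = lung_centers[rng.integers(len(lung_centers))]
        center = c + (rng.random(3) - 0.5) * 0.8 * np.asarray(spec.lung_axes)
        radius = rng.uniform(2.0, 4.0)
        nod = np.linalg.norm(pts - center, axis=-1) <= radius
        hu[nod & lung_mask] = HU_NODULE

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=spec.size)
        hu = hu + noise * body  # noise confined to the body

    geom = VolumeGeometry(
        origin=spec.origin,
        spacing=spec.spacing,
        direction=np.eye(3),
        size=spec.size,
    )
    return CTVolume(hu, geom, slice_thickness=sz, series_id=f"phantom-{spec.seed}")


def degrade_to_thick(hr: CTVolume, axis: str, factor: int) -> CTVolume:
    """Derive a thick-slice series by boxcar-averaging the thin stack.

    ``axis='axial'`` averages blocks of ``factor`` thin slices along the
    patient z axis; ``axis='coronal'`` averages along the patient y axis
    and re-grids the result so its third array axis is the
    anterior-posterior axis (a proper coronal stack). A trailing
    remainder of slices that does not fill a block is dropped. Slice
    thickness equals the new inter-slice spacing (contiguous slabs).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not np.allclose(hr.geometry.direction, np.eye(3), atol=1e-6):
        raise ValueError("degrade_to_thick expects a canonical axial HR volume")
    arr = hr.intensities
    sx, sy, sz = hr.geometry.spacing
    nx, ny, nz = arr.shape

    if axis == "axial":
        nb = nz // factor
        blocks = arr[:, :, : nb * factor].reshape(nx, ny, nb, factor)
        thick = blocks.mean(axis=3)
        new_spacing = (sx, sy, sz * factor)
        # origin shifts to the center of the first block
        origin = hr.geometry.origin + np.array([0.0, 0.0, sz * (factor - 1) / 2.0])
        geom = VolumeGeometry(origin, new_spacing, np.eye(3), thick.shape)
        return CTVolume(thick, geom, slice_thickness=sz * factor,
                        series_id=(hr.series_id or "hr") + "-thick-axial")

    if axis == "coronal":
        nb = ny // factor
        blocks = arr[:, : nb * factor, :].reshape(nx, nb, factor, nz)
        avg = blocks.mean(axis=2)  # (nx, nb, nz)
        # re-grid: coronal array axes are (x, -z, +y)
        thick = avg.transpose(0, 2, 1)[:, ::-1, :]
        direction = canonical_coronal_direction()
        new_spacing = (sx, sz, sy * factor)
        origin = hr.geometry.origin + np.array(
            [0.0, sy * (factor - 1) / 2.0, sz * (nz - 1)]
        )
        geom = VolumeGeometry(origin, new_spacing, direction, thick.shape)
        return CTVolume(np.ascontiguousarray(thick), geom,
                        slice_thickness=sy * factor,
                        series_id=(hr.series_id or "hr") + "-thick-coronal")

    raise ValueError(f"axis must be 'axial' or 'coronal', got {axis!r}")


def make_triplet(spec: PhantomSpec, factor: int = 5) -> tuple[CTVolume, CTVolume, CTVolume]:
    """Generate (thin_axial, thick_axial, thick_coronal) for one case.

    Both thick series are derived from the same HR volume, mirroring a
    scanner reconstructing 5 mm axial and 5 mm coronal stacks from one
    acquisition.
    """
    hr = make_phantom_hr(spec)
    thick_axial = degrade_to_thick(hr, "axial", factor)
    thick_coronal = degrade_to_thick(hr, "coronal", factor)
    return hr, thick_axial, thick_coronal
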