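"""Series admission rules for a CT case.

A usable case consists of three series from one study: a thin axial
stack (1–1.25 mm slices, interval 0.7–1.25 mm and no wider than the
thickness), a 5 mm axial stack and a 5 mm coronal stack, with the two
planes right orthogonal to each other. Cases violating any rule are
rejected with per-rule reasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CTVolume, VolumeGeometry

__all__ = [
    "SeriesRequirements",
    "TripletVerdict",
    "check_orthogonality",
    "validate_triplet",
]


@dataclass
class SeriesRequirements:
    """Admission thresholds, all in mm."""

    thin_thickness_range: tuple[float, float] = (1.0, 1.25)
    thin_interval_range: tuple[float, float] = (0.7, 1.25)
    thick_thickness: float = 5.0
    thick_interval: float = 5.0
    tolerance: float = 1e-3
    ortho_tol: float = 1e-3

    def __post_init__(self) -> None:
        vals = [*self.thin_thickness_range, *self.thin_interval_range,
                self.thick_thickness, self.thick_interval]
        if any(v <= 0 for v in vals):
            raise ValueError("all requirement values must be positive")


@dataclass
class TripletVerdict:
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.accepted


def _is_axis_aligned(direction: np.ndarray, tol: float) -> bool:
    # every direction column must coincide with a signed patient axis
    for col in direction.T:
        off = np.sort(np.abs(col))[:2]  # two smallest |components|
        if np.any(off > tol):
            return False
    return True


def check_orthogonality(
    axial: VolumeGeometry, coronal: VolumeGeometry, tol: float = 1e-3
) -> bool:
    """True iff the two slice planes are right orthogonal.

    Requires the coronal slice normal to be orthogonal to the axial
    slice normal within ``tol`` (absolute cosine residual) and the
    in-plane axes of both series to align with the patient axes within
    ``tol``. Pure predicate, symmetric in its arguments and independent
    of voxel spacing.
    """
    if abs(float(axial.slice_normal @ coronal.slice_normal)) > tol:
        return False
    return _is_axis_aligned(axial.direction, tol) and _is_axis_aligned(
        coronal.direction, tol
    )


def _interval_from_positions(vol: CTVolume) -> float:
    """Inter-slice spacing as recorded in the geometry (mm)."""
    return float(vol.geometry.spacing[2])


def validate_triplet(
    thin_axial: CTVolume,
    thick_axial: CTVolume,
    thick_coronal: CTVolume,
    req: SeriesRequirements | None = None,
) -> TripletVerdict:
    """Apply the admission rules to one case; report each failure.

    Thickness is taken from the SliceThickness metadata carried on the
    volume; the interval is the inter-slice spacing computed from slice
    positions at read time.
    """
    req = req or SeriesRequirements()
    tol = req.tolerance
    reasons: list[str] = []

    t = thin_axial.slice_thickness
    lo, hi = req.thin_thickness_range
    if t is None or not (lo - tol <= t <= hi + tol):
        reasons.append(
            f"thin axial thickness {t} mm outside [{lo}, {hi}] mm"
        )
    iv = _interval_from_positions(thin_axial)
    ilo, ihi = req.thin_interval_range
    if not (ilo - tol <= iv <= ihi + tol):
        reasons.append(f"thin axial interval {iv} mm outside [{ilo}, {ihi}] mm")
    if t is not None and iv > t + tol:
        reasons.append(f"thin axial interval {iv} mm exceeds thickness {t} mm")

    for name, vol in (("thick axial", thick_axial), ("thick coronal", thick_coronal)):
        tt = vol.slice_thickness
        if tt is None or abs(tt - req.thick_thickness) > tol:
            reasons.append(f"{name} thickness {tt} mm != {req.thick_thickness} mm")
        ivv = _interval_from_positions(vol)
        if abs(ivv - req.thick_interval) > tol:
            reasons.append(f"{name} interval {ivv} mm != {req.thick_interval} mm")

    if not check_orthogonality(
        thick_axial.geometry, thick_coronal.geometry, req.ortho_tol
    ):
        reasons.append("thick axial and coronal planes are not right orthogonal")

    return TripletVerdict(accepted=not reasons, reasons=reasons)
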