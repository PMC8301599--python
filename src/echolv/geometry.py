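"""Standard left-ventricular coordinate frame and anchor-point parameterization.

The LV wall is parameterized by 48 *anchor points*: the radius from the central
z-axis at 6 rotations (30..330 degrees, counterclockwise from +x), on 2
boundaries (endocardium, epicardium), at 4 short-axis slice levels (25, 50, 75
and 100 % of the apex-to-base distance).  The coordinate frame is right-handed:
z runs from the apex (low z) to the base (high z), the anterior/posterior walls
lie along +y/-y, and the septal wall lies on the negative x-axis (standard
radiological short-axis orientation).

Apex and base z-positions are tracked per frame; slice levels are defined as
fractions of the *current* apex-to-base distance, which compensates for
through-plane motion of the heart during the cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import GeometryError, OutOfRangeError

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import CineDataset

ANCHOR_THETAS_DEG: tuple[float, ...] = (30.0, 90.0, 150.0, 210.0, 270.0, 330.0)
ANCHOR_Z_FRACS: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
BOUNDARIES: tuple[str, str] = ("endo", "epi")
#: slice levels as fractions of the apex-to-base distance
SLICE_FRACTIONS: tuple[float, ...] = ANCHOR_Z_FRACS
N_ANCHORS = len(ANCHOR_THETAS_DEG) * len(ANCHOR_Z_FRACS) * len(BOUNDARIES)


@dataclass(frozen=True)
class AnchorIndex:
    """One of the 48 anchor sites: (rotation, boundary, slice level)."""

    theta_deg: float
    boundary: str
    z_frac: float

    def __post_init__(self) -> None:
        if float(self.theta_deg) not in ANCHOR_THETAS_DEG:
            raise GeometryError(
                f"theta_deg must be one of {ANCHOR_THETAS_DEG}, got {self.theta_deg}"
            )
        if self.boundary not in BOUNDARIES:
            raise GeometryError(f"boundary must be 'endo' or 'epi', got {self.boundary!r}")
        if float(self.z_frac) not in ANCHOR_Z_FRACS:
            raise GeometryError(
                f"z_frac must be one of {ANCHOR_Z_FRACS}, got {self.z_frac}"
            )
        object.__setattr__(self, "theta_deg", float(self.theta_deg))
        object.__setattr__(self, "z_frac", float(self.z_frac))


@lru_cache(maxsize=1)
def anchor_grid() -> tuple[AnchorIndex, ...]:
    """The 48 anchors in canonical order: z ascending, endo before epi, theta ascending."""
    return tuple(
        AnchorIndex(theta, boundary, z)
        for z in ANCHOR_Z_FRACS
        for boundary in BOUNDARIES
        for theta in ANCHOR_THETAS_DEG
    )


@lru_cache(maxsize=1)
def _anchor_columns() -> dict[AnchorIndex, int]:
    return {anchor: i for i, anchor in enumerate(anchor_grid())}


def anchor_column(anchor: AnchorIndex) -> int:
    """Column position of *anchor* in the canonical 48-wide layout."""
    return _anchor_columns()[anchor]


@dataclass
class AnchorRadii:
    """Radii (mm) on the 48-anchor grid across frames.

    ``values`` has shape ``(n_frames, 48)`` in the :func:`anchor_grid` column
    order; ``cycle_phase`` gives the cycle fraction of each frame (phase 0 is
    end-diastole).  Validation enforces strictly positive radii and the
    anatomical ordering epicardium >= endocardium; model *predictions* are not
    guaranteed to satisfy either, so they are constructed with
    ``validate=False``.
    """

    values: np.ndarray
    cycle_phase: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cycle_phase = np.asarray(self.cycle_phase, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_ANCHORS:
            raise GeometryError(
                f"values must have shape (n_frames, {N_ANCHORS}), got {self.values.shape}"
            )
        if self.cycle_phase.shape != (self.values.shape[0],):
            raise GeometryError("cycle_phase length must match the number of frames")
        if self.validate:
            if not np.all(self.values > 0):
                raise GeometryError("anchor radii must be strictly positive")
            grid = self.values.reshape(self.n_frames, 4, 2, 6)
            if not np.all(grid[:, :, 1, :] >= grid[:, :, 0, :]):
                raise GeometryError("epicardial radius must be >= endocardial radius")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def radius(self, anchor: AnchorIndex, frame: int) -> float:
        return float(self.values[frame, anchor_column(anchor)])

    def to_tidy(self, animal_id: str | None = None) -> pd.DataFrame:
        """Long-format table: one row per (frame, anchor)."""
        anchors = anchor_grid()
        frames = np.repeat(np.arange(self.n_frames), N_ANCHORS)
        df = pd.DataFrame(
            {
                "frame": frames,
                "cycle_phase": self.cycle_phase[frames],
                "theta_deg": np.tile([a.theta_deg for a in anchors], self.n_frames),
                "boundary": np.tile([a.boundary for a in anchors], self.n_frames),
                "z_frac": np.tile([a.z_frac for a in anchors], self.n_frames),
                "radius_mm": self.values.ravel(),
            }
        )
        if animal_id is not None:
            df.insert(0, "animal_id", animal_id)
        return df

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, validate: bool = True) -> "AnchorRadii":
        frames = np.sort(df["frame"].unique())
        values = np.empty((len(frames), N_ANCHORS))
        phase = np.empty(len(frames))
        cols = _anchor_columns()
        for fi, f in enumerate(frames):
            sub = df[df["frame"] == f]
            phase[fi] = float(sub["cycle_phase"].iloc[0])
            for _, row in sub.iterrows():
                a = AnchorIndex(row["theta_deg"], row["boundary"], row["z_frac"])
                values[fi, cols[a]] = row["radius_mm"]
        return cls(values=values, cycle_phase=phase, validate=validate)


# ---------------------------------------------------------------------------
# slice extraction


def slice_positions_mm(apex_z: float, base_z: float,
                       fractions: Sequence[float] = SLICE_FRACTIONS) -> np.ndarray:
    if not apex_z < base_z:
        raise GeometryError(f"apex_z ({apex_z}) must be below base_z ({base_z})")
    return apex_z + np.asarray(fractions, dtype=float) * (base_z - apex_z)


def extract_slices(dataset: "CineDataset", frame: int,
                   fractions: Sequence[float] = SLICE_FRACTIONS) -> np.ndarray:
    """Interpolate short-axis slices at the standard levels for one frame.

    Levels are fractions of the apex-to-base distance *at the requested frame*
    (through-plane compensation).  Intensities are linearly interpolated
    between stored slices; a level that coincides with a stored plane is
    returned exactly.

    Returns an array of shape ``(len(fractions), ny, nx)``.
    """
    z_req = slice_positions_mm(float(dataset.apex_z[frame]),
                               float(dataset.base_z[frame]), fractions)
    nz = dataset.intensities.shape[1]
    pos = (z_req - dataset.slice_origin_z) / dataset.slice_spacing
    if pos.min() < -1e-9 or pos.max() > nz - 1 + 1e-9:
        raise OutOfRangeError(
            f"frame {frame}: requested slice positions {z_req} mm fall outside the "
            f"stored stack ([{dataset.slice_origin_z}, "
            f"{dataset.slice_origin_z + (nz - 1) * dataset.slice_spacing}] mm)"
        )
    pos = np.clip(pos, 0.0, nz - 1)
    i0 = np.minimum(np.floor(pos).astype(int), nz - 2)
    w = pos - i0
    vol = dataset.intensities[frame].astype(float)
    return (1.0 - w)[:, None, None] * vol[i0] + w[:, None, None] * vol[i0 + 1]


@dataclass
class SliceStack:
    """Standard-level short-axis images for every frame of one dataset.

    ``images`` has shape ``(n_frames, n_slices, ny, nx)``.  This is the input
    actually consumed by the boundary models; it can be precomputed once per
    dataset and reused across cross-validation iterations.
    """

    images: np.ndarray
    cycle_phase: np.ndarray
    animal_id: str
    apex_z: np.ndarray
    base_z: np.ndarray
    cycle_duration_s: float
    pixel_spacing: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]


def slice_stack(dataset: "CineDataset",
                fractions: Sequence[float] = SLICE_FRACTIONS) -> SliceStack:
    """Extract the four standard slices for every frame of *dataset*."""
    images = np.stack(
        [extract_slices(dataset, t, fractions) for t in range(len(dataset.cycle_phase))]
    ).astype(np.float32)
    return SliceStack(
        images=images,
        cycle_phase=np.asarray(dataset.cycle_phase, dtype=float),
        animal_id=dataset.animal_id,
        apex_z=np.asarray(dataset.apex_z, dtype=float),
        base_z=np.asarray(dataset.base_z, dtype=float),
        cycle_duration_s=dataset.cycle_duration_s,
        pixel_spacing=dataset.pixel_spacing,
    )


# ---------------------------------------------------------------------------
# polar <-> cartesian


def anchors_to_points(radii: AnchorRadii, frame: int,
                      apex_z: float, base_z: float) -> np.ndarray:
    """3D coordinates (mm) of all 48 anchors at one frame, shape (48, 3)."""
    anchors = anchor_grid()
    theta = np.radians([a.theta_deg for a in anchors])
    z_frac = np.array([a.z_frac for a in anchors])
    r = radii.values[frame]
    return np.column_stack(
        [r * np.cos(theta), r * np.sin(theta), apex_z + z_frac * (base_z - apex_z)]
    )


def point_to_polar(point: Sequence[float]) -> tuple[float, float]:
    """Inverse of the anchor placement: (radius mm, theta deg in [0, 360))."""
    x, y = float(point[0]), float(point[1])
    return math.hypot(x, y), math.degrees(math.atan2(y, x)) % 360.0


# ---------------------------------------------------------------------------
# rigid reorientation

class RigidTransform:
    """Rigid transform (rotation + translation, mm) mapping scanner to standard axes.

    Real acquisitions are manually reoriented so that the LV long axis lies on
    z and the septum on -x; this class carries that user-supplied alignment.
    Phantom data are generated pre-aligned, so the identity is the default.
    """

    def __init__(self, rotation: np.ndarray | None = None,
                 translation_mm: Sequence[float] | None = None) -> None:
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation must be a 3x3 orthonormal matrix")
        self.rotation = R
        self.translation_mm = (
            np.zeros(3) if translation_mm is None else np.asarray(translation_mm, float)
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(cls, angles_deg: Sequence[float],
                   translation_mm: Sequence[float] | None = None) -> "RigidTransform":
        """Extrinsic x-y-z Euler angles in degrees."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
        return cls(R, translation_mm)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation_mm

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation_mm)

    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3)) and np.allclose(self.translation_mm, 0)


def reorient_dataset(dataset: "CineDataset", transform: RigidTransform,
                     order: int = 1) -> "CineDataset":
    """Resample the cine stack under a rigid transform of physical coordinates.

    Output voxel grids coincide with the input grids; the image center is the
    in-plane origin and stored-slice positions define z.  Intensities outside
    the input field of view are filled with the volume minimum.
    """
    from dataclasses import replace

    if transform.is_identity():
        return dataset
    t, nz, ny, nx = dataset.intensities.shape
    scale = np.diag([dataset.slice_spacing, dataset.pixel_spacing, dataset.pixel_spacing])
    origin = np.array(
        [dataset.slice_origin_z,
         -(ny - 1) / 2 * dataset.pixel_spacing,
         -(nx - 1) / 2 * dataset.pixel_spacing]
    )
    # physical coords are (x, y, z); voxel axes are (z, y, x)
    perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    vox_to_mm = perm @ scale
    Rinv = transform.rotation.T
    mm_to_vox = np.linalg.inv(vox_to_mm)
    o_phys = perm @ origin
    # affine_transform maps output voxel v to input voxel: matrix @ v + offset
    matrix = mm_to_vox @ Rinv @ vox_to_mm
    offset = mm_to_vox @ (Rinv @ (o_phys - transform.translation_mm) - o_phys)
    fill = float(dataset.intensities.min())
    out = np.empty_like(dataset.intensities)
    for i in range(t):
        out[i] = ndimage.affine_transform(
            dataset.intensities[i].astype(float), matrix, offset=offset,
            order=order, mode="constant", cval=fill,
        ).astype(dataset.intensities.dtype)
    return replace(dataset, intensities=out)
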