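"""4D surface meshing: anchor radii -> standardized 60 x 60 x 60 LV surfaces.

Anchor radii (6 rotations x 4 slice levels per boundary, over one cycle) are
interpolated to a dense, standardized sampling: 60 rotations around the
z-axis, 60 apex-to-base levels, and 60 uniformly spaced cycle positions.
Interpolation proceeds axis by axis, in a fixed, documented order:

1. **theta** -- a closed periodic interpolating cubic through the six anchor
   radii of each (slice, frame);
2. **z** -- a natural cubic spline across the four slice levels, extended to
   an apex point where the radius is 0 at level 0 (the basal end is left
   open);
3. **time** -- a periodic cubic spline across the cycle, resampled to the 60
   uniform phases.

The curves interpolate (they pass through every control value exactly) and
are C1-smooth, including across the 360->0 degree and phase 1->0 wraps.  An
alternative tension-based Bezier engine in the spirit of Hobby's curve
construction is available via ``engine="hobby"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import geometry
from .exceptions import GeometryError, InsufficientDataError

N_THETA = 60
N_Z = 60
N_TIME = 60
THETA_SAMPLES_DEG = np.arange(N_THETA) * (360.0 / N_THETA)
Z_SAMPLES = np.arange(1, N_Z + 1) / N_Z  # (0, 1]; excludes the singular apex point
TIME_SAMPLES = np.arange(N_TIME) / N_TIME


@dataclass
class LVMesh:
    """Dense 4D sampling of the endo- and epi-cardial surfaces.

    ``radii`` has shape (2, n_time, n_z, n_theta) with boundary order
    (endo, epi); ``z_fracs`` are apex-to-base fractions and ``apex_z`` /
    ``base_z`` give the per-time-sample track positions in mm, so the
    physical z of sample (t, iz) is ``apex_z[t] + z_fracs[iz] *
    (base_z[t] - apex_z[t])``.
    """

    radii: np.ndarray
    theta_deg: np.ndarray
    z_fracs: np.ndarray
    phases: np.ndarray
    apex_z: np.ndarray
    base_z: np.ndarray
    cycle_duration_s: float = 0.12

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.ndim != 4 or self.radii.shape[0] != 2:
            raise GeometryError("radii must have shape (2, n_time, n_z, n_theta)")
        if not np.all(self.radii > 0):
            raise GeometryError("mesh radii must be strictly positive")

    @staticmethod
    def boundary_index(boundary: str) -> int:
        try:
            return geometry.BOUNDARIES.index(boundary)
        except ValueError:
            raise GeometryError(f"boundary must be 'endo' or 'epi', got {boundary!r}")

    @property
    def n_time(self) -> int:
        return self.radii.shape[1]

    def z_mm(self, t_index: int) -> np.ndarray:
        return self.apex_z[t_index] + self.z_fracs * (
            self.base_z[t_index] - self.apex_z[t_index]
        )


# ---------------------------------------------------------------------------
# closed-curve engines


def _periodic_radius_spline(anchor_deg: np.ndarray, radii: np.ndarray) -> CubicSpline:
    """Periodic cubic spline r(theta) through radii at anchor angles (deg).

    ``radii`` may be multi-dimensional with the angle axis first.
    """
    th = np.concatenate([anchor_deg, [anchor_deg[0] + 360.0]])
    vals = np.concatenate([radii, radii[:1]], axis=0)
    return CubicSpline(th, vals, bc_type="periodic", axis=0)


def _wrap_angles(output_deg: np.ndarray, start_deg: float) -> np.ndarray:
    return (np.asarray(output_deg, dtype=float) - start_deg) % 360.0 + start_deg


def _hobby_velocity(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Hobby's velocity (control-handle length) function at tension 1."""
    st, sp = np.sin(theta), np.sin(phi)
    ct, cp = np.cos(theta), np.cos(phi)
    rt5 = np.sqrt(5.0)
    num = 2.0 + np.sqrt(2.0) * (st - sp / 16.0) * (sp - st / 16.0) * (ct - cp)
    den = 3.0 * (1.0 + 0.5 * (rt5 - 1.0) * ct + 0.5 * (3.0 - rt5) * cp)
    return num / den


def _hobby_closed_points(points: np.ndarray, samples_per_segment: int = 64) -> np.ndarray:
    """Closed C1 cubic-Bezier curve through ``points`` (n, 2).

    Tension-based construction in the spirit of Hobby's curve algorithm:
    tangent directions are taken along the chord between each point's
    neighbours (a standard closed-curve choice) and control-handle lengths
    use Hobby's velocity formula at tension 1.  Segment endpoints are
    included in the samples, so the returned polyline passes through every
    control point exactly.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    tang_ang = np.arctan2(tang[:, 1], tang[:, 0])

    out = []
    ts = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)
    for i in range(n):
        p0, p3 = pts[i], pts[(i + 1) % n]
        chord = p3 - p0
        ell = np.linalg.norm(chord)
        omega = np.arctan2(chord[1], chord[0])
        theta = (tang_ang[i] - omega + np.pi) % (2 * np.pi) - np.pi
        phi = (omega - tang_ang[(i + 1) % n] + np.pi) % (2 * np.pi) - np.pi
        r0 = _hobby_velocity(theta, phi) * ell
        r1 = _hobby_velocity(phi, theta) * ell
        c1 = p0 + r0 * np.array([np.cos(omega + theta), np.sin(omega + theta)])
        c2 = p3 - r1 * np.array([np.cos(omega - phi), np.sin(omega - phi)])
        t = ts[:, None]
        seg = ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * c1
               + 3 * (1 - t) * t ** 2 * c2 + t ** 3 * p3)
        out.append(seg)
    return np.vstack(out)


def interpolate_closed_curve(
    radii: Sequence[float] | np.ndarray,
    output_deg: np.ndarray = THETA_SAMPLES_DEG,
    anchor_deg: Sequence[float] = geometry.ANCHOR_THETAS_DEG,
    engine: str = "spline",
) -> np.ndarray:
    """Radii of a smooth closed contour through the six anchor radii.

    The default engine is a periodic parametric cubic spline in polar form,
    which reproduces a circle exactly when all input radii are equal;
    ``engine="hobby"`` uses the tension-based Bezier construction (exact at
    the anchors, approximate elsewhere, sampled densely and read off by
    angle).
    """
    radii = np.asarray(radii, dtype=float)
    anchor_deg = np.asarray(anchor_deg, dtype=float)
    if radii.shape[0] != len(anchor_deg):
        raise GeometryError(
            f"expected {len(anchor_deg)} radii at the standard angles, got {radii.shape}"
        )
    if np.any(radii <= 0):
        raise GeometryError("contour radii must be strictly positive")
    if engine == "spline":
        cs = _periodic_radius_spline(anchor_deg, radii)
        return cs(_wrap_angles(output_deg, anchor_deg[0]))
    if engine == "hobby":
        th = np.radians(anchor_deg)
        pts = np.column_stack([radii * np.cos(th), radii * np.sin(th)])
        curve = _hobby_closed_points(pts)
        ang = np.degrees(np.arctan2(curve[:, 1], curve[:, 0])) % 360.0
        rad = np.hypot(curve[:, 0], curve[:, 1])
        order = np.argsort(ang)
        ang_s, rad_s = ang[order], rad[order]
        ang_ext = np.concatenate([ang_s - 360.0, ang_s, ang_s + 360.0])
        rad_ext = np.concatenate([rad_s, rad_s, rad_s])
        return np.interp(np.asarray(output_deg, float) % 360.0, ang_ext, rad_ext)
    raise ValueError(f"unknown curve engine {engine!r}")


# ---------------------------------------------------------------------------
# mesh construction


def build_lv_mesh(
    radii: geometry.AnchorRadii,
    apex_z: np.ndarray,
    base_z: np.ndarray,
    cycle_duration_s: float = 0.12,
    engine: str = "spline",
    n_theta: int = N_THETA,
    n_z: int = N_Z,
    n_time: int = N_TIME,
    phases_out: np.ndarray | None = None,
) -> LVMesh:
    """Interpolate anchor radii into the dense standardized 4D mesh.

    ``apex_z``/``base_z`` are per-input-frame tracks (mm) and are resampled
    to the output phases with the same periodic temporal spline.
    ``phases_out`` overrides the default uniform grid of ``n_time`` phases.
    """
    F = radii.n_frames
    if F < 8:
        raise InsufficientDataError(f"mesh construction needs >= 8 frames, got {F}")
    apex_z = np.asarray(apex_z, dtype=float)
    base_z = np.asarray(base_z, dtype=float)
    phases = radii.cycle_phase
    theta_out = np.arange(n_theta) * (360.0 / n_theta)
    z_out = np.arange(1, n_z + 1) / n_z
    if phases_out is None:
        phases_out = np.arange(n_time) / n_time
    phases_out = np.asarray(phases_out, dtype=float)

    anchor_deg = np.asarray(geometry.ANCHOR_THETAS_DEG)
    vals = radii.values.reshape(F, 4, 2, 6)  # (frame, z, boundary, theta)

    out = np.empty((2, len(phases_out), n_z, n_theta))
    for b in range(2):
        A = np.moveaxis(vals[:, :, b, :], 2, 0)  # (6 theta, frame, 4 z)
        # 1) closed curve in theta
        if engine == "spline":
            cs_theta = _periodic_radius_spline(anchor_deg, A)
            r_theta = cs_theta(_wrap_angles(theta_out, anchor_deg[0]))  # (n_theta, F, 4)
        elif engine == "hobby":
            r_theta = np.empty((n_theta, F, 4))
            for t in range(F):
                for zi in range(4):
                    r_theta[:, t, zi] = interpolate_closed_curve(
                        A[:, t, zi], output_deg=theta_out, engine="hobby"
                    )
        else:
            raise ValueError(f"unknown curve engine {engine!r}")
        # 2) natural cubic in z, closed to radius 0 at the apex
        z_knots = np.concatenate([[0.0], np.asarray(geometry.ANCHOR_Z_FRACS)])
        y_z = np.concatenate(
            [np.zeros((1, n_theta, F)), np.moveaxis(r_theta, 2, 0)], axis=0
        )  # (5, n_theta, F)
        r_z = CubicSpline(z_knots, y_z, bc_type="natural", axis=0)(z_out)
        # (n_z, n_theta, F)
        # 3) periodic cubic in cycle phase
        ph_knots = np.concatenate([phases, [phases[0] + 1.0]])
        y_t = np.concatenate([r_z, r_z[..., :1]], axis=-1)
        cs_t = CubicSpline(ph_knots, np.moveaxis(y_t, 2, 0), bc_type="periodic", axis=0)
        ph_eval = phases[0] + np.mod(phases_out - phases[0], 1.0)
        out[b] = cs_t(ph_eval)  # (n_time, n_z, n_theta)

    def resample_track(track: np.ndarray) -> np.ndarray:
        y = np.concatenate([track, track[:1]])
        cs = CubicSpline(np.concatenate([phases, [phases[0] + 1.0]]), y,
                         bc_type="periodic")
        return cs(phases[0] + np.mod(phases_out - phases[0], 1.0))

    if np.any(out <= 0):
        raise GeometryError(
            "interpolated mesh contains non-positive radii; anchor radii are "
            "too irregular for a valid closed surface"
        )
    return LVMesh(
        radii=out,
        theta_deg=theta_out,
        z_fracs=z_out,
        phases=phases_out,
        apex_z=resample_track(apex_z),
        base_z=resample_track(base_z),
        cycle_duration_s=cycle_duration_s,
    )


# ---------------------------------------------------------------------------
# export


def mesh_points(mesh: LVMesh, boundary: str, t_index: int) -> np.ndarray:
    """Cartesian vertices (n_z * n_theta, 3) of one boundary at one time sample."""
    b = mesh.boundary_index(boundary)
    r = mesh.radii[b, t_index]  # (n_z, n_theta)
    th = np.radians(mesh.theta_deg)[None, :]
    z = mesh.z_mm(t_index)[:, None]
    x = r * np.cos(th)
    y = r * np.sin(th)
    zz = np.broadcast_to(z, r.shape)
    return np.column_stack([x.ravel(), y.ravel(), zz.ravel()])


def mesh_to_frame(mesh: LVMesh) -> pd.DataFrame:
    """Long-format table of the full 4D mesh (radius and cartesian coordinates)."""
    rows = []
    for b, bname in enumerate(geometry.BOUNDARIES):
        for t in range(mesh.n_time):
            pts = mesh_points(mesh, bname, t)
            nz, nth = mesh.radii.shape[2:]
            zi, ti = np.divmod(np.arange(nz * nth), nth)
            rows.append(pd.DataFrame({
                "boundary": bname,
                "t_index": t,
                "z_index": zi,
                "angle_index": ti,
                "radius_mm": mesh.radii[b, t].ravel(),
                "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
            }))
    return pd.concat(rows, ignore_index=True)


def mesh_to_obj(mesh: LVMesh, boundary: str, t_index: int, path) -> None:
    """Write one boundary surface at one time sample as a Wavefront OBJ."""
    pts = mesh_points(mesh, boundary, t_index)
    nz, nth = mesh.radii.shape[2:]
    with open(path, "w") as fh:
        fh.write(f"# echolv {boundary} surface, time sample {t_index}\n")
        for p in pts:
            fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        for iz in range(nz - 1):
            for it in range(nth):
                a = iz * nth + it + 1
                b_ = iz * nth + (it + 1) % nth + 1
                c = (iz + 1) * nth + it + 1
                d = (iz + 1) * nth + (it + 1) % nth + 1
                fh.write(f"f {a} {b_} {d}\n")
                fh.write(f"f {a} {d} {c}\n")
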