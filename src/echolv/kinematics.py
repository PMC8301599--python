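"""Lagrangian strain, strain rates and global function from an LV mesh.

Strain follows the engineering (Lagrangian) definition against the
end-diastolic reference (cycle phase 0):

* circumferential: ``eps_C(t, z) = (perimeter_t - perimeter_0) / perimeter_0``
  with the perimeter the closed polyline length of the 60-point contour at
  slice level z;
* longitudinal: ``eps_L(t, theta) = (length_t - length_0) / length_0`` with
  the length the 3D polyline length of the apex-to-base surface curve at a
  fixed rotation (60 z samples, per-frame apex/base tracks included).

Strain *rates* (1/s) are ordinary-least-squares slopes of strain against
time within four windows: systole ``[0, ps]`` and diastole ``[ps, 1]``, each
split at its midpoint into early/late halves (``ps`` = the peak-systole
phase, located globally at the endocardial cavity-volume minimum).  The
diastolic windows include the cycle wrap-around sample (phase 1, where
strain is 0 again by definition).

Global function metrics come from the endocardial cavity volume, a
trapezoidal sum over z of the shoelace polygon area of each contour with the
apex closed at zero area (volumes in mm^3 = uL): EDV at phase 0, PSV the
minimum over phases, SV = EDV - PSV, EF = 100 * SV / EDV.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import GeometryError, InsufficientDataError
from .mesh import LVMesh

#: reporting sites: slice levels (as apex-to-base fractions) for
#: circumferential curves and rotation labels for longitudinal curves
CIRC_LOCATIONS: dict[str, float] = {"basal": 1.00, "mid_lv": 0.50, "apical": 0.25}
LONG_LOCATIONS: dict[str, float] = {
    "anterior_free_wall": 30.0,
    "anterior": 90.0,
    "anterior_septum": 150.0,
    "posterior_septum": 210.0,
    "posterior": 270.0,
    "posterior_free_wall": 330.0,
}
RATE_NAMES = ("early_systolic_sr", "late_systolic_sr",
              "early_diastolic_sr", "late_diastolic_sr")


def _closed_perimeter(xy: np.ndarray) -> float:
    if xy.shape[0] <= 2 or len(np.unique(xy.round(12), axis=0)) <= 2:
        raise GeometryError("degenerate contour: fewer than 3 distinct points")
    d = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _contour_xy(mesh: LVMesh, b: int, t: int, iz: int) -> np.ndarray:
    r = mesh.radii[b, t, iz]
    th = np.radians(mesh.theta_deg)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def circumferential_strain(mesh: LVMesh, boundary: str = "endo",
                           z_index: int = 29) -> np.ndarray:
    """Circumferential strain curve over the mesh phases at one slice level."""
    b = mesh.boundary_index(boundary)
    perims = np.array([
        _closed_perimeter(_contour_xy(mesh, b, t, z_index))
        for t in range(mesh.n_time)
    ])
    return (perims - perims[0]) / perims[0]


def longitudinal_strain(mesh: LVMesh, boundary: str = "endo",
                        theta_index: int = 0) -> np.ndarray:
    """Longitudinal strain curve at one rotation, using 3D surface curve lengths."""
    b = mesh.boundary_index(boundary)
    th = np.radians(mesh.theta_deg[theta_index])
    lengths = np.empty(mesh.n_time)
    for t in range(mesh.n_time):
        r = mesh.radii[b, t, :, theta_index]
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), mesh.z_mm(t)])
        d = np.diff(pts, axis=0)
        lengths[t] = np.sum(np.linalg.norm(d, axis=1))
    if np.any(lengths <= 0):
        raise GeometryError("degenerate longitudinal curve")
    return (lengths - lengths[0]) / lengths[0]


def strain_rates(curve: np.ndarray, ps_phase: float, cycle_duration_s: float,
                 phases: np.ndarray | None = None) -> dict[str, float]:
    """Windowed OLS strain rates (1/s) from a strain curve over the cycle.

    Windows: systole ``[0, ps_phase]`` and diastole ``[ps_phase, 1]``, each
    split at its midpoint.  The diastolic half-windows use an appended
    wrap-around observation at phase 1 carrying the phase-0 strain value.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.shape[0]
    if phases is None:
        phases = np.arange(n) / n
    if not 0.0 < ps_phase < 1.0:
        raise ValueError(f"ps_phase must lie strictly inside (0, 1), got {ps_phase}")
    ph = np.concatenate([phases, [1.0]])
    eps = np.concatenate([curve, [curve[0]]])
    t_sec = ph * cycle_duration_s
    eps_tol = 1e-12
    windows = {
        "early_systolic_sr": (0.0, ps_phase / 2.0),
        "late_systolic_sr": (ps_phase / 2.0, ps_phase),
        "early_diastolic_sr": (ps_phase, (1.0 + ps_phase) / 2.0),
        "late_diastolic_sr": ((1.0 + ps_phase) / 2.0, 1.0),
    }
    out: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        m = (ph >= lo - eps_tol) & (ph <= hi + eps_tol)
        if name.startswith(("early_sys", "late_sys")):
            m &= ph <= 1.0 - 1e-9  # wrap sample belongs to diastole only
        if m.sum() < 3:
            raise InsufficientDataError(
                f"{name}: window [{lo:.3f}, {hi:.3f}] holds only {m.sum()} samples"
            )
        slope = np.polyfit(t_sec[m], eps[m], 1)[0]
        out[name] = float(slope)
    return out


# ---------------------------------------------------------------------------
# global function


def _shoelace_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def cavity_volumes(mesh: LVMesh, boundary: str = "endo") -> np.ndarray:
    """Cavity volume (uL = mm^3) at every mesh phase.

    Trapezoidal integration over z of the shoelace polygon area of each
    contour, with the apex closed by a zero-area point at the apex track
    position.
    """
    b = mesh.boundary_index(boundary)
    vols = np.empty(mesh.n_time)
    for t in range(mesh.n_time):
        areas = np.array([
            _shoelace_area(_contour_xy(mesh, b, t, iz))
            for iz in range(mesh.radii.shape[2])
        ])
        z = mesh.z_mm(t)
        z_full = np.concatenate([[mesh.apex_z[t]], z])
        a_full = np.concatenate([[0.0], areas])
        vols[t] = np.trapezoid(a_full, z_full)
    return vols


def global_function(mesh: LVMesh) -> dict[str, float]:
    """End-diastolic/peak-systolic volumes, stroke volume and ejection fraction.

    Peak systole is the phase of minimum endocardial cavity volume (earliest
    frame on ties), shared as the landmark for all strain-rate windows.
    """
    vols = cavity_volumes(mesh, "endo")
    edv = float(vols[0])
    if edv <= 0:
        raise GeometryError("zero end-diastolic volume: invalid mesh")
    i_ps = int(np.argmin(vols))
    psv = float(vols[i_ps])
    sv = edv - psv
    return {
        "edv_ul": edv,
        "psv_ul": psv,
        "sv_ul": sv,
        "ef_pct": 100.0 * sv / edv,
        "ps_phase": float(mesh.phases[i_ps]),
    }


# ---------------------------------------------------------------------------
# metric table


def _nearest_index(grid: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(np.asarray(grid) - value)))


def _peak(curve: np.ndarray) -> float:
    return float(curve[int(np.argmax(np.abs(curve)))])


def metric_table(mesh: LVMesh, ps_phase: float | None = None,
                 boundary: str = "endo") -> pd.DataFrame:
    """Standard kinematic metric table for one mesh.

    Rows: peak strain plus four windowed strain rates for each of 3
    circumferential levels (basal, mid-LV, apical) and 6 longitudinal
    rotations, plus the 4 global function metrics -- 49 rows.  Columns:
    ``metric, frame_type, location, boundary, value, units``.
    """
    glob = global_function(mesh)
    if ps_phase is None:
        ps_phase = glob["ps_phase"]
    if ps_phase <= 0.0:  # time-constant mesh: volume minimum sits at phase 0
        ps_phase = 0.35
    rows: list[dict] = []

    def add_curve_metrics(curve: np.ndarray, frame_type: str, location: str) -> None:
        rows.append({"metric": "peak_strain", "frame_type": frame_type,
                     "location": location, "boundary": boundary,
                     "value": _peak(curve), "units": "dimensionless"})
        rates = strain_rates(curve, ps_phase, mesh.cycle_duration_s, mesh.phases)
        for name in RATE_NAMES:
            rows.append({"metric": name, "frame_type": frame_type,
                         "location": location, "boundary": boundary,
                         "value": rates[name], "units": "1/s"})

    for loc, zf in CIRC_LOCATIONS.items():
        iz = _nearest_index(mesh.z_fracs, zf)
        add_curve_metrics(circumferential_strain(mesh, boundary, iz), "circ", loc)
    for loc, theta in LONG_LOCATIONS.items():
        it = _nearest_index(mesh.theta_deg, theta)
        add_curve_metrics(longitudinal_strain(mesh, boundary, it), "long", loc)

    units = {"edv_ul": "uL", "psv_ul": "uL", "sv_ul": "uL", "ef_pct": "%"}
    for name in ("edv_ul", "psv_ul", "sv_ul", "ef_pct"):
        rows.append({"metric": name, "frame_type": "global", "location": "global",
                     "boundary": "endo", "value": glob[name], "units": units[name]})
    return pd.DataFrame(rows)
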