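"""Reduced quasi-static forward model of a layered breast phantom.

A three-material phantom (fat / fibroglandular / tumor, outside to inside) is
loaded by a very-low-frequency sinusoidal surface traction; at 0.1 Hz inertia
is negligible and the response at any instant is the static equilibrium under
the instantaneous traction.  The full 3-D finite-element problem is reduced to
a 1-D series (uniaxial) stack extruded over the 2-D imaging plane: the axial
Cauchy stress is uniform through every column (stress continuity), each layer
deforms by the uniaxial incompressible law of its material, and the axial
displacement at depth z is the accumulated layer compression between z and the
fixed distal face.  Columns passing through the tumor carry the tumor layer;
columns outside its lateral extent do not.

The reduction keeps exactly the observable the inversion consumes — axial
displacements of points inside the tumor — self-consistent with the
constitutive laws, at desk scale and fully deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .mr_core import MRParams, stretch_from_stress

__all__ = [
    "LinearParams",
    "PhantomGeometry",
    "LoadSpec",
    "DisplacementField",
    "STUDY_INSTANTS_S",
    "solve_layer_stretches",
    "displacement_field_at",
    "elastic_reference_field",
    "sample_axial",
    "default_tumor_points",
    "save_field",
    "load_field",
]

#: The eight sampling instants of the sinusoidal load, in seconds.
STUDY_INSTANTS_S: tuple[float, ...] = (7.75, 8.0, 8.25, 8.5, 8.75, 9.0, 9.25, 9.5)


@dataclass(frozen=True)
class LinearParams:
    """Linear-elastic material: axial strain eps = sigma / E, nu = 0.5.

    Used for the unit-modulus "elastic tumor" reference of the inversion.
    Lateral contraction is the linearized incompressible -eps/2.
    """

    e: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.e <= 0.0:
            raise ValueError("E must be positive")
        if self.nu != 0.5:
            raise ValueError("only the incompressible case nu = 0.5 is supported")


Material = MRParams | LinearParams


@dataclass(frozen=True)
class PhantomGeometry:
    """Layered phantom geometry, millimetres.

    The probe sits at axial depth 0; depth increases away from it.  The face
    at ``axial_mm`` is fully constrained.  ``layers`` stack from the probe
    face downward and must fill the axial extent.  The tumor occupies
    ``tumor_axial_mm`` within its host layer, laterally centred with extent
    ``tumor_lateral_mm``.
    """

    axial_mm: float = 100.0
    lateral_mm: float = 60.0
    elev_mm: float = 20.0
    layers: tuple[tuple[str, float], ...] = (("fat", 15.0), ("fibroglandular", 85.0))
    tumor_axial_mm: tuple[float, float] = (65.0, 75.0)
    tumor_lateral_mm: float = 10.0
    tumor_name: str = "tumor"

    def __post_init__(self) -> None:
        if any(t <= 0 for _, t in self.layers):
            raise ValueError("layer thicknesses must be positive")
        total = sum(t for _, t in self.layers)
        if abs(total - self.axial_mm) > 1e-9:
            raise ValueError(
                f"layer thicknesses sum to {total} mm, expected {self.axial_mm} mm"
            )
        z1, z2 = self.tumor_axial_mm
        if not (0.0 < z1 < z2 < self.axial_mm):
            raise ValueError("tumor axial interval must lie inside the phantom")
        host = self.host_layer_bounds()
        if not (host[0] <= z1 and z2 <= host[1]):
            raise ValueError("tumor interval must lie inside the host layer")
        if not (0.0 < self.tumor_lateral_mm <= self.lateral_mm):
            raise ValueError("tumor lateral extent must fit inside the phantom")

    def layer_bounds(self) -> list[tuple[str, float, float]]:
        """(name, z_top, z_bottom) of every layer, probe face downward."""
        out, z = [], 0.0
        for name, t in self.layers:
            out.append((name, z, z + t))
            z += t
        return out

    def host_layer_bounds(self) -> tuple[float, float]:
        """Axial bounds of the (deepest) layer hosting the tumor."""
        z1, z2 = self.tumor_axial_mm
        for _, top, bot in self.layer_bounds():
            if top <= z1 and z2 <= bot:
                return (top, bot)
        raise ValueError("no single layer contains the tumor interval")

    @property
    def lateral_mid_mm(self) -> float:
        return 0.5 * self.lateral_mm

    def tumor_lateral_bounds(self) -> tuple[float, float]:
        h = 0.5 * self.tumor_lateral_mm
        return (self.lateral_mid_mm - h, self.lateral_mid_mm + h)

    def column_segments(self, through_tumor: bool) -> list[tuple[str, float, float]]:
        """Axial material segments of a column, optionally with the tumor."""
        segs = self.layer_bounds()
        if not through_tumor:
            return segs
        z1, z2 = self.tumor_axial_mm
        out: list[tuple[str, float, float]] = []
        for name, top, bot in segs:
            if bot <= z1 or top >= z2:
                out.append((name, top, bot))
                continue
            if top < z1:
                out.append((name, top, z1))
            out.append((self.tumor_name, max(top, z1), min(bot, z2)))
            if bot > z2:
                out.append((name, z2, bot))
        return out


@dataclass(frozen=True)
class LoadSpec:
    """Sinusoidal surface traction: traction(t) = amplitude * sin(2 pi f t).

    ``amplitude_pa`` is the peak traction with compression positive.  The
    default instants are the eight consecutive sampling times of the
    quasi-static protocol.
    """

    amplitude_pa: float = 5000.0
    frequency_hz: float = 0.1
    sample_times_s: tuple[float, ...] = STUDY_INSTANTS_S

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0.0:
            raise ValueError("frequency must be positive")
        if np.any(np.diff(self.sample_times_s) <= 0.0):
            raise ValueError("sample_times must be strictly increasing")

    def traction_at(self, t: float) -> float:
        """Instantaneous surface traction, Pa (compression positive)."""
        return self.amplitude_pa * float(np.sin(2.0 * np.pi * self.frequency_hz * t))


@dataclass
class DisplacementField:
    """Gridded axial/lateral displacements (mm) of the imaging plane.

    ``ux`` is axial displacement (positive toward increasing depth), ``uy``
    lateral, both shaped (n_axial, n_lateral) on the rectilinear grid given by
    ``grid_axial_mm`` x ``grid_lateral_mm``.
    """

    grid_axial_mm: np.ndarray
    grid_lateral_mm: np.ndarray
    ux_mm: np.ndarray
    uy_mm: np.ndarray
    time_s: float = 0.0
    role: str = "post"

    def __post_init__(self) -> None:
        shape = (len(self.grid_axial_mm), len(self.grid_lateral_mm))
        if self.ux_mm.shape != shape or self.uy_mm.shape != shape:
            raise ValueError("displacement arrays incongruent with the grid")

    def interpolator(self, component: str = "ux") -> RegularGridInterpolator:
        data = self.ux_mm if component == "ux" else self.uy_mm
        return RegularGridInterpolator(
            (self.grid_axial_mm, self.grid_lateral_mm), data, bounds_error=True
        )


def _axial_strain(material: Material, sigma: float) -> float:
    """Axial engineering strain of a layer under axial Cauchy stress sigma."""
    if isinstance(material, LinearParams):
        return sigma / material.e
    return stretch_from_stress(material, sigma) - 1.0


def _lateral_strain(material: Material, axial_strain: float) -> float:
    """Lateral engineering strain under incompressibility."""
    if isinstance(material, LinearParams):
        return -0.5 * axial_strain
    return (1.0 + axial_strain) ** -0.5 - 1.0


def solve_layer_stretches(
    geometry: PhantomGeometry,
    materials: Mapping[str, Material],
    traction_pa: float,
) -> dict[str, float]:
    """Per-layer axial stretch under a uniform compressive traction.

    In the series stack the axial Cauchy stress equals ``-traction`` in every
    layer; each layer's stretch solves its own uniaxial law at that stress.
    """
    if not np.isfinite(traction_pa):
        raise ValueError("traction must be finite")
    sigma = -float(traction_pa)
    names = {name for name, _, _ in geometry.column_segments(through_tumor=True)}
    out: dict[str, float] = {}
    for name in sorted(names):
        if name not in materials:
            raise KeyError(f"no material defined for layer {name!r}")
        mat = materials[name]
        if isinstance(mat, LinearParams):
            out[name] = 1.0 + sigma / mat.e
            continue
        try:
            out[name] = stretch_from_stress(mat, sigma)
        except ValueError as err:
            raise ValueError(f"layer {name!r}: {err}") from err
    return out


def _column_displacements(
    geometry: PhantomGeometry,
    materials: Mapping[str, Material],
    sigma: float,
    z_grid: np.ndarray,
    through_tumor: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial displacement and lateral strain along one column type."""
    segs = geometry.column_segments(through_tumor)
    eps = {name: _axial_strain(materials[name], sigma) for name in
           {s[0] for s in segs}}
    # u(z) = -integral_z^L eps dz'  (fixed face at z = L; compression eps < 0
    # moves material toward +z).  Piecewise-constant strain per segment.
    u = np.zeros_like(z_grid)
    eps_ax = np.zeros_like(z_grid)
    for name, top, bot in segs:
        below = np.clip(bot - np.maximum(z_grid, top), 0.0, bot - top)
        u -= eps[name] * below
        inside = (z_grid >= top) & (z_grid < bot)
        eps_ax[inside] = eps[name]
    # points exactly at the fixed face keep the deepest segment's strain
    eps_ax[z_grid >= segs[-1][2]] = eps[segs[-1][0]]
    eps_lat = np.array(
        [_lateral_strain(materials[_segment_at(segs, z)], e)
         for z, e in zip(z_grid, eps_ax)]
    )
    return u, eps_lat


def _segment_at(segs: list[tuple[str, float, float]], z: float) -> str:
    for name, top, bot in segs:
        if top <= z < bot:
            return name
    return segs[-1][0]


def displacement_field_at(
    geometry: PhantomGeometry,
    materials: Mapping[str, Material],
    load: LoadSpec,
    t: float,
    grid_step_mm: tuple[float, float] = (0.5, 1.0),
) -> DisplacementField:
    """Quasi-static displacement field at time ``t``.

    The instantaneous traction is ``load.traction_at(t)``; the field follows
    from the per-layer uniaxial solution, with lateral spreading symmetric
    about the phantom midline (u_y = eps_lat * (y - y_mid)).
    """
    if t < 0.0:
        raise ValueError("t must be non-negative")
    tau = load.traction_at(t)
    dz, dy = grid_step_mm
    z = np.arange(0.0, geometry.axial_mm + 0.5 * dz, dz)
    y = np.arange(0.0, geometry.lateral_mm + 0.5 * dy, dy)

    sigma = -tau
    u_t, el_t = _column_displacements(geometry, materials, sigma, z, True)
    u_b, el_b = _column_displacements(geometry, materials, sigma, z, False)

    y1, y2 = geometry.tumor_lateral_bounds()
    in_tumor_col = (y >= y1) & (y <= y2)
    ux = np.where(in_tumor_col[None, :], u_t[:, None], u_b[:, None])
    eps_lat = np.where(in_tumor_col[None, :], el_t[:, None], el_b[:, None])
    uy = eps_lat * (y - geometry.lateral_mid_mm)[None, :]
    return DisplacementField(z, y, ux, uy, time_s=float(t), role="post")


def elastic_reference_field(
    geometry: PhantomGeometry,
    load: LoadSpec,
    t: float,
    e_pa: float = 1.0,
    nu: float = 0.5,
    known_materials: Mapping[str, Material] | None = None,
    grid_step_mm: tuple[float, float] = (0.5, 1.0),
) -> DisplacementField:
    """Displacement field with the tumor replaced by a linear-elastic solid.

    The surrounding layers keep their (known) hyperelastic laws; the tumor
    obeys eps = sigma / E with the given modulus (default the 1 Pa reference
    of the inversion) and nu = 0.5.
    """
    from .mr_core import BREAST_MATERIALS

    mats = dict(known_materials if known_materials is not None else BREAST_MATERIALS)
    mats[geometry.tumor_name] = LinearParams(e=e_pa, nu=nu)
    return displacement_field_at(geometry, mats, load, t, grid_step_mm)


def default_tumor_points(
    geometry: PhantomGeometry, n_axial: int = 4, n_lateral: int = 3
) -> list[tuple[float, float]]:
    """A deterministic grid of points inside the tumor (default 12).

    Points are spread over the central 70% of the tumor in both directions.
    """
    z1, z2 = geometry.tumor_axial_mm
    y1, y2 = geometry.tumor_lateral_bounds()
    zm, ym = 0.15 * (z2 - z1), 0.15 * (y2 - y1)
    zs = np.linspace(z1 + zm, z2 - zm, n_axial)
    ys = np.linspace(y1 + ym, y2 - ym, n_lateral)
    return [(float(z), float(y)) for z in zs for y in ys]


def sample_axial(
    fields: Sequence[DisplacementField],
    points: Sequence[tuple[float, float]],
    relative_to_depth: float | None = None,
) -> np.ndarray:
    """Axial displacements at the given points, time-major point-minor.

    Bilinear interpolation on each field's grid.  With ``relative_to_depth``
    the interpolated value at (that depth, same lateral position) is
    subtracted point-wise, turning the sample into deformation relative to a
    reference interface (e.g. the tumor's distal face).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (axial, lateral) pairs")
    out = []
    for f in fields:
        interp = f.interpolator("ux")
        vals = interp(pts)
        if relative_to_depth is not None:
            ref_pts = np.column_stack(
                [np.full(len(pts), relative_to_depth), pts[:, 1]]
            )
            vals = vals - interp(ref_pts)
        out.append(vals)
    return np.concatenate(out)


def save_field(path, field: DisplacementField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("grid_axial_mm", data=field.grid_axial_mm)
        f.create_dataset("grid_lateral_mm", data=field.grid_lateral_mm)
        f.create_dataset("ux_mm", data=field.ux_mm)
        f.create_dataset("uy_mm", data=field.uy_mm)
        f.attrs["time_s"] = field.time_s
        f.attrs["role"] = field.role


def load_field(path) -> DisplacementField:
    with h5py.File(path, "r") as f:
        return DisplacementField(
            grid_axial_mm=f["grid_axial_mm"][:],
            grid_lateral_mm=f["grid_lateral_mm"][:],
            ux_mm=f["ux_mm"][:],
            uy_mm=f["uy_mm"][:],
            time_s=float(f.attrs["time_s"]),
            role=str(f.attrs["role"]),
        )
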