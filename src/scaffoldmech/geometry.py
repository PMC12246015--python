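"""Parametric 0/90 strand-lattice scaffold geometry.

A scaffold is a stack of ``N_V`` horizontal layers inside a cylindrical
envelope of diameter ``D_scaffold`` and height ``H_scaffold``.  Each layer
holds ``N_H`` parallel cylindrical strands of diameter ``D_strand`` spaced
``Y`` apart (center to center); successive layers alternate between 0 and
90 degrees.  Adjacent layers interpenetrate by ``D_strand - h`` where ``h``
is the vertical center-to-center span, as extruded hydrogel strands fuse
where they cross.

Default span conventions (both can be overridden per design):

* ``Y = (D_scaffold - 2*D_strand) / (N_H - 1)`` -- the outermost strand
  centers are inset one strand diameter from the envelope, leaving a
  printing margin of half a strand diameter at the rim.
* ``h = H_scaffold / N_V`` -- layers fill the height at a uniform period
  with the stack centered; the outermost strand surfaces protrude by
  ``(D_strand - h)/2`` and are trimmed by the envelope.

Porosity is ``1 - V_solid / V_envelope`` with the solid volume measured by
voxel integration of the union of clipped strand cylinders (interpenetration
counted once).  The minimal equivalent pore diameter ``D_pore`` is the
diameter of the circle whose area equals the open square window
``(Y - D_strand)^2`` bounded by four strands of two adjacent layers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScaffoldSpec",
    "Strand",
    "StrandLayout",
    "PoreMetrics",
    "InvalidGeometryError",
    "build_layout",
    "porosity",
    "pore_equivalent_diameter",
    "pore_window_area",
    "export_mesh",
]

#: geometric slack (mm) used in fit checks
_TOL = 1e-9


class InvalidGeometryError(ValueError):
    """Raised when a lattice specification cannot produce a valid scaffold."""


@dataclass(frozen=True)
class ScaffoldSpec:
    """Named lattice design.  Lengths in mm.

    ``Y`` and ``h`` default to the span conventions in the module docstring
    when not given explicitly.
    """

    name: str
    D_scaffold: float = 10.0
    H_scaffold: float = 4.8
    D_strand: float = 0.7
    N_H: int = 7
    N_V: int = 9
    Y: float = field(default=None)  # type: ignore[assignment]
    h: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.D_strand <= 0:
            raise InvalidGeometryError("D_strand must be positive")
        if self.D_scaffold <= 0 or self.H_scaffold <= 0:
            raise InvalidGeometryError("envelope dimensions must be positive")
        if self.N_H < 2:
            raise InvalidGeometryError("N_H must be at least 2")
        if self.N_V < 1:
            raise InvalidGeometryError("N_V must be at least 1")
        if self.Y is None:
            object.__setattr__(
                self, "Y", (self.D_scaffold - 2.0 * self.D_strand) / (self.N_H - 1)
            )
        if self.h is None:
            object.__setattr__(self, "h", self.H_scaffold / self.N_V)
        if self.Y <= self.D_strand:
            raise InvalidGeometryError(
                f"horizontal span Y={self.Y:.4g} mm leaves no open pore window "
                f"(D_strand={self.D_strand:.4g} mm)"
            )
        if (self.N_V - 1) * self.h > self.H_scaffold + _TOL:
            raise InvalidGeometryError("layer stack does not fit the envelope height")

    @property
    def radius(self) -> float:
        return 0.5 * self.D_scaffold

    @property
    def strand_radius(self) -> float:
        return 0.5 * self.D_strand

    def with_name(self, name: str) -> "ScaffoldSpec":
        return replace(self, name=name)


@dataclass(frozen=True)
class Strand:
    """One strand: a horizontal cylinder clipped to the envelope circle.

    ``orientation`` 0 means the axis runs along x (offset is the y position);
    90 means the axis runs along y (offset is the x position).  ``p0``/``p1``
    are the chord endpoints on the envelope circle (mm).
    """

    layer: int
    orientation: int
    offset: float
    z: float
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]

    @property
    def length(self) -> float:
        return math.dist(self.p0, self.p1)


@dataclass(frozen=True)
class StrandLayout:
    """Concrete strand list of one design plus its cylindrical envelope."""

    spec: ScaffoldSpec
    strands: tuple[Strand, ...]

    @property
    def envelope(self) -> tuple[float, float]:
        return (self.spec.D_scaffold, self.spec.H_scaffold)

    def layer_heights(self) -> list[float]:
        return sorted({s.z for s in self.strands})


@dataclass(frozen=True)
class PoreMetrics:
    porosity: float
    solid_volume: float  # mm^3
    total_volume: float  # mm^3
    pore_window_area: float  # mm^2
    D_pore: float  # um
    standard_error: float  # porosity units


def _layer_centers(spec: ScaffoldSpec) -> np.ndarray:
    """Layer center heights, stack vertically centered in the envelope."""
    span = (spec.N_V - 1) * spec.h
    z0 = 0.5 * (spec.H_scaffold - span)
    return z0 + spec.h * np.arange(spec.N_V)


def _lateral_offsets(spec: ScaffoldSpec) -> np.ndarray:
    return (np.arange(spec.N_H) - 0.5 * (spec.N_H - 1)) * spec.Y


def build_layout(spec: ScaffoldSpec) -> StrandLayout:
    """Place ``N_V`` alternating 0/90 layers of ``N_H`` strands each.

    Strands whose lateral offset reaches the envelope radius would have a
    zero-length chord and are excluded.  A spec whose offsets leave no strand
    inside the envelope raises :class:`InvalidGeometryError`.
    """
    R = spec.radius
    strands: list[Strand] = []
    for layer, z in enumerate(_layer_centers(spec)):
        orientation = 0 if layer % 2 == 0 else 90
        for off in _lateral_offsets(spec):
            if abs(off) >= R - _TOL:
                continue  # tangent or outside: zero-length chord
            half = math.sqrt(R * R - off * off)
            if orientation == 0:
                p0, p1 = (-half, off, z), (half, off, z)
            else:
                p0, p1 = (off, -half, z), (off, half, z)
            strands.append(Strand(layer, orientation, float(off), float(z), p0, p1))
    if not strands:
        raise InvalidGeometryError(
            f"design {spec.name!r}: no strand lies inside the envelope"
        )
    return StrandLayout(spec=spec, strands=tuple(strands))


# ---------------------------------------------------------------------------
# porosity
# ---------------------------------------------------------------------------

def _voxel_solid_volume(layout: StrandLayout, res: float) -> float:
    """Solid volume of the strand union by voxel counting.

    Strands are axis-aligned horizontal cylinders, so occupancy factorizes:
    a voxel at (x, y, z) is solid iff it lies inside the envelope circle and
    inside an x-oriented strand section (a disk in the (y, z) plane) or a
    y-oriented one (a disk in (x, z)).  The 3D count then reduces to 2D masks
    and one integer matrix product, which keeps 25 um grids cheap.
    """
    spec = layout.spec
    R, r = spec.radius, spec.strand_radius
    nxy = int(round(spec.D_scaffold / res))
    nz = int(round(spec.H_scaffold / res))
    c_xy = (np.arange(nxy) + 0.5) * res - R
    c_z = (np.arange(nz) + 0.5) * res
    env = (c_xy[:, None] ** 2 + c_xy[None, :] ** 2) <= R * R
    mask_x = np.zeros((nxy, nz), dtype=bool)  # over (y, z)
    mask_y = np.zeros((nxy, nz), dtype=bool)  # over (x, z)
    for s in layout.strands:
        m = mask_x if s.orientation == 0 else mask_y
        m |= (c_xy[:, None] - s.offset) ** 2 + (c_z[None, :] - s.z) ** 2 <= r * r
    per_y = mask_x.sum(axis=1)
    per_x = mask_y.sum(axis=1)
    both = mask_x.astype(np.int64) @ mask_y.astype(np.int64).T  # (y, x)
    counts = per_y[:, None] + per_x[None, :] - both  # (y, x)
    total = int((counts * env.T).sum())  # env is symmetric in x/y
    return total * res**3


def _mc_solid_volume(
    layout: StrandLayout, n_points: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo solid volume and its standard error."""
    spec = layout.spec
    R, r = spec.radius, spec.strand_radius
    x_strands = [(s.offset, s.z) for s in layout.strands if s.orientation == 0]
    y_strands = [(s.offset, s.z) for s in layout.strands if s.orientation == 90]
    hits = 0
    remaining = n_points
    chunk = 1 << 18
    while remaining > 0:
        n = min(chunk, remaining)
        remaining -= n
        pts = rng.random((n, 3))
        x = (pts[:, 0] - 0.5) * spec.D_scaffold
        y = (pts[:, 1] - 0.5) * spec.D_scaffold
        z = pts[:, 2] * spec.H_scaffold
        inside = x * x + y * y <= R * R
        solid = np.zeros(n, dtype=bool)
        for off, zl in x_strands:
            solid |= (y - off) ** 2 + (z - zl) ** 2 <= r * r
        for off, zl in y_strands:
            solid |= (x - off) ** 2 + (z - zl) ** 2 <= r * r
        hits += int((inside & solid).sum())
    box = spec.D_scaffold**2 * spec.H_scaffold
    p = hits / n_points
    return p * box, math.sqrt(max(p * (1 - p), 1e-12) / n_points) * box


def porosity(
    layout: StrandLayout,
    resolution: float = 0.025,
    seed: int = 0,
    method: str = "voxel",
    mc_points: int = 2_000_000,
) -> PoreMetrics:
    """Porosity and pore metrics of a laid-out design.

    Parameters
    ----------
    resolution:
        Voxel edge length in mm; must not exceed ``D_strand / 10``.
    seed:
        Seeds the Monte-Carlo sampler (``method="mc"``); the voxel method is
        deterministic and ignores it.
    method:
        ``"voxel"`` (default) or ``"mc"`` stratified point sampling.
    """
    spec = layout.spec
    if resolution > spec.D_strand / 10 + _TOL:
        raise ValueError(
            f"resolution {resolution} mm too coarse for D_strand={spec.D_strand} mm; "
            f"need <= D_strand/10"
        )
    total = math.pi * spec.radius**2 * spec.H_scaffold
    window = pore_window_area(spec)
    d_pore = pore_equivalent_diameter(spec)
    if not layout.strands:
        warnings.warn("empty layout: porosity is 1 by definition")
        return PoreMetrics(1.0, 0.0, total, window, d_pore, 0.0)
    if method == "voxel":
        solid = _voxel_solid_volume(layout, resolution)
        # discretization error estimate from one coarser grid
        coarse = _voxel_solid_volume(layout, 2 * resolution)
        se = abs(solid - coarse) / total
    elif method == "mc":
        rng = np.random.default_rng(seed)
        solid, se_vol = _mc_solid_volume(layout, mc_points, rng)
        se = se_vol / total
    else:
        raise ValueError(f"unknown method {method!r}; use 'voxel' or 'mc'")
    return PoreMetrics(
        porosity=1.0 - solid / total,
        solid_volume=solid,
        total_volume=total,
        pore_window_area=window,
        D_pore=d_pore,
        standard_error=se,
    )


def pore_window_area(spec: ScaffoldSpec) -> float:
    """Minimum open window (mm^2) between four strands of adjacent layers.

    In projection along the scaffold axis two parallel strands of one layer
    and two orthogonal strands of the next bound a square opening of side
    ``Y - D_strand``.
    """
    gap = spec.Y - spec.D_strand
    if gap <= 0:
        raise InvalidGeometryError("Y <= D_strand: pore window is closed")
    return gap * gap


def pore_equivalent_diameter(spec: ScaffoldSpec) -> float:
    """Minimal equivalent pore diameter in um.

    Diameter of the circle whose area equals the minimal pore window:
    ``D_pore = 2 (Y - D_strand) / sqrt(pi)``.
    """
    gap = spec.Y - spec.D_strand
    if gap <= 0:
        raise InvalidGeometryError("Y <= D_strand: pore window is closed")
    return 2.0 * gap / math.sqrt(math.pi) * 1000.0


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def strand_meshes(layout: StrandLayout, sections: int = 32) -> list:
    """Per-strand capped tube meshes (trimesh objects, units mm)."""
    import trimesh

    meshes = []
    for s in layout.strands:
        meshes.append(
            trimesh.creation.cylinder(
                radius=layout.spec.strand_radius,
                segment=np.array([s.p0, s.p1]),
                sections=sections,
            )
        )
    return meshes


def export_mesh(layout: StrandLayout, path: str, format: str | None = None) -> str:
    """Write the strand tubes as a triangulated surface (STL or legacy VTK).

    Each strand is a watertight capped cylinder; shells are concatenated
    without boolean union.  Returns the path written.
    """
    import trimesh

    if not layout.strands:
        raise InvalidGeometryError("cannot export an empty layout")
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in ("stl", "vtk"):
        raise ValueError(f"unsupported format {fmt!r}; supported: stl, vtk")
    mesh = trimesh.util.concatenate(strand_meshes(layout))
    if fmt == "stl":
        mesh.export(path, file_type="stl")
    else:
        _write_vtk_polydata(mesh, path, layout.spec.name)
    return str(path)


def _write_vtk_polydata(mesh, path: str, name: str) -> None:
    """Minimal legacy-VTK ASCII POLYDATA writer (triangles only)."""
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"scaffold {name} (mm)\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
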