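"""Membrane geometry: two walls pierced by a finite cylindrical nanopore.

The membrane is a slab of thickness L_p (the pore length) whose two faces
are infinite planes normal to the x axis, pierced by a cylindrical bore of
radius R_p centred on the pore axis (the x axis through ``pore_center``).
All surfaces are continuous: a bead interacts with the membrane through the
Euclidean distance from its centre to the nearest point of the relevant
surface, so the repulsive/attractive fields are continuous around the
aperture rim (the circle where a wall face meets the bore).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import SimulationParameters

#: sentinel distance (sigma units) meaning "no wall within any cutoff"
NO_WALL = 1.0e9

REGION_CIS = "cis"
REGION_PORE = "pore"
REGION_TRANS = "trans"


@dataclass(frozen=True)
class MembraneGeometry:
    """Geometric description of the membrane; pore axis fixed to +x."""

    pore_center: tuple[float, float, float]
    pore_length: float
    pore_radius: float

    def __post_init__(self) -> None:
        if self.pore_radius <= 0 or self.pore_length <= 0:
            raise ValueError("pore_radius and pore_length must be positive")

    @property
    def cis_plane_x(self) -> float:
        return self.pore_center[0] - self.pore_length / 2.0

    @property
    def trans_plane_x(self) -> float:
        return self.pore_center[0] + self.pore_length / 2.0

    @classmethod
    def from_parameters(cls, params: SimulationParameters
                        ) -> "MembraneGeometry":
        return cls(pore_center=params.pore_center,
                   pore_length=params.pore_length,
                   pore_radius=params.pore_radius)

    def _rho(self, points: np.ndarray) -> np.ndarray:
        dy = points[..., 1] - self.pore_center[1]
        dz = points[..., 2] - self.pore_center[2]
        return np.hypot(dy, dz)


def region_of(point, geom: MembraneGeometry) -> str:
    """Classify a point as cis, pore or trans.

    Inside the axial span of the membrane, points within the bore are
    ``pore``; points at or beyond the bore radius sit in the wall's
    interaction zone and are assigned cis/trans by the sign of their axial
    offset from the pore centre (they are never force-free).
    """
    p = np.asarray(point, dtype=float)
    x = p[0]
    if x < geom.cis_plane_x:
        return REGION_CIS
    if x > geom.trans_plane_x:
        return REGION_TRANS
    if geom._rho(p) < geom.pore_radius:
        return REGION_PORE
    return REGION_CIS if x < geom.pore_center[0] else REGION_TRANS


def in_pore_mask(points: np.ndarray, geom: MembraneGeometry) -> np.ndarray:
    """Boolean mask of points inside the pore bore (vectorized region_of)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x = pts[:, 0]
    return ((x >= geom.cis_plane_x) & (x <= geom.trans_plane_x)
            & (geom._rho(pts) < geom.pore_radius))


def wall_distance(points, geom: MembraneGeometry) -> np.ndarray | float:
    """Distance to the nearest point of the two annular wall faces.

    The wall surface is the union of the two face planes minus the open
    aperture disc; a point facing the aperture (radial < R_p) sees the rim
    circle instead of a perpendicular foot.  Points inside the bore have no
    wall interaction and get the sentinel ``NO_WALL``.  Points inside the
    solid slab (which only occur transiently on integrator failure) get the
    depth below the nearer face so the repulsion pushes them back out.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x = pts[:, 0]
    rho = geom._rho(pts)
    x0, x1, rp = geom.cis_plane_x, geom.trans_plane_x, geom.pore_radius

    d = np.full(len(pts), NO_WALL)
    outside_cis = x < x0
    outside_trans = x > x1
    inside_span = ~outside_cis & ~outside_trans
    ax = np.where(outside_cis, x0 - x, x - x1)  # axial gap, outside only

    facing_wall = rho >= rp
    m = (outside_cis | outside_trans) & facing_wall
    d[m] = ax[m]
    m = (outside_cis | outside_trans) & ~facing_wall
    d[m] = np.hypot(ax[m], rp - rho[m])  # nearest point on the rim circle
    m = inside_span & facing_wall  # interior of the solid slab
    d[m] = np.minimum(x[m] - x0, x1 - x[m])

    if np.asarray(points).ndim == 1:
        return float(d[0])
    return d


def pore_surface_distance(points, geom: MembraneGeometry
                          ) -> np.ndarray | float:
    """Distance to the finite cylindrical bore surface.

    Within the axial span this is |R_p - radial|; beyond either end it is
    the distance to the nearer rim circle.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x = pts[:, 0]
    rho = geom._rho(pts)
    x0, x1, rp = geom.cis_plane_x, geom.trans_plane_x, geom.pore_radius

    ax = np.maximum(np.maximum(x0 - x, x - x1), 0.0)
    d = np.hypot(ax, rp - rho)
    if np.asarray(points).ndim == 1:
        return float(d[0])
    return d


def export_obj(geom: MembraneGeometry, path, *, lateral_extent: float = 10.0,
               n_theta: int = 64, n_axial: int = 8) -> None:
    """Write a triangulated membrane surface as a Wavefront OBJ (debugging).

    The laterally infinite wall faces are truncated at
    ``pore_radius + lateral_extent``.
    """
    cx, cy, cz = geom.pore_center
    x0, x1, rp = geom.cis_plane_x, geom.trans_plane_x, geom.pore_radius
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    verts: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []

    def ring(xpos: float, radius: float) -> list[int]:
        start = len(verts) + 1  # OBJ indices are 1-based
        for t in theta:
            verts.append((xpos, cy + radius * np.cos(t),
                          cz + radius * np.sin(t)))
        return list(range(start, start + n_theta))

    def stitch(a: list[int], b: list[int]) -> None:
        n = len(a)
        for i in range(n):
            j = (i + 1) % n
            faces.append((a[i], a[j], b[j]))
            faces.append((a[i], b[j], b[i]))

    router = rp + lateral_extent
    # two annular faces
    for xpos in (x0, x1):
        stitch(ring(xpos, rp), ring(xpos, router))
    # bore surface
    xs = np.linspace(x0, x1, n_axial + 1)
    rings = [ring(float(xv), rp) for xv in xs]
    for a, b in zip(rings[:-1], rings[1:]):
        stitch(a, b)

    with open(path, "w") as fh:
        fh.write("# poretrans membrane surface\n")
        for v in verts:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")
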