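"""NACA-section rectangular-plate fish body and prescribed body-wave motion.

The swimmer is modelled as a rectangular planform plate of total length L
with a symmetric NACA 4-digit section extruded vertically over its height —
a standard abstraction for subcarangiform bodies.  The body-wave model
drives the model by displacing every surface node laterally by
``h(x/BL, t) × BL`` metres, with the nodal velocity taken as the analytic
time derivative; axial and vertical coordinates are unchanged (the wave is
defined as displacement perpendicular to the direction of travel, so no
arc-length correction is applied).

Two length scales coexist: kinematic quantities (station positions, swim
speeds) are expressed in body lengths (BL, 0.397 m by default) while the
model geometry and pair separations use the total model length L (0.439 m
by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from fishwake.kinematics import BodyWaveParams, envelope

__all__ = [
    "FishGeometry",
    "FishBody",
    "naca_half_thickness",
    "build_fish_body",
    "deform_body",
]

# closed-trailing-edge variant of the 4-digit thickness polynomial
_NACA_COEFFS = (0.2969, -0.1260, -0.3516, 0.2843, -0.1036)


@dataclass(frozen=True)
class FishGeometry:
    """Dimensions of the plate model and the kinematic length scale.

    Defaults follow the digitized salmonid: model total length 0.439 m,
    height 0.0893 m, maximum section thickness 0.0451 m, and body length
    0.397 m used to convert kinematic BL units to metres.
    """

    length: float = 0.439
    height: float = 0.0893
    max_thickness: float = 0.0451
    body_length: float = 0.397

    def __post_init__(self) -> None:
        for name in ("length", "height", "max_thickness", "body_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_thickness >= self.length:
            raise ValueError("max_thickness must be below the model length")

    @property
    def thickness_ratio(self) -> float:
        return self.max_thickness / self.length


@dataclass
class FishBody:
    """Triangulated closed body surface with per-node prescribed motion.

    ``vertices`` are 3-D positions in metres (x chordwise from the snout,
    y lateral, z vertical); ``faces`` index triangles with outward-pointing
    normals.  ``rest_x`` keeps the undeformed chordwise coordinate of every
    vertex (deformation depends on it only), and ``velocities`` holds the
    prescribed nodal velocity set by :func:`deform_body`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    rest_vertices: np.ndarray
    geometry: FishGeometry
    velocities: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.velocities is None:
            self.velocities = np.zeros_like(self.vertices)

    @property
    def rest_x(self) -> np.ndarray:
        return self.rest_vertices[:, 0]

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Outward unit normals and areas of every triangle."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        normals = np.zeros_like(cross)
        ok = areas > 0
        normals[ok] = cross[ok] / (2.0 * areas[ok, None])
        return normals, areas

    def closure_defect(self) -> float:
        """Norm of Σ area·normal over the surface (0 for a closed body)."""
        normals, areas = self.face_normals_areas()
        return float(np.linalg.norm((normals * areas[:, None]).sum(axis=0)))

    def surface_area(self) -> float:
        return float(self.face_normals_areas()[1].sum())

    def lateral_surface_area(self) -> float:
        """Wetted area of the two lateral walls (caps excluded).

        For a thin section this approaches twice the planform area
        ``2 × length × height``.
        """
        normals, areas = self.face_normals_areas()
        side = np.abs(normals[:, 2]) < 0.99
        return float(areas[side].sum())

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def export(self, path: str | Path) -> None:
        """Write the surface as ASCII OBJ or STL (by extension)."""
        path = Path(path)
        mesh = self.to_trimesh()
        if path.suffix.lower() == ".stl":
            path.write_bytes(
                mesh.export(file_type="stl_ascii").encode()
                if isinstance(mesh.export(file_type="stl_ascii"), str)
                else mesh.export(file_type="stl_ascii")
            )
        else:
            mesh.export(path)

    def nodes_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "x_m": self.vertices[:, 0],
                "y_m": self.vertices[:, 1],
                "z_m": self.vertices[:, 2],
                "vx_m_s": self.velocities[:, 0],
                "vy_m_s": self.velocities[:, 1],
                "vz_m_s": self.velocities[:, 2],
            }
        ).to_csv(path, index=False)


def naca_half_thickness(xc, t_ratio: float):
    """Half-thickness of a symmetric NACA 4-digit section, as chord fraction.

    Uses the standard four-digit thickness polynomial with the closed
    trailing-edge last coefficient (−0.1036), so the half-thickness is
    exactly zero at both ``xc = 0`` and ``xc = 1``.
    """
    xc = np.asarray(xc, dtype=float)
    if np.any(xc < 0) or np.any(xc > 1):
        raise ValueError("chordwise fraction must lie in [0, 1]")
    if not 0 < t_ratio < 1:
        raise ValueError("thickness ratio must lie in (0, 1)")
    c0, c1, c2, c3, c4 = _NACA_COEFFS
    yt = 5.0 * t_ratio * (
        c0 * np.sqrt(xc) + xc * (c1 + xc * (c2 + xc * (c3 + xc * c4)))
    )
    return yt if yt.ndim else float(yt)


def _cosine_spacing(n: int) -> np.ndarray:
    """n+1 points on [0, 1] clustered toward both ends."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n + 1)))


def section_outline(geom: FishGeometry, n_chord: int) -> np.ndarray:
    """Closed 2-D outline of the section, counterclockwise from the snout.

    Returns ``(2*n_chord, 2)`` points: upper surface snout→tail is traversed
    on the −y side first so that the polygon is counterclockwise in (x, y).
    """
    xc = _cosine_spacing(n_chord)
    yt = naca_half_thickness(xc, geom.thickness_ratio) * geom.length
    x = xc * geom.length
    lower = np.column_stack([x[:-1], -yt[:-1]])  # snout → tail, −y side
    upper = np.column_stack([x[::-1][:-1], yt[::-1][:-1]])  # tail → snout, +y
    return np.vstack([lower, upper])


def build_fish_body(
    geom: FishGeometry, n_chord: int = 40, n_span: int = 8
) -> FishBody:
    """Extrude the NACA section into a closed triangulated plate body.

    The section outline (cosine-clustered toward leading and trailing
    edges) is replicated at ``n_span + 1`` vertical levels spanning the
    height; side walls become triangle strips and the top/bottom caps are
    fans about an interior point (the symmetric section is convex in the
    thin direction, so the fan triangulation is valid).
    """
    if n_chord < 10:
        raise ValueError("n_chord must be >= 10")
    if n_span < 2:
        raise ValueError("n_span must be >= 2")
    outline = section_outline(geom, n_chord)
    m = len(outline)
    z_levels = np.linspace(-0.5 * geom.height, 0.5 * geom.height, n_span + 1)
    rings = [
        np.column_stack([outline[:, 0], outline[:, 1], np.full(m, z)])
        for z in z_levels
    ]
    vertices = np.vstack(rings)
    faces = []
    for k in range(n_span):
        base0 = k * m
        base1 = (k + 1) * m
        for i in range(m):
            j = (i + 1) % m
            # outward orientation: outline is CCW viewed from +z
            faces.append((base0 + i, base0 + j, base1 + j))
            faces.append((base0 + i, base1 + j, base1 + i))
    # caps: fan about centroid of the section at each end
    centroid = outline.mean(axis=0)
    bot_center = len(vertices)
    top_center = bot_center + 1
    vertices = np.vstack(
        [
            vertices,
            [centroid[0], centroid[1], z_levels[0]],
            [centroid[0], centroid[1], z_levels[-1]],
        ]
    )
    for i in range(m):
        j = (i + 1) % m
        faces.append((bot_center, j, i))  # bottom cap faces −z
        faces.append((top_center, n_span * m + i, n_span * m + j))  # +z
    body = FishBody(
        vertices=vertices,
        faces=np.asarray(faces, dtype=int),
        rest_vertices=vertices.copy(),
        geometry=geom,
    )
    return body


def lateral_displacement_m(
    x_m, t: float, params: BodyWaveParams, geom: FishGeometry
):
    """Lateral displacement (m) of material points at chordwise position x_m."""
    from fishwake.kinematics import evaluate_displacement

    x_bl = np.asarray(x_m, dtype=float) / geom.body_length
    return evaluate_displacement(x_bl, t, params) * geom.body_length


def lateral_velocity_m(
    x_m, t: float, params: BodyWaveParams, geom: FishGeometry
):
    """Analytic lateral velocity ∂h/∂t (m/s) at chordwise position x_m."""
    x_bl = np.asarray(x_m, dtype=float) / geom.body_length
    phase = 2.0 * np.pi * (
        params.frequency * t - x_bl / params.wavelength
    )
    env = envelope(x_bl, params)
    return (
        -2.0 * np.pi * params.frequency * env * np.sin(phase) * geom.body_length
    )


def deform_body(
    body: FishBody, params: BodyWaveParams, t: float
) -> FishBody:
    """Apply the body wave at time ``t`` as prescribed nodal motion.

    Every node moves laterally by ``h(x/BL, t)·BL`` metres from its rest
    position; the prescribed nodal velocity is the analytic time
    derivative.  Connectivity, axial and vertical coordinates are
    untouched.  Returns a new :class:`FishBody`; the input is not mutated.
    """
    geom = body.geometry
    x = body.rest_x
    dy = lateral_displacement_m(x, t, params, geom)
    vy = lateral_velocity_m(x, t, params, geom)
    vertices = body.rest_vertices.copy()
    vertices[:, 1] += dy
    velocities = np.zeros_like(vertices)
    velocities[:, 1] = vy
    return FishBody(
        vertices=vertices,
        faces=body.faces,
        rest_vertices=body.rest_vertices,
        geometry=geom,
        velocities=velocities,
    )
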