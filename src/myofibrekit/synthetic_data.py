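"""Synthetic inputs: idealized ventricle meshes, dispersed fibre fields and
analytic warps.

Everything the downstream pipeline consumes can be generated here without
external data:

* a truncated thick-walled ellipsoidal ventricle (apex pointing along -z,
  base plane z = const) meshed into labelled tetrahedra,
* a "diffusion-MRI-like" fibre field: a rule-based mean field perturbed by
  independent in-plane and out-of-plane pi-periodic von Mises deviations
  with prescribed concentrations, and
* closed-form diffeomorphic warps (affine + Gaussian bump) whose exact
  displacement and gradient serve as oracles for the mapping stage.

Mesh generation triangulates a deterministic structured lattice of points
in (generalized radius, polar angle, azimuth) with a Delaunay pass, then
keeps the tetrahedra whose centroids lie inside the shell.  A small seeded
jitter (applied within each coordinate surface, so boundary nodes stay
exactly on their surface) breaks the co-spherical ties a regular lattice
would otherwise present to the triangulation.  The result is reproducible
bit-for-bit for a fixed spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .dispersion import sample_pi_vonmises
from .fibre_mapping import DisplacementField
from .geometry_frames import LocalFrameField, TetMesh, boundary_faces
from .rbm_fibres import FibreField

__all__ = [
    "SyntheticSpec",
    "WarpSpec",
    "AnalyticWarp",
    "generate_ventricle_mesh",
    "generate_slab_mesh",
    "sample_dispersed_fibre_field",
    "make_analytic_warp",
]


@dataclass
class SyntheticSpec:
    """Geometry of a truncated thick-walled ellipsoidal ventricle.

    ``inner_radius`` / ``outer_radius`` are the equatorial semi-axes (mm) of
    the endo-/epicardial ellipsoids; the polar semi-axes are scaled by
    ``long_axis_ratio`` (1 = sphere), long axis along -z (apex down).
    ``truncation_fraction`` is the kept portion: the base plane sits at
    z = (2 * truncation_fraction - 1) * long_axis_ratio * outer_radius, so
    1.0 keeps the full closed shell and 0.5 cuts at the equator.
    """

    inner_radius: float = 7.0
    outer_radius: float = 10.0
    truncation_fraction: float = 0.75
    long_axis_ratio: float = 1.0
    target_edge_length: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.outer_radius > self.inner_radius > 0):
            raise ValueError("require outer_radius > inner_radius > 0")
        if not (0.0 < self.truncation_fraction <= 1.0):
            raise ValueError("truncation_fraction must be in (0, 1]")
        if self.long_axis_ratio < 1.0:
            raise ValueError("long_axis_ratio must be >= 1")
        wall = self.outer_radius - self.inner_radius
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be positive")
        if self.target_edge_length > wall:
            raise ValueError(
                f"target_edge_length {self.target_edge_length} mm cannot resolve "
                f"the {wall} mm wall (must be <= outer_radius - inner_radius)"
            )

    @property
    def base_z(self) -> float:
        return (2.0 * self.truncation_fraction - 1.0) * self.long_axis_ratio * self.outer_radius


def _shell_points(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Structured lattice inside the truncated shell.

    Returns the (n, 3) points and an (n,) bool mask of base-plane points.
    Jitter is applied in lattice coordinates so that points on the inner /
    outer surfaces and the base plane stay exactly on them.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.target_edge_length
    ri, ro, k = spec.inner_radius, spec.outer_radius, spec.long_axis_ratio
    zb = spec.base_z
    full = spec.truncation_fraction >= 1.0

    n_r = max(2, int(round((ro - ri) / h)))
    r_levels = np.linspace(ri, ro, n_r + 1)
    pts: list[np.ndarray] = []
    on_base: list[bool] = []
    jit = 0.12 * h

    for li, r in enumerate(r_levels):
        interior_level = 0 < li < n_r
        c_r = k * r
        if full or zb >= c_r:
            theta_max = np.pi
        else:
            theta_max = float(np.arccos(np.clip(-zb / c_r, -1.0, 1.0)))
        arc = max(r, c_r) * theta_max
        n_t = max(3, int(np.ceil(arc / h)))
        thetas = np.linspace(0.0, theta_max, n_t + 1)
        for ti, theta in enumerate(thetas):
            at_base = (not full) and theta_max < np.pi and ti == n_t
            pole = theta < 1e-12 or theta > np.pi - 1e-12
            if pole:
                rr = r + (rng.uniform(-jit, jit) if interior_level else 0.0)
                pts.append(np.array([[0.0, 0.0, -k * rr * np.cos(theta)]]))
                on_base.append(at_base)
                continue
            ring_r = r * np.sin(theta)
            n_p = max(3, int(np.ceil(2.0 * np.pi * ring_r / h)))
            phi = 2.0 * np.pi * np.arange(n_p) / n_p + rng.uniform(0.0, 2.0 * np.pi)
            th = np.full(n_p, theta)
            if not at_base and 0 < ti < n_t:
                th = th + rng.uniform(-jit, jit, n_p) / max(r, c_r)
                th = np.clip(th, 1e-3, theta_max - 1e-3 if not full else np.pi - 1e-3)
            phi = phi + rng.uniform(-jit, jit, n_p) / ring_r
            rr = np.full(n_p, r)
            if interior_level:
                rr = rr + rng.uniform(-jit, jit, n_p)
            ring = np.column_stack(
                [
                    rr * np.sin(th) * np.cos(phi),
                    rr * np.sin(th) * np.sin(phi),
                    -k * rr * np.cos(th),
                ]
            )
            if at_base:
                ring[:, 2] = zb
            pts.append(ring)
            on_base.extend([at_base] * n_p)
    points = np.vstack(pts)
    base_mask = np.zeros(len(points), dtype=bool)
    ofs = 0
    for block, flag in zip(pts, on_base):
        base_mask[ofs : ofs + len(block)] = flag
        ofs += len(block)
    return points, base_mask


def _generalized_radius(xyz: np.ndarray, long_axis_ratio: float) -> np.ndarray:
    return np.sqrt(xyz[..., 0] ** 2 + xyz[..., 1] ** 2 + (xyz[..., 2] / long_axis_ratio) ** 2)


def generate_ventricle_mesh(spec: SyntheticSpec) -> TetMesh:
    """Labelled tet mesh of the truncated thick-walled ellipsoid.

    Boundary facets are labelled ``lv_endo`` (inner surface), ``epi``
    (outer surface) and ``base`` (truncation plane); deterministic for a
    fixed spec (the seed only steers the tie-breaking jitter).
    """
    points, base_mask = _shell_points(spec)
    tri = Delaunay(points)
    tets = tri.simplices
    cent = points[tets].mean(axis=1)
    m = _generalized_radius(cent, spec.long_axis_ratio)
    keep = (m > spec.inner_radius) & (m < spec.outer_radius)
    tets = tets[keep]
    # drop exactly/nearly flat simplices (co-planar lattice points on the base)
    x = points[tets]
    e = x[:, 1:] - x[:, :1]
    vol = np.abs(np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))) / 6.0
    tets = tets[vol > 1e-9 * spec.target_edge_length**3]

    used = np.unique(tets)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = points[used]
    tets = remap[tets]
    base_mask = base_mask[used]

    faces = boundary_faces(tets)
    mr = _generalized_radius(nodes, spec.long_axis_ratio)
    dev_in = np.abs(mr[faces] - spec.inner_radius).max(axis=1)
    dev_out = np.abs(mr[faces] - spec.outer_radius).max(axis=1)
    if spec.truncation_fraction < 1.0:
        dev_base = np.abs(nodes[faces][:, :, 2] - spec.base_z).max(axis=1)
        devs = np.column_stack([dev_in, dev_out, dev_base])
        names = np.array(["lv_endo", "epi", "base"], dtype=object)
    else:
        devs = np.column_stack([dev_in, dev_out])
        names = np.array(["lv_endo", "epi"], dtype=object)
    labels = names[devs.argmin(axis=1)]
    return TetMesh(nodes=nodes, tets=tets, facets=faces, facet_labels=labels)


def generate_slab_mesh(
    n: tuple[int, int, int] = (6, 6, 6),
    lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    endo_label: str = "lv_endo",
) -> TetMesh:
    """Structured tetrahedral slab on [0,Lx]x[0,Ly]x[0,Lz] for solver checks.

    The face x = 0 is labelled ``endo_label``, x = Lx is ``epi`` and the
    remaining four faces are ``base`` (zero-flux in the transmural solve),
    so the harmonic wall-depth field is exactly x / Lx.
    """
    nx, ny, nz = n
    lx, ly, lz = lengths
    gx, gy, gz = (np.linspace(0, L, k + 1) for L, k in ((lx, nx), (ly, ny), (lz, nz)))
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, kk):
        return (i * (ny + 1) + j) * (nz + 1) + kk

    # Kuhn subdivision of each cube into 6 tets; the pattern is translation
    # invariant, so shared faces between neighbouring cubes conform.
    perms = [
        (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
        (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
    ]
    corners = lambda i, j, kk: [
        nid(i + a, j + b, kk + c)
        for a, b, c in [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                        (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    ]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for kk in range(nz):
                c = corners(i, j, kk)
                tets.extend([c[p] for p in perm] for perm in perms)
    tets = np.asarray(tets, dtype=np.int64)
    faces = boundary_faces(tets)
    fx = nodes[faces][:, :, 0]
    labels = np.full(len(faces), "base", dtype=object)
    labels[np.all(np.abs(fx) < 1e-12, axis=1)] = endo_label
    labels[np.all(np.abs(fx - lx) < 1e-12, axis=1)] = "epi"
    return TetMesh(nodes=nodes, tets=tets, facets=faces, facet_labels=labels)


# --------------------------------------------------------------------------
# dispersed fibre sampling
# --------------------------------------------------------------------------

def sample_dispersed_fibre_field(
    mesh: TetMesh,
    frames: LocalFrameField,
    mean_angles_deg: np.ndarray,
    b_in: float,
    b_out: float,
    seed: int,
) -> FibreField:
    """Rule-based mean field perturbed by independent axial dispersions.

    Per element, the in-plane deviation is drawn from the pi-periodic von
    Mises with concentration ``b_in`` and the out-of-plane elevation from
    the one with ``b_out``; the fibre is

        f = cos(phi) (cos(alpha) c0 + sin(alpha) l0) + sin(phi) r0,

    with ``alpha`` the mean rotation angle plus the in-plane deviation.
    The sheet is the transmural direction orthogonalized against ``f`` and
    ``n0 = f0 x s0``.
    """
    mean = np.asarray(mean_angles_deg, dtype=float)
    if mean.shape[0] != mesh.n_elements:
        raise ValueError(
            f"mean angles ({mean.shape[0]}) and mesh elements "
            f"({mesh.n_elements}) mismatch"
        )
    if frames.c0.shape[0] != mesh.n_elements:
        raise ValueError("frame field and mesh element counts mismatch")
    if b_in < 0 or b_out < 0:
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    th = sample_pi_vonmises(b_in, mesh.n_elements, rng)
    ph = sample_pi_vonmises(b_out, mesh.n_elements, rng)
    alpha = np.radians(mean) + th
    inplane = np.cos(alpha)[:, None] * frames.c0 + np.sin(alpha)[:, None] * frames.l0
    f0 = np.cos(ph)[:, None] * inplane + np.sin(ph)[:, None] * frames.r0
    return FibreField.from_fibre_and_sheet(f0, frames.r0)


# --------------------------------------------------------------------------
# analytic warps
# --------------------------------------------------------------------------

@dataclass
class WarpSpec:
    """Affine map plus a Gaussian bump, with closed-form gradient.

    The warp is x -> A x + t + amplitude * exp(-|x-c|^2 / (2 w^2)) * d; the
    composition must be a diffeomorphism on the region of interest
    (checked by sampling the gradient determinant).
    """

    affine: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bump_amplitude: float = 0.0
    bump_width: float = 1.0
    bump_centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bump_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.bump_centre = np.asarray(self.bump_centre, dtype=float).reshape(3)
        self.bump_direction = np.asarray(self.bump_direction, dtype=float).reshape(3)
        if self.bump_width <= 0:
            raise ValueError("bump_width must be positive")


class AnalyticWarp:
    """Callable closed-form warp with exact displacement and gradient."""

    def __init__(self, spec: WarpSpec):
        self.spec = spec

    def map(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        s = self.spec
        r2 = ((x - s.bump_centre) ** 2).sum(axis=-1, keepdims=True)
        bump = s.bump_amplitude * np.exp(-r2 / (2.0 * s.bump_width**2))
        return x @ s.affine.T + s.translation + bump * s.bump_direction

    def displacement(self, x: np.ndarray) -> np.ndarray:
        return self.map(x) - np.asarray(x, dtype=float)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Exact warp gradient dphi_i/dx_j at each point; shape (..., 3, 3)."""
        x = np.asarray(x, dtype=float)
        s = self.spec
        dx = x - s.bump_centre
        r2 = (dx**2).sum(axis=-1, keepdims=True)
        g = s.bump_amplitude * np.exp(-r2 / (2.0 * s.bump_width**2))
        outer = s.bump_direction[None, :, None] * (-dx / s.bump_width**2)[..., None, :]
        return s.affine + g[..., None] * outer


def make_analytic_warp(
    spec: WarpSpec, mesh: TetMesh, n_check: int = 2048, seed: int = 0
) -> tuple[DisplacementField, AnalyticWarp]:
    """Surface displacement field of the closed-form warp on a mesh.

    The gradient determinant is sampled at the mesh nodes and at ``n_check``
    random points of the bounding box; a non-positive determinant anywhere
    raises (non-diffeomorphic spec).  Returns the field (prescribed on all
    external-surface nodes) together with the warp object, whose exact
    displacement/gradient serve as oracles downstream.
    """
    warp = AnalyticWarp(spec)
    rng = np.random.default_rng(seed)
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    sample = np.vstack([mesh.nodes, rng.uniform(lo, hi, size=(n_check, 3))])
    dets = np.linalg.det(warp.gradient(sample))
    if np.any(dets <= 0.0):
        raise ValueError(
            f"warp is not a diffeomorphism on the mesh bounding box "
            f"(min det grad = {dets.min():.3g})"
        )
    surf = mesh.surface_nodes()
    u = np.zeros((mesh.n_nodes, 3))
    known = np.zeros(mesh.n_nodes, dtype=bool)
    u[surf] = warp.displacement(mesh.nodes[surf])
    known[surf] = True
    return DisplacementField(u=u, known=known), warp
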