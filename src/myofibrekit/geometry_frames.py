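"""Labelled tetrahedral ventricular meshes, the transmural (wall-depth)
coordinate, local circumferential-radial-longitudinal frames and AHA17
segment labels.

The transmural coordinate ``ebar`` is the harmonic interpolant between the
endocardial (0) and epicardial (1) surfaces, discretized with linear (P1)
tetrahedral finite elements -- the Laplace-Dirichlet construction that
rule-based fibre methods are built on.  The local frame per element is

* ``r0``  -- normalized gradient of ``ebar`` (radial / transmural, endo->epi),
* ``l0``  -- the prescribed long axis, orthogonalized against ``r0``,
* ``c0``  -- ``l0 x r0`` (circumferential).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

__all__ = [
    "TetMesh",
    "TransmuralField",
    "LocalFrameField",
    "SegmentLabelField",
    "RV_SEGMENT",
    "solve_transmural_coordinate",
    "build_local_frames",
    "assign_aha17",
]

#: Sentinel segment id used for right-ventricular free-wall elements
#: (the LV proper gets labels 1..17).
RV_SEGMENT = 0

ENDO_LABELS = ("lv_endo", "rv_endo")
VALID_LABELS = ("lv_endo", "rv_endo", "epi", "base")


# --------------------------------------------------------------------------
# mesh container
# --------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Tetrahedral mesh with labelled boundary triangles.

    Parameters
    ----------
    nodes : (n, 3) float array, mm
    tets : (m, 4) int array
        Node indices; tets are re-oriented on construction so that every
        signed volume is positive.
    facets : (k, 3) int array
        Boundary triangles.
    facet_labels : (k,) array of str
        One label per boundary triangle, each in
        ``{"lv_endo", "rv_endo", "epi", "base"}``.
    """

    nodes: np.ndarray
    tets: np.ndarray
    facets: np.ndarray
    facet_labels: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.facets = np.asarray(self.facets, dtype=np.int64)
        self.facet_labels = np.asarray(self.facet_labels, dtype=object)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (m, 4)")
        if self.facets.shape[0] != self.facet_labels.shape[0]:
            raise ValueError("one label per boundary facet required")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise ValueError("tet node index out of range")
        if self.facets.size and (self.facets.min() < 0 or self.facets.max() >= len(self.nodes)):
            raise ValueError("facet node index out of range")
        bad = set(np.unique(self.facet_labels)) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown boundary labels: {sorted(bad)}")
        # orient all tets positively
        vol = self._signed_volumes()
        flip = vol < 0
        if np.any(flip):
            t = self.tets[flip].copy()
            t[:, [0, 1]] = t[:, [1, 0]]
            self.tets[flip] = t
        if np.any(self._signed_volumes() <= 0.0):
            raise ValueError("mesh contains degenerate (zero-volume) tets")

    # -- geometry -----------------------------------------------------------

    def _signed_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        e = x[:, 1:] - x[:, :1]
        return np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        return self._signed_volumes()

    def total_volume(self) -> float:
        return float(self._signed_volumes().sum())

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def nodes_with_label(self, *labels: str) -> np.ndarray:
        """Sorted unique node indices lying on facets with any given label."""
        mask = np.isin(self.facet_labels.astype(str), labels)
        return np.unique(self.facets[mask])

    def surface_nodes(self) -> np.ndarray:
        return np.unique(self.facets)

    def shape_gradients(self) -> np.ndarray:
        """(m, 4, 3) gradients of the P1 barycentric shape functions."""
        x = self.nodes[self.tets]
        e = np.swapaxes(x[:, 1:] - x[:, :1], 1, 2)  # (m, 3, 3) columns = edges
        einv = np.linalg.inv(e)                      # rows: grads of lam1..lam3
        g = np.empty((self.n_elements, 4, 3))
        g[:, 1:] = einv  # row i of E^-1 is grad(lambda_{i+1})
        g[:, 0] = -einv.sum(axis=1)
        return g

    def validate(self) -> None:
        """Raise if any TetMesh invariant is violated."""
        if np.any(self._signed_volumes() <= 0):
            raise ValueError("non-positive tet volume")
        # facets must be faces of some tet
        faces = _tet_faces(self.tets)
        face_set = {tuple(sorted(f)) for f in faces.reshape(-1, 3)}
        for f in self.facets:
            if tuple(sorted(f)) not in face_set:
                raise ValueError("boundary facet is not a tet face")


def _tet_faces(tets: np.ndarray) -> np.ndarray:
    """(m, 4, 3) local faces of each tet."""
    return tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]]


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces appearing in exactly one tet, as an (k, 3) index array."""
    faces = _tet_faces(tets).reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


# --------------------------------------------------------------------------
# field containers
# --------------------------------------------------------------------------

@dataclass
class TransmuralField:
    """Per-node normalized wall depth, 0 at endocardium, 1 at epicardium."""

    ebar: np.ndarray

    def __post_init__(self) -> None:
        self.ebar = np.asarray(self.ebar, dtype=float)

    def element_means(self, mesh: TetMesh) -> np.ndarray:
        return self.ebar[mesh.tets].mean(axis=1)


@dataclass
class LocalFrameField:
    """Per-element circumferential / radial / longitudinal unit triads."""

    c0: np.ndarray
    r0: np.ndarray
    l0: np.ndarray

    def __post_init__(self) -> None:
        self.c0 = np.asarray(self.c0, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        self.l0 = np.asarray(self.l0, dtype=float)

    def max_orthonormality_error(self) -> float:
        errs = [
            np.abs(np.einsum("ij,ij->i", a, b)).max()
            for a, b in ((self.c0, self.r0), (self.c0, self.l0), (self.r0, self.l0))
        ]
        errs += [
            np.abs(np.linalg.norm(v, axis=1) - 1.0).max()
            for v in (self.c0, self.r0, self.l0)
        ]
        return float(max(errs))


@dataclass
class SegmentLabelField:
    """Per-element AHA17 segment ids (1..17); RV free wall is ``RV_SEGMENT``."""

    segment: np.ndarray

    def __post_init__(self) -> None:
        self.segment = np.asarray(self.segment, dtype=np.int64)


# --------------------------------------------------------------------------
# P1 Laplace machinery
# --------------------------------------------------------------------------

def stiffness_matrix(mesh: TetMesh) -> sp.csr_matrix:
    """Assemble the P1 Laplace stiffness matrix K_ij = integral grad v_i . grad v_j."""
    grads = mesh.shape_gradients()            # (m, 4, 3)
    vols = mesh.tet_volumes()                 # (m,)
    ke = np.einsum("eik,ejk,e->eij", grads, grads, vols)  # (m, 4, 4)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix(
        (ke.reshape(-1), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def solve_dirichlet(
    K: sp.csr_matrix, dirichlet_nodes: np.ndarray, dirichlet_values: np.ndarray
) -> np.ndarray:
    """Solve K u = 0 with Dirichlet data; natural (zero-flux) elsewhere.

    ``dirichlet_values`` may be (d,) for a scalar field or (d, c) for ``c``
    simultaneous right-hand sides sharing the same constrained nodes.
    """
    n = K.shape[0]
    fixed = np.zeros(n, dtype=bool)
    fixed[dirichlet_nodes] = True
    free = ~fixed
    vals = np.atleast_2d(np.asarray(dirichlet_values, dtype=float).T).T  # (d, c)
    if vals.shape[0] != len(dirichlet_nodes):
        raise ValueError("one Dirichlet value (row) per constrained node required")
    u = np.zeros((n, vals.shape[1]))
    u[dirichlet_nodes] = vals
    rhs = -K[free][:, fixed] @ u[fixed]
    Kff = K[free][:, free].tocsc()
    if Kff.shape[0]:
        lu = spla.splu(Kff)
        u[free] = np.column_stack([lu.solve(np.asarray(rhs[:, j]).ravel())
                                   for j in range(rhs.shape[1])])
    return u if np.asarray(dirichlet_values).ndim > 1 else u[:, 0]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def solve_transmural_coordinate(mesh: TetMesh) -> TransmuralField:
    """Harmonic wall-depth coordinate: 0 on endocardium, 1 on epicardium.

    Natural (zero-flux) boundary condition on the base; by the discrete
    maximum principle interior values lie strictly inside (0, 1).
    """
    endo = mesh.nodes_with_label(*ENDO_LABELS)
    epi = mesh.nodes_with_label("epi")
    if endo.size == 0:
        raise ValueError("mesh has no endocardial ('lv_endo'/'rv_endo') boundary facets")
    if epi.size == 0:
        raise ValueError("mesh has no epicardial ('epi') boundary facets")
    # nodes on both surfaces (possible at a sharp rim) take the epicardial value
    endo = np.setdiff1d(endo, epi)
    K = stiffness_matrix(mesh)
    nodes = np.concatenate([endo, epi])
    vals = np.concatenate([np.zeros(endo.size), np.ones(epi.size)])
    ebar = solve_dirichlet(K, nodes, vals)
    if not np.all(np.isfinite(ebar)):
        raise ValueError("singular transmural Laplace system")
    return TransmuralField(ebar=ebar)


def element_gradient(mesh: TetMesh, nodal_field: np.ndarray) -> np.ndarray:
    """Per-element (constant) gradient of a P1 nodal scalar field."""
    grads = mesh.shape_gradients()
    return np.einsum("ei,eik->ek", nodal_field[mesh.tets], grads)


def build_local_frames(
    mesh: TetMesh,
    ebar: TransmuralField,
    long_axis: np.ndarray,
    degenerate_tol: float = 1e-8,
) -> LocalFrameField:
    """Per-element (c0, r0, l0) triads from the transmural gradient.

    Elements where ``grad ebar`` (relative to the field's typical magnitude)
    vanishes inherit the frame of the nearest valid element, with a warning.
    """
    axis = np.asarray(long_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("long_axis must be non-zero")
    axis = axis / nrm

    g = element_gradient(mesh, ebar.ebar)
    gn = np.linalg.norm(g, axis=1)
    scale = max(gn.max(), 1.0e-300)
    ok = gn > degenerate_tol * scale
    if not np.any(ok):
        raise ValueError("transmural gradient vanishes on every element")
    if not np.all(ok):
        warnings.warn(
            f"{np.count_nonzero(~ok)} element(s) with degenerate transmural "
            "gradient; using nearest valid neighbour frames",
            stacklevel=2,
        )
        cent = mesh.element_centroids()
        tree = cKDTree(cent[ok])
        _, j = tree.query(cent[~ok])
        g[~ok] = g[np.flatnonzero(ok)[j]]
        gn = np.linalg.norm(g, axis=1)

    r0 = g / gn[:, None]
    l0 = axis[None, :] - np.einsum("k,ek->e", axis, r0)[:, None] * r0
    ln = np.linalg.norm(l0, axis=1)
    bad = ln < degenerate_tol
    if np.any(bad):
        # long axis parallel to r0: pick any tangent direction deterministically
        alt = np.array([1.0, 0.0, 0.0])
        if abs(axis[0]) > 0.9:
            alt = np.array([0.0, 1.0, 0.0])
        l0[bad] = alt - np.einsum("ek,k->e", r0[bad], alt)[:, None] * r0[bad]
        ln = np.linalg.norm(l0, axis=1)
    l0 /= ln[:, None]
    c0 = np.cross(l0, r0)
    c0 /= np.linalg.norm(c0, axis=1)[:, None]
    return LocalFrameField(c0=c0, r0=r0, l0=l0)


def assign_aha17(
    mesh: TetMesh,
    long_axis: np.ndarray,
    rv_insertion_reference: np.ndarray,
    rv_mask: np.ndarray | None = None,
    apex_fraction: float | None = None,
) -> SegmentLabelField:
    """American Heart Association 17-segment labels for the LV.

    The long-axis coordinate runs from the base plane (0) towards the apex
    (increasing along ``long_axis``, which must point base -> apex).  The cap
    below the endocardial apex (no cavity at that depth) is segment 17; the
    remaining extent is split into equal basal / mid / apical thirds with
    6 / 6 / 4 circumferential sectors.  The azimuth is measured from
    ``rv_insertion_reference`` (anterior direction, right-handed about the
    base->apex axis); segment 1 is the basal sector centred on it.

    Elements above the base plane (negative axis coordinate beyond a small
    tolerance) raise an error.  ``rv_mask`` marks RV free-wall elements,
    which receive ``RV_SEGMENT`` instead of a 1-17 label.
    """
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.asarray(rv_insertion_reference, dtype=float)
    ref = ref - (ref @ axis) * axis
    if np.linalg.norm(ref) < 1e-12:
        raise ValueError("rv_insertion_reference is parallel to the long axis")
    ref /= np.linalg.norm(ref)
    perp = np.cross(axis, ref)

    base_nodes = mesh.nodes_with_label("base")
    if base_nodes.size == 0:
        raise ValueError("mesh has no 'base' facets to define the base plane")
    origin = mesh.nodes[base_nodes].mean(axis=0)
    cent = mesh.element_centroids() - origin
    s = cent @ axis
    span = s.max()
    if span <= 0:
        raise ValueError("no elements below the base plane")
    if np.any(s < -1e-6 * span):
        raise ValueError("elements above the base plane")

    # cavity extent: deepest endocardial point along the axis
    endo_nodes = mesh.nodes_with_label(*ENDO_LABELS)
    if apex_fraction is None:
        if endo_nodes.size:
            s_cav = ((mesh.nodes[endo_nodes] - origin) @ axis).max()
        else:
            s_cav = 0.9 * span
        s_cav = min(s_cav, 0.97 * span)
    else:
        s_cav = (1.0 - apex_fraction) * span

    alpha = np.degrees(np.arctan2(cent @ perp, cent @ ref)) % 360.0

    seg = np.empty(mesh.n_elements, dtype=np.int64)
    third = np.clip((s / s_cav * 3.0).astype(int), 0, 3)  # 0 basal,1 mid,2 apical,3 cap
    sec6 = (((alpha + 30.0) % 360.0) / 60.0).astype(int)  # sector 0 centred on ref
    sec4 = (((alpha + 45.0) % 360.0) / 90.0).astype(int)
    seg[third == 0] = 1 + sec6[third == 0]
    seg[third == 1] = 7 + sec6[third == 1]
    seg[third == 2] = 13 + sec4[third == 2]
    seg[third == 3] = 17
    if rv_mask is not None:
        seg[np.asarray(rv_mask, dtype=bool)] = RV_SEGMENT
    return SegmentLabelField(segment=seg)
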