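"""Deformable probabilistic atlas encoded as a simplex mesh.

The segmentation prior is a mesh (triangles in 2D, tetrahedra in 3D) whose
nodes carry label probabilities.  Deforming the node positions away from the
reference configuration is penalised by a topology-preserving cost that is
zero at the identity, smooth for admissible deformations, and grows without
bound as any simplex approaches zero volume.  Per-voxel label priors are
obtained by barycentric interpolation of the node label probabilities inside
the enclosing simplex.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "SimplexAtlas",
    "LabelPriorField",
    "FoldedMeshError",
    "simplex_penalty",
    "penalty_gradient",
    "rasterize_label_prior",
    "barycentric_membership",
    "make_toy_atlas",
    "save_atlas",
    "load_atlas",
]

_BARY_TOL = 1e-9


class FoldedMeshError(ValueError):
    """Raised when an operation requires an unfolded mesh but a simplex has
    non-positive volume."""


@dataclasses.dataclass
class SimplexAtlas:
    """Reference mesh geometry plus per-node label probabilities.

    Attributes
    ----------
    ref_positions : (M_nodes, D) float array
        Node coordinates in voxel units (0-based voxel-center convention).
    simplices : (M, D+1) int array
        Node indices of each simplex, consistently oriented so that the
        signed volume in the reference configuration is strictly positive.
    node_label_probs : (M_nodes, K) float array
        Per-node label probabilities; rows sum to one.
    stiffness : float
        Mesh stiffness K > 0 multiplying the deformation penalty.
    grid_shape : tuple of int
        Shape of the voxel grid the atlas is defined on.
    class_names : list of str
    """

    ref_positions: np.ndarray
    simplices: np.ndarray
    node_label_probs: np.ndarray
    stiffness: float
    grid_shape: tuple
    class_names: list = None

    def __post_init__(self):
        self.ref_positions = np.asarray(self.ref_positions, dtype=float)
        self.simplices = np.asarray(self.simplices, dtype=int)
        self.node_label_probs = np.asarray(self.node_label_probs, dtype=float)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.class_names is None:
            self.class_names = [f"class{k}" for k in range(self.n_classes)]
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.ref_positions.shape[0]

    @property
    def n_simplices(self) -> int:
        return self.simplices.shape[0]

    @property
    def ndim(self) -> int:
        return self.ref_positions.shape[1]

    @property
    def n_classes(self) -> int:
        return self.node_label_probs.shape[1]

    def validate(self):
        if self.ref_positions.ndim != 2:
            raise ValueError("ref_positions must be (M_nodes, D)")
        D = self.ndim
        if D not in (2, 3):
            raise ValueError(f"only 2D and 3D meshes supported, got D={D}")
        if len(self.grid_shape) != D:
            raise ValueError("grid_shape dimensionality mismatch")
        if self.simplices.shape[1] != D + 1:
            raise ValueError("simplices must be (M, D+1)")
        if self.simplices.max() >= self.n_nodes or self.simplices.min() < 0:
            raise ValueError("simplex node index out of range")
        if self.node_label_probs.shape[0] != self.n_nodes:
            raise ValueError("node_label_probs row count mismatch")
        row_sums = self.node_label_probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("node_label_probs rows must sum to 1")
        if np.any(self.node_label_probs < -1e-12):
            raise ValueError("node_label_probs must be nonnegative")
        if not self.stiffness > 0:
            raise ValueError("stiffness must be positive")
        vols = signed_volumes(self.ref_positions, self.simplices)
        if np.any(vols <= 0):
            raise ValueError("reference simplices must have positive signed volume")

    def check_positions(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != self.ref_positions.shape:
            raise ValueError(
                f"positions shape {x.shape} does not match atlas "
                f"{self.ref_positions.shape}"
            )
        return x


@dataclasses.dataclass
class LabelPriorField:
    """Per-voxel label prior on the voxels covered by the mesh.

    ``probs`` has one row per covered voxel; ``voxel_index_map`` holds the
    flat (C-order) grid index of each row.
    """

    probs: np.ndarray
    voxel_index_map: np.ndarray
    grid_shape: tuple


def signed_volumes(positions: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Signed simplex volumes (area in 2D) for the given node positions."""
    verts = positions[simplices]  # (M, D+1, D)
    edges = verts[:, 1:, :] - verts[:, :1, :]  # (M, D, D)
    D = positions.shape[1]
    return np.linalg.det(edges) / math.factorial(D)


def _edge_matrices(positions, simplices):
    verts = positions[simplices]
    # columns are edge vectors p_j - p_0
    return np.swapaxes(verts[:, 1:, :] - verts[:, :1, :], 1, 2), verts


def simplex_penalty(x, x_ref_like, atlas: SimplexAtlas, *, per_simplex=False):
    """Topology-preserving deformation penalty summed over simplices.

    For each simplex, let ``J`` be the Jacobian of the affine map taking the
    simplex in ``x_ref_like`` to the one in ``x``, ``V`` the reference volume
    and ``dc`` the centroid displacement.  The cost is

        U_m = V * [ (det J - 1)^2 + (1/det J - 1)^2 + ||J - I||_F^2 + ||dc||^2 ]

    which is zero iff the deformation is the identity and diverges as det J
    approaches zero.  Returns ``inf`` if any simplex (in either argument) has
    non-positive volume.
    """
    x = atlas.check_positions(x)
    r = atlas.check_positions(x_ref_like)
    D = atlas.ndim
    A, verts_x = _edge_matrices(x, atlas.simplices)
    B, verts_r = _edge_matrices(r, atlas.simplices)
    detA = np.linalg.det(A)
    detB = np.linalg.det(B)
    if np.any(detA <= 0) or np.any(detB <= 0):
        return np.inf
    V = detB / math.factorial(D)
    Binv = np.linalg.inv(B)
    J = A @ Binv
    d = detA / detB
    I = np.eye(D)
    frob = np.sum((J - I) ** 2, axis=(1, 2))
    dc = verts_x.mean(axis=1) - verts_r.mean(axis=1)
    g = (d - 1.0) ** 2 + (1.0 / d - 1.0) ** 2
    per = V * (g + frob + np.sum(dc * dc, axis=1))
    return per if per_simplex else float(per.sum())


def penalty_gradient(x, x_ref_like, atlas: SimplexAtlas, wrt: str = "deformed"):
    """Gradient of :func:`simplex_penalty` w.r.t. the deformed or reference
    node positions; shape (M_nodes, D).

    Raises :class:`FoldedMeshError` on folded configurations, where the
    penalty is infinite and the gradient undefined.
    """
    if wrt not in ("deformed", "reference"):
        raise ValueError("wrt must be 'deformed' or 'reference'")
    x = atlas.check_positions(x)
    r = atlas.check_positions(x_ref_like)
    D = atlas.ndim
    A, verts_x = _edge_matrices(x, atlas.simplices)
    B, verts_r = _edge_matrices(r, atlas.simplices)
    detA = np.linalg.det(A)
    detB = np.linalg.det(B)
    if np.any(detA <= 0) or np.any(detB <= 0):
        raise FoldedMeshError("penalty gradient undefined on folded mesh")
    V = detB / math.factorial(D)
    Binv = np.linalg.inv(B)
    BinvT = np.swapaxes(Binv, 1, 2)
    J = A @ Binv
    d = detA / detB
    I = np.eye(D)
    JmI = J - I
    frob = np.sum(JmI**2, axis=(1, 2))
    dc = verts_x.mean(axis=1) - verts_r.mean(axis=1)
    cen2 = np.sum(dc * dc, axis=1)
    g = (d - 1.0) ** 2 + (1.0 / d - 1.0) ** 2
    gp = 2.0 * (d - 1.0) - 2.0 * (1.0 / d - 1.0) / d**2

    if wrt == "deformed":
        AinvT = np.swapaxes(np.linalg.inv(A), 1, 2)
        # dU/dA = V [ g'(d) d A^{-T} + 2 (J - I) B^{-T} ]
        dUdA = V[:, None, None] * (
            (gp * d)[:, None, None] * AinvT + 2.0 * JmI @ BinvT
        )
        # centroid term: dU/dvert_j = V * 2 dc / (D+1) for every vertex
        dcen = (V[:, None] * (2.0 / (D + 1)) * dc)[:, None, :].repeat(D + 1, axis=1)
        grad_edges = dUdA  # columns correspond to p_j - p_0, j = 1..D
    else:
        # U = V(B) [ g(d) + F + cen2 ]; dV/dB = V B^{-T}
        # dF/dB = -2 J^T (J - I) B^{-T}; dg/dB = -g'(d) d B^{-T}
        JT = np.swapaxes(J, 1, 2)
        dUdB = (V * (g + frob + cen2))[:, None, None] * BinvT + V[:, None, None] * (
            -(gp * d)[:, None, None] * BinvT - 2.0 * (JT @ JmI) @ BinvT
        )
        dcen = (-(V[:, None]) * (2.0 / (D + 1)) * dc)[:, None, :].repeat(D + 1, axis=1)
        grad_edges = dUdB

    # map edge-matrix gradient to vertex gradients:
    # column j of dU/dA is dU/d(p_j - p_0); p_0 receives minus the column sum
    grad_verts = np.empty((atlas.n_simplices, D + 1, D))
    grad_verts[:, 1:, :] = np.swapaxes(grad_edges, 1, 2)
    grad_verts[:, 0, :] = -grad_edges.sum(axis=2)
    grad_verts += dcen

    out = np.zeros_like(x)
    np.add.at(out, atlas.simplices.ravel(), grad_verts.reshape(-1, D))
    return out


def _voxel_centers(grid_shape):
    axes = [np.arange(s, dtype=float) for s in grid_shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def barycentric_membership(x, atlas: SimplexAtlas, points=None):
    """Assign points (default: all voxel centers) to enclosing simplices.

    Returns ``(simplex_index, bary_weights, point_index)`` for the points
    that fall inside some simplex.  Points on shared faces go to the
    lowest-index containing simplex.  Raises on folded meshes.
    """
    x = atlas.check_positions(x)
    D = atlas.ndim
    use_grid = points is None
    if use_grid:
        points = _voxel_centers(atlas.grid_shape)
    n_pts = points.shape[0]
    vols = signed_volumes(x, atlas.simplices)
    if np.any(vols <= 0):
        raise FoldedMeshError("cannot rasterize a folded mesh")

    A, verts = _edge_matrices(x, atlas.simplices)
    Ainv = np.linalg.inv(A)
    p0 = verts[:, 0, :]

    M = atlas.n_simplices
    grid_shape = atlas.grid_shape
    lo_all = np.floor(verts.min(axis=1)).astype(np.int64)
    hi_all = np.ceil(verts.max(axis=1)).astype(np.int64)
    np.clip(lo_all, 0, np.asarray(grid_shape) - 1, out=lo_all)
    np.clip(hi_all, 0, np.asarray(grid_shape) - 1, out=hi_all)
    widths = hi_all - lo_all + 1

    # ties on shared faces resolve to the lowest simplex index
    assigned = np.full(n_pts, M, dtype=np.int64)

    if use_grid:
        strides = np.array(
            [int(np.prod(grid_shape[d + 1:])) for d in range(D)], dtype=np.int64
        )
        wmax = widths.max(axis=0)
        off_axes = [np.arange(w) for w in wmax]
        offs = np.stack(
            [m.ravel() for m in np.meshgrid(*off_axes, indexing="ij")], axis=1
        )  # (n_off, D)
        n_off = offs.shape[0]
        chunk = max(1, int(4_000_000 // max(n_off, 1)))
        starts = list(range(0, M, chunk))
        # process chunks high-to-low and pairs in descending simplex order so
        # plain fancy assignment leaves the lowest containing index in place
        for s0 in reversed(starts):
            sl = slice(s0, min(s0 + chunk, M))
            coords = lo_all[sl, None, :] + offs[None, :, :]  # (c, n_off, D)
            valid = np.all(offs[None, :, :] < widths[sl, None, :], axis=2)
            rel = coords - p0[sl, None, :]
            lam = np.einsum("mij,mnj->mni", Ainv[sl], rel)
            lam0 = 1.0 - lam.sum(axis=2)
            ok = valid & (lam0 >= -_BARY_TOL) & np.all(lam >= -_BARY_TOL, axis=2)
            mi, ni = np.nonzero(ok)
            if mi.size == 0:
                continue
            vox = (coords[mi, ni] * strides).sum(axis=1)
            assigned[vox[::-1]] = np.minimum(assigned[vox[::-1]], mi[::-1] + s0)
    else:
        for m in range(M):
            inside = np.all(
                (points >= lo_all[m] - 1e-9) & (points <= hi_all[m] + 1e-9), axis=1
            )
            cand = np.nonzero(inside & (assigned > m))[0]
            if cand.size == 0:
                continue
            rel = points[cand] - p0[m]
            lam = rel @ Ainv[m].T
            lam0 = 1.0 - lam.sum(axis=1)
            ok = (lam0 >= -_BARY_TOL) & np.all(lam >= -_BARY_TOL, axis=1)
            assigned[cand[ok]] = m

    covered = np.nonzero(assigned < M)[0]
    win = assigned[covered]
    rel = points[covered] - p0[win]
    lam = np.einsum("nij,nj->ni", Ainv[win], rel)
    weights = np.concatenate([1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1)
    return win, weights, covered


class MembershipCache:
    """Warm-started point-location for repeated membership queries.

    Mesh optimizers evaluate the objective at a sequence of nearby
    configurations; almost every voxel then stays in its previous simplex or
    moves to one sharing a node with it.  The cache verifies the previous
    assignment in one vectorized pass, repairs failures via node-sharing
    neighbor simplices, and falls back to a full search for the remainder.
    Results agree with :func:`barycentric_membership` up to the choice of
    simplex for points lying exactly on shared faces (where barycentric
    interpolation is continuous, so interpolated fields are unaffected).
    """

    def __init__(self, atlas: SimplexAtlas):
        self.atlas = atlas
        self._last = None  # (n_pts,) simplex per grid voxel, M = uncovered
        M, D = atlas.n_simplices, atlas.ndim
        node_to_simp = [[] for _ in range(atlas.n_nodes)]
        for m, simp in enumerate(atlas.simplices):
            for node in simp:
                node_to_simp[node].append(m)
        nb = [
            sorted({s for node in simp for s in node_to_simp[node]})
            for simp in atlas.simplices
        ]
        nbmax = max(len(b) for b in nb)
        self._neighbors = np.full((M, nbmax), M, dtype=np.int64)
        for m, b in enumerate(nb):
            self._neighbors[m, : len(b)] = b
        self._points = _voxel_centers(atlas.grid_shape)

    def query(self, x):
        """Return ``(simplex_index, bary_weights, point_index)`` for all
        covered grid voxels, like :func:`barycentric_membership`."""
        atlas = self.atlas
        x = atlas.check_positions(x)
        M, D = atlas.n_simplices, atlas.ndim
        vols = signed_volumes(x, atlas.simplices)
        if np.any(vols <= 0):
            raise FoldedMeshError("cannot rasterize a folded mesh")
        if self._last is None:
            simp, w, vox = barycentric_membership(x, atlas)
            self._store(simp, vox)
            return simp, w, vox

        points = self._points
        n_pts = points.shape[0]
        A, verts = _edge_matrices(x, atlas.simplices)
        Ainv = np.linalg.inv(A)
        p0 = verts[:, 0, :]

        assigned = np.full(n_pts, M, dtype=np.int64)
        # pass 1: verify cached simplex
        cached = self._last
        has = cached < M
        idx = np.nonzero(has)[0]
        cm = cached[idx]
        lam = np.einsum("nij,nj->ni", Ainv[cm], points[idx] - p0[cm])
        ok = (1.0 - lam.sum(axis=1) >= -_BARY_TOL) & np.all(
            lam >= -_BARY_TOL, axis=1
        )
        assigned[idx[ok]] = cm[ok]

        # pass 2: neighbors of the cached simplex
        todo = np.nonzero(assigned == M)[0]
        if todo.size:
            prev = np.where(cached[todo] < M, cached[todo], 0)
            cand = self._neighbors[prev]  # (n_todo, nbmax), padded with M
            real = cand < M
            cand_safe = np.where(real, cand, 0)
            rel = points[todo, None, :] - p0[cand_safe]
            lam = np.einsum("nkij,nkj->nki", Ainv[cand_safe], rel)
            good = (
                real
                & (1.0 - lam.sum(axis=2) >= -_BARY_TOL)
                & np.all(lam >= -_BARY_TOL, axis=2)
            )
            found = good.any(axis=1)
            first = np.argmax(good, axis=1)
            assigned[todo[found]] = cand_safe[found, first[found]]
            todo = todo[~found]

        # pass 3: full search for the stragglers
        if todo.size:
            simp_t, _, rows = barycentric_membership(
                x, atlas, points=points[todo]
            )
            assigned[todo[rows]] = simp_t

        covered = np.nonzero(assigned < M)[0]
        win = assigned[covered]
        lam = np.einsum("nij,nj->ni", Ainv[win], points[covered] - p0[win])
        weights = np.concatenate(
            [1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1
        )
        self._store(win, covered)
        return win, weights, covered

    def _store(self, simp, vox):
        last = np.full(self._points.shape[0], self.atlas.n_simplices,
                       dtype=np.int64)
        last[vox] = simp
        self._last = last


def rasterize_label_prior(x, atlas: SimplexAtlas) -> LabelPriorField:
    """Barycentric interpolation of node label probabilities onto voxel
    centers inside the deformed mesh.

    Voxels outside every simplex are excluded from the field.
    """
    simp_idx, w, vox_idx = barycentric_membership(x, atlas)
    nodes = atlas.simplices[simp_idx]  # (n, D+1)
    probs = np.einsum("nj,njk->nk", w, atlas.node_label_probs[nodes])
    # clip tiny negatives from boundary-tolerant weights, renormalize
    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=1, keepdims=True)
    return LabelPriorField(probs=probs, voxel_index_map=vox_idx,
                           grid_shape=atlas.grid_shape)


# ---------------------------------------------------------------------------
# toy atlas construction


def _freudenthal_simplices(node_shape):
    """Consistently oriented simplices subdividing a regular node lattice
    (2 triangles per square in 2D, 6 tetrahedra per cube in 3D)."""
    D = len(node_shape)
    idx = np.arange(int(np.prod(node_shape))).reshape(node_shape)
    simplices = []
    if D == 2:
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[:-1, 1:].ravel()
        d = idx[1:, 1:].ravel()
        simplices = np.concatenate(
            [np.stack([a, b, d], axis=1), np.stack([a, d, c], axis=1)]
        )
    else:
        c000 = idx[:-1, :-1, :-1].ravel()
        c100 = idx[1:, :-1, :-1].ravel()
        c010 = idx[:-1, 1:, :-1].ravel()
        c110 = idx[1:, 1:, :-1].ravel()
        c001 = idx[:-1, :-1, 1:].ravel()
        c101 = idx[1:, :-1, 1:].ravel()
        c011 = idx[:-1, 1:, 1:].ravel()
        c111 = idx[1:, 1:, 1:].ravel()
        # Kuhn subdivision along the 6 permutations of the main diagonal
        paths = [
            (c000, c100, c110, c111),
            (c000, c100, c101, c111),
            (c000, c010, c110, c111),
            (c000, c010, c011, c111),
            (c000, c001, c101, c111),
            (c000, c001, c011, c111),
        ]
        simplices = np.concatenate([np.stack(p, axis=1) for p in paths])
    return np.asarray(simplices, dtype=int)


def _orient_simplices(positions, simplices):
    vols = signed_volumes(positions, simplices)
    flip = vols < 0
    simplices = simplices.copy()
    simplices[flip, -2:] = simplices[flip, -2:][:, ::-1]
    return simplices


# defaults giving structures compact prior support: transitions span about
# +/-2 voxels and probabilities below the floor are truncated to zero
TOY_BOUNDARY_SOFTNESS = 1.0
TOY_PROB_FLOOR = 5e-3

_DEFAULT_CLASS_NAMES = {
    2: ["background", "brain"],
    3: ["background", "brain", "ventricle"],
    4: ["background", "gm", "wm", "ventricle"],
    5: ["background", "gm", "wm", "deep_gm", "ventricle"],
}


def concentric_radii(grid_shape, k_classes):
    """Ring boundary radii (inner structure first) for the concentric toy
    anatomy, as fractions of the smallest grid dimension."""
    s = min(grid_shape)
    fracs = {
        2: [0.40],
        3: [0.15, 0.40],
        4: [0.15, 0.30, 0.42],
        5: [0.12, 0.20, 0.32, 0.42],
    }[k_classes]
    return [f * s for f in fracs]


def make_toy_atlas(grid_shape, k_classes=4, stiffness=0.1, node_spacing=6.0,
                   seed=0, boundary_softness=TOY_BOUNDARY_SOFTNESS,
                   prob_floor=TOY_PROB_FLOOR):
    """Construct a concentric toy atlas on the given grid.

    The anatomy is a set of nested quasi-spherical structures around the grid
    center (e.g. background / gray matter / white matter / ventricle), with
    label probabilities transitioning smoothly (logistic profile with scale
    ``boundary_softness`` voxels) across ring boundaries.  Node probabilities
    below ``prob_floor`` are truncated to zero, giving each structure compact
    prior support.  The mesh is a regular simplex lattice extending a 2-voxel
    margin beyond the grid so every voxel center is covered.  Deterministic
    for fixed arguments.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    D = len(grid_shape)
    if D not in (2, 3):
        raise ValueError("grid must be 2D or 3D")
    if k_classes < 2 or k_classes > 5:
        raise ValueError("k_classes must be in 2..5")
    if min(grid_shape) < 2 * node_spacing:
        raise ValueError("grid too small for requested node spacing")

    margin = 2.0
    node_axes = []
    for s in grid_shape:
        n = max(int(np.ceil((s - 1 + 2 * margin) / node_spacing)) + 1, 2)
        node_axes.append(np.linspace(-margin, s - 1 + margin, n))
    node_shape = tuple(len(a) for a in node_axes)
    mesh = np.meshgrid(*node_axes, indexing="ij")
    positions = np.stack([m.ravel() for m in mesh], axis=1)
    simplices = _orient_simplices(positions, _freudenthal_simplices(node_shape))

    center = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    r = np.linalg.norm(positions - center, axis=1)
    radii = concentric_radii(grid_shape, k_classes)

    def sig(z):
        return 1.0 / (1.0 + np.exp(-z / boundary_softness))

    # cumulative "inside boundary b" probabilities, innermost boundary first
    cums = [sig(rb - r) for rb in radii]
    probs = np.zeros((positions.shape[0], k_classes))
    # innermost structure is the last class (matches _DEFAULT_CLASS_NAMES)
    inner_to_outer = list(range(k_classes - 1, 0, -1))
    prev = np.zeros_like(r)
    for cls, cum in zip(inner_to_outer, cums):
        probs[:, cls] = np.clip(cum - prev, 0.0, 1.0)
        prev = cum
    probs[:, 0] = np.clip(1.0 - prev, 0.0, 1.0)
    probs[probs < prob_floor] = 0.0
    probs /= probs.sum(axis=1, keepdims=True)

    return SimplexAtlas(
        ref_positions=positions,
        simplices=simplices,
        node_label_probs=probs,
        stiffness=float(stiffness),
        grid_shape=grid_shape,
        class_names=list(_DEFAULT_CLASS_NAMES[k_classes]),
    )


# ---------------------------------------------------------------------------
# serialization

ATLAS_FORMAT_VERSION = "1"


def save_atlas(path, atlas: SimplexAtlas):
    """Write an atlas archive (NPZ with documented keys)."""
    np.savez_compressed(
        path,
        version=np.array(ATLAS_FORMAT_VERSION),
        ref_positions=atlas.ref_positions,
        simplices=atlas.simplices,
        node_label_probs=atlas.node_label_probs,
        stiffness=np.array(atlas.stiffness),
        grid_shape=np.array(atlas.grid_shape),
        class_names=np.array(atlas.class_names),
    )


def load_atlas(path) -> SimplexAtlas:
    with np.load(path, allow_pickle=False) as z:
        if str(z["version"]) != ATLAS_FORMAT_VERSION:
            raise ValueError(f"unsupported atlas version {z['version']}")
        return SimplexAtlas(
            ref_positions=z["ref_positions"],
            simplices=z["simplices"],
            node_label_probs=z["node_label_probs"],
            stiffness=float(z["stiffness"]),
            grid_shape=tuple(int(s) for s in z["grid_shape"]),
            class_names=[str(c) for c in z["class_names"]],
        )
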