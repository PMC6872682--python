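"""Rigid mesh superimposition: Kabsch solver, trimmed ICP, and the RMSD
surface-distance quality metric.

The registration quality metric used throughout is the root-mean-squared
distance (RMSD): the square root of the mean squared distance from points
of one surface to the closest point on the other surface. Closest points
are true point-to-triangle feet, not nearest vertices, so the metric is
independent of the tessellation of either surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import MeshError, TriangleMesh, face_areas

__all__ = [
    "RigidTransform",
    "IcpParams",
    "RegistrationResult",
    "DegenerateGeometryError",
    "kabsch",
    "icp_register",
    "surface_rmsd",
    "closest_point_on_mesh",
    "MeshProximity",
    "sample_surface_points",
    "principal_axes_prealign",
]


class DegenerateGeometryError(ValueError):
    """Point configuration too degenerate for a rigid fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(self.rotation, dtype=np.float64)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation has det != +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, float))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Rotation angle of R (degrees), from its trace."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_json(self) -> str:
        return json.dumps({"matrix": self.to_matrix().tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(json.loads(text)["matrix"])


@dataclass(frozen=True)
class IcpParams:
    """Tuning knobs of the trimmed ICP variant.

    trim_fraction discards the worst correspondences each iteration,
    which makes partial-overlap superimpositions (crown-only reference
    areas, two-stage scans) robust to points without a true counterpart.
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-6  # mm change in RMSD between iterations
    trim_fraction: float = 0.1
    correspondence_mode: str = "vertex_to_surface"  # or "vertex_to_vertex"
    sample_count: int = 2000
    seed: int = 0  # for the area-weighted sampling of the moving surface

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if not 0.0 <= self.trim_fraction <= 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5]")
        if self.correspondence_mode not in ("vertex_to_surface", "vertex_to_vertex"):
            raise ValueError(f"unknown correspondence_mode {self.correspondence_mode!r}")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rmsd: float  # mm, over the retained correspondence set
    iterations: int
    converged: bool
    n_correspondences: int
    rmsd_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# closest point on a triangle mesh


def _closest_point_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point on triangle (a,b,c) to p, pairwise over leading axis.

    Vectorised region classification (vertex / edge / interior cases).
    """
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        if m.any():
            out[m] = value[m] if value.ndim == 2 else value
            done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    den_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))  # edge BC

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    interior = a + v[:, None] * ab + w[:, None] * ac
    out[~done] = interior[~done]
    return out


class MeshProximity:
    """Exact closest-point queries against a triangle mesh.

    A KD-tree on triangle centroids prunes the search: the best distance
    among the k nearest centroids' triangles bounds the answer, and any
    triangle whose centroid is farther than that bound plus its own
    circumscribing radius cannot win. The surviving candidates are
    checked exactly, so results agree with brute force to machine
    precision.
    """

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise MeshError("proximity query against an empty mesh")
        self.mesh = mesh
        self.tri = mesh.triangles()
        self.centroids = self.tri.mean(axis=1)
        self.radii = np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self.max_radius = float(self.radii.max())
        self.tree = cKDTree(self.centroids)

    def _exact_over(self, points, face_idx):
        t = self.tri[face_idx]
        return _closest_point_on_triangles(points, t[:, 0], t[:, 1], t[:, 2])

    def query(self, points: np.ndarray, k_seed: int = 8):
        """Return (closest_points, distances, face_indices) for each query."""
        points = np.atleast_2d(np.asarray(points, float))
        n, m = len(points), len(self.centroids)
        k = min(k_seed, m)
        _, seed_idx = self.tree.query(points, k=k)
        seed_idx = seed_idx.reshape(n, k)
        flat_pts = np.repeat(points, k, axis=0)
        cand = self._exact_over(flat_pts, seed_idx.ravel())
        d = np.linalg.norm(cand - flat_pts, axis=1).reshape(n, k)
        best = d.argmin(axis=1)
        best_d = d[np.arange(n), best]
        best_face = seed_idx[np.arange(n), best]
        best_pt = cand.reshape(n, k, 3)[np.arange(n), best]

        # second pass over every triangle that could still beat the bound
        balls = self.tree.query_ball_point(points, best_d + self.max_radius)
        counts = np.fromiter((len(b) for b in balls), dtype=np.int64, count=n)
        if counts.sum():
            flat_faces = np.concatenate([np.asarray(b, dtype=np.int64) for b in balls])
            flat_pidx = np.repeat(np.arange(n), counts)
            # drop faces already evaluated in the seed pass
            seeded = np.zeros((n, m), dtype=bool) if m * n <= 4_000_000 else None
            if seeded is not None:
                seeded[np.repeat(np.arange(n), k), seed_idx.ravel()] = True
                fresh = ~seeded[flat_pidx, flat_faces]
            else:
                fresh = ~(seed_idx[flat_pidx] == flat_faces[:, None]).any(axis=1)
            flat_faces, flat_pidx = flat_faces[fresh], flat_pidx[fresh]
            # prune with per-face radii before exact evaluation
            cd = np.linalg.norm(self.centroids[flat_faces] - points[flat_pidx], axis=1)
            keep = cd - self.radii[flat_faces] < best_d[flat_pidx]
            flat_faces, flat_pidx = flat_faces[keep], flat_pidx[keep]
            if len(flat_faces):
                cc = self._exact_over(points[flat_pidx], flat_faces)
                dd = np.linalg.norm(cc - points[flat_pidx], axis=1)
                order = np.lexsort((dd, flat_pidx))
                flat_pidx, flat_faces = flat_pidx[order], flat_faces[order]
                dd, cc = dd[order], cc[order]
                first = np.unique(flat_pidx, return_index=True)[1]
                win_p = flat_pidx[first]
                better = dd[first] < best_d[win_p]
                win_p = win_p[better]
                best_d[win_p] = dd[first][better]
                best_pt[win_p] = cc[first][better]
                best_face[win_p] = flat_faces[first][better]
        return best_pt, best_d, best_face

    def query_brute_force(self, points: np.ndarray):
        """Reference O(n_points * n_faces) query, for verification."""
        points = np.atleast_2d(np.asarray(points, float))
        n, m = len(points), len(self.tri)
        flat_pts = np.repeat(points, m, axis=0)
        faces = np.tile(np.arange(m), n)
        cand = self._exact_over(flat_pts, faces)
        d = np.linalg.norm(cand - flat_pts, axis=1).reshape(n, m)
        best = d.argmin(axis=1)
        idx = np.arange(n)
        return cand.reshape(n, m, 3)[idx, best], d[idx, best], best


def closest_point_on_mesh(point, mesh: TriangleMesh):
    """Exact closest point on the mesh surface: (point, distance mm, face index)."""
    prox = MeshProximity(mesh)
    pts, d, fi = prox.query(np.asarray(point, float).reshape(1, 3))
    return pts[0], float(d[0]), int(fi[0])


# ---------------------------------------------------------------------------
# Kabsch and ICP


def _twist_between(T_new: RigidTransform, T_old: RigidTransform, centre: np.ndarray) -> np.ndarray:
    """6-vector (rotation vector, translation at ``centre``) of T_new ∘ T_old⁻¹."""
    from scipy.spatial.transform import Rotation

    D = T_new.compose(T_old.inverse())
    rv = Rotation.from_matrix(D.rotation).as_rotvec()
    return np.concatenate([rv, D.apply(centre) - centre])


def _apply_twist(twist: np.ndarray, scale: float, T: RigidTransform, centre: np.ndarray) -> RigidTransform:
    """Compose ``exp(scale * twist)`` (about ``centre``) onto ``T``."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(twist[:3] * scale).as_matrix()
    t = centre + scale * twist[3:] - R @ centre
    return RigidTransform(R, t).compose(T)


def kabsch(moving_points: np.ndarray, fixed_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping corresponded moving -> fixed.

    SVD (Kabsch) solution with the reflection excluded by sign-correcting
    the smallest singular value.
    """
    m = np.asarray(moving_points, float)
    f = np.asarray(fixed_points, float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if len(m) < 3:
        raise DegenerateGeometryError("need at least 3 corresponded points")
    mu_m, mu_f = m.mean(axis=0), f.mean(axis=0)
    mc, fc = m - mu_m, f - mu_f
    # collinearity check on the moving set
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise DegenerateGeometryError("moving points are (near-)collinear")
    H = mc.T @ fc  # sum of outer products moving x fixed
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_f - R @ mu_m
    return RigidTransform(R, t)


def sample_surface_points(mesh: TriangleMesh, n: int, seed: int = 0) -> np.ndarray:
    """Area-weighted random points on the mesh surface, deterministic per seed."""
    areas = face_areas(mesh)
    total = areas.sum()
    if total <= 0:
        raise MeshError("mesh has zero surface area")
    rng = np.random.default_rng(seed)
    fi = rng.choice(len(areas), size=n, p=areas / total)
    tri = mesh.triangles()[fi]
    r1 = np.sqrt(rng.random(n))[:, None]
    r2 = rng.random(n)[:, None]
    return (1 - r1) * tri[:, 0] + r1 * (1 - r2) * tri[:, 1] + r1 * r2 * tri[:, 2]


def principal_axes_prealign(moving: TriangleMesh, fixed: TriangleMesh) -> RigidTransform:
    """Centroid + principal-axes initial alignment.

    The sign ambiguity of the eigenvectors is resolved by trying the four
    proper-rotation sign combinations and keeping the one with the lowest
    vertex RMSD to the fixed surface.
    """
    prox = MeshProximity(fixed)

    def axes(mesh):
        v = mesh.vertices - mesh.vertices.mean(axis=0)
        _, _, Vt = np.linalg.svd(v, full_matrices=False)
        E = Vt.T
        if np.linalg.det(E) < 0:
            E[:, 2] = -E[:, 2]
        return E

    Em, Ef = axes(moving), axes(fixed)
    mu_m = moving.vertices.mean(axis=0)
    mu_f = fixed.vertices.mean(axis=0)
    probe = moving.vertices[:: max(1, moving.n_vertices // 400)]
    best, best_cost = None, np.inf
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = Ef @ np.diag(signs) @ Em.T
        T = RigidTransform(R, mu_f - R @ mu_m)
        _, d, _ = prox.query(T.apply(probe))
        cost = float(np.sqrt(np.mean(d**2)))
        if cost < best_cost:
            best, best_cost = T, cost
    return best


def icp_register(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    init: RigidTransform | None = None,
    params: IcpParams | None = None,
) -> RegistrationResult:
    """Trimmed iterative-closest-point rigid registration of two meshes.

    Each iteration: transform an area-weighted sample of the moving
    surface, find exact closest points on the fixed surface, discard the
    worst ``trim_fraction`` of correspondences, and re-solve the rigid
    fit in closed form. Iteration stops when the retained-set RMSD
    changes by less than ``convergence_tol`` or ``max_iterations`` is
    reached. The reported RMSD is over the retained set under the final
    transform; a large value on disjoint inputs is the caller's signal
    that the surfaces do not actually overlap.
    """
    params = params or IcpParams()
    init = init or RigidTransform.identity()
    if moving.n_faces == 0 or fixed.n_faces == 0:
        raise MeshError("icp_register requires two non-empty meshes")

    if params.correspondence_mode == "vertex_to_vertex":
        samples = moving.vertices
        if len(samples) > params.sample_count:
            step = len(samples) / params.sample_count
            samples = samples[(np.arange(params.sample_count) * step).astype(int)]
        target_tree = cKDTree(fixed.vertices)
        prox = None
    else:
        n = min(params.sample_count, max(3 * moving.n_faces, 100))
        samples = sample_surface_points(moving, params.sample_count, seed=params.seed)
        prox = MeshProximity(fixed)
        target_tree = None

    n_keep = max(3, int(np.ceil(len(samples) * (1.0 - params.trim_fraction))))
    centre = samples.mean(axis=0)

    def correspond(transform):
        p = transform.apply(samples)
        if prox is not None:
            cp, d, _ = prox.query(p)
        else:
            d, vi = target_tree.query(p)
            cp = fixed.vertices[vi]
        return cp, d

    T = init
    prev_rmsd = np.inf
    prev_delta = None
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        cp, d = correspond(T)
        order = np.argsort(d)[:n_keep]
        rmsd = float(np.sqrt(np.mean(d[order] ** 2)))
        if not np.isfinite(rmsd):
            raise FloatingPointError("non-finite RMSD during ICP")
        history.append(rmsd)
        if abs(prev_rmsd - rmsd) < params.convergence_tol:
            converged = True
            break
        prev_rmsd = rmsd
        T_new = kabsch(samples[order], cp[order])

        # geometric-series extrapolation of the incremental update: the
        # point-to-point inner loop contracts linearly, so when
        # successive updates point the same way, jump ahead by the
        # series sum and keep the jump only if it lowers the RMSD
        delta = _twist_between(T_new, T, centre)
        if prev_delta is not None:
            norm_now, norm_prev = np.linalg.norm(delta), np.linalg.norm(prev_delta)
            if 0 < norm_now < norm_prev:
                cos = float(delta @ prev_delta) / (norm_now * norm_prev)
                ratio = norm_now / norm_prev
                if cos > 0.9 and ratio < 0.999:
                    boost = min(ratio / (1.0 - ratio), 25.0)
                    T_acc = _apply_twist(delta, boost, T_new, centre)
                    _, d_acc = correspond(T_acc)
                    acc_order = np.argsort(d_acc)[:n_keep]
                    if float(np.sqrt(np.mean(d_acc[acc_order] ** 2))) < rmsd:
                        T_new = T_acc
                        delta = _twist_between(T_new, T, centre)
        prev_delta = delta
        T = T_new

    # final RMSD under the final transform, retained set only
    p = T.apply(samples)
    if prox is not None:
        _, d, _ = prox.query(p)
    else:
        d, _ = target_tree.query(p)
    order = np.argsort(d)[:n_keep]
    final_rmsd = float(np.sqrt(np.mean(d[order] ** 2)))
    return RegistrationResult(
        transform=T,
        rmsd=final_rmsd,
        iterations=iterations,
        converged=converged,
        n_correspondences=n_keep,
        rmsd_history=history,
    )


def surface_rmsd(source, target: TriangleMesh, sample_count: int | None = None, seed: int = 0) -> float:
    """RMSD (mm) from source points to their closest points on the target surface.

    ``source`` may be a point array or a mesh (its vertices are used, or
    an area-weighted surface sample when ``sample_count`` is given). The
    measure is asymmetric: distances run source -> target only.
    """
    if isinstance(source, TriangleMesh):
        if source.n_vertices == 0:
            raise MeshError("empty source")
        pts = (
            sample_surface_points(source, sample_count, seed=seed)
            if sample_count
            else source.vertices
        )
    else:
        pts = np.atleast_2d(np.asarray(source, float))
        if len(pts) == 0:
            raise MeshError("empty source point set")
    prox = MeshProximity(target)
    _, d, _ = prox.query(pts)
    return float(np.sqrt(np.mean(d**2)))
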