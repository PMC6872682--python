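"""Root long-axis estimation and inter-axis angles.

A tooth root's long axis is estimated by distributing a fixed number of
points (50 by default) evenly over the root surface and fitting the
total-least-squares line through them: the line through the centroid
along the principal eigenvector of the centred covariance. Root
inclination is directionless, so axes are sign-ambiguous and all angle
arithmetic uses absolute dot products, giving angles in [0, 90] degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import MeshError, TriangleMesh
from .registration import sample_surface_points

__all__ = [
    "AxisLine",
    "sample_root_surface",
    "fit_axis",
    "angle_between_axes",
]


@dataclass(frozen=True)
class AxisLine:
    """A line: centroid (mm) plus a sign-ambiguous unit direction."""

    centroid: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, float).reshape(3)
        d = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "centroid", c)
        object.__setattr__(self, "direction", d)

    def to_dict(self) -> dict:
        return {"centroid": self.centroid.tolist(), "direction": self.direction.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AxisLine":
        return cls(np.asarray(d["centroid"]), np.asarray(d["direction"]))

    def transformed(self, transform) -> "AxisLine":
        return AxisLine(
            transform.apply(self.centroid),
            transform.rotation @ self.direction,
        )


def sample_root_surface(
    root: TriangleMesh,
    n: int = 50,
    seed: int = 0,
    oversample: int = 25,
    method: str = "spiral",
) -> np.ndarray:
    """Spatially even points on the root surface, deterministic per seed.

    The default ``'spiral'`` method builds a structured net: the surface
    is split into ``n`` equal-area strata along its principal axis and
    one point is placed per stratum at golden-angle azimuths, with
    consecutive strata taking antipodal azimuths so that first-order
    azimuthal moments cancel. The net is fully deterministic (the seed
    is ignored) and keeps the moment error of a 50-point sample far
    below the per-point spacing, which a random even sample cannot do.

    ``method='farthest_point'`` draws an area-weighted random oversample
    (``oversample * n`` candidates) and thins it by greedy
    farthest-point subsampling; ``method='random'`` is a pure
    area-weighted sample. Both are seed-deterministic and exist for
    sensitivity analysis.
    """
    if root.n_faces == 0:
        raise MeshError("cannot sample an empty root mesh")
    if method == "spiral":
        return _spiral_net_sample(root, n)
    if method == "random":
        return sample_surface_points(root, n, seed=seed)
    if method != "farthest_point":
        raise ValueError(f"unknown sampling method {method!r}")
    candidates = sample_surface_points(root, n * oversample, seed=seed)
    return _farthest_point_subsample(candidates, n)


def _spiral_net_sample(mesh: TriangleMesh, n: int) -> np.ndarray:
    """Deterministic antipodally paired golden-angle net on the surface.

    Strata are equal-area along the principal axis (area-weighted
    quantiles of face-centroid heights); each stratum's point is the
    exact closest surface point to a probe placed just outside the local
    surface radius at the stratum height and target azimuth, so every
    sample lies on a triangle of the mesh.
    """
    from .registration import MeshProximity  # deferred: avoids import cycle

    from .mesh import face_areas

    v = mesh.vertices
    c = v.mean(axis=0)
    _, _, Vt = np.linalg.svd(v - c, full_matrices=False)
    u = Vt[0]
    if u[int(np.argmax(np.abs(u)))] < 0:
        u = -u
    e1 = np.cross(u, [1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.cross(u, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    areas = face_areas(mesh)
    t_faces = (mesh.triangles().mean(axis=1) - c) @ u
    order = np.argsort(t_faces)
    cum = np.cumsum(areas[order])
    cum /= cum[-1]
    q = (np.arange(n) + 0.5) / n
    t_k = t_faces[order[np.searchsorted(cum, q)]]

    golden = np.pi * (3.0 - np.sqrt(5.0))
    psi = np.empty(n)
    base = (np.arange((n + 1) // 2) * golden) % (2.0 * np.pi)
    psi[0::2] = base
    psi[1::2] = (base[: n // 2] + np.pi) % (2.0 * np.pi)

    t_v = (v - c) @ u
    r_v = np.linalg.norm((v - c) - np.outer(t_v, u), axis=1)
    window = max((t_v.max() - t_v.min()) / n, 0.5)
    r_loc = np.empty(n)
    for k in range(n):
        sel = np.abs(t_v - t_k[k]) <= window
        r_loc[k] = r_v[sel].max() if sel.any() else r_v.max()
    probes = (
        c
        + np.outer(t_k, u)
        + (r_loc + 0.5)[:, None] * (np.outer(np.cos(psi), e1) + np.outer(np.sin(psi), e2))
    )
    pts, _, _ = MeshProximity(mesh).query(probes)
    return pts


def _farthest_point_subsample(points: np.ndarray, n: int) -> np.ndarray:
    """Greedy farthest-point thinning; starts at the point farthest from the centroid."""
    if len(points) <= n:
        return points.copy()
    start = int(np.argmax(np.linalg.norm(points - points.mean(axis=0), axis=1)))
    chosen = np.empty(n, dtype=np.int64)
    chosen[0] = start
    dmin = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, n):
        nxt = int(np.argmax(dmin))
        chosen[i] = nxt
        dmin = np.minimum(dmin, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen]


def fit_axis(points: np.ndarray) -> AxisLine:
    """Total-least-squares line through a 3D point cloud.

    The direction is the principal eigenvector of the centred covariance
    (the direction minimising the sum of squared orthogonal distances);
    the sign is normalised so the component of largest magnitude is
    positive, which is canonical but semantically irrelevant.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] <= 1e-24:
        raise ValueError("all points coincident: axis undefined")
    if evals[-1] - evals[-2] <= 1e-9 * max(evals[-1], 1.0):
        warnings.warn(
            "point cloud is nearly isotropic in its top two principal "
            "directions; fitted axis is ambiguous",
            stacklevel=2,
        )
    direction = evecs[:, -1]
    k = int(np.argmax(np.abs(direction)))
    if direction[k] < 0:
        direction = -direction
    return AxisLine(centroid, direction)


def angle_between_axes(a: AxisLine, b: AxisLine) -> float:
    """Angle between two undirected axes, degrees in [0, 90].

    Flip-invariant and symmetric; the dot product is clamped to [-1, 1]
    before arccos for floating-point safety at near-parallel axes.
    """
    c = abs(float(np.dot(a.direction, b.direction)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
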