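"""Synthetic dental study generator.

Builds labeled anterior-tooth surface meshes (crown, cervical band,
tapered root ending in an apex), two-stage partial scans with scanner
noise and arbitrary poses, crowns-only digital casts, and "predicted"
teeth whose roots have been rotated about the cervical region by a known
angle. Because the ground-truth root axes and the injected angulation
errors are known exactly, every stage of the measurement pipeline can be
validated without physical specimens.

Tooth frame convention: z is the occluso-apical axis (apex at z=0,
incisal edge at the top), x is mesio-distal, y is labio-lingual with the
labial side at +y. Units are millimetres throughout.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .axis import AxisLine
from .mesh import Region, TriangleMesh, concatenate, write_mesh
from .registration import RigidTransform

__all__ = [
    "ToothType",
    "Jaw",
    "Side",
    "ToothParams",
    "ScanParams",
    "PredictionParams",
    "GroundTruth",
    "StudyBundle",
    "generate_tooth",
    "simulate_partial_scan",
    "simulate_prediction",
    "generate_cast",
    "generate_study",
    "composed_rotation_angle_deg",
]


class ToothType(enum.IntEnum):
    CENTRAL_INCISOR = 1
    LATERAL_INCISOR = 2
    CANINE = 3


class Jaw(enum.IntEnum):
    MAXILLA = 1
    MANDIBLE = 2


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


# typical permanent anterior tooth dimensions (mm): crown height, root
# length, crown (mesio-distal) width — textbook averages; the study the
# generator emulates reports no specimen morphometry, so these are the
# package's own defaults.
_DIMENSIONS = {
    (Jaw.MAXILLA, ToothType.CENTRAL_INCISOR): (10.5, 13.0, 8.5),
    (Jaw.MAXILLA, ToothType.LATERAL_INCISOR): (9.0, 13.0, 6.5),
    (Jaw.MAXILLA, ToothType.CANINE): (10.0, 17.0, 7.5),
    (Jaw.MANDIBLE, ToothType.CENTRAL_INCISOR): (9.0, 12.5, 5.3),
    (Jaw.MANDIBLE, ToothType.LATERAL_INCISOR): (9.5, 14.0, 5.9),
    (Jaw.MANDIBLE, ToothType.CANINE): (11.0, 16.0, 6.9),
}

# labio-lingual/mesio-distal cross-section aspect per tooth type
_ASPECT = {
    ToothType.CENTRAL_INCISOR: 0.80,
    ToothType.LATERAL_INCISOR: 0.85,
    ToothType.CANINE: 0.95,
}


@dataclass(frozen=True)
class ToothParams:
    tooth_type: ToothType = ToothType.CENTRAL_INCISOR
    jaw: Jaw = Jaw.MANDIBLE
    side: Side = Side.RIGHT
    crown_height: float = 9.0
    root_length: float = 12.5
    crown_width: float = 5.3
    root_taper: float = 0.8  # fraction of cervical radius lost toward the apex
    root_curvature_deg: float = 0.0
    mesh_resolution: int = 1  # ring/segment subdivision level

    def __post_init__(self) -> None:
        if min(self.crown_height, self.root_length, self.crown_width) <= 0:
            raise ValueError("tooth dimensions must be positive")
        if not 0.0 < self.root_taper <= 1.0:
            raise ValueError("root_taper must be in (0, 1]")

    @classmethod
    def for_type(cls, tooth_type: ToothType, jaw: Jaw, side: Side = Side.RIGHT, **kw) -> "ToothParams":
        ch, rl, cw = _DIMENSIONS[(Jaw(jaw), ToothType(tooth_type))]
        return cls(
            tooth_type=ToothType(tooth_type),
            jaw=Jaw(jaw),
            side=Side(side),
            crown_height=ch,
            root_length=rl,
            crown_width=cw,
            **kw,
        )


@dataclass(frozen=True)
class ScanParams:
    """Two-stage surface-scan emulation parameters."""

    noise_sd: float = 0.01  # mm, Gaussian along vertex normals
    clip_fraction: float = 0.75  # fraction of tooth height each stage retains
    pose_rotation_max_deg: float = 10.0
    pose_translation_max_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.clip_fraction < 1.0:
            raise ValueError("clip_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PredictionParams:
    """Known root-angulation error injected into a predicted tooth."""

    tip_deg: float = 0.0  # rotation moving the apex mesio-distally (about y)
    torque_deg: float = 0.0  # rotation moving the apex labio-lingually (about x)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tip_deg) and np.isfinite(self.torque_deg)):
            raise ValueError("tip/torque must be finite")


@dataclass
class GroundTruth:
    """Per-tooth oracle: true axis, injected discrepancy, applied transforms."""

    true_axis: AxisLine
    injected_angle_deg: float
    transforms: list[RigidTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.injected_angle_deg <= 90.0:
            raise ValueError("injected angle must lie in [0, 90] degrees")


def _rotation_xy(tip_deg: float, torque_deg: float) -> np.ndarray:
    """Composed root-rotation: torque about x applied after tip about y."""
    ty, tx = np.deg2rad(tip_deg), np.deg2rad(torque_deg)
    Ry = np.array(
        [[np.cos(ty), 0, np.sin(ty)], [0, 1, 0], [-np.sin(ty), 0, np.cos(ty)]]
    )
    Rx = np.array(
        [[1, 0, 0], [0, np.cos(tx), -np.sin(tx)], [0, np.sin(tx), np.cos(tx)]]
    )
    return Rx @ Ry


def composed_rotation_angle_deg(tip_deg: float, torque_deg: float) -> float:
    """Rotation angle (degrees) of the composed tip/torque rotation, from its trace."""
    R = _rotation_xy(tip_deg, torque_deg)
    return float(np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# tooth construction


def generate_tooth(params: ToothParams, seed: int = 0) -> tuple[TriangleMesh, AxisLine]:
    """Generate a watertight labeled tooth mesh and its true root axis.

    The root is a tapered (optionally curved) cone of elliptical
    cross-section ending in an apex vertex; the crown is a bulged cap
    that flattens labio-lingually toward the incisal edge for incisors
    and narrows to a cusp for canines. A slight labial bulge breaks the
    180-degree rotational symmetry of the elliptical cross-section so
    that crown-based registration has a unique optimum. The true root
    axis is the construction axis (+z) through the root centroid,
    evaluated before any curvature perturbation. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    res = max(0, int(params.mesh_resolution))
    n_theta = 20 * 2**res
    n_root = 12 * 2**res  # root rings, apex side to cervix
    n_crown = 8 * 2**res

    Lr, Lc = params.root_length, params.crown_height
    rx_cervix = params.crown_width / 2.0
    aspect = _ASPECT[params.tooth_type]
    pointed = params.tooth_type == ToothType.CANINE

    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # azimuthal cross-section asymmetry (egg shape + developmental
    # grooves): constant along the tooth so the axis is unbiased, but it
    # removes the rotational near-symmetry an ellipse would have
    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, 2)
    profile = 1.0 + 0.05 * np.cos(theta - phase1) + 0.045 * np.cos(2.0 * theta - phase2)

    rings = []  # (z, rx, ry, y_offset, label)
    # root: u runs 1/n_root .. 1 (cervix); linear taper toward the apex
    for i in range(1, n_root + 1):
        u = i / n_root
        r = rx_cervix * ((1.0 - params.root_taper) + params.root_taper * u)
        rings.append((Lr * u, r, r * aspect, 0.0, Region.ROOT))
    rings[-1] = rings[-1][:4] + (Region.CERVICAL,)
    # crown: v runs over (0, 1]; bulge + incisal shaping + labial offset
    for i in range(1, n_crown + 1):
        v = i / n_crown
        bulge = 1.0 + 0.25 * np.sin(np.pi * v)
        if pointed:
            shrink = 1.0 - 0.85 * v**1.6
            rx = rx_cervix * bulge * shrink
            ry = rx * aspect
        else:
            rx = rx_cervix * bulge * (1.0 - 0.35 * v**2)
            ry = rx_cervix * aspect * bulge * (1.0 - 0.8 * v**1.5)
        y_off = 0.15 * rx_cervix * np.sin(np.pi * v)
        label = Region.CERVICAL if i == 1 else Region.CROWN
        rings.append((Lr + Lc * v, max(rx, 0.2), max(ry, 0.15), y_off, label))

    verts = [np.array([0.0, 0.0, 0.0])]  # apex
    labels = [int(Region.ROOT)]
    for z, rx, ry, y_off, label in rings:
        jitter = rng.normal(0.0, 0.02, n_theta)
        px = (rx * profile + jitter) * cos_t
        py = (ry * profile + jitter * aspect) * sin_t
        # re-centre: the asymmetric profile must not displace ring
        # centroids with z, or it would tilt the construction axis
        ring = np.column_stack(
            [px - px.mean(), py - py.mean() + y_off, np.full(n_theta, z)]
        )
        verts.append(ring)
        labels.extend([int(label)] * n_theta)
    top_z = Lr + Lc
    verts.append(np.array([0.0, rings[-1][3], top_z]))
    labels.append(int(Region.CROWN))

    vertices = np.vstack([v.reshape(-1, 3) for v in verts])
    labels = np.asarray(labels, dtype=np.uint8)

    faces = []
    n_rings = len(rings)
    ring_start = lambda i: 1 + i * n_theta  # noqa: E731
    # apex fan (outward = downward)
    r0 = ring_start(0)
    for j in range(n_theta):
        faces.append([0, r0 + (j + 1) % n_theta, r0 + j])
    # side quads
    for i in range(n_rings - 1):
        a, b = ring_start(i), ring_start(i + 1)
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            faces.append([a + j, a + j1, b + j1])
            faces.append([a + j, b + j1, b + j])
    # incisal cap
    top = len(vertices) - 1
    rt = ring_start(n_rings - 1)
    for j in range(n_theta):
        faces.append([top, rt + j, rt + (j + 1) % n_theta])

    root_mask = labels == int(Region.ROOT)
    axis = AxisLine(vertices[root_mask].mean(axis=0), np.array([0.0, 0.0, 1.0]))

    if params.root_curvature_deg:
        w = np.clip((Lr - vertices[:, 2]) / Lr, 0.0, None)
        bend = root_mask & (vertices[:, 2] < Lr)
        vertices = vertices.copy()
        vertices[bend, 1] += np.tan(np.deg2rad(params.root_curvature_deg)) * Lr * w[bend] ** 2

    mesh = TriangleMesh(vertices, np.asarray(faces, dtype=np.int64), labels)
    return mesh, axis


# ---------------------------------------------------------------------------
# scans, predictions, casts


def _random_pose(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_rot_deg)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = max_trans_mm * rng.random() ** (1.0 / 3.0)
    return RigidTransform.from_axis_angle(axis, angle, radius * direction)


def simulate_partial_scan(
    tooth: TriangleMesh, stage: str, params: ScanParams
) -> tuple[TriangleMesh, RigidTransform]:
    """One stage of the two-stage scan of a whole extracted tooth.

    ``stage='crown_side'`` keeps the upper ``clip_fraction`` of the tooth
    height (crown and cervical part of the root); ``'root_side'`` keeps
    the lower ``clip_fraction`` (whole root plus part of the crown).
    Gaussian measurement noise is applied along vertex normals, then a
    random rigid pose (bounded rotation/translation) is applied and
    returned. The tooth is expected in its canonical frame (z along the
    construction axis).
    """
    if stage not in ("crown_side", "root_side"):
        raise ValueError(f"unknown scan stage {stage!r}")
    if tooth.labels is None:
        raise ValueError("simulate_partial_scan expects a labeled tooth mesh")
    if params.clip_fraction <= 0.5:
        raise ValueError(
            "clip_fraction <= 0.5 leaves no overlap between the two scan stages"
        )
    z = tooth.vertices[:, 2]
    zmin, zmax = z.min(), z.max()
    height = zmax - zmin
    if stage == "crown_side":
        mask = z >= zmax - params.clip_fraction * height - 1e-12
    else:
        mask = z <= zmin + params.clip_fraction * height + 1e-12
    scan = tooth.submesh_from_vertex_mask(mask)
    if scan.n_faces == 0:
        raise ValueError("clip plane removed the whole surface")

    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0 if stage == "crown_side" else 1])
    )
    if params.noise_sd > 0:
        normals = scan.vertex_normals()
        scan.vertices = scan.vertices + normals * rng.normal(
            0.0, params.noise_sd, len(scan.vertices)
        )[:, None]
    pose = _random_pose(rng, params.pose_rotation_max_deg, params.pose_translation_max_mm)
    return scan.transformed(pose), pose


def simulate_prediction(
    tooth: TriangleMesh, params: PredictionParams
) -> tuple[TriangleMesh, GroundTruth]:
    """Predicted tooth: crown unchanged, root rotated by a known rotation.

    The root vertices are rotated about the cervical-band centroid by the
    composed tip/torque rotation, emulating a crown-based root predictor
    whose crowns are right but whose root direction is wrong. The
    injected discrepancy is the rotation angle of the composed rotation
    (from its trace); the true axis is the principal axis of the root
    region's vertices.
    """
    if tooth.labels is None:
        raise ValueError("simulate_prediction expects a labeled tooth mesh")
    root_mask = tooth.labels == int(Region.ROOT)
    cerv_mask = tooth.labels == int(Region.CERVICAL)
    if not root_mask.any() or not cerv_mask.any():
        raise ValueError("tooth must have root and cervical labels")

    root_pts = tooth.vertices[root_mask]
    centred = root_pts - root_pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    direction = Vt[0] / np.linalg.norm(Vt[0])
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    true_axis = AxisLine(root_pts.mean(axis=0), direction)

    R = _rotation_xy(params.tip_deg, params.torque_deg)
    pivot = tooth.vertices[cerv_mask].mean(axis=0)
    transform = RigidTransform(R, pivot - R @ pivot)

    pred = tooth.copy()
    pred.vertices[root_mask] = transform.apply(pred.vertices[root_mask])
    angle = composed_rotation_angle_deg(params.tip_deg, params.torque_deg)
    return pred, GroundTruth(true_axis, angle, [transform])


def arch_placements(widths: list[float], arch_spacing: float = 1.0) -> list[RigidTransform]:
    """Rigid placements distributing teeth along a circular dental arch.

    Each tooth is rotated about z so its labial (+y) side faces outward
    and translated to its slot on the arch.
    """
    widths = list(widths)
    slots = [w + arch_spacing for w in widths]
    total = sum(slots)
    radius = max(18.0, total / np.pi * 1.2)
    placements = []
    s = 0.0
    for w, slot in zip(widths, slots):
        centre = s + slot / 2.0 - total / 2.0
        phi = centre / radius
        R = np.array(
            [
                [np.cos(-phi), -np.sin(-phi), 0.0],
                [np.sin(-phi), np.cos(-phi), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        pos = np.array([radius * np.sin(phi), radius * np.cos(phi) - radius, 0.0])
        placements.append(RigidTransform(R, pos))
        s += slot
    return placements


def generate_cast(
    teeth: list[TriangleMesh], arch_spacing: float = 1.0
) -> tuple[TriangleMesh, list[RigidTransform]]:
    """Crowns-only digital cast: crown + cervical band of each tooth on an arch.

    Roots are removed (a cast carries no root information); the cervical
    band is kept, emulating a cast on which the cemento-enamel junction
    is visible. Per-vertex tooth ids make each cast crown recoverable.
    Overlapping crown placements produce a warning, not an error.
    """
    if not teeth:
        raise ValueError("need at least one tooth")
    for t in teeth:
        if t.labels is None:
            raise ValueError("cast generation requires labeled teeth")
    widths = [float(np.ptp(t.vertices[:, 0])) for t in teeth]
    placements = arch_placements(widths, arch_spacing)
    parts = []
    for k, (tooth, place) in enumerate(zip(teeth, placements)):
        keep = (tooth.labels == int(Region.CROWN)) | (tooth.labels == int(Region.CERVICAL))
        crown = tooth.submesh_from_vertex_mask(keep)
        crown.tooth_ids = np.full(crown.n_vertices, k, dtype=np.int32)
        parts.append(crown.transformed(place))
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            lo_i, hi_i = parts[i].bounds()
            lo_j, hi_j = parts[j].bounds()
            if np.all(hi_i >= lo_j) and np.all(hi_j >= lo_i):
                warnings.warn(f"cast crowns {i} and {j} overlap", stacklevel=2)
    return concatenate(parts), placements


# ---------------------------------------------------------------------------
# whole-study generation


@dataclass
class StudyTooth:
    """One tooth of a synthetic study, everything in its local frame."""

    tooth_id: int
    params: ToothParams
    mesh: TriangleMesh
    true_axis: AxisLine
    scan_a: TriangleMesh  # crown-side stage, posed
    scan_a_pose: RigidTransform
    scan_b: TriangleMesh  # root-side stage, posed
    scan_b_pose: RigidTransform
    prediction: TriangleMesh
    ground_truth: GroundTruth
    placement: RigidTransform  # local frame -> cast/arch frame
    index_in_jaw: int


@dataclass
class StudyBundle:
    """A complete synthetic study: teeth, scans, casts, predictions, oracle."""

    teeth: list[StudyTooth]
    casts: dict[Jaw, TriangleMesh]
    cast_placements: dict[Jaw, list[RigidTransform]]
    predictions: dict[Jaw, TriangleMesh]  # whole-jaw predicted models, cast frame
    ground_truth: pd.DataFrame
    seed: int
    scan_params: ScanParams

    def write_fixture(self, directory) -> None:
        """Write the bundle as PLY files plus ground_truth.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t in self.teeth:
            write_mesh(t.mesh, directory / f"tooth_{t.tooth_id:02d}_full.ply")
            write_mesh(t.scan_a, directory / f"tooth_{t.tooth_id:02d}_scanA.ply")
            write_mesh(t.scan_b, directory / f"tooth_{t.tooth_id:02d}_scanB.ply")
            write_mesh(t.prediction, directory / f"tooth_{t.tooth_id:02d}_pred.ply")
        for jaw, cast in self.casts.items():
            write_mesh(cast, directory / f"cast_{jaw.name.lower()}.ply")
        for jaw, pred in self.predictions.items():
            write_mesh(pred, directory / f"prediction_{jaw.name.lower()}.ply")
        self.ground_truth.to_csv(directory / "ground_truth.csv", index=False)


# tooth-type composition of the emulated sample: (jaw, type, count, sides)
_SAMPLE_COMPOSITION = [
    (Jaw.MAXILLA, ToothType.CENTRAL_INCISOR, 3),
    (Jaw.MAXILLA, ToothType.LATERAL_INCISOR, 3),
    (Jaw.MAXILLA, ToothType.CANINE, 4),
    (Jaw.MANDIBLE, ToothType.CENTRAL_INCISOR, 14),
    (Jaw.MANDIBLE, ToothType.LATERAL_INCISOR, 13),
    (Jaw.MANDIBLE, ToothType.CANINE, 18),
]


def _allocate_counts(n_teeth: int) -> list[tuple[Jaw, ToothType, int]]:
    """Largest-remainder allocation of n_teeth to the default composition."""
    total = sum(c for _, _, c in _SAMPLE_COMPOSITION)
    raw = [(jaw, tt, n_teeth * c / total) for jaw, tt, c in _SAMPLE_COMPOSITION]
    counts = [int(np.floor(r)) for _, _, r in raw]
    remainder = n_teeth - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for _, _, r in raw])
    for i in range(remainder):
        counts[order[i]] += 1
    return [(jaw, tt, c) for (jaw, tt, _), c in zip(raw, counts)]


def draw_discrepancy_angles(n: int, mean: float, sd: float, rng) -> np.ndarray:
    """Injected discrepancy draw: normal(mean, sd) truncated to [0, 89] deg.

    ``sd=0`` returns ``mean`` for every tooth. ``rng`` may be a Generator
    or an integer seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    b = (89.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _solve_tip_torque(delta_deg: float, azimuth_rad: float) -> tuple[float, float]:
    """Tip/torque whose composed rotation has angle exactly delta_deg."""
    if delta_deg <= 0:
        return 0.0, 0.0
    a0 = delta_deg * np.cos(azimuth_rad)
    b0 = delta_deg * np.sin(azimuth_rad)

    def f(s):
        return composed_rotation_angle_deg(s * a0, s * b0) - delta_deg

    if f(1.0) >= -1e-12:
        return a0, b0
    s = brentq(f, 1.0, 2.0, xtol=1e-12)
    return s * a0, s * b0


def generate_study(
    n_teeth: int = 55,
    discrepancy_mean: float = 9.7,
    discrepancy_sd: float = 7.0,
    scan: ScanParams | None = None,
    seed: int = 0,
    angles=None,
) -> StudyBundle:
    """Generate a full synthetic study with known injected root angulation.

    Tooth types follow the emulated sample's jaw/type composition
    (10 maxillary, 45 mandibular at n=55). Per-tooth injected
    discrepancy angles are drawn from a normal truncated at zero
    (defaults: mean 9.7 deg, SD 7 deg, covering the 2-38 degree range
    the pipeline is meant to resolve) and realised as a tip/torque root
    rotation whose composed rotation angle equals the draw exactly.
    Everything is reproducible from ``seed``. An explicit ``angles``
    array (degrees, one per tooth) overrides the truncated-normal draw,
    e.g. to inject a controlled discrepancy spectrum.
    """
    if n_teeth < 1:
        raise ValueError("n_teeth must be >= 1")
    if discrepancy_sd < 0 or discrepancy_mean < 0:
        raise ValueError("discrepancy distribution parameters must be non-negative")
    scan = scan or ScanParams()
    rng = np.random.default_rng(seed)

    if angles is not None:
        angles = np.asarray(angles, float)
        if angles.shape != (n_teeth,):
            raise ValueError("angles must have one entry per tooth")
        if angles.min() < 0 or angles.max() > 89:
            raise ValueError("explicit angles must lie in [0, 89] degrees")
        draw_consumed = truncnorm.rvs(  # keep the rng stream identical
            -1, 1, size=n_teeth, random_state=rng
        )
        del draw_consumed
    else:
        angles = draw_discrepancy_angles(n_teeth, discrepancy_mean, discrepancy_sd, rng)

    teeth: list[StudyTooth] = []
    rows = []
    tooth_id = 0
    jaws: dict[Jaw, list[StudyTooth]] = {Jaw.MAXILLA: [], Jaw.MANDIBLE: []}
    for jaw, tt, count in _allocate_counts(n_teeth):
        for i in range(count):
            side = Side.RIGHT if i % 2 == 0 else Side.LEFT
            base = ToothParams.for_type(tt, jaw, side)
            size = rng.uniform(0.95, 1.05, size=3)
            params = replace(
                base,
                crown_height=base.crown_height * size[0],
                root_length=base.root_length * size[1],
                crown_width=base.crown_width * size[2],
            )
            tooth_seed = int(rng.integers(0, 2**31 - 1))
            mesh, axis = generate_tooth(params, seed=tooth_seed)

            scan_seed = int(rng.integers(0, 2**31 - 1))
            sp = replace(scan, seed=scan_seed)
            scan_a, pose_a = simulate_partial_scan(mesh, "crown_side", sp)
            scan_b, pose_b = simulate_partial_scan(mesh, "root_side", sp)

            delta = float(angles[tooth_id])
            tip, torque = _solve_tip_torque(delta, rng.uniform(0.0, 2.0 * np.pi))
            pred, gt = simulate_prediction(
                mesh, PredictionParams(tip, torque, seed=tooth_seed)
            )

            entry = StudyTooth(
                tooth_id=tooth_id,
                params=params,
                mesh=mesh,
                true_axis=axis,
                scan_a=scan_a,
                scan_a_pose=pose_a,
                scan_b=scan_b,
                scan_b_pose=pose_b,
                prediction=pred,
                ground_truth=gt,
                placement=RigidTransform.identity(),  # set after cast layout
                index_in_jaw=len(jaws[jaw]),
            )
            teeth.append(entry)
            jaws[jaw].append(entry)
            rows.append(
                {
                    "tooth_id": tooth_id,
                    "tooth_type": int(tt),
                    "jaw": int(jaw),
                    "side": side.value,
                    "injected_angle_deg": gt.injected_angle_deg,
                    "tip_deg": tip,
                    "torque_deg": torque,
                }
            )
            tooth_id += 1

    casts: dict[Jaw, TriangleMesh] = {}
    cast_placements: dict[Jaw, list[RigidTransform]] = {}
    predictions: dict[Jaw, TriangleMesh] = {}
    for jaw, members in jaws.items():
        if not members:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # dense arches may brush neighbours
            cast, placements = generate_cast([t.mesh for t in members])
        casts[jaw] = cast
        cast_placements[jaw] = placements
        parts = []
        for k, t in enumerate(members):
            t.placement = placements[k]
            placed = t.prediction.transformed(placements[k])
            placed.tooth_ids = np.full(placed.n_vertices, k, dtype=np.int32)
            parts.append(placed)
        predictions[jaw] = concatenate(parts)

    return StudyBundle(
        teeth=teeth,
        casts=casts,
        cast_placements=cast_placements,
        predictions=predictions,
        ground_truth=pd.DataFrame(rows),
        seed=seed,
        scan_params=scan,
    )
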