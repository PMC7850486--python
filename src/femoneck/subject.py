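"""Synthetic-subject generator: anatomy, materials, muscles, linkage, gait.

Stands in for the CT/MRI/gait data of a real participant.  The femur is a
constructive solid (tapered shaft tube, neck frustum, head sphere, condylar
lobes, trochanteric bumps) so every morphological parameter of the geometry
protocol is known analytically by construction; the generated mesh carries
this ground truth so downstream measurement stages can be tested for exact
recovery.

Global units: mm, N, MPa, kg, degrees; gravity 9.81 m/s^2.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh import TetMesh, extract_surface, tet_volumes

G = 9.81  # m/s^2

__all__ = [
    "SubjectSpec", "DensityImage", "GaitTrial", "CASE_PRESETS",
    "generate_femur", "generate_density", "generate_gait",
    "generate_linkage_and_muscles", "write_gait_csv", "read_gait",
]


class GeometryInfeasibleError(ValueError):
    """Raised when the prescribed morphology cannot form a valid femur."""


@dataclass(frozen=True)
class SubjectSpec:
    """Prescribed subject: demographics, femur morphology, tissue and gait.

    Morphology defaults are the study-cohort means; ``sample`` draws a
    random subject within mean +/- 2 SD of the cohort ranges.
    """

    seed: int = 0
    body_mass: float = 69.8        # kg
    height: float = 159.0          # cm
    femur_length: float = 423.38   # L, mm
    neck_shaft_angle: float = 128.62  # FNA, deg
    anteversion: float = 10.35     # ATA, deg
    head_diameter: float = 42.98   # FHD, mm
    offset_absolute: float = 36.89  # OSA, mm
    offset_vertical: float = 49.48  # OSV, mm (femoral head centre to lesser troch.)
    gt_height: float = 3.12        # GTH, signed mm (+ above head centre)
    cortical_density: float = 1800.0    # mg/cm^3
    trabecular_density: float = 300.0   # mg/cm^3
    cortical_shell: float = 4.0    # mm
    stance_fraction: float = 0.6   # fraction of the gait cycle in stance
    grf_peak1: float = 0.15        # early double-support peak, fraction of cycle
    grf_peak2: float = 0.50        # late double-support peak, fraction of cycle
    grf_peak_bw: float | None = None  # override peak vertical GRF in BW
    element_size: float = 4.0      # target mean tet edge length, mm
    cycle_duration: float = 1.1    # s

    def validate(self) -> None:
        if self.femur_length <= 0 or self.head_diameter <= 0 or self.body_mass <= 0:
            raise ValueError("lengths and mass must be positive")
        if not 0 < self.neck_shaft_angle < 180:
            raise ValueError("neck-shaft angle must be in (0, 180) degrees")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance fraction must be in (0, 1)")

    @property
    def body_weight(self) -> float:
        """Body weight in N."""
        return self.body_mass * G


# Cohort morphology table: (mean, SD) per parameter.
_COHORT = {
    "head_diameter": (42.98, 1.07),
    "femur_length": (423.38, 9.89),
    "neck_shaft_angle": (128.62, 3.65),
    "offset_absolute": (36.89, 3.39),
    "offset_vertical": (49.48, 10.38),
    "gt_height": (3.12, 3.27),
    "anteversion": (10.35, 1.71),
}

# Per-case presets (case id -> morphology row + demographics).
CASE_PRESETS = {
    1: dict(body_mass=61.4, height=164, head_diameter=43.88, femur_length=426.50,
            neck_shaft_angle=128.50, offset_absolute=31.90, offset_vertical=50.20,
            gt_height=-1.20, anteversion=11.60),
    2: dict(body_mass=75.8, height=156, head_diameter=42.00, femur_length=424.60,
            neck_shaft_angle=132.90, offset_absolute=34.60, offset_vertical=60.06,
            gt_height=-4.50, anteversion=12.93),
    3: dict(body_mass=78.6, height=161, head_diameter=41.40, femur_length=410.60,
            neck_shaft_angle=123.30, offset_absolute=40.40, offset_vertical=49.48,
            gt_height=4.50, anteversion=8.19),
    4: dict(body_mass=66.3, height=160, head_diameter=44.00, femur_length=439.42,
            neck_shaft_angle=132.30, offset_absolute=36.80, offset_vertical=57.30,
            gt_height=3.10, anteversion=9.95),
    5: dict(body_mass=67.0, height=155, head_diameter=43.60, femur_length=415.80,
            neck_shaft_angle=126.10, offset_absolute=40.75, offset_vertical=30.36,
            gt_height=2.30, anteversion=9.09),
}


def case_preset(case: int, **overrides) -> SubjectSpec:
    return replace(SubjectSpec(), **{**CASE_PRESETS[case], **overrides})


def sample_spec(seed: int) -> SubjectSpec:
    """Random subject within cohort mean +/- 2 SD (uniform), fixed seed."""
    rng = np.random.default_rng(seed)
    kw = {k: m + (2 * rng.uniform(-1, 1)) * s for k, (m, s) in _COHORT.items()}
    kw["body_mass"] = float(rng.uniform(60, 80))
    kw["height"] = float(rng.uniform(152, 166))
    return replace(SubjectSpec(seed=seed), **kw)


# ---------------------------------------------------------------------------
# Constructive femur solid
# ---------------------------------------------------------------------------

class FemurSolid:
    """Implicit femur: union of analytic primitives in the anatomical frame.

    Frame: x anterior, y medial, z superior (shaft axis = z axis); the most
    distal point of the medial condyle sits at z = 0 so the head apex lies
    at z = L.
    """

    PRIMS = ("shaft", "neck", "head", "medial_condyle", "lateral_condyle",
             "greater_trochanter", "lesser_trochanter")

    def __init__(self, spec: SubjectSpec):
        spec.validate()
        L = spec.femur_length
        fna, ata = np.radians(spec.neck_shaft_angle), np.radians(spec.anteversion)
        theta = np.pi - fna  # neck axis elevation from +z
        if np.sin(theta) < 0.15:
            raise GeometryInfeasibleError("neck-shaft angle too close to 180 deg")
        r_head = spec.head_diameter / 2.0
        ln = spec.offset_absolute / np.sin(theta)  # neck length OSN -> FHC
        if ln <= r_head * 1.05:
            raise GeometryInfeasibleError(
                f"head (radius {r_head:.1f} mm) swallows the neck (length {ln:.1f} mm)")
        self.d_neck = np.array([np.sin(theta) * np.sin(ata),
                                np.sin(theta) * np.cos(ata),
                                np.cos(theta)])
        z_fhc = L - r_head
        self.fhc = np.array([0.0, 0.0, z_fhc - ln * np.cos(theta)]) + ln * self.d_neck
        self.osn = np.array([0.0, 0.0, z_fhc - ln * np.cos(theta)])
        if self.osn[2] < 0.7 * L:
            raise GeometryInfeasibleError("neck origin implausibly low on the shaft")
        self.r_head, self.ln, self.L = r_head, ln, L
        # neck frustum radii (base at OSN, tip at head junction)
        self.r_neck_base = min(0.40 * spec.head_diameter, 0.9 * ln)
        self.r_neck_tip = 0.33 * spec.head_diameter
        # condyles
        self.r_cond = 0.050 * L
        y_c = self.r_cond + 1.0
        self.c_med = np.array([0.0, y_c, self.r_cond])          # bottom at z=0
        self.c_lat = np.array([0.0, -y_c, self.r_cond + 1.5])
        # shaft taper profile (z knots, radius)
        self.z_top = self.osn[2] + 0.035 * L
        self.prof_z = np.array([0.0, 0.12 * L, 0.35 * L, 0.62 * L,
                                self.osn[2] - 0.03 * L, self.z_top])
        self.prof_r = np.array([0.047 * L, 0.040 * L, 0.032 * L, 0.032 * L,
                                0.038 * L, 0.042 * L])
        # greater trochanter bump
        self.r_gt = 0.040 * L
        gt_apex_z = z_fhc + spec.gt_height
        self.c_gt = np.array([0.0, -0.030 * L, gt_apex_z - self.r_gt])
        self.gt_apex = np.array([0.0, self.c_gt[1], gt_apex_z])
        if self.c_gt[2] < self.osn[2] - 0.1 * L:
            raise GeometryInfeasibleError("greater trochanter detached from shaft")
        # lesser trochanter bump (posteromedial)
        self.r_lt = 0.020 * L
        z_ltc = z_fhc - spec.offset_vertical
        r_sh = np.interp(z_ltc, self.prof_z, self.prof_r)
        u = np.array([-0.45, 0.80, 0.0])
        u /= np.linalg.norm(u)
        self.c_lt = u * (r_sh + 0.45 * self.r_lt) + np.array([0.0, 0.0, z_ltc])
        self.z_fhc = z_fhc

    # -- primitive signed distances (vectorised over (n,3) points) ---------

    def _sphere(self, p, c, r):
        return np.linalg.norm(p - c, axis=-1) - r

    def sdf_parts(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        rad = np.hypot(p[:, 0], p[:, 1])
        r_prof = np.interp(p[:, 2], self.prof_z, self.prof_r)
        shaft = np.maximum.reduce([rad - r_prof, p[:, 2] - self.z_top,
                                   self.r_cond * 0.5 - p[:, 2]])
        # neck frustum along d_neck from OSN (s=0) to FHC (s=ln)
        q = p - self.osn
        s = q @ self.d_neck
        rr = np.linalg.norm(q - s[:, None] * self.d_neck, axis=-1)
        r_n = self.r_neck_base + (self.r_neck_tip - self.r_neck_base) * \
            np.clip(s / self.ln, 0, 1)
        neck = np.maximum.reduce([rr - r_n, -s, s - self.ln])
        parts = np.stack([
            shaft, neck,
            self._sphere(p, self.fhc, self.r_head),
            self._sphere(p, self.c_med, self.r_cond),
            self._sphere(p, self.c_lat, self.r_cond),
            self._sphere(p, self.c_gt, self.r_gt),
            self._sphere(p, self.c_lt, self.r_lt),
        ], axis=-1)
        return parts

    def sdf(self, p: np.ndarray) -> np.ndarray:
        return self.sdf_parts(p).min(axis=-1)

    def active_primitive(self, p: np.ndarray) -> np.ndarray:
        return self.sdf_parts(p).argmin(axis=-1)

    def gradient(self, p: np.ndarray, h: float = 1e-3) -> np.ndarray:
        g = np.empty_like(p, dtype=float)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = h
            g[:, k] = (self.sdf(p + dp) - self.sdf(p - dp)) / (2 * h)
        n = np.linalg.norm(g, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return g / n

    def project(self, p: np.ndarray, iters: int = 4) -> np.ndarray:
        """Newton-project points onto the zero level set."""
        p = p.copy()
        for _ in range(iters):
            d = self.sdf(p)
            p -= d[:, None] * self.gradient(p)
        return p

    def bbox(self, margin: float = 6.0):
        centres = np.array([self.fhc, self.c_med, self.c_lat, self.c_gt, self.c_lt])
        radii = np.array([self.r_head, self.r_cond, self.r_cond, self.r_gt, self.r_lt])
        lo = (centres - radii[:, None]).min(axis=0)
        hi = (centres + radii[:, None]).max(axis=0)
        rmax = self.prof_r.max()
        lo = np.minimum(lo, [-rmax, -rmax, 0.0])
        hi = np.maximum(hi, [rmax, rmax, self.z_top])
        return lo - margin, hi + margin

    def ground_truth(self, spec: SubjectSpec) -> dict:
        ata = np.radians(spec.anteversion)
        return {
            "FHC": self.fhc, "FHD": spec.head_diameter, "L": spec.femur_length,
            "FNA": spec.neck_shaft_angle, "OSN": self.osn,
            "OSA": spec.offset_absolute,
            "OSH": spec.offset_absolute * np.cos(ata),
            "OSV": spec.offset_vertical, "LTC": self.c_lt,
            "GTH": spec.gt_height, "ATA": spec.anteversion,
            "shaft_axis": np.array([0.0, 0.0, 1.0]),
            "neck_axis": self.d_neck,
            "condylar_dir": np.array([0.0, 1.0, 0.0]),
            "knee_centre": 0.5 * (self.c_med + self.c_lat),
            "r_neck_base": self.r_neck_base,
        }


# Kuhn subdivision of the unit cube into six conforming tets
_KUHN = np.array([
    [0b000, 0b100, 0b110, 0b111],
    [0b000, 0b100, 0b111, 0b101],
    [0b000, 0b010, 0b111, 0b110],
    [0b000, 0b010, 0b011, 0b111],
    [0b000, 0b001, 0b101, 0b111],
    [0b000, 0b001, 0b111, 0b011],
])


def _lattice_tets(inside: np.ndarray) -> np.ndarray:
    """Six-tet Kuhn split of every lattice cube, keeping all-inside tets."""
    nx, ny, nz = inside.shape
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    corner = {}
    for b in range(8):
        dx, dy, dz = (b >> 2) & 1, (b >> 1) & 1, b & 1
        corner[b] = idx[dx:nx - 1 + dx, dy:ny - 1 + dy, dz:nz - 1 + dz].ravel()
    flat_inside = inside.ravel()
    tets = []
    for t in _KUHN:
        conn = np.stack([corner[b] for b in t], axis=1)
        keep = flat_inside[conn].all(axis=1)
        tets.append(conn[keep])
    return np.concatenate(tets)


def generate_femur(spec: SubjectSpec) -> TetMesh:
    """Mesh the constructive femur solid on a snapped body lattice.

    Lattice nodes inside the solid are tetrahedralised by a conforming Kuhn
    subdivision; boundary nodes are then Newton-projected onto the implicit
    surface, so surface nodes lie on the analytic geometry to ~1e-6 mm and
    the stored ground-truth morphology is exact by construction.
    """
    solid = FemurSolid(spec)
    h = spec.element_size / 1.26  # mean Kuhn-tet edge is 1.26 * lattice pitch
    lo, hi = solid.bbox()
    ns = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    axes = [lo[k] + h * np.arange(ns[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = (solid.sdf(pts) <= 0.0).reshape(ns)
    tets = _lattice_tets(inside)
    if len(tets) == 0:
        raise GeometryInfeasibleError("solid thinner than the requested element size")
    # compact node numbering; largest face-connected component only
    used = np.unique(tets)
    remap = np.full(len(pts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes, tets = pts[used].copy(), remap[tets]
    nodes, tets, keep = _clean_mesh(nodes, tets)
    # Remove staircase corner slivers: tets whose four corners all lie on
    # the boundary flatten (and invert) when the boundary is snapped onto a
    # curved surface.  Deleting them exposes no interior node, so the loop
    # is monotone and terminates.
    for _ in range(30):
        surf_ids = np.unique(extract_surface(tets))
        on_surf = np.zeros(len(nodes), bool)
        on_surf[surf_ids] = True
        flat = on_surf[tets].all(axis=1)
        if not flat.any():
            break
        nodes, tets, keep = _clean_mesh(nodes, tets[~flat])
    # snap every boundary node onto the analytic surface; back the few
    # remaining offenders off toward the lattice
    orig = nodes.copy()
    surf_ids = np.unique(extract_surface(tets))
    nodes[surf_ids] = solid.project(orig[surf_ids], iters=6)
    for _ in range(40):
        vols = tet_volumes(nodes, tets)
        bad = vols <= 1e-9
        if not bad.any():
            break
        move = np.unique(tets[bad])
        nodes[move] = 0.5 * (nodes[move] + orig[move])
    surface = extract_surface(tets)
    mesh = TetMesh(nodes, tets, surface)
    mesh.frame = {"anterior": np.array([1.0, 0, 0]), "medial": np.array([0, 1.0, 0]),
                  "superior": np.array([0, 0, 1.0])}
    gt = solid.ground_truth(spec)
    gt["spec"] = {k: getattr(spec, k) for k in
                  ("body_mass", "height", "femur_length", "neck_shaft_angle",
                   "anteversion", "head_diameter", "offset_absolute",
                   "offset_vertical", "gt_height", "element_size", "seed")}
    mesh.ground_truth = gt
    mesh.node_sets = _name_sets(mesh, solid)
    mesh.validate()
    return mesh


def _clean_mesh(nodes, tets, max_rounds: int = 20):
    """Largest face-connected component; strip non-manifold boundary edges.

    Returns (nodes, tets, keep) where ``keep`` indexes the retained nodes in
    the input numbering (for remapping companion per-node arrays).
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    for _ in range(max_rounds):
        # face-connected components via shared-face adjacency
        faces = np.concatenate([tets[:, [0, 2, 1]], tets[:, [0, 1, 3]],
                                tets[:, [1, 2, 3]], tets[:, [0, 3, 2]]])
        owner = np.tile(np.arange(len(tets)), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T)
        key, owner = key[order], owner[order]
        same = np.all(key[1:] == key[:-1], axis=1)
        a, b = owner[:-1][same], owner[1:][same]
        adj = coo_matrix((np.ones(len(a)), (a, b)), shape=(len(tets),) * 2)
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp > 1:
            largest = np.bincount(labels).argmax()
            tets = tets[labels == largest]
        surface = extract_surface(tets)
        edges = np.concatenate([surface[:, [0, 1]], surface[:, [1, 2]],
                                surface[:, [2, 0]]])
        ek = np.sort(edges, axis=1)
        uniq, inv, counts = np.unique(ek, axis=0, return_inverse=True,
                                      return_counts=True)
        bad = uniq[counts != 2]
        if len(bad) == 0:
            break
        bad_pairs = {tuple(e) for e in bad}
        drop = np.zeros(len(tets), bool)
        tet_edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for i, j in tet_edges:
            ek2 = np.sort(tets[:, [i, j]], axis=1)
            drop |= np.fromiter((tuple(e) in bad_pairs for e in ek2),
                                bool, len(tets))
        tets = tets[~drop]
        if len(tets) == 0:
            raise GeometryInfeasibleError("mesh cleaning removed all elements")
    used = np.unique(tets)
    remap = np.full(len(nodes), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used].copy(), remap[tets], used


def _name_sets(mesh: TetMesh, solid: FemurSolid) -> dict:
    surf = mesh.surface_nodes
    p = mesh.nodes[surf]
    act = solid.active_primitive(p)
    names = dict(zip(solid.PRIMS, range(len(solid.PRIMS))))
    sets = {}
    for label, prim in [("femoral_head", "head"), ("neck", "neck"),
                        ("medial_condyle", "medial_condyle"),
                        ("lateral_condyle", "lateral_condyle"),
                        ("greater_trochanter", "greater_trochanter"),
                        ("lesser_trochanter", "lesser_trochanter")]:
        sets[label] = surf[act == names[prim]]
    # patella groove: anterior distal shaft band between the condyles
    shaft_nodes = surf[act == names["shaft"]]
    q = mesh.nodes[shaft_nodes]
    mask = (q[:, 2] < 2.6 * solid.r_cond) & (np.abs(q[:, 1]) < 0.45 * solid.r_cond) \
        & (q[:, 0] > 0.4 * np.interp(q[:, 2], solid.prof_z, solid.prof_r))
    sets["patella_groove"] = shaft_nodes[mask]
    for k, v in sets.items():
        if len(v) == 0:
            raise GeometryInfeasibleError(f"named node set {k!r} came out empty")
    return sets


# ---------------------------------------------------------------------------
# Density image
# ---------------------------------------------------------------------------

@dataclass
class DensityImage:
    """Calibrated 3-D radiological density grid (mg/cm^3), axis-aligned."""

    data: np.ndarray       # (nx, ny, nz)
    spacing: np.ndarray    # mm, per axis
    origin: np.ndarray     # mm, world position of voxel (0,0,0) centre
    calibrated: bool = True
    phantom_samples: list = field(default_factory=list)  # (raw, known density)

    def validate(self) -> None:
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.calibrated and (self.data.min() < 0 or self.data.max() > 2000):
            raise ValueError("calibrated densities must lie in [0, 2000] mg/cm^3")

    def world_to_voxel(self, p: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(p) - self.origin) / self.spacing

    def sample(self, p: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world points (mm)."""
        from scipy.ndimage import map_coordinates
        v = self.world_to_voxel(p)
        return map_coordinates(self.data, v.T, order=1, mode="nearest")

    def to_nifti(self, path: str) -> None:
        import nibabel as nib
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), aff), path)

    @classmethod
    def from_nifti(cls, path: str, calibrated: bool = True) -> "DensityImage":
        import nibabel as nib
        img = nib.load(path)
        aff = img.affine
        return cls(np.asarray(img.dataobj, dtype=float), np.diag(aff)[:3].copy(),
                   aff[:3, 3].copy(), calibrated=calibrated)


def generate_density(spec: SubjectSpec, mesh: TetMesh, spacing: float = 1.5,
                     uniform: float | None = None, shell_mm: float | None = None,
                     raw_units: bool = False) -> DensityImage:
    """Synthetic calibrated density image for a generated femur.

    Cortical-level density inside a surface shell, trabecular level in the
    interior, smooth linear transition; zero (below any bone threshold)
    outside the bone.  ``uniform`` overrides every in-bone voxel;
    ``shell_mm`` overrides the cortical shell thickness (0 gives trabecular
    density throughout).  With ``raw_units`` the image is emitted in
    uncalibrated scanner units together with synthetic phantom samples so
    the calibration fit can be exercised.
    """
    import warnings

    solid = FemurSolid(_spec_from_mesh(spec, mesh))
    shell = spec.cortical_shell if shell_mm is None else shell_mm
    if spacing > shell and shell > 0:
        warnings.warn("voxel spacing exceeds the cortical shell thickness; "
                      "the mapped shell will be diffuse", stacklevel=2)
    lo, hi = solid.bbox(margin=4.0)
    ns = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[k] + spacing * np.arange(ns[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    d = solid.sdf(pts).reshape(ns)
    depth = -d
    trans = 2.0  # mm, shell-to-trabecular transition width
    frac = np.clip((depth - shell) / trans, 0.0, 1.0)
    rho = spec.cortical_density + frac * (spec.trabecular_density - spec.cortical_density)
    if uniform is not None:
        rho = np.full_like(rho, uniform)
    rho = np.where(depth > 0, rho, 0.0)
    img = DensityImage(rho, np.full(3, float(spacing)), lo.astype(float))
    if raw_units:
        # synthetic scanner: raw = (rho - intercept) / slope, plus a phantom
        slope, intercept = 0.8, -15.0
        img.data = (img.data - intercept) / slope
        img.calibrated = False
        img.phantom_samples = [((rho_k - intercept) / slope, rho_k)
                               for rho_k in (0.0, 200.0, 400.0, 800.0, 1200.0, 1600.0)]
    img.validate()
    return img


def _spec_from_mesh(spec: SubjectSpec, mesh: TetMesh) -> SubjectSpec:
    stored = mesh.ground_truth.get("spec")
    if stored:
        keep = {k: v for k, v in stored.items() if k in SubjectSpec.__dataclass_fields__}
        return replace(spec, **keep)
    return spec


# ---------------------------------------------------------------------------
# Gait trial
# ---------------------------------------------------------------------------

DOF_NAMES = ["hip_flexion", "hip_adduction", "hip_rotation",
             "knee_flexion", "ankle_flexion"]


@dataclass
class GaitTrial:
    """One full stride discretised into 100 even intervals.

    ``angles`` are degrees per DOF, ``grf`` the ground reaction force on the
    stance (right) foot in lab coordinates (N), ``cop`` its centre of
    pressure (mm, lab).  ``pct`` is the %gait index 1..100.
    """

    pct: np.ndarray
    angles: pd.DataFrame       # 100 x DOF_NAMES, deg
    grf: np.ndarray            # 100 x 3, N
    cop: np.ndarray            # 100 x 3, mm
    body_mass: float
    cycle_duration: float = 1.1

    def validate(self) -> None:
        if len(self.pct) != 100:
            raise ValueError("a gait trial must have exactly 100 intervals")
        if not np.all(np.isfinite(self.angles.to_numpy())):
            raise ValueError("joint angles must be finite")

    @property
    def tau(self) -> np.ndarray:
        return self.pct / 100.0


def _bump(tau, centre, sigma):
    """Smooth periodic bump (von Mises shaped), unit peak at ``centre``."""
    return np.exp(-2.0 * (1 - np.cos(2 * np.pi * (tau - centre))) / (2 * np.pi * sigma) ** 2)


def generate_gait(spec: SubjectSpec) -> GaitTrial:
    """Canonical level-walking trial: double-bump vertical GRF over stance
    (peaks at the spec's double-support instants), zero in swing, smooth
    periodic joint-angle trajectories."""
    spec.validate()
    pct = np.arange(1, 101)
    tau = pct / 100.0
    sf = spec.stance_fraction
    stance = tau <= sf

    bw = spec.body_weight
    plateau = np.where(stance, np.sin(np.pi * np.clip(tau, 0, sf) / sf) ** 0.6, 0.0)
    fz = 0.75 * plateau + 0.45 * _bump(tau, spec.grf_peak1, 0.05) \
        + 0.40 * _bump(tau, spec.grf_peak2, 0.05)
    fz = np.where(stance, fz, 0.0)
    if spec.grf_peak_bw is not None:
        fz *= spec.grf_peak_bw / fz.max()
    fx = np.where(stance, -0.06 * np.sin(2 * np.pi * tau / sf) * plateau, 0.0)
    fy = np.where(stance, 0.03 * plateau, 0.0)
    grf = bw * np.stack([fx, fy, fz], axis=1)

    ang = pd.DataFrame(index=pct, columns=DOF_NAMES, dtype=float)
    # reduced range of motion, consistent with the conservative gait
    # patterns of older adults
    ang["hip_flexion"] = 8 + 14 * np.cos(2 * np.pi * tau)
    ang["hip_adduction"] = 5 + 1.5 * np.cos(2 * np.pi * tau - 0.6)
    ang["hip_rotation"] = 2 * np.sin(2 * np.pi * tau + 1.0)
    ang["knee_flexion"] = (8 + 12 * _bump(tau, 0.15, 0.07)
                           + 55 * _bump(tau, 0.72, 0.09))
    ang["ankle_flexion"] = (8 * _bump(tau, 0.35, 0.12)
                            - 18 * _bump(tau, 0.55, 0.07)
                            - 4 * _bump(tau, 0.03, 0.05))

    # centre of pressure: rolls heel to toe under the foot; mediolaterally
    # the foot is placed on the line of progression, a fixed 80 mm medial
    # to the hip (step width consistent with level walking).
    from . import msk
    linkage = msk.reference_linkage(spec)
    cop = np.zeros((100, 3))
    frac = np.clip(tau, 0, sf) / sf
    prog = np.where(stance, -40 + 130 * frac, 0.0)
    for i in range(100):
        pose = linkage.forward_kinematics(ang.iloc[i].to_dict())
        ankle = pose["ankle_pos"]
        cop[i] = np.array([ankle[0] + prog[i],
                           linkage.hip_lab[1] + 80.0,
                           ankle[2] - 60.0])
    trial = GaitTrial(pct, ang, grf, cop, spec.body_mass, spec.cycle_duration)
    trial.validate()
    return trial


def generate_linkage_and_muscles(spec: SubjectSpec, mesh: TetMesh):
    """Seven-segment lower-limb linkage with femur-attached muscle paths.

    Delegates to :mod:`femoneck.msk`; femoral attachment points are snapped
    onto the mesh surface and the hip centre coincides with the femoral head
    sphere centre by construction.
    """
    from . import msk
    return msk.build_linkage(spec, mesh)


# ---------------------------------------------------------------------------
# Gait trial I/O
# ---------------------------------------------------------------------------

def write_gait_csv(trial: GaitTrial, path: str) -> None:
    df = trial.angles.copy()
    df.insert(0, "gait_pct", trial.pct)
    for j, c in enumerate(["grf_x", "grf_y", "grf_z"]):
        df[c] = trial.grf[:, j]
    for j, c in enumerate(["cop_x", "cop_y", "cop_z"]):
        df[c] = trial.cop[:, j]
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# body_mass_kg={trial.body_mass} "
                 f"cycle_duration_s={trial.cycle_duration}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_gait(path: str, body_mass: float | None = None) -> GaitTrial:
    """Read a gait trial from CSV (native) or the tab-delimited MOT/STO
    dialect with an ``nRows``/``nColumns`` header block."""
    with open(path) as fh:
        text = fh.read()
    meta = {"body_mass_kg": body_mass or 70.0, "cycle_duration_s": 1.1}
    if "nRows" in text.split("endheader")[0] and "endheader" in text:
        head, body = text.split("endheader", 1)
        df = pd.read_csv(_io.StringIO(body.strip()), sep=r"\s+")
    else:
        lines = text.splitlines()
        if lines[0].startswith("#"):
            for tok in lines[0].lstrip("# ").split():
                k, v = tok.split("=")
                meta[k] = float(v)
            text = "\n".join(lines[1:])
        df = pd.read_csv(_io.StringIO(text))
    if body_mass is not None:
        meta["body_mass_kg"] = body_mass
    cols = {c.lower(): c for c in df.columns}
    ang = pd.DataFrame({d: df[cols[d]].to_numpy() for d in DOF_NAMES})
    grf = np.stack([df[cols[f"grf_{a}"]].to_numpy() for a in "xyz"], axis=1)
    cop = np.stack([df[cols[f"cop_{a}"]].to_numpy() for a in "xyz"], axis=1)
    pct = df[cols["gait_pct"]].to_numpy().astype(int) if "gait_pct" in cols \
        else np.arange(1, len(df) + 1)
    ang.index = pct
    trial = GaitTrial(pct, ang, grf, cop, meta["body_mass_kg"],
                      meta["cycle_duration_s"])
    trial.validate()
    return trial
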