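"""Body-level musculoskeletal solver.

Personalises Hill-type maximal isometric forces (PCSA route for segmented
muscles, lower-limb-mass scaling for the rest), computes joint moments by
recursive Newton-Euler inverse dynamics, resolves muscle redundancy by
static optimisation (minimum sum of squared activations with per-DOF
reserve actuators of unitary maximum force), and computes joint contact
forces by free-body joint reaction analysis, per gait interval.

The linkage is the seven-segment lower-limb model: pelvis, two femora, two
tibiae, two feet; hip = ideal ball-and-socket, knee and ankle = ideal
hinges.  Only the right-side chain carries loads in a right-femur analysis.
Units: mm for geometry, N for force, N.m for moments, kg, degrees.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from scipy.signal import butter, filtfilt

G = 9.81

__all__ = [
    "Muscle", "ScalingContext", "LinkageModel", "MuscleForceSolution",
    "JointLoads", "fmax_from_volume", "fmax_scaled_generic",
    "filter_coordinates", "inverse_dynamics", "static_optimization",
    "joint_reaction", "solve_gait", "build_linkage", "reference_linkage",
    "linkage_to_json", "linkage_from_json", "femur_loads",
]


# ---------------------------------------------------------------------------
# Maximal isometric force personalisation
# ---------------------------------------------------------------------------

def fmax_from_volume(v_m: float, l_opt: float, k: float = 61.0) -> float:
    """F_max = k * V_M / l_opt, with V_M/l_opt the muscle PCSA.

    ``v_m`` in cm^3, ``l_opt`` in cm, ``k`` the specific tension in N/cm^2
    (default 61); returns N.
    """
    if l_opt <= 0:
        raise ValueError("optimal fibre length must be positive")
    if v_m < 0 or k <= 0:
        raise ValueError("volume must be >= 0 and specific tension > 0")
    return k * v_m / l_opt


def fmax_scaled_generic(m_ll: float, m_ll_gen: float, f_max_gen: float) -> float:
    """Linear lower-limb-mass scaling of a generic-model F_max (N)."""
    if m_ll_gen <= 0:
        raise ValueError("generic lower-limb mass must be positive")
    return (m_ll / m_ll_gen) * f_max_gen


@dataclass
class ScalingContext:
    """Quantities entering the F_max personalisation."""

    k: float = 61.0          # specific tension, N/cm^2
    m_ll: float = 11.2       # subject lower-limb mass, kg
    m_ll_gen: float = 11.78  # generic-model lower-limb mass, kg

    def __post_init__(self):
        if self.k <= 0 or self.m_ll <= 0 or self.m_ll_gen <= 0:
            raise ValueError("specific tension and masses must be positive")


# ---------------------------------------------------------------------------
# Muscle table
# ---------------------------------------------------------------------------

@dataclass
class Muscle:
    name: str
    seg_o: str              # origin segment
    p_o: np.ndarray         # origin point, segment-local mm
    seg_i: str              # insertion segment
    p_i: np.ndarray         # insertion point, segment-local mm
    f_max: float            # N
    l_opt: float            # cm
    l_ts: float             # cm
    pennation: float        # deg
    v_max: float = 10.0     # optimal fibre lengths / s
    volume: float | None = None  # cm^3, segmented muscles only
    segmented: bool = False
    in_fe_model: bool = False
    femoral_end: str | None = None   # 'origin' | 'insertion' | None
    femoral_organ: np.ndarray | None = None  # attachment in organ-mesh frame
    via_pelvis: np.ndarray | None = None     # pelvic via point (deep hip flexors)

    @property
    def tendon_gain(self) -> float:
        """Tendon-line force per unit activation (cos-pennation applied)."""
        return self.f_max * np.cos(np.radians(self.pennation))


# pelvic via points: the deep hip flexors wrap over the pelvic brim, so a
# straight origin-insertion line would pass through the joint centre; the
# femoral-side pull is directed toward the brim instead.
_VIA_PELVIS = {"psoas": (48.0, 22.0, -5.0), "iliacus": (48.0, 12.0, -8.0)}

# name: (segmented, V_M cm^3 | F_maxGen N, l_opt cm, penn deg,
#        origin seg, origin anchor, insertion seg, insertion anchor, in FE list)
# Femoral anchors are symbolic keys resolved on the generated femur; other
# segments use literal local coordinates (x anterior, y medial, z up; origin
# at the segment's proximal joint centre).
_MUSCLE_DEFS = {
    "adductor_brevis":     (True, 60.0, 10.3, 0, "pelvis", (20, 55, -10), "femur", "add_brevis", True),
    "adductor_longus":     (True, 100.0, 10.8, 6, "pelvis", (30, 60, -5), "femur", "add_longus", True),
    "adductor_magnus":     (True, 350.0, 14.5, 5, "pelvis", (-20, 50, -35), "femur", "add_magnus", True),
    "biceps_femoris_lh":   (True, 130.0, 10.9, 0, "pelvis", (-35, 40, -30), "tibia", (-10, -38, -45), True),
    "biceps_femoris_sh":   (True, 60.0, 17.3, 23, "femur", "bf_short", "tibia", (-12, -36, -42), True),
    "gemellus":            (False, 200.0, 2.4, 0, "pelvis", (-45, 40, -5), "femur", "gemellus", True),
    "gluteus_maximus":     (True, 550.0, 14.4, 5, "pelvis", (-60, -20, 40), "femur", "glut_max", True),
    "gluteus_medius":      (True, 320.0, 7.3, 8, "pelvis", (5, -35, 75), "femur", "glut_med", True),
    "gluteus_minimus":     (False, 700.0, 3.8, 1, "pelvis", (8, -30, 55), "femur", "glut_min", True),
    "gracilis":            (True, 75.0, 35.2, 3, "pelvis", (15, 58, -15), "tibia", (-5, 38, -50), False),
    "iliacus":             (True, 180.0, 10.0, 7, "pelvis", (15, 20, 55), "femur", "iliacus", True),
    "gastroc_lateralis":   (True, 70.0, 6.4, 8, "femur", "gastroc_lat", "foot", (-60, -10, -35), True),
    "gastroc_medialis":    (True, 160.0, 4.5, 17, "femur", "gastroc_med", "foot", (-60, 10, -35), True),
    "pectineus":           (False, 400.0, 13.3, 0, "pelvis", (25, 30, 5), "femur", "pectineus", True),
    "piriformis":          (False, 600.0, 2.6, 10, "pelvis", (-40, 60, 20), "femur", "piriformis", True),
    "psoas":               (False, 1200.0, 10.4, 8, "pelvis", (10, 35, 80), "femur", "psoas", True),
    "quadratus_femoris":   (False, 400.0, 5.4, 0, "pelvis", (-40, 35, -25), "femur", "quad_fem", True),
    "rectus_femoris":      (True, 220.0, 11.4, 5, "pelvis", (20, 5, 10), "tibia", (48, 0, -55), False),
    "sartorius":           (True, 90.0, 52.0, 0, "pelvis", (25, -15, 40), "tibia", (0, 35, -60), False),
    "semimembranosus":     (True, 160.0, 6.9, 15, "pelvis", (-38, 45, -28), "tibia", (-25, 30, -40), False),
    "semitendinosus":      (True, 95.0, 20.1, 5, "pelvis", (-40, 42, -32), "tibia", (-10, 35, -55), False),
    "soleus":              (True, 280.0, 3.0, 25, "tibia", (-25, 0, -90), "foot", (-60, 0, -30), False),
    "tensor_fasciae_latae": (True, 60.0, 9.5, 3, "pelvis", (15, -30, 45), "tibia", (25, -30, -50), False),
    "tibialis_anterior":   (True, 105.0, 9.8, 5, "tibia", (20, -15, -150), "foot", (60, 20, -30), False),
    "vastus_intermedius":  (True, 270.0, 8.7, 3, "femur", "vast_int", "tibia", (48, 0, -55), True),
    "vastus_lateralis":    (True, 430.0, 8.4, 5, "femur", "vast_lat", "tibia", (48, -8, -55), True),
    "vastus_medialis":     (True, 230.0, 8.9, 5, "femur", "vast_med", "tibia", (48, 8, -55), True),
}


def _femoral_anchors(solid) -> dict:
    """Anatomically placed femoral attachment points (organ frame, mm)."""
    L = solid.L

    def radial(zf, dx, dy, out=1.0):
        z = zf * L
        u = np.array([dx, dy, 0.0])
        u /= np.linalg.norm(u)
        r = np.interp(z, solid.prof_z, solid.prof_r)
        return u * r * out + np.array([0, 0, z])

    z_lt = solid.c_lt[2]
    on = {
        "glut_med": solid.gt_apex,
        "glut_min": solid.gt_apex + np.array([8.0, 3.0, -8.0]),
        "piriformis": solid.gt_apex + np.array([-8.0, 2.0, -4.0]),
        "gemellus": solid.c_gt + solid.r_gt * np.array([-0.6, 0.35, -0.25]),
        "quad_fem": radial(z_lt / L + 0.012, -0.7, -0.3),
        "glut_max": radial(0.70, -0.8, -0.6),
        "iliacus": solid.c_lt + solid.r_lt * np.array([0.3, 0.7, 0.3]),
        "psoas": solid.c_lt + solid.r_lt * np.array([0.4, 0.5, 0.7]),
        "pectineus": radial(z_lt / L - 0.03, -0.5, 0.8),
        "add_brevis": radial(0.60, -0.6, 0.75),
        "add_longus": radial(0.52, -0.5, 0.85),
        "add_magnus": radial(0.30, -0.4, 0.9),
        "bf_short": radial(0.45, -0.9, 0.2),
        "gastroc_med": solid.c_med + solid.r_cond * np.array([-0.72, 0.25, 0.40]),
        "gastroc_lat": solid.c_lat + solid.r_cond * np.array([-0.72, -0.25, 0.40]),
        "vast_int": radial(0.55, 0.95, 0.1),
        "vast_lat": radial(0.55, 0.25, -0.95),
        "vast_med": radial(0.45, 0.3, 0.9),
    }
    return {k: solid.project(np.atleast_2d(np.asarray(v, float)))[0]
            for k, v in on.items()}


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------

# segment mass fractions of body mass and COM position along the segment
_THIGH_F, _SHANK_F, _FOOT_F = 0.100, 0.0465, 0.0145
_LL_FRACTION = _THIGH_F + _SHANK_F + _FOOT_F


@dataclass
class LinkageModel:
    """Seven-segment lower-limb linkage (right chain carries the analysis)."""

    segments: dict                    # name -> dict(mass, com_local, inertia, length)
    hip_lab: np.ndarray               # right hip centre, lab frame mm
    hip_centre: np.ndarray            # hip centre in organ/femur-anatomical frame
    knee_local: np.ndarray            # knee centre in femur-local frame (origin hip)
    ankle_local: np.ndarray           # ankle centre in tibia-local frame (origin knee)
    muscles: list = field(default_factory=list)
    scaling: ScalingContext = field(default_factory=ScalingContext)
    surface_sample: np.ndarray | None = None  # femur surface points, msk frame
    body_mass: float = 70.0

    KNEE_AXIS = np.array([0.0, 1.0, 0.0])   # femur-local hinge axis
    ANKLE_AXIS = np.array([0.0, 1.0, 0.0])  # tibia-local hinge axis
    JOINT_COUNT = 6
    DOF_AXES = ("hip_x", "hip_y", "hip_z", "knee", "ankle")

    def femur_local(self, p_organ: np.ndarray) -> np.ndarray:
        return np.asarray(p_organ, float) - self.hip_centre

    def forward_kinematics(self, angles: dict) -> dict:
        """Segment poses (lab frame) for one set of joint angles (deg)."""
        hf, ha, hr = (np.radians(angles[k]) for k in
                      ("hip_flexion", "hip_adduction", "hip_rotation"))
        kf = np.radians(angles["knee_flexion"])
        af = np.radians(angles["ankle_flexion"])
        R_hip = _rot_y(-hf) @ _rot_x(ha) @ _rot_z(hr)
        R_knee = _rot_y(kf)
        R_ankle = _rot_y(-af)
        R_fem = R_hip
        knee_pos = self.hip_lab + R_fem @ self.knee_local
        R_tib = R_fem @ R_knee
        ankle_pos = knee_pos + R_tib @ self.ankle_local
        R_foot = R_tib @ R_ankle
        return {"hip_pos": self.hip_lab, "R_fem": R_fem,
                "knee_pos": knee_pos, "R_tib": R_tib,
                "ankle_pos": ankle_pos, "R_foot": R_foot,
                "knee_axis": R_fem @ self.KNEE_AXIS,
                "ankle_axis": R_tib @ self.ANKLE_AXIS}

    def pull_direction(self, muscle: Muscle, end: str, pose: dict) -> np.ndarray:
        """Unit direction of the tendon pull at one attachment (lab frame);
        respects a pelvic via point on the femoral side."""
        a = self.attachment_lab(muscle, end, pose)
        if muscle.via_pelvis is not None and end == muscle.femoral_end:
            b = self.hip_lab + muscle.via_pelvis
        else:
            other = "insertion" if end == "origin" else "origin"
            b = self.attachment_lab(muscle, other, pose)
        u = b - a
        return u / np.linalg.norm(u)

    def attachment_lab(self, muscle: Muscle, end: str, pose: dict) -> np.ndarray:
        seg = muscle.seg_o if end == "origin" else muscle.seg_i
        p = muscle.p_o if end == "origin" else muscle.p_i
        if seg == "pelvis":
            return self.hip_lab + p
        if seg == "femur":
            return self.hip_lab + pose["R_fem"] @ p
        if seg == "tibia":
            return pose["knee_pos"] + pose["R_tib"] @ p
        if seg == "foot":
            return pose["ankle_pos"] + pose["R_foot"] @ p
        raise KeyError(seg)


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _arr(x):
    return None if x is None else np.asarray(x, float)


def linkage_to_json(linkage: LinkageModel, path: str) -> None:
    """Serialise a linkage (segments, joints, muscle set) to JSON."""
    import json

    def conv(v):
        return v.tolist() if isinstance(v, np.ndarray) else v
    d = {
        "segments": {k: {kk: conv(vv) for kk, vv in seg.items()}
                     for k, seg in linkage.segments.items()},
        "hip_lab": conv(linkage.hip_lab), "hip_centre": conv(linkage.hip_centre),
        "knee_local": conv(linkage.knee_local),
        "ankle_local": conv(linkage.ankle_local),
        "body_mass": linkage.body_mass,
        "scaling": {"k": linkage.scaling.k, "m_ll": linkage.scaling.m_ll,
                    "m_ll_gen": linkage.scaling.m_ll_gen},
        "surface_sample": conv(linkage.surface_sample),
        "muscles": [{k: conv(getattr(m, k)) for k in
                     ("name", "seg_o", "p_o", "seg_i", "p_i", "f_max", "l_opt",
                      "l_ts", "pennation", "v_max", "volume", "segmented",
                      "in_fe_model", "femoral_end", "femoral_organ",
                      "via_pelvis")} for m in linkage.muscles],
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def linkage_from_json(path: str) -> LinkageModel:
    import json
    with open(path) as fh:
        d = json.load(fh)
    segments = {k: {kk: (_arr(vv) if isinstance(vv, list) else vv)
                    for kk, vv in seg.items()}
                for k, seg in d["segments"].items()}
    muscles = [Muscle(name=m["name"], seg_o=m["seg_o"], p_o=_arr(m["p_o"]),
                      seg_i=m["seg_i"], p_i=_arr(m["p_i"]), f_max=m["f_max"],
                      l_opt=m["l_opt"], l_ts=m["l_ts"], pennation=m["pennation"],
                      v_max=m["v_max"], volume=m["volume"],
                      segmented=m["segmented"], in_fe_model=m["in_fe_model"],
                      femoral_end=m["femoral_end"],
                      femoral_organ=_arr(m["femoral_organ"]),
                      via_pelvis=_arr(m["via_pelvis"]))
               for m in d["muscles"]]
    return LinkageModel(segments=segments, hip_lab=_arr(d["hip_lab"]),
                        hip_centre=_arr(d["hip_centre"]),
                        knee_local=_arr(d["knee_local"]),
                        ankle_local=_arr(d["ankle_local"]), muscles=muscles,
                        scaling=ScalingContext(**d["scaling"]),
                        surface_sample=_arr(d["surface_sample"]),
                        body_mass=d["body_mass"])


def build_linkage(spec, mesh=None) -> LinkageModel:
    """Construct the linkage and personalised muscle set for a subject.

    With a generated femur mesh, femoral attachment anchors are snapped to
    the nearest surface node (so the attachment lies exactly on the FE
    surface); without a mesh the analytic solid surface is used directly.
    The hip joint centre coincides with the femoral head sphere centre.
    """
    from .subject import FemurSolid

    solid = FemurSolid(spec)
    anchors = _femoral_anchors(solid)
    sample = None
    if mesh is not None:
        from scipy.spatial import cKDTree
        surf = mesh.surface_nodes
        tree = cKDTree(mesh.nodes[surf])
        lo, hi = mesh.nodes.min(0) - 1, mesh.nodes.max(0) + 1
        snapped = {}
        for k, p in anchors.items():
            if np.any(p < lo) or np.any(p > hi):
                raise ValueError(f"muscle anchor {k!r} outside the mesh bounding box")
            d, j = tree.query(p)
            if d > 10.0:
                raise ValueError(f"muscle anchor {k!r} is {d:.1f} mm from the surface")
            snapped[k] = mesh.nodes[surf[j]].copy()
        anchors = snapped
        sample = mesh.nodes[surf[::2]].copy()

    hip_centre = solid.fhc.copy()
    knee_organ = 0.5 * (solid.c_med + solid.c_lat)
    knee_local = knee_organ - hip_centre
    l_fem = float(np.linalg.norm(knee_local))
    l_tib = 0.246 * spec.height * 10.0
    l_foot = 0.152 * spec.height * 10.0
    ankle_local = np.array([0.0, 0.0, -l_tib])

    bm = spec.body_mass
    m_ll = _LL_FRACTION * bm
    scaling = ScalingContext(m_ll=m_ll)
    segments = {"pelvis": {"mass": bm - 2 * m_ll, "com_local": np.array([0.0, 90.0, 120.0]),
                           "length": 200.0}}
    for side in ("r", "l"):
        segments[f"femur_{side}"] = {
            "mass": _THIGH_F * bm, "com_local": 0.433 * knee_local,
            "length": l_fem, "rog": 0.323}
        segments[f"tibia_{side}"] = {
            "mass": _SHANK_F * bm, "com_local": 0.433 * ankle_local,
            "length": l_tib, "rog": 0.302}
        segments[f"foot_{side}"] = {
            "mass": _FOOT_F * bm, "com_local": np.array([40.0, 10.0, -40.0]),
            "length": l_foot, "rog": 0.30}
    for name, seg in segments.items():
        ell = seg["length"] / 1000.0
        it = seg["mass"] * (seg.get("rog", 0.3) * ell) ** 2
        seg["inertia"] = np.diag([it, it, 0.15 * it])

    muscles = []
    for name, (segm, vol_or_f, l_opt, penn, so, po, si, pi, fe) in _MUSCLE_DEFS.items():
        if segm:
            f_max = fmax_from_volume(vol_or_f, l_opt, scaling.k)
            volume = vol_or_f
        else:
            f_max = fmax_scaled_generic(scaling.m_ll, scaling.m_ll_gen, vol_or_f)
            volume = None
        femoral_end = "origin" if so == "femur" else (
            "insertion" if si == "femur" else None)
        femoral_organ = None
        p_o = anchors[po] - hip_centre if so == "femur" else np.asarray(po, float)
        p_i = anchors[pi] - hip_centre if si == "femur" else np.asarray(pi, float)
        if femoral_end == "origin":
            femoral_organ = anchors[po]
        elif femoral_end == "insertion":
            femoral_organ = anchors[pi]
        via = _VIA_PELVIS.get(name)
        muscles.append(Muscle(
            name=name, seg_o=so, p_o=p_o, seg_i=si, p_i=p_i,
            f_max=f_max, l_opt=l_opt, l_ts=1.2 * l_opt, pennation=penn,
            volume=volume, segmented=segm, in_fe_model=fe,
            femoral_end=femoral_end, femoral_organ=femoral_organ,
            via_pelvis=None if via is None else np.asarray(via, float)))

    hip_lab = np.array([0.0, 0.0, l_fem + l_tib + 70.0])
    return LinkageModel(segments=segments, hip_lab=hip_lab, hip_centre=hip_centre,
                        knee_local=knee_local, ankle_local=ankle_local,
                        muscles=muscles, scaling=scaling,
                        surface_sample=sample, body_mass=bm)


def reference_linkage(spec) -> LinkageModel:
    """Linkage built from the analytic solid only (no mesh required)."""
    return build_linkage(spec, mesh=None)


# ---------------------------------------------------------------------------
# Coordinate filtering
# ---------------------------------------------------------------------------

def filter_coordinates(series: np.ndarray, cutoff: float, fs: float,
                       order: int = 4) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter of uniformly sampled series.

    ``series`` is (n,) or (n, k); DC is preserved exactly for constant
    input.  Raises if the cutoff reaches the Nyquist frequency.
    """
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz is at/above Nyquist ({fs / 2} Hz)")
    b, a = butter(order, cutoff / (fs / 2))
    return filtfilt(b, a, np.asarray(series, float), axis=0)


# ---------------------------------------------------------------------------
# Inverse dynamics
# ---------------------------------------------------------------------------

def newton_euler_chain(joint_pos, R, com_local, masses, inertias_local,
                       ext_forces, ext_points, dt, quasi_static=False):
    """Recursive Newton-Euler for a serial chain, distal segment last.

    All kinematic inputs are (n_seg, n_t, ...) arrays sampled uniformly in
    time (assumed periodic for differentiation).  ``ext_forces``/``ext_points``
    apply to the most distal segment (N, lab mm).  Returns per-segment
    proximal joint forces (N) and moments (N.m) in the lab frame.

    Geometry is mm; moment arms are converted to metres internally.
    """
    n_seg, n_t = R.shape[0], R.shape[1]
    com = np.einsum("stij,sj->sti", R, com_local) + joint_pos  # lab mm

    if quasi_static:
        acc = np.zeros_like(com)
        omega = np.zeros((n_seg, n_t, 3))
        alpha = np.zeros((n_seg, n_t, 3))
    else:
        acc = (np.roll(com, -1, axis=1) - 2 * com + np.roll(com, 1, axis=1)) / dt**2
        dR = (np.roll(R, -1, axis=1) - np.roll(R, 1, axis=1)) / (2 * dt)
        W = np.einsum("stij,stkj->stik", dR, R)  # skew(omega)
        omega = np.stack([W[..., 2, 1], W[..., 0, 2], W[..., 1, 0]], axis=-1)
        alpha = (np.roll(omega, -1, axis=1) - np.roll(omega, 1, axis=1)) / (2 * dt)

    g = np.array([0.0, 0.0, -G])
    F_prox = np.zeros((n_seg, n_t, 3))
    M_prox = np.zeros((n_seg, n_t, 3))
    F_child = np.zeros((n_t, 3))
    M_child = np.zeros((n_t, 3))
    child_joint = None
    for s in range(n_seg - 1, -1, -1):
        m = masses[s]
        fe = ext_forces if s == n_seg - 1 else np.zeros((n_t, 3))
        pe = ext_points if s == n_seg - 1 else com[s]
        F = m * acc[s] / 1000.0 - m * g - fe + F_child
        I_lab = np.einsum("tij,jk,tlk->til", R[s], inertias_local[s], R[s])
        Iw = np.einsum("tij,tj->ti", I_lab, omega[s])
        rot = np.einsum("tij,tj->ti", I_lab, alpha[s]) + np.cross(omega[s], Iw)
        M = rot - np.cross((joint_pos[s] - com[s]) / 1000.0, F) \
            - np.cross((pe - com[s]) / 1000.0, fe)
        if child_joint is not None:
            M += M_child + np.cross((child_joint - com[s]) / 1000.0, F_child)
        F_prox[s], M_prox[s] = F, M
        F_child, M_child = F, M
        child_joint = joint_pos[s]
    return F_prox, M_prox


def _chain_arrays(linkage: LinkageModel, trial):
    """FK over a whole trial -> per-segment pose arrays (femur, tibia, foot)."""
    n = len(trial.pct)
    poses = [linkage.forward_kinematics(trial.angles.iloc[i].to_dict())
             for i in range(n)]
    jp = np.stack([[linkage.hip_lab] * n,
                   [p["knee_pos"] for p in poses],
                   [p["ankle_pos"] for p in poses]])
    R = np.stack([[p["R_fem"] for p in poses],
                  [p["R_tib"] for p in poses],
                  [p["R_foot"] for p in poses]])
    segs = ["femur_r", "tibia_r", "foot_r"]
    com_local = np.stack([linkage.segments[s]["com_local"] for s in segs])
    masses = np.array([linkage.segments[s]["mass"] for s in segs])
    inertias = np.stack([linkage.segments[s]["inertia"] for s in segs])
    return poses, jp, R, com_local, masses, inertias


def inverse_dynamics(linkage: LinkageModel, trial, quasi_static: bool = True,
                     cutoff_hz: float = 6.0) -> pd.DataFrame:
    """Per-interval joint moments (N.m) for the right-leg chain.

    Quasi-static mode zeroes every inertial term (each gait interval is a
    static snapshot); dynamic mode differentiates coordinates filtered with
    a zero-lag Butterworth low-pass at ``cutoff_hz``.
    """
    for dof in trial.angles.columns:
        pass
    missing = [d for d in ("hip_flexion", "hip_adduction", "hip_rotation",
                           "knee_flexion", "ankle_flexion")
               if d not in trial.angles.columns]
    if missing:
        raise ValueError(f"gait trial lacks DOF columns: {missing}")
    work = trial
    if not quasi_static:
        fs = len(trial.pct) / trial.cycle_duration
        filt = filter_coordinates(trial.angles.to_numpy(), cutoff_hz, fs)
        work = type(trial)(trial.pct, pd.DataFrame(filt, index=trial.angles.index,
                                                   columns=trial.angles.columns),
                           trial.grf, trial.cop, trial.body_mass,
                           trial.cycle_duration)
    poses, jp, R, com_local, masses, inertias = _chain_arrays(linkage, work)
    dt = work.cycle_duration / len(work.pct)
    F, M = newton_euler_chain(jp, R, com_local, masses, inertias,
                              work.grf, work.cop, dt, quasi_static=quasi_static)
    out = pd.DataFrame(index=work.pct)
    out[["hip_x", "hip_y", "hip_z"]] = M[0]
    out["knee"] = np.einsum("ti,ti->t", M[1],
                            np.stack([p["knee_axis"] for p in poses]))
    out["ankle"] = np.einsum("ti,ti->t", M[2],
                             np.stack([p["ankle_axis"] for p in poses]))
    return out


# ---------------------------------------------------------------------------
# Static optimisation
# ---------------------------------------------------------------------------

_SEG_LEVEL = {"pelvis": 0, "femur": 1, "tibia": 2, "foot": 3}
_JOINT_OF_LEVEL = {1: "hip", 2: "knee", 3: "ankle"}


def _muscle_rows(linkage: LinkageModel, pose: dict):
    """Moment-generating matrix A (5 x n): N.m per unit activation."""
    centres = {"hip": linkage.hip_lab, "knee": pose["knee_pos"],
               "ankle": pose["ankle_pos"]}
    axes = {"knee": pose["knee_axis"], "ankle": pose["ankle_axis"]}
    n = len(linkage.muscles)
    A = np.zeros((5, n))
    for i, mus in enumerate(linkage.muscles):
        lo, li = _SEG_LEVEL[mus.seg_o], _SEG_LEVEL[mus.seg_i]
        end_hi = "origin" if lo >= li else "insertion"
        p_hi = linkage.attachment_lab(mus, end_hi, pose)
        l_lo, l_hi = min(lo, li), max(lo, li)
        # pull on the distal side, toward the proximal end (or via point)
        u = linkage.pull_direction(mus, end_hi, pose)
        gain = mus.tendon_gain
        for lvl in range(l_lo + 1, l_hi + 1):
            joint = _JOINT_OF_LEVEL[lvl]
            mom = np.cross((p_hi - centres[joint]) / 1000.0, u * gain)
            if joint == "hip":
                A[0:3, i] += mom
            elif joint == "knee":
                A[3, i] += mom @ axes["knee"]
            else:
                A[4, i] += mom @ axes["ankle"]
    return A


@dataclass
class MuscleForceSolution:
    names: list
    activations: np.ndarray    # (n_t, n_muscles) in [0, 1]
    forces: np.ndarray         # tendon-line forces, N
    reserves: np.ndarray       # (n_t, 5) reserve torques, N.m
    objective: np.ndarray      # (n_t,) sum of squared activations
    poses: list = field(default_factory=list)


def static_optimization(moments: pd.DataFrame, linkage: LinkageModel,
                        poses: list | None = None,
                        reserve_warn_fraction: float = 0.05) -> MuscleForceSolution:
    """Minimum-activation-squared muscle recruitment with reserve actuators.

    Solves, per interval, min sum(a^2) + sum(tau_res^2) subject to the
    moment balance A a + tau_res = M and 0 <= a <= 1 (reserves, one ideal
    torque per DOF with unitary maximum force, enter the cost at weight 1 so
    they are unfavourable to recruit).  With the reserves eliminated this is
    a bound-constrained linear least-squares problem, solved exactly by a
    convex solver.
    """
    n_t = len(moments)
    names = [m.name for m in linkage.muscles]
    acts = np.zeros((n_t, len(names)))
    reserves = np.zeros((n_t, 5))
    forces = np.zeros_like(acts)
    gains = np.array([m.tendon_gain for m in linkage.muscles])
    Mmat = moments[["hip_x", "hip_y", "hip_z", "knee", "ankle"]].to_numpy()
    eye = np.eye(len(names))
    for t in range(n_t):
        A = _muscle_rows(linkage, poses[t])
        res = lsq_linear(np.vstack([eye, A]),
                         np.concatenate([np.zeros(len(names)), Mmat[t]]),
                         bounds=(0.0, 1.0), tol=1e-12)
        a = res.x
        acts[t] = a
        reserves[t] = Mmat[t] - A @ a
        forces[t] = a * gains
    peak = np.abs(Mmat).max(axis=0)
    frac = np.abs(reserves).max(axis=0) / np.where(peak > 0, peak, np.inf)
    if np.any(frac > reserve_warn_fraction):
        worst = LinkageModel.DOF_AXES[int(np.argmax(frac))]
        warnings.warn(f"reserve torque reaches {100 * frac.max():.1f}% of the "
                      f"peak joint moment on DOF {worst}", stacklevel=2)
    return MuscleForceSolution(names, acts, forces, reserves,
                               (acts ** 2).sum(axis=1), poses or [])


# ---------------------------------------------------------------------------
# Joint reaction analysis
# ---------------------------------------------------------------------------

@dataclass
class JointLoads:
    jcf_hip: np.ndarray    # (n_t, 3) on the femur, femur anatomical frame, N
    jcf_knee: np.ndarray   # (n_t, 3) on the femur from the tibia, femur frame
    jcf_net: np.ndarray    # |hip + knee force on the femur|, N

    def validate(self):
        if not (np.all(np.isfinite(self.jcf_hip)) and np.all(np.isfinite(self.jcf_knee))):
            raise ValueError("joint contact forces must be finite")


def _muscle_world_forces(linkage, solution, t):
    """Per-muscle (point, force) pairs at both attachments, lab frame."""
    pose = solution.poses[t]
    out = []
    for i, mus in enumerate(linkage.muscles):
        f = solution.forces[t, i]
        po = linkage.attachment_lab(mus, "origin", pose)
        pi = linkage.attachment_lab(mus, "insertion", pose)
        uo = linkage.pull_direction(mus, "origin", pose)
        ui = linkage.pull_direction(mus, "insertion", pose)
        # each attachment is pulled toward the opposite end (or via point)
        out.append((mus, po, f * uo, pi, f * ui))
    return out


def joint_reaction(solution: MuscleForceSolution, linkage: LinkageModel,
                   trial, quasi_static: bool = True) -> JointLoads:
    """Joint contact forces from subtree free-body balance with solved
    muscle forces, expressed in the femur anatomical frame."""
    n_t = len(trial.pct)
    _, jp, R, com_local, masses, _ = _chain_arrays(linkage, trial)
    com = np.einsum("stij,sj->sti", R, com_local) + jp
    dt = trial.cycle_duration / n_t
    if quasi_static:
        acc = np.zeros_like(com)
    else:
        acc = (np.roll(com, -1, axis=1) - 2 * com + np.roll(com, 1, axis=1)) / dt**2
    g = np.array([0.0, 0.0, -G])
    jcf_hip = np.zeros((n_t, 3))
    jcf_knee = np.zeros((n_t, 3))
    for t in range(n_t):
        pose = solution.poses[t]
        pairs = _muscle_world_forces(linkage, solution, t)
        for joint, seg_slice, store in (("hip", slice(0, 3), jcf_hip),
                                        ("knee", slice(1, 3), jcf_knee)):
            lvl = 1 if joint == "hip" else 2
            F = np.zeros(3)
            for s in range(seg_slice.start, 3):
                F += masses[s] * acc[s, t] / 1000.0 - masses[s] * g
            F -= trial.grf[t]
            for mus, po, fo, pi, fi in pairs:
                if _SEG_LEVEL[mus.seg_o] >= lvl:
                    F -= fo
                if _SEG_LEVEL[mus.seg_i] >= lvl:
                    F -= fi
            store[t] = pose["R_fem"].T @ F
    # force on the femur from the tibia is the reaction of the knee JCF
    net = np.linalg.norm(jcf_hip - jcf_knee, axis=1)
    loads = JointLoads(jcf_hip, -jcf_knee, net)
    loads.validate()
    return loads


def solve_gait(linkage: LinkageModel, trial, quasi_static: bool = True,
               cutoff_hz: float = 6.0):
    """Full body-level pipeline: inverse dynamics, static optimisation,
    joint reaction analysis.  Returns (moments, MuscleForceSolution,
    JointLoads)."""
    moments = inverse_dynamics(linkage, trial, quasi_static, cutoff_hz)
    poses = [linkage.forward_kinematics(trial.angles.iloc[i].to_dict())
             for i in range(len(trial.pct))]
    solution = static_optimization(moments, linkage, poses)
    loads = joint_reaction(solution, linkage, trial, quasi_static)
    return moments, solution, loads


def femur_loads(linkage: LinkageModel, solution: MuscleForceSolution, t: int,
                include_weight: bool = True):
    """External loads on the femur at interval ``t`` in the femur frame.

    Returns (points, forces): attachment points (femur anatomical/organ
    frame, mm) and force vectors (N) for every FE-model muscle attached to
    the femur, plus optionally the femur segment weight at its COM.
    """
    pose = solution.poses[t]
    Rf = pose["R_fem"]
    pts, fvs = [], []
    for i, mus in enumerate(linkage.muscles):
        if not (mus.in_fe_model and mus.femoral_end):
            continue
        f = solution.forces[t, i]
        u = linkage.pull_direction(mus, mus.femoral_end, pose)
        pts.append(mus.femoral_organ)
        fvs.append(Rf.T @ (f * u))
    if include_weight:
        m = linkage.segments["femur_r"]["mass"]
        com_organ = linkage.hip_centre + linkage.segments["femur_r"]["com_local"]
        pts.append(com_organ)
        fvs.append(Rf.T @ np.array([0.0, 0.0, -m * G]))
    return np.asarray(pts), np.asarray(fvs)
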