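"""Femoral morphology measurement on a surface mesh.

Implements the plane/axis protocol for the standard parameter set: femoral
head centre and diameter (best-fit sphere), total length L, neck-shaft
angle FNA, shaft/neck axis intersection OSN, absolute/horizontal offsets
OSA/OSH, vertical offset OSV to the lesser trochanter centre, greater
trochanter height GTH (signed, positive above the head centre) and
anteversion ATA against the condylar line.

The longitudinal direction is initialised as the principal axis of the
surface point cloud and refined to the shaft axis (the line through the
circle-fit midpoints of the transversal sections at 50% and 80% of L) by
fixed-point iteration; all scalar outputs are invariant under rigid motion
of the mesh.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .mesh import TetMesh

__all__ = ["MorphologyReport", "MorphologyError", "fit_sphere", "fit_circle",
           "build_planes_and_axes", "measure"]


class MorphologyError(ValueError):
    """Raised when the measurement protocol cannot be applied."""


@dataclass
class MorphologyReport:
    FHC: np.ndarray   # femoral head centre, mm
    FHD: float        # femoral head diameter, mm
    L: float          # total femur length, mm
    FNA: float        # neck-shaft angle, deg
    OSN: np.ndarray   # shaft/neck axis intersection (closest approach), mm
    OSA: float        # absolute offset head centre -> shaft axis, mm
    OSH: float        # horizontal (mediolateral) offset, mm
    OSV: float        # vertical offset head centre -> lesser trochanter, mm
    LTC: np.ndarray   # lesser trochanter centre, mm
    GTH: float        # greater trochanter height, signed mm
    ATA: float        # anteversion angle, deg

    TABLE_COLUMNS = ["FHD", "L", "FNA", "OSA", "OSH", "OSV", "GTH", "ATA"]

    def validate(self) -> None:
        if self.FHD <= 0 or self.L <= 0:
            raise MorphologyError("FHD and L must be positive")
        if not 0 < self.FNA < 180:
            raise MorphologyError("FNA out of (0, 180) degrees")
        if self.OSH > self.OSA + 1e-6:
            raise MorphologyError("OSH cannot exceed OSA")

    def to_json(self, path: str) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
             for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    def to_csv_row(self, path: str) -> None:
        vals = ",".join(f"{getattr(self, c):.4f}" for c in self.TABLE_COLUMNS)
        with open(path, "w") as fh:
            fh.write(",".join(self.TABLE_COLUMNS) + "\n" + vals + "\n")


# ---------------------------------------------------------------------------
# Primitive fits
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray, trim: float | None = 3.0):
    """Least-squares sphere fit; returns (centre, radius, rms residual).

    Algebraic linear formulation; with ``trim`` the fit is repeated after
    discarding points whose residual exceeds ``trim`` * rms (robustness to
    sparse surface defects).  Requires >= 4 non-coplanar points.
    """
    p = np.asarray(points, float)
    if p.ndim != 2 or len(p) < 4:
        raise MorphologyError("sphere fit needs at least 4 points")
    if np.linalg.matrix_rank(p - p.mean(0), tol=1e-8 * max(1.0, np.abs(p).max())) < 3:
        raise MorphologyError("sphere fit needs non-coplanar points")

    def _fit(q):
        A = np.hstack([2 * q, np.ones((len(q), 1))])
        b = (q ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        centre, d = sol[:3], sol[3]
        radius = np.sqrt(max(d + centre @ centre, 0.0))
        res = np.linalg.norm(q - centre, axis=1) - radius
        return centre, radius, res

    centre, radius, res = _fit(p)
    if trim is not None:
        for _ in range(2):
            rms = np.sqrt(np.mean(res ** 2))
            keep = np.abs(res) <= max(trim * rms, 1e-12)
            if keep.sum() < 4 or keep.all():
                break
            centre, radius, res = _fit(p[keep])
            p = p[keep]
    return centre, radius, float(np.sqrt(np.mean(res ** 2)))


def fit_circle(points3: np.ndarray, normal: np.ndarray, trim: float | None = 3.0):
    """Circle fit of 3-D points projected onto the plane of ``normal``.

    Returns (centre3d, radius, rms) with the centre placed at the mean
    height of the points along the normal.
    """
    n = normal / np.linalg.norm(normal)
    e1 = np.cross(n, [1.0, 0, 0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0, 1.0, 0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    p = np.asarray(points3, float)
    if len(p) < 3:
        raise MorphologyError("circle fit needs at least 3 points")
    q = np.stack([p @ e1, p @ e2], axis=1)

    def _fit(qq):
        A = np.hstack([2 * qq, np.ones((len(qq), 1))])
        b = (qq ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        c, d = sol[:2], sol[2]
        r = np.sqrt(max(d + c @ c, 0.0))
        return c, r, np.linalg.norm(qq - c, axis=1) - r

    c, r, res = _fit(q)
    if trim is not None:
        for _ in range(2):
            rms = np.sqrt(np.mean(res ** 2))
            keep = np.abs(res) <= max(trim * rms, 1e-12)
            if keep.sum() < 3 or keep.all():
                break
            q = q[keep]
            c, r, res = _fit(q)
    height = float(np.mean(points3 @ n))
    centre3 = c[0] * e1 + c[1] * e2 + height * n
    return centre3, float(r), float(np.sqrt(np.mean(res ** 2)))


def _closest_approach(p1, d1, p2, d2):
    """Midpoint of the common perpendicular of two (possibly skew) lines."""
    d1, d2 = d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2)
    r = p2 - p1
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    den = a * c - b * b
    if den < 1e-12:
        return p1 + (r @ d1) * d1  # parallel: project
    t1 = (c * (r @ d1) - b * (r @ d2)) / den
    t2 = (b * (r @ d1) - a * (r @ d2)) / den
    return 0.5 * (p1 + t1 * d1 + p2 + t2 * d2)


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

def _head_fit(mesh: TetMesh, pts: np.ndarray, u: np.ndarray):
    if "femoral_head" in mesh.node_sets:
        hp = mesh.nodes[mesh.node_sets["femoral_head"]]
    else:  # top 15% of the longitudinal extent
        s = pts @ u
        hp = pts[s > s.min() + 0.85 * (s.max() - s.min())]
    centre, radius, rms = fit_sphere(hp)
    if rms > 0.02 * radius:
        raise MorphologyError(
            f"no spherical femoral head found (fit rms {rms:.2f} mm "
            f"on radius {radius:.2f} mm)")
    return centre, radius, rms


def build_planes_and_axes(mesh: TetMesh, slab_half: float | None = None) -> dict:
    """Longitudinal direction, 50%/80% transversal planes, shaft and neck axes.

    Raises :class:`MorphologyError` for degenerate geometry (empty cross
    sections, or no spherical head to carry the neck axis).
    """
    surf = mesh.surface_nodes
    pts = mesh.nodes[surf]
    # principal axis of the surface cloud, oriented proximally (toward head)
    c0 = pts.mean(axis=0)
    u = np.linalg.svd(pts - c0, full_matrices=False)[2][0]
    if "femoral_head" in mesh.node_sets:
        if (mesh.nodes[mesh.node_sets["femoral_head"]].mean(0) - c0) @ u < 0:
            u = -u
    else:
        # proximal (head) end has the smaller transverse spread
        s = pts @ u
        spread = []
        for sel in (s > s.max() - 0.1 * (s.max() - s.min()),
                    s < s.min() + 0.1 * (s.max() - s.min())):
            q = pts[sel] - pts[sel].mean(0)
            spread.append(np.linalg.norm(q - np.outer(q @ u, u), axis=1).mean())
        if spread[0] > spread[1]:
            u = -u
    if slab_half is None:
        sizes = np.linalg.norm(mesh.nodes[mesh.surface[:, 0]]
                               - mesh.nodes[mesh.surface[:, 1]], axis=1)
        slab_half = max(1.5, 0.7 * float(np.median(sizes)))
    # exclude trochanters/head/neck/condyles from the shaft sections
    excl = np.zeros(len(mesh.nodes), bool)
    for name in ("greater_trochanter", "lesser_trochanter", "femoral_head",
                 "neck", "medial_condyle", "lateral_condyle"):
        if name in mesh.node_sets:
            excl[mesh.node_sets[name]] = True
    shaft_pts = pts[~excl[surf]]

    centres = None
    for _ in range(15):
        s = pts @ u
        s0, L = s.min(), s.max() - s.min()
        ss = shaft_pts @ u
        centres = []
        for f in (0.5, 0.8):
            sel = np.abs(ss - (s0 + f * L)) < slab_half
            if sel.sum() < 8:
                raise MorphologyError(f"empty shaft cross-section at {f:.0%} of L")
            c3, _, _ = fit_circle(shaft_pts[sel], u)
            centres.append(c3)
        u_new = centres[1] - centres[0]
        u_new /= np.linalg.norm(u_new)
        if u_new @ u < 0:
            u_new = -u_new
        done = np.arccos(np.clip(u_new @ u, -1, 1)) < 1e-12
        u = u_new
        if done:
            break
    shaft_point, shaft_dir = centres[0], u
    s = pts @ u
    L = float(s.max() - s.min())

    # neck axis: line through the head centre and the centroid of the
    # minimal-area neck cross-section, swept along the head->shaft direction
    fhc, r_head, head_rms = _head_fit(mesh, pts, u)
    v_axis = fhc - (shaft_point + ((fhc - shaft_point) @ u) * u)
    if np.linalg.norm(v_axis) < 1.2 * r_head:
        raise MorphologyError("head centre lies on the shaft axis: no neck")
    if "neck" in mesh.node_sets:
        d = mesh.nodes[mesh.node_sets["neck"]].mean(0) - fhc
    else:  # down toward the shaft axis at roughly 45 degrees
        d = -v_axis - 1.2 * r_head * u
    d = d / np.linalg.norm(d)
    # neck candidate pool: the neck node set when present, otherwise every
    # surface node off the head sphere (the inner radial band at each
    # station then isolates the neck, the closest surface to its axis)
    if "neck" in mesh.node_sets:
        pool = mesh.nodes[mesh.node_sets["neck"]]
    else:
        pool = pts[np.linalg.norm(pts - fhc, axis=1) > 1.04 * r_head]
    for _ in range(5):
        best = None
        q = pool - fhc
        a = q @ d
        rad = np.linalg.norm(q - np.outer(a, d), axis=1)
        for st in np.linspace(1.08 * r_head, 2.2 * r_head, 14):
            sel = np.abs(a - st) < slab_half
            if sel.sum() < 8:
                continue
            inner = np.percentile(rad[sel], 15)
            ring = pool[sel & (rad < inner + 2.5)]
            if len(ring) < 8:
                continue
            c3, r, _ = fit_circle(ring, d)
            if best is None or r < best[1]:
                best = (c3, r, st)
        if best is None:
            raise MorphologyError("no neck cross-sections found")
        d_new = best[0] - fhc
        d_new /= np.linalg.norm(d_new)
        d = d_new
    neck_waist, r_neck = best[0], best[1]
    neck_dir = (fhc - neck_waist) / np.linalg.norm(fhc - neck_waist)

    return {"longitudinal": u, "L": L, "s_min": float(s.min()),
            "shaft_point": shaft_point, "shaft_dir": shaft_dir,
            "plane_points": centres, "fhc": fhc, "head_radius": r_head,
            "head_rms": head_rms, "neck_point": neck_waist,
            "neck_dir": neck_dir, "neck_radius": r_neck}


def measure(mesh: TetMesh) -> MorphologyReport:
    """Full morphological parameter set of a femur surface mesh."""
    ax = build_planes_and_axes(mesh)
    u, fhc = ax["longitudinal"], ax["fhc"]
    shaft_point, shaft_dir = ax["shaft_point"], ax["shaft_dir"]
    neck_dir = ax["neck_dir"]

    fna = float(np.degrees(np.arccos(np.clip(neck_dir @ (-shaft_dir), -1, 1))))
    osn = _closest_approach(shaft_point, shaft_dir, fhc, neck_dir)
    v = fhc - (shaft_point + ((fhc - shaft_point) @ shaft_dir) * shaft_dir)
    osa = float(np.linalg.norm(v))

    # condylar (mediolateral) line from the two condyle sets
    try:
        c_med, _, _ = fit_sphere(mesh.nodes[mesh.node_sets["medial_condyle"]])
        c_lat, _, _ = fit_sphere(mesh.nodes[mesh.node_sets["lateral_condyle"]])
    except KeyError as e:
        raise MorphologyError(f"missing condyle node set: {e}") from e
    cd = c_med - c_lat
    e_ml = cd - (cd @ u) * u
    e_ml /= np.linalg.norm(e_ml)
    osh = float(abs(v @ e_ml))

    # lesser trochanter centre and vertical offset
    try:
        ltc, _, _ = fit_sphere(mesh.nodes[mesh.node_sets["lesser_trochanter"]])
    except KeyError as e:
        raise MorphologyError(f"missing lesser trochanter set: {e}") from e
    osv = float(abs((fhc - ltc) @ u))

    gt = mesh.nodes[mesh.node_sets["greater_trochanter"]] if \
        "greater_trochanter" in mesh.node_sets else None
    if gt is None:
        raise MorphologyError("missing greater trochanter set")
    gth = float((gt @ u).max() - fhc @ u)

    # anteversion: neck axis vs condylar line in the transverse plane
    nt = neck_dir - (neck_dir @ u) * u
    nt /= np.linalg.norm(nt)
    ata = float(np.degrees(np.arccos(np.clip(abs(nt @ e_ml), -1, 1))))

    rep = MorphologyReport(FHC=fhc, FHD=2 * ax["head_radius"], L=ax["L"],
                           FNA=fna, OSN=osn, OSA=osa, OSH=osh, OSV=osv,
                           LTC=ltc, GTH=gth, ATA=ata)
    rep.validate()
    return rep
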