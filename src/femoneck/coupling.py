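"""Body-organ coupling: frame registration and the quasi-static gait sweep.

The body-level model and the organ-level FE mesh live in different image
frames (MRI-derived kinematic model vs CT-derived femur).  An iterative
closest point (ICP) registration recovers the rigid map between them; the
per-interval muscle forces are then transferred as point loads at the
closest FE surface nodes and one linear solve is run per gait interval
(quasi-static: inertial terms zeroed).  The static-equivalence residual
compares the joint-contact-force resultant of the body model with the FE
reaction resultant per interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import msk, post
from .fe import FEModel, LoadCase, select_bc_nodes
from .materials import PowerLaw, build_material_map
from .mesh import TetMesh
from .subject import (SubjectSpec, generate_density, generate_femur,
                      generate_gait)

__all__ = ["RigidTransform", "ResidualReport", "SweepResult", "icp_register",
           "place_muscle_loads", "misalign_mesh", "run_gait_sweep",
           "check_static_equivalence"]

# default synthetic body-vs-CT frame misalignment, so ICP is genuinely
# exercised: 15 degrees about a fixed oblique axis plus a 20 mm shift
DEFAULT_MISALIGNMENT = (15.0, np.array([0.36, 0.48, 0.80]),
                        np.array([12.0, -9.0, 13.0]))


@dataclass
class RigidTransform:
    """p_target = R @ p_source + t."""

    R: np.ndarray
    t: np.ndarray
    rms: float = 0.0
    iterations: int = 0
    converged: bool = True

    def apply(self, p: np.ndarray) -> np.ndarray:
        return np.atleast_2d(p) @ self.R.T + self.t

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return np.atleast_2d(v) @ self.R.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t, self.rms,
                              self.iterations, self.converged)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def validate(self) -> None:
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("rotation is a reflection")


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit dst ~ R src + t for known correspondences."""
    cs, cd = src.mean(0), dst.mean(0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return RigidTransform(R, cd - R @ cs)


def icp_register(source: np.ndarray, target: np.ndarray, tol: float = 1e-6,
                 max_iter: int = 200, init: str = "pca") -> RigidTransform:
    """Point-to-point ICP with SVD (Kabsch) updates.

    Initialised by centroid + principal-axes alignment (best of the four
    proper-rotation sign combinations) unless ``init='identity'``.
    Non-convergence within ``max_iter`` returns the best transform found,
    flagged ``converged=False`` with a warning.
    """
    src = np.asarray(source, float)
    dst = np.asarray(target, float)
    if len(src) < 3 or len(dst) < 3:
        raise ValueError("ICP needs at least 3 points per cloud")
    if np.linalg.matrix_rank(src - src.mean(0), tol=1e-9) < 2:
        raise ValueError("source points are collinear")
    tree = cKDTree(dst)

    def rms_of(T):
        d, _ = tree.query(T.apply(src))
        return float(np.sqrt(np.mean(d ** 2)))

    best = RigidTransform(np.eye(3), dst.mean(0) - src.mean(0))
    if init == "pca":
        Us = np.linalg.svd(src - src.mean(0), full_matrices=False)[2]
        Ud = np.linalg.svd(dst - dst.mean(0), full_matrices=False)[2]
        cands = []
        for s1 in (1, -1):
            for s2 in (1, -1):
                A = Us * np.array([s1, s2, s1 * s2])[:, None]
                R = Ud.T @ A
                if np.linalg.det(R) < 0:
                    R = (Ud * np.array([1, 1, -1])[:, None]).T @ A
                T = RigidTransform(R, dst.mean(0) - R @ src.mean(0))
                cands.append((rms_of(T), T))
        best = min(cands, key=lambda c: c[0])[1]

    T = best
    prev_rms = np.inf
    for it in range(1, max_iter + 1):
        moved = T.apply(src)
        d, j = tree.query(moved)
        rms = float(np.sqrt(np.mean(d ** 2)))
        if abs(prev_rms - rms) < tol:
            T.rms, T.iterations, T.converged = rms, it, True
            return T
        prev_rms = rms
        T = _kabsch(src, dst[j])
    T.rms, T.iterations, T.converged = prev_rms, max_iter, False
    warnings.warn(f"ICP did not converge in {max_iter} iterations "
                  f"(rms {prev_rms:.3g} mm)", stacklevel=2)
    return T


def misalign_mesh(mesh: TetMesh, angle_deg: float, axis: np.ndarray,
                  translation: np.ndarray) -> tuple[TetMesh, RigidTransform]:
    """Rigidly transformed copy of a mesh (stand-in for the CT frame)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    T = RigidTransform(R, np.asarray(translation, float))
    gt = dict(mesh.ground_truth)
    for key in ("FHC", "OSN", "LTC", "knee_centre"):
        if key in gt:
            gt[key] = T.apply(gt[key])[0]
    for key in ("shaft_axis", "neck_axis", "condylar_dir"):
        if key in gt:
            gt[key] = T.rotate(gt[key])[0]
    out = TetMesh(T.apply(mesh.nodes), mesh.tets.copy(), mesh.surface.copy(),
                  {k: v.copy() for k, v in mesh.node_sets.items()},
                  {k: T.rotate(v)[0] for k, v in mesh.frame.items()}, gt)
    return out, T


def place_muscle_loads(attachments: np.ndarray, forces: np.ndarray,
                       mesh: TetMesh, transform: RigidTransform | None = None,
                       warn_mm: float = 2.0, err_mm: float = 10.0,
                       bc_mode: str = "relaxed_three_node",
                       interval: int | None = None,
                       tree: cKDTree | None = None):
    """Transfer body-frame forces to nearest-surface-node point loads.

    Returns (LoadCase, distances).  The sum of nodal loads equals the sum
    of the transformed forces exactly; per-attachment placement distances
    are recorded, with a warning above ``warn_mm`` and an error above
    ``err_mm`` (a likely mis-registration).
    """
    p = np.atleast_2d(np.asarray(attachments, float))
    f = np.atleast_2d(np.asarray(forces, float))
    if transform is not None:
        p, f = transform.apply(p), transform.rotate(f)
    surf = mesh.surface_nodes
    if tree is None:
        tree = cKDTree(mesh.nodes[surf])
    d, j = tree.query(p)
    if d.max() > err_mm:
        raise ValueError(f"attachment {int(np.argmax(d))} lies "
                         f"{d.max():.1f} mm from the surface: mis-registration?")
    if d.max() > warn_mm:
        warnings.warn(f"attachment placement distance {d.max():.2f} mm "
                      f"exceeds {warn_mm} mm", stacklevel=2)
    nodes = surf[j]
    uniq, inv = np.unique(nodes, return_inverse=True)
    agg = np.zeros((len(uniq), 3))
    np.add.at(agg, inv, f)
    return LoadCase(uniq, agg, bc_mode, interval), d


@dataclass
class ResidualReport:
    """Per-interval static-equivalence residuals (the quasi-static force
    balance: body mass times acceleration is zeroed, so muscle plus joint
    forces should cancel; delta collects what does not)."""

    pct: np.ndarray
    delta: np.ndarray            # (n, 3) residual force vector, femur frame, N
    delta_mag: np.ndarray        # N
    jcf_net: np.ndarray          # N
    r_fem: np.ndarray            # N
    pct_delta: np.ndarray        # %, NaN where JCF_net ~ 0
    placement_mm: np.ndarray     # (n, k) per-muscle placement distances
    body_mass: float = 0.0
    acceleration: float = 0.0    # quasi-static mode: identically zero

    def validate(self):
        ok = ~np.isnan(self.pct_delta)
        if np.any(self.pct_delta[ok] < 0):
            raise ValueError("%delta must be non-negative")


def check_static_equivalence(report: ResidualReport,
                             threshold_pct: float = 10.0) -> pd.DataFrame:
    """Flag intervals whose |JCF_net - R_FEM|/JCF_net exceeds the threshold.

    Intervals with JCF_net ~ 0 (deep swing) are reported on the absolute
    residual instead, with ``defined`` False.
    """
    defined = ~np.isnan(report.pct_delta)
    ok = np.where(defined, report.pct_delta <= threshold_pct, True)
    return pd.DataFrame({"gait_pct": report.pct, "defined": defined,
                         "pct_delta": report.pct_delta,
                         "abs_delta": np.abs(report.jcf_net - report.r_fem),
                         "pass": ok})


@dataclass
class SweepResult:
    results: pd.DataFrame
    report: post.CouplingReport
    residual: ResidualReport
    icp: RigidTransform
    mesh: TetMesh                  # organ (CT-frame) mesh
    snapshots: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        import json
        import os
        os.makedirs(outdir, exist_ok=True)
        self.results.to_csv(f"{outdir}/results.csv", index=False,
                            float_format="%.10g")
        self.report.to_json(f"{outdir}/coupling_report.json")
        summary = {
            "peak_e1_pct": self.report.overall_peak_e1_pct,
            "peak_e3_pct": self.report.overall_peak_e3_pct,
            "peak_gait_pct": self.report.overall_pct_e1,
            "strain_peaks_pct": self.report.strain_peaks_pct,
            "elastic_check": self.report.elastic_check,
            "regressions": self.report.regressions,
            "icp_rms_mm": self.icp.rms,
            "max_stance_pct_delta": float(np.nanmax(
                self.results.loc[self.results.stance, "pct_delta"])),
        }
        with open(f"{outdir}/summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        from .mesh import write_vtu
        for pct, fld in self.snapshots.items():
            write_vtu(f"{outdir}/strain_{pct:03d}.vtu", self.mesh.nodes,
                      self.mesh.tets,
                      point_data={"u": fld.displacements,
                                  "e1": fld.principal[:, 0],
                                  "e3": fld.principal[:, 2]},
                      cell_data={"strain": fld.element_strain})


def run_gait_sweep(spec: SubjectSpec, bc_mode: str = "relaxed_three_node",
                   include_weight: bool = True, quadratic: bool = False,
                   misalignment=DEFAULT_MISALIGNMENT, radius_mm: float = 3.0,
                   snapshot_pcts=(15, 30, 50, 75), keep_snapshots: bool = False,
                   apply_hip_jcf: bool = False) -> SweepResult:
    """End-to-end body-organ pipeline on one synthetic subject.

    Generates anatomy/materials/linkage/gait, solves the body model,
    registers the body frame onto the (deliberately misaligned) CT-frame
    mesh by ICP, and runs the 100 quasi-static FE solves.  The FE load set
    is the femur-attached FE-model muscle forces plus (by default) the
    femur segment weight, i.e. every external force on the femur free body
    except the joint contact forces; ``apply_hip_jcf`` adds the hip JCF as
    an explicit head load for sensitivity studies.
    """
    mesh = generate_femur(spec)
    image = generate_density(spec, mesh)
    materials = build_material_map(mesh, image, PowerLaw())
    linkage = msk.build_linkage(spec, mesh)
    trial = generate_gait(spec)
    moments, solution, jloads = msk.solve_gait(linkage, trial)

    ct_mesh, true_T = misalign_mesh(mesh, *misalignment)
    icp = icp_register(linkage.surface_sample, ct_mesh.nodes[ct_mesh.surface_nodes])
    icp.validate()

    if quadratic:
        ct_fe_mesh = ct_mesh.to_quadratic()
    else:
        ct_fe_mesh = ct_mesh
    model = FEModel(ct_fe_mesh, materials)
    model.apply_constraints(select_bc_nodes(ct_fe_mesh, bc_mode))

    region = post.neck_region(ct_mesh)
    neigh = post.surface_neighbourhoods(ct_mesh, region, radius_mm)
    tree = cKDTree(ct_mesh.nodes[ct_mesh.surface_nodes])

    n_t = len(trial.pct)
    e1 = np.zeros(n_t)
    e3 = np.zeros(n_t)
    locs = np.zeros((n_t, 3))
    r_fem = np.zeros(n_t)
    delta = np.zeros((n_t, 3))
    placements = []
    snapshots = {}
    stance = trial.grf[:, 2] > 0
    for t in range(n_t):
        pts, fvs = msk.femur_loads(linkage, solution, t,
                                   include_weight=include_weight)
        if apply_hip_jcf:
            pts = np.vstack([pts, linkage.hip_centre])
            fvs = np.vstack([fvs, jloads.jcf_hip[t]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lc, dists = place_muscle_loads(pts, fvs, ct_mesh, icp,
                                           bc_mode=bc_mode, interval=t + 1,
                                           tree=tree)
        placements.append(dists)
        try:
            fld = model.solve(lc, validate_loads=False)
        except Exception as e:
            raise RuntimeError(f"FE solve failed at gait interval {t + 1}: {e}")
        pk = post.averaged_peak(fld, ct_mesh, region, radius_mm, neigh)
        e1[t], e3[t] = pk.peak_e1_pct, pk.peak_e3_pct
        locs[t] = pk.loc_e1
        r_fem[t] = fld.r_fem
        # residual: applied loads (back in the body frame) plus joint forces
        applied_msk = icp.inverse().rotate(np.asarray(lc.forces).sum(axis=0))[0]
        delta[t] = applied_msk + jloads.jcf_hip[t] + jloads.jcf_knee[t]
        if int(trial.pct[t]) in snapshot_pcts and keep_snapshots:
            snapshots[int(trial.pct[t])] = fld

    jcf_net = jloads.jcf_net
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_delta = np.where(jcf_net > 1.0,
                             np.abs(jcf_net - r_fem) / jcf_net * 100.0, np.nan)
    residual = ResidualReport(trial.pct, delta, np.linalg.norm(delta, axis=1),
                              jcf_net, r_fem, pct_delta,
                              np.array(placements, dtype=object),
                              body_mass=spec.body_mass)
    residual.validate()

    names = solution.names
    glutmed = solution.forces[:, names.index("gluteus_medius")]
    bw = spec.body_weight
    hip_mag = np.linalg.norm(jloads.jcf_hip, axis=1)
    knee_mag = np.linalg.norm(jloads.jcf_knee, axis=1)
    results = pd.DataFrame({
        "gait_pct": trial.pct, "stance": stance,
        "JCF_hip": hip_mag, "JCF_knee": knee_mag, "JCF_net": jcf_net,
        "R_FEM": r_fem, "pct_delta": pct_delta,
        "e1_pct": e1, "e3_pct": e3,
        "glutmed_N": glutmed, "glutmed_BW": glutmed / bw,
        "hip_JCF_BW": hip_mag / bw, "grf_z_BW": trial.grf[:, 2] / bw,
    })
    report = post.CouplingReport(trial.pct, e1, e3, locs).finalise(
        glutmed_bw=glutmed / bw, hip_jcf_bw=hip_mag / bw)
    return SweepResult(results, report, residual, icp, ct_mesh, snapshots)
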