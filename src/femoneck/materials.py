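"""Density-to-elasticity material mapping.

Maps a calibrated radiological density image to per-element isotropic
Young's moduli: phantom-based linear calibration of raw scanner values,
quadrature-averaged element densities on the tetrahedral mesh, and a
configurable density-modulus power law (default a Morgan-type
E = 6850 * rho_app^1.49 MPa with rho_app in g/cm^3).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh

__all__ = ["MaterialMap", "PowerLaw", "calibrate", "element_density",
           "modulus_from_density", "build_material_map"]

# 4-point Gauss rule for tetrahedra (degree 2), barycentric coordinates
_A, _B = 0.5854101966249685, 0.1381966011250105
_TET4_QP = np.array([
    [_A, _B, _B, _B], [_B, _A, _B, _B], [_B, _B, _A, _B], [_B, _B, _B, _A]])


@dataclass(frozen=True)
class PowerLaw:
    """E = a * (rho/1000)^b MPa for rho in mg/cm^3, floored at e_min."""

    a: float = 6850.0
    b: float = 1.49
    e_min: float = 1.0  # MPa

    def __call__(self, rho):
        return modulus_from_density(rho, (self.a, self.b), self.e_min)


@dataclass
class MaterialMap:
    E: np.ndarray              # per-element Young's modulus, MPa
    nu: float                  # Poisson ratio, global
    rho: np.ndarray            # per-element mean density, mg/cm^3
    calibration: tuple | None = None   # (slope, intercept, r2)
    law: PowerLaw = PowerLaw()

    def validate(self, mesh: TetMesh | None = None) -> None:
        if not np.all(self.E > 0):
            raise ValueError("all element moduli must be positive")
        if not 0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if len(self.E) != len(self.rho):
            raise ValueError("E and rho must have one entry per element")
        if mesh is not None and len(self.E) != mesh.n_tets:
            raise ValueError("material map does not match the mesh")

    def to_csv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame({"element_id": np.arange(len(self.E)),
                      "rho": self.rho, "E": self.E}).to_csv(
            path, index=False, float_format="%.6g")


def calibrate(phantom_samples) -> tuple[float, float, float]:
    """Least-squares line raw -> density from phantom inserts.

    Returns (slope, intercept, r_squared); needs >= 2 distinct raw values.
    """
    raw = np.asarray([s[0] for s in phantom_samples], float)
    rho = np.asarray([s[1] for s in phantom_samples], float)
    if len(raw) < 2 or np.ptp(raw) == 0:
        raise ValueError("calibration needs at least two distinct raw values")
    slope, intercept = np.polyfit(raw, rho, 1)
    pred = slope * raw + intercept
    ss_res = float(((rho - pred) ** 2).sum())
    ss_tot = float(((rho - rho.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def element_density(mesh: TetMesh, image, order: int = 2,
                    calibration: tuple | None = None) -> np.ndarray:
    """Quadrature-averaged density per element (mg/cm^3).

    The image is sampled trilinearly at the Gauss points of each (straight
    sided) tetrahedron; ``order`` 1 uses the centroid alone.  Raises if an
    element lies outside the image, naming it.
    """
    corners = mesh.nodes[mesh.tets[:, :4]]        # (m, 4, 3)
    qp = np.array([[0.25, 0.25, 0.25, 0.25]]) if order <= 1 else _TET4_QP
    pts = np.einsum("qa,maj->mqj", qp, corners)   # (m, q, 3)
    flat = pts.reshape(-1, 3)
    v = image.world_to_voxel(flat)
    shape = np.array(image.data.shape)
    out_mask = np.any((v < -0.5) | (v > shape - 0.5), axis=1)
    if out_mask.any():
        bad = int(np.nonzero(out_mask.reshape(len(corners), -1).any(axis=1))[0][0])
        raise ValueError(f"element {bad} lies outside the density image")
    vals = image.sample(flat)
    if calibration is not None:
        slope, intercept = calibration[:2]
        vals = slope * vals + intercept
    elif not image.calibrated:
        raise ValueError("image is in raw units; pass a calibration")
    return vals.reshape(len(corners), -1).mean(axis=1)


def modulus_from_density(rho, law=(6850.0, 1.49), e_min: float = 1.0):
    """Power-law modulus E = a*(rho/1000)^b MPa, floored at ``e_min``.

    ``rho`` in mg/cm^3 (so rho/1000 is apparent density in g/cm^3);
    monotone in rho; raises for negative densities.
    """
    a, b = law
    rho = np.asarray(rho, float)
    if np.any(rho < 0):
        raise ValueError("negative density")
    return np.maximum(a * (rho / 1000.0) ** b, e_min)


def build_material_map(mesh: TetMesh, image, law: PowerLaw = PowerLaw(),
                       nu: float = 0.3, order: int = 2) -> MaterialMap:
    """Full chain: (calibrate if raw) -> element densities -> moduli."""
    cal = None
    if not image.calibrated:
        cal = calibrate(image.phantom_samples)
    rho = element_density(mesh, image, order=order, calibration=cal)
    mm = MaterialMap(E=law(rho), nu=nu, rho=rho, calibration=cal, law=law)
    mm.validate(mesh)
    return mm
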