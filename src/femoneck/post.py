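"""Femoral-neck strain post-processing.

Extracts the neck region of interest (between the subcapital plane at the
head-sphere boundary and an intertrochanteric plane, both perpendicular to
the neck axis), averages nodal principal strains over 3-mm surface
neighbourhoods before peak extraction (continuum hypothesis: suppress
point-load artefacts), compares peaks against the elastic limits of bone
(0.73% tensile / 1.04% compressive), locates strain-peak timing within the
gait cycle and regresses peak strain against muscle / joint forces.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .mesh import TetMesh

__all__ = ["PeakResult", "CouplingReport", "neck_region", "averaged_peak",
           "compare_elastic_limit", "peak_timing", "correlate",
           "TENSILE_ELASTIC_LIMIT", "COMPRESSIVE_ELASTIC_LIMIT"]

# elastic limits of human cortical bone, % strain
TENSILE_ELASTIC_LIMIT = 0.73
COMPRESSIVE_ELASTIC_LIMIT = 1.04


def neck_region(mesh: TetMesh, axes: dict | None = None,
                margin: float = 0.0) -> np.ndarray:
    """Surface node ids of the femoral-neck region of interest.

    Bounded by the subcapital plane (at the head-sphere boundary) and the
    intertrochanteric plane, both perpendicular to the neck axis.
    """
    if axes is None:
        from . import morphology
        axes = morphology.build_planes_and_axes(mesh)
    fhc, d = axes["fhc"], -np.asarray(axes["neck_dir"])  # head -> shaft
    r_head = axes["head_radius"]
    surf = mesh.surface_nodes
    s = (mesh.nodes[surf] - fhc) @ d
    s_lo = r_head * (1.0 + 0.02) + margin
    # intertrochanteric bound: where the neck axis meets the shaft axis
    s_hi = float(np.linalg.norm(axes["neck_point"] - fhc) * 2.0)
    if "neck" in mesh.node_sets:
        sn = (mesh.nodes[mesh.node_sets["neck"]] - fhc) @ d
        s_hi = min(s_hi, float(sn.max()))
    rad = np.linalg.norm((mesh.nodes[surf] - fhc) - np.outer(s, d), axis=1)
    ids = surf[(s >= s_lo) & (s <= s_hi) & (rad < 1.4 * r_head)]
    if len(ids) == 0:
        raise ValueError("empty femoral-neck region")
    return ids


@dataclass
class PeakResult:
    peak_e1: float           # most tensile averaged strain (dimensionless)
    peak_e3: float           # most compressive averaged strain
    loc_e1: np.ndarray       # mm
    loc_e3: np.ndarray

    @property
    def peak_e1_pct(self) -> float:
        return 100.0 * self.peak_e1

    @property
    def peak_e3_pct(self) -> float:
        return 100.0 * self.peak_e3


def averaged_peak(fieldobj, mesh: TetMesh, region: np.ndarray,
                  radius: float = 3.0, neighbours: dict | None = None) -> PeakResult:
    """Peak principal strains after surface-circle averaging.

    For every region node, e1 and e3 are averaged over surface nodes within
    a Euclidean ``radius`` (mm); the tensile peak is the maximum of the e1
    means, the compressive peak the minimum of the e3 means.  Passing a
    precomputed ``neighbours`` dict (from :func:`surface_neighbourhoods`)
    avoids rebuilding the k-d tree per gait interval.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if neighbours is None:
        neighbours = surface_neighbourhoods(mesh, region, radius)
    e1 = fieldobj.principal[:, 0]
    e3 = fieldobj.principal[:, 2]
    m1 = np.array([e1[nb].mean() for nb in neighbours["lists"]])
    m3 = np.array([e3[nb].mean() for nb in neighbours["lists"]])
    i1, i3 = int(np.argmax(m1)), int(np.argmin(m3))
    return PeakResult(float(m1[i1]), float(m3[i3]),
                      mesh.nodes[region[i1]].copy(), mesh.nodes[region[i3]].copy())


def surface_neighbourhoods(mesh: TetMesh, region: np.ndarray,
                           radius: float) -> dict:
    """Per-region-node lists of surface nodes within ``radius`` mm."""
    import warnings
    surf = mesh.surface_nodes
    span = np.ptp(mesh.nodes[region], axis=0).max()
    if radius > 0 and radius >= span:
        warnings.warn("averaging radius spans the whole region", stacklevel=2)
    if radius == 0:
        return {"lists": [np.array([r]) for r in region], "radius": 0.0}
    tree = cKDTree(mesh.nodes[surf])
    lists = [surf[idx] for idx in
             tree.query_ball_point(mesh.nodes[region], r=radius)]
    return {"lists": lists, "radius": radius}


def compare_elastic_limit(peak_e1_pct: float, peak_e3_pct: float,
                          tensile: float = TENSILE_ELASTIC_LIMIT,
                          compressive: float = COMPRESSIVE_ELASTIC_LIMIT) -> dict:
    """Strict-inequality pass/fail of peak strains against elastic limits.

    Inputs and thresholds in % strain; compressive peaks are compared in
    magnitude.
    """
    return {"tensile_pass": bool(peak_e1_pct < tensile),
            "compressive_pass": bool(abs(peak_e3_pct) < compressive),
            "tensile_limit": tensile, "compressive_limit": compressive}


def peak_timing(series: np.ndarray, prominence_fraction: float = 0.05,
                pct: np.ndarray | None = None) -> list[int]:
    """%gait of local maxima above a prominence floor, ascending.

    The floor is ``prominence_fraction`` of the series range, suppressing
    numerical ripple; a flat series yields an empty list.  The series is
    treated as periodic in the gait cycle.
    """
    y = np.asarray(series, float)
    rng = float(np.ptp(y))
    if rng == 0:
        return []
    if pct is None:
        pct = np.arange(1, len(y) + 1)
    # pad cyclically so a maximum at either end is still detected
    yy = np.concatenate([y[-2:], y, y[:2]])
    locs, _ = find_peaks(yy, prominence=prominence_fraction * rng)
    locs = locs - 2
    locs = locs[(locs >= 0) & (locs < len(y))]
    return sorted(int(pct[i]) for i in locs)


def correlate(strain_series: np.ndarray, force_series: np.ndarray):
    """OLS regression of per-interval peak strain on a normalised force.

    Returns (slope, intercept, r_squared).  Raises on a zero-variance
    predictor.
    """
    x = np.asarray(force_series, float)
    y = np.asarray(strain_series, float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


@dataclass
class CouplingReport:
    """Gait-sweep summary: per-interval peaks, timing, limits, regressions."""

    pct: np.ndarray                 # %gait 1..100
    peak_e1_pct: np.ndarray         # per-interval averaged tensile peak, %
    peak_e3_pct: np.ndarray         # per-interval averaged compressive peak, %
    peak_locations_e1: np.ndarray   # (n, 3) mm
    overall_peak_e1_pct: float = 0.0
    overall_peak_e3_pct: float = 0.0
    overall_pct_e1: int = 0         # %gait of the overall tensile peak
    strain_peaks_pct: list = field(default_factory=list)
    elastic_check: dict = field(default_factory=dict)
    regressions: dict = field(default_factory=dict)

    def finalise(self, glutmed_bw: np.ndarray | None = None,
                 hip_jcf_bw: np.ndarray | None = None,
                 prominence_fraction: float = 0.05) -> "CouplingReport":
        i = int(np.argmax(self.peak_e1_pct))
        self.overall_peak_e1_pct = float(self.peak_e1_pct[i])
        self.overall_pct_e1 = int(self.pct[i])
        self.overall_peak_e3_pct = float(self.peak_e3_pct.min())
        self.strain_peaks_pct = peak_timing(self.peak_e1_pct,
                                            prominence_fraction, self.pct)
        self.elastic_check = compare_elastic_limit(self.overall_peak_e1_pct,
                                                   self.overall_peak_e3_pct)
        if glutmed_bw is not None:
            self.regressions["e1_vs_glutmed"] = correlate(self.peak_e1_pct,
                                                          glutmed_bw)
        if hip_jcf_bw is not None:
            self.regressions["e1_vs_hip_jcf"] = correlate(self.peak_e1_pct,
                                                          hip_jcf_bw)
        return self

    def to_json(self, path: str) -> None:
        import json

        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in asdict(self).items()}, fh, indent=1)
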