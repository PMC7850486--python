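"""Body-level solve for the default subject: inverse dynamics, static
optimisation, joint reaction analysis.

Writes results/muscle_forces.csv (per-interval muscle forces and joint
contact forces) and prints the peak gluteus medius force and hip JCF in
body weights.
"""
import pathlib

import numpy as np
import pandas as pd

from femoneck import msk, subject

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

spec = subject.SubjectSpec()
mesh = subject.generate_femur(spec)
linkage = msk.build_linkage(spec, mesh)
trial = subject.generate_gait(spec)
moments, solution, loads = msk.solve_gait(linkage, trial)

df = pd.DataFrame(solution.forces, columns=solution.names)
df.insert(0, "gait_pct", trial.pct)
df["JCF_hip"] = np.linalg.norm(loads.jcf_hip, axis=1)
df["JCF_knee"] = np.linalg.norm(loads.jcf_knee, axis=1)
df["JCF_net"] = loads.jcf_net
df.to_csv(OUT / "muscle_forces.csv", index=False, float_format="%.6g")

bw = spec.body_weight
gm = df["gluteus_medius"]
print(f"peak gluteus medius force {gm.max():.0f} N "
      f"({gm.max() / bw:.2f} BW) at {int(df.gait_pct[gm.idxmax()])}% gait")
print(f"peak hip JCF {df.JCF_hip.max():.0f} N ({df.JCF_hip.max() / bw:.2f} BW)")
print(f"peak reserve torque {np.abs(solution.reserves).max():.3f} N.m "
      f"({100 * np.abs(solution.reserves).max() / moments.abs().max().max():.2f}% "
      f"of the peak joint moment)")
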