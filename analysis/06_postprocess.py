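"""Post-process the gait sweep: peak timing, elastic-limit check and the
strain-force regressions (peak e1 vs gluteus medius force and vs hip JCF,
both normalised by body weight).

Reads results/sweep/results.csv (run 05_gait_sweep.py first) and writes
results/coupling_summary.json.
"""
import json
import pathlib

import numpy as np
import pandas as pd

from femoneck import post

BASE = pathlib.Path(__file__).resolve().parents[1] / "results"
df = pd.read_csv(BASE / "sweep" / "results.csv")

rep = post.CouplingReport(df["gait_pct"].to_numpy(), df["e1_pct"].to_numpy(),
                          df["e3_pct"].to_numpy(), np.zeros((len(df), 3)))
rep.finalise(glutmed_bw=df["glutmed_BW"].to_numpy(),
             hip_jcf_bw=df["hip_JCF_BW"].to_numpy())

stance_peaks = [p for p in rep.strain_peaks_pct
                if df.loc[df.gait_pct == p, "stance"].iloc[0]]
summary = {
    "peak_e1_pct": rep.overall_peak_e1_pct,
    "peak_e3_pct": rep.overall_peak_e3_pct,
    "peak_gait_pct": rep.overall_pct_e1,
    "stance_strain_peaks_pct": stance_peaks,
    "elastic_check": rep.elastic_check,
    "r2_e1_vs_glutmed": rep.regressions["e1_vs_glutmed"][2],
    "r2_e1_vs_hip_jcf": rep.regressions["e1_vs_hip_jcf"][2],
}
with open(BASE / "coupling_summary.json", "w") as fh:
    json.dump(summary, fh, indent=1)

print(f"stance strain peaks at {stance_peaks}% gait "
      f"(generator double-support instants: 15% and 50%)")
print(f"peak e1 {summary['peak_e1_pct']:.3f}% "
      f"-> tensile pass: {summary['elastic_check']['tensile_pass']}")
print(f"R^2 e1 vs gluteus medius/BW: {summary['r2_e1_vs_glutmed']:.3f}; "
      f"e1 vs hip JCF/BW: {summary['r2_e1_vs_hip_jcf']:.3f}")
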