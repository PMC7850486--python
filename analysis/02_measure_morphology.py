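"""Measure femoral morphology on the five case presets and compare with
the prescribed (generator ground-truth) values.

Writes results/morphology.csv: one row per case, measured alongside
prescribed, mirroring the study's per-case morphology table layout.
"""
import pathlib

import pandas as pd

from femoneck import morphology, subject

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for case in range(1, 6):
    spec = subject.case_preset(case)
    mesh = subject.generate_femur(spec)
    rep = morphology.measure(mesh)
    gt = mesh.ground_truth
    row = {"case": case}
    for k in rep.TABLE_COLUMNS:
        row[k] = round(float(getattr(rep, k)), 2)
        row[f"{k}_prescribed"] = round(float(gt[k]), 2)
    rows.append(row)
    print(f"case {case}: FHD {row['FHD']} (prescribed {row['FHD_prescribed']}), "
          f"FNA {row['FNA']} ({row['FNA_prescribed']}), "
          f"ATA {row['ATA']} ({row['ATA_prescribed']})")

df = pd.DataFrame(rows)
df.to_csv(OUT / "morphology.csv", index=False)
err_len = max(abs(df[k] - df[f"{k}_prescribed"]).max()
              for k in ("FHD", "L", "OSA", "OSH", "OSV", "GTH"))
err_ang = max(abs(df[k] - df[f"{k}_prescribed"]).max() for k in ("FNA", "ATA"))
print(f"worst length error {err_len:.2f} mm, worst angle error {err_ang:.2f} deg")
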