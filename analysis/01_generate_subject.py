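"""Generate the default synthetic subject and the five case-preset femora.

Writes the subject artefacts (mesh, density image, linkage, gait trial)
under results/subject/ and prints basic mesh statistics.
"""
import pathlib

from femoneck import msk, subject

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "subject"
OUT.mkdir(parents=True, exist_ok=True)

spec = subject.SubjectSpec()
mesh = subject.generate_femur(spec)
print(f"default subject: {mesh.n_nodes} nodes, {mesh.n_tets} tets, "
      f"volume {mesh.volumes().sum() / 1000:.0f} cm^3")
mesh.write(str(OUT / "femur.msh"))
mesh.write_meta(str(OUT / "femur_meta.json"))
mesh.write_stl(str(OUT / "femur.stl"))
subject.generate_density(spec, mesh).to_nifti(str(OUT / "density.nii"))
subject.write_gait_csv(subject.generate_gait(spec), str(OUT / "gait.csv"))
msk.linkage_to_json(msk.build_linkage(spec, mesh), str(OUT / "linkage.json"))

for case in range(1, 6):
    cspec = subject.case_preset(case)
    cmesh = subject.generate_femur(cspec)
    gt = cmesh.ground_truth
    print(f"case {case}: FHD {gt['FHD']:.2f} mm, L {gt['L']:.2f} mm, "
          f"FNA {gt['FNA']:.2f} deg -> {cmesh.n_tets} tets")
print(f"artefacts in {OUT}")
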