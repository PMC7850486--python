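"""Synthetic-subject generator: determinism, ground truth, gait invariants."""
import numpy as np
import pytest

from femoneck import subject
from femoneck.subject import (GeometryInfeasibleError, SubjectSpec,
                              case_preset, generate_density, generate_femur,
                              generate_gait, read_gait, sample_spec,
                              write_gait_csv)


class TestFemurGeneration:
    def test_same_seed_bitwise_identical(self, default_spec, femur):
        again = generate_femur(default_spec)
        assert np.array_equal(femur.nodes, again.nodes)
        assert np.array_equal(femur.tets, again.tets)

    def test_case1_ground_truth_matches_prescription(self):
        mesh = generate_femur(case_preset(1, element_size=6.0))
        assert mesh.ground_truth["FNA"] == pytest.approx(128.50)
        assert mesh.ground_truth["FHD"] == pytest.approx(43.88)
        assert mesh.ground_truth["L"] == pytest.approx(426.50)

    def test_refinement_monotonicity(self):
        coarse = generate_femur(SubjectSpec(element_size=6.0))
        fine = generate_femur(SubjectSpec(element_size=4.5))
        assert fine.n_tets > coarse.n_tets

    def test_element_size_honoured_within_20pct(self, femur, default_spec):
        e = femur.nodes[femur.tets]
        edges = [np.linalg.norm(e[:, i] - e[:, j], axis=1)
                 for i in range(4) for j in range(i + 1, 4)]
        mean_edge = float(np.mean(edges))
        assert abs(mean_edge - default_spec.element_size) \
            < 0.2 * default_spec.element_size

    def test_mesh_invariants(self, femur):
        femur.validate()  # positive volumes, closed surface, non-empty sets
        assert all(len(v) > 0 for v in femur.node_sets.values())

    def test_degenerate_geometry_rejected(self):
        # head larger than the whole neck support
        with pytest.raises(GeometryInfeasibleError):
            generate_femur(SubjectSpec(head_diameter=90.0, offset_absolute=20.0))
        with pytest.raises(ValueError):
            SubjectSpec(neck_shaft_angle=190.0).validate()

    def test_sampled_specs_within_cohort_band(self):
        for seed in range(1, 6):
            sp = sample_spec(seed)
            assert 42.98 - 2 * 1.07 <= sp.head_diameter <= 42.98 + 2 * 1.07
            assert 128.62 - 2 * 3.65 <= sp.neck_shaft_angle <= 128.62 + 2 * 3.65


class TestDensityImage:
    def test_in_bone_density_within_levels(self, default_spec, femur, density):
        inside = density.data[density.data > 0]
        assert inside.min() >= default_spec.trabecular_density - 1e-9
        assert inside.max() <= default_spec.cortical_density + 1e-9

    def test_uniform_override(self, default_spec, femur):
        img = generate_density(default_spec, femur, uniform=1234.0, spacing=3.0)
        assert np.all(img.data[img.data > 0] == 1234.0)

    def test_zero_shell_gives_trabecular_interior(self, default_spec, femur):
        img = generate_density(default_spec, femur, shell_mm=0.0, spacing=3.0)
        centre = femur.nodes.mean(axis=0)
        # sample well inside the shaft
        val = img.sample(np.array([[0.0, 0.0, 0.5 * default_spec.femur_length]]))
        assert val[0] == pytest.approx(default_spec.trabecular_density, rel=0.05)

    def test_coarse_spacing_warns(self, default_spec, femur):
        with pytest.warns(UserWarning, match="spacing"):
            generate_density(default_spec, femur, spacing=6.0)

    def test_nifti_roundtrip(self, default_spec, femur, tmp_path):
        img = generate_density(default_spec, femur, spacing=3.0)
        img.to_nifti(str(tmp_path / "d.nii"))
        back = subject.DensityImage.from_nifti(str(tmp_path / "d.nii"))
        assert np.allclose(back.data, img.data, atol=0.1)
        assert np.allclose(back.spacing, img.spacing)


class TestGaitTrial:
    def test_hundred_intervals(self, gait_trial):
        assert len(gait_trial.pct) == 100
        assert list(gait_trial.pct) == list(range(1, 101))

    def test_swing_unloaded(self, gait_trial):
        # 80% of the cycle is swing: GRF exactly zero
        assert np.all(gait_trial.grf[79] == 0.0)
        assert np.all(gait_trial.grf[60:] == 0.0)

    def test_grf_peak_override_scales_to_body_weight(self):
        spec = SubjectSpec(body_mass=70.0, grf_peak_bw=1.2)
        trial = generate_gait(spec)
        assert trial.grf[:, 2].max() == pytest.approx(1.2 * 70.0 * 9.81)

    def test_grf_peaks_at_double_support_instants(self, gait_trial):
        fz = gait_trial.grf[:, 2]
        peaks = [i + 1 for i in range(1, 99)
                 if fz[i] > fz[i - 1] and fz[i] >= fz[i + 1]]
        assert any(abs(p - 15) <= 1 for p in peaks)
        assert any(abs(p - 50) <= 1 for p in peaks)

    def test_bad_stance_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_gait(SubjectSpec(stance_fraction=1.2))

    def test_csv_roundtrip(self, gait_trial, tmp_path):
        path = tmp_path / "gait.csv"
        write_gait_csv(gait_trial, str(path))
        back = read_gait(str(path))
        assert np.allclose(back.grf, gait_trial.grf)
        assert np.allclose(back.angles.to_numpy(), gait_trial.angles.to_numpy())
        assert back.body_mass == gait_trial.body_mass

    def test_mot_dialect_reader(self, gait_trial, tmp_path):
        path = tmp_path / "gait.mot"
        cols = (["gait_pct"] + list(gait_trial.angles.columns)
                + ["grf_x", "grf_y", "grf_z", "cop_x", "cop_y", "cop_z"])
        data = np.column_stack([gait_trial.pct, gait_trial.angles.to_numpy(),
                                gait_trial.grf, gait_trial.cop])
        with open(path, "w") as fh:
            fh.write("trial\nversion=1\nnRows=100\nnColumns=%d\nendheader\n"
                     % len(cols))
            fh.write("\t".join(cols) + "\n")
            for row in data:
                fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
        back = read_gait(str(path), body_mass=gait_trial.body_mass)
        assert np.allclose(back.grf, gait_trial.grf, atol=1e-3)


class TestLinkageGeneration:
    def test_glutmed_inserts_on_greater_trochanter(self, femur, linkage):
        gm = next(m for m in linkage.muscles if m.name == "gluteus_medius")
        gt_nodes = femur.nodes[femur.node_sets["greater_trochanter"]]
        d = np.linalg.norm(gt_nodes - gm.femoral_organ, axis=1)
        assert d.min() < 1e-9  # snapped onto a greater-trochanter node

    def test_hip_centre_is_head_sphere_centre(self, femur, linkage):
        assert np.linalg.norm(linkage.hip_centre
                              - femur.ground_truth["FHC"]) < 1e-9

    def test_femoral_attachments_on_surface(self, femur, linkage):
        surf = femur.nodes[femur.surface_nodes]
        for m in linkage.muscles:
            if m.femoral_end:
                d = np.linalg.norm(surf - m.femoral_organ, axis=1).min()
                assert d < 1.0, m.name

    def test_fe_model_muscle_count(self, linkage):
        # 19 muscles carry the FE flag; 18 of them attach to the femur (the
        # long biceps head spans pelvis to tibia and carries no femur load)
        fe_marked = [m for m in linkage.muscles if m.in_fe_model]
        attached = [m for m in fe_marked if m.femoral_end]
        assert len(fe_marked) == 19
        assert len(attached) == 18

    def test_seven_segments(self, linkage):
        assert len(linkage.segments) == 7
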