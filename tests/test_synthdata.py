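"""Generator contract: symmetric templates, Hardy-Weinberg genotypes,
covariate structure, localized planted effects, seed determinism."""

import numpy as np
import pytest
from scipy import stats

from facemod import synthdata
from facemod.synthdata import SimulationSpec, SnpSpec, generate_template_face


class TestTemplate:
    def test_reflection_relabel_is_identity(self, template64):
        t = template64
        reflected = t.coordinates.copy()
        reflected[:, 0] *= -1
        assert np.array_equal(reflected[t.mirror_map], t.coordinates)

    def test_mirror_map_is_involution(self, template64):
        mm = template64.mirror_map
        assert np.array_equal(mm[mm], np.arange(len(mm)))

    def test_midline_landmarks_on_midsagittal_plane(self, template64):
        t = template64
        midline = np.flatnonzero(t.mirror_map == np.arange(t.n_landmarks))
        assert midline.size > 0
        assert np.all(t.coordinates[midline, 0] == 0.0)

    def test_named_landmarks_anatomically_ordered(self, template64):
        t = template64
        y = {name: t.named_coordinate(name)[1] for name in t.named_landmarks}
        assert y["nasion"] > y["prosthion"] > y["gnathion"]
        assert y["prosthion"] > y["stomion"] > y["gnathion"]
        # zygions are the widest points
        zyg_width = abs(t.named_coordinate("zygion_r")[0])
        assert np.all(np.abs(t.coordinates[:, 0]) <= zyg_width)
        bizygomatic = np.linalg.norm(
            t.named_coordinate("zygion_l") - t.named_coordinate("zygion_r")
        )
        face_height = np.linalg.norm(
            t.named_coordinate("nasion") - t.named_coordinate("gnathion")
        )
        assert bizygomatic > face_height

    @pytest.mark.parametrize("bad_l", [8, 14, 33])
    def test_too_small_or_odd_rejected(self, bad_l):
        with pytest.raises(ValueError):
            generate_template_face(bad_l)


class TestSimulation:
    def test_same_seed_bitwise_identical(self):
        spec = lambda: SimulationSpec(  # noqa: E731
            n_subjects=(40, 30, 50), n_landmarks=32,
            snp_specs=[SnpSpec("a", 0.3)], seed=7,
        )
        c1 = synthdata.simulate_cohorts(spec())
        c2 = synthdata.simulate_cohorts(spec())
        for a, b in zip(c1, c2):
            assert np.array_equal(a.configurations, b.configurations)
            assert np.array_equal(a.genotypes, b.genotypes)

    def test_different_seed_differs(self):
        kw = dict(n_subjects=(40, 30, 50), n_landmarks=32,
                  snp_specs=[SnpSpec("a", 0.3)])
        c1 = synthdata.simulate_cohorts(SimulationSpec(seed=1, **kw))
        c2 = synthdata.simulate_cohorts(SimulationSpec(seed=2, **kw))
        assert not np.array_equal(c1[0].genotypes, c2[0].genotypes)

    def test_hard_calls_in_0_1_2(self, small_study):
        g = small_study.cohorts[0].genotypes
        assert np.isin(g, (0.0, 1.0, 2.0)).all()

    def test_dosage_mode_within_bounds(self):
        spec = SimulationSpec(
            n_subjects=(60, 40, 50), n_landmarks=32,
            snp_specs=[SnpSpec("a", 0.3)], dosage_mode="dosage", seed=3,
        )
        g = synthdata.simulate_cohorts(spec)[0].genotypes
        assert g.min() >= 0 and g.max() <= 2
        assert not np.isin(g, (0.0, 1.0, 2.0)).all()

    def test_allele_frequency_within_binomial_interval(self):
        maf, n = 0.10, 2000
        spec = SimulationSpec(
            n_subjects=(n, 10, 10), n_landmarks=32,
            snp_specs=[SnpSpec("a", maf)], seed=5,
        )
        g = synthdata.simulate_cohorts(spec)[0].genotypes[:, 0]
        freq = g.mean() / 2
        lo, hi = stats.binom.interval(0.99, 2 * n, maf)
        assert lo / (2 * n) <= freq <= hi / (2 * n)

    def test_null_snps_uncorrelated_with_coordinates(self):
        spec = SimulationSpec(
            n_subjects=(400, 10, 10), n_landmarks=32,
            snp_specs=[SnpSpec("a", 0.3, beta=0.0)], seed=9,
        )
        c = synthdata.simulate_cohorts(spec)[0]
        g = c.genotypes[:, 0]
        flat = c.configurations.reshape(c.n, -1)
        r = np.array([np.corrcoef(flat[:, j], g)[0, 1] for j in range(flat.shape[1])])
        # null |r| at n=400 has mean sqrt(2/(pi n)) ~ 0.04; coordinate columns
        # are strongly mutually correlated (rigid transforms), so the raw mean
        # fluctuates on the same scale
        expected = np.sqrt(2 / (np.pi * c.n))
        assert abs(np.mean(r)) < 2 * expected
        assert np.mean(np.abs(r)) < 2 * expected
        assert np.abs(r).max() < 6 / np.sqrt(c.n)

    def test_planted_effect_energy_concentrates_on_module(self):
        spec = SimulationSpec(
            n_subjects=(800, 10, 10), n_landmarks=64, noise_sd=2.0,
            snp_specs=[SnpSpec("hit", 0.25, beta=5.0 * 2.0, target_module="mandible")],
            seed=13,
        )
        study = synthdata.simulate_study(spec)
        c = study.cohorts[0]
        planted = study.planted_landmarks["hit"]
        # remove the rigid nuisance transforms before regressing on dosage
        from facemod.procrustes import gpa, symmetrize

        sym = symmetrize(c.configurations, study.template.mirror_map)
        aligned = gpa(sym).aligned
        g = c.genotypes[:, 0] - c.genotypes[:, 0].mean()
        flat = aligned.reshape(c.n, -1)
        flat = flat - flat.mean(axis=0)
        slopes = (flat.T @ g / (g @ g)).reshape(-1, 3)
        inside = np.sum(slopes[planted] ** 2)
        assert inside / np.sum(slopes**2) > 0.8

    def test_effect_field_is_unit_norm_shape_change(self, small_study):
        field = small_study.effect_fields["rs_planted"]
        planted = small_study.planted_landmarks["rs_planted"]
        assert np.isclose(np.linalg.norm(field), 1.0)
        outside = np.setdiff1d(np.arange(field.shape[0]), planted)
        assert np.all(field[outside] == 0)
        # orthogonal to module translations and scaling
        assert abs(field[planted].sum()) < 1e-8
        module = small_study.template.coordinates[planted]
        centered = module - module.mean(axis=0)
        assert abs(np.sum(centered * field[planted])) < 1e-8

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SnpSpec("a", maf=0.0)
        with pytest.raises(ValueError):
            SnpSpec("a", maf=0.6)
        with pytest.raises(ValueError):
            SnpSpec("a", maf=0.2, beta=-1.0)
        with pytest.raises(ValueError):
            SimulationSpec(n_subjects=(0, 10, 10), n_landmarks=32)
        with pytest.raises(ValueError):
            SimulationSpec(n_subjects=(10, 10, 10), n_landmarks=8)

    def test_target_module_resolvable(self):
        spec = SimulationSpec(
            n_subjects=(20, 20, 20), n_landmarks=32,
            snp_specs=[SnpSpec("a", 0.3, beta=1.0, target_module=9999)], seed=1,
        )
        with pytest.raises(ValueError, match="not present"):
            synthdata.simulate_study(spec)


def test_write_study_round_trip(tmp_path, small_study):
    from facemod import shapeio

    synthdata.write_study(small_study, tmp_path, genotype_format="matrix")
    cohort = small_study.cohorts[0]
    configs, ids = shapeio.read_landmarks(tmp_path / f"{cohort.cohort_id}.landmarks.tsv")
    assert ids == cohort.subject_ids
    np.testing.assert_allclose(configs, cohort.configurations, atol=1e-9)
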