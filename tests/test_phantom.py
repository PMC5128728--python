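"""Generator correctness: geometry, ground truth, and the iBAQ table."""

import numpy as np
import pytest

from chromovol import proteomics
from chromovol.phantom import (
    PackingError,
    PhantomSpec,
    ProteinBlock,
    Tube,
    generate_intensity_table,
    generate_phantom,
    ki67_depleted_spec,
    metaphase_spec,
    prophase_spec,
)


def straight_tube_phantom(diameter_um=1.0, length_um=5.0):
    tube = Tube.straight((2.0, 2.0, 2.0), (2.0, 2.0, 2.0 + length_um), diameter_um)
    spec = PhantomSpec(
        image_shape=(80, 180, 400),
        spacing_nm=(60.0, 24.0, 24.0),
        n_chromosomes=1,
        tubes=(tube,),
        periphery_thickness_nm=0.0,
        noise_sd=0.0,
        seed=0,
    )
    return generate_phantom(spec)


class TestTruthConsistency:
    def test_truth_volume_is_voxel_count_times_voxel_volume(self, metaphase_phantom):
        _, truth = metaphase_phantom
        voxvol = truth.labels.voxel_volume_um3
        counts = np.bincount(truth.labels.labels.ravel())[1:]
        assert np.allclose(truth.volume_um3, counts * voxvol, atol=voxvol)

    def test_straight_tube_volume_matches_cylinder(self):
        _, truth = straight_tube_phantom()
        expected = np.pi * 0.5**2 * 5.0
        assert truth.volume_um3[0] == pytest.approx(expected, rel=0.02)

    def test_straight_tube_truth_surface_and_axis(self):
        _, truth = straight_tube_phantom()
        r, length = 0.5, 5.0
        assert truth.surface_um2[0] == pytest.approx(
            2 * np.pi * r * length + 2 * np.pi * r**2, rel=1e-6
        )
        assert truth.length_um[0] == pytest.approx(length, rel=1e-6)
        assert truth.diameter_um[0] == pytest.approx(1.0, rel=1e-6)

    def test_shell_volume_matches_analytic_tube_shell(self):
        # radius 0.5 um = ~20 voxels at 24 nm in-plane (>= 10-voxel radius)
        tube = Tube.straight((2.0, 2.0, 2.0), (2.0, 2.0, 7.0), 1.0)
        spec = PhantomSpec(
            image_shape=(80, 180, 400),
            spacing_nm=(60.0, 24.0, 24.0),
            n_chromosomes=1,
            tubes=(tube,),
            periphery_thickness_nm=150.0,
            noise_sd=0.0,
            seed=0,
        )
        grid, truth = generate_phantom(spec)
        voxvol = truth.labels.voxel_volume_um3
        measured = truth.periphery_mask.sum() * voxvol
        # lateral annulus plus the two half-balls of radius r + t that
        # wrap the flat end caps (the shell follows distance to the axis)
        r, t, length = 0.5, 0.15, 5.0
        analytic = np.pi * length * ((r + t) ** 2 - r**2) + 4.0 / 3.0 * np.pi * (r + t) ** 3
        assert measured == pytest.approx(analytic, rel=0.05)


class TestStageSpecs:
    def test_metaphase_truth_totals(self, metaphase_phantom):
        _, truth = metaphase_phantom
        assert truth.labels.n_labels == 46
        assert truth.volume_um3.sum() == pytest.approx(175.9, rel=0.02)

    def test_metaphase_diameters_match_requested_distribution(self, metaphase_phantom):
        _, truth = metaphase_phantom
        assert truth.diameter_um.mean() == pytest.approx(1.15, rel=0.05)

    def test_prophase_truth(self, prophase_phantom):
        _, truth = prophase_phantom
        assert truth.labels.n_labels == 43
        assert truth.volume_um3.sum() == pytest.approx(109.8, rel=0.06)
        assert truth.nucleolus_volume_um3 == pytest.approx(54.4, rel=0.10)
        assert truth.envelope_mask is not None and truth.envelope_mask.any()

    def test_ki67_variant_has_no_periphery(self):
        spec = ki67_depleted_spec(seed=0)
        assert spec.periphery_thickness_nm == 0.0
        assert spec.clumped

    def test_gray_levels_in_image(self, metaphase_phantom):
        grid, truth = metaphase_phantom
        chroma = grid.data[truth.labels.labels > 0]
        # noise sd 5 around 80
        assert abs(float(chroma.mean()) - 80.0) < 2.0

    def test_determinism(self):
        spec = PhantomSpec(
            image_shape=(40, 90, 90),
            n_chromosomes=3,
            total_volume_um3=8.0,
            noise_sd=3.0,
            seed=7,
        )
        g1, t1 = generate_phantom(spec)
        g2, t2 = generate_phantom(spec)
        assert np.array_equal(g1.data, g2.data)
        assert np.array_equal(t1.labels.labels, t2.labels.labels)


class TestValidation:
    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(spacing_nm=(0.0, 48.0, 48.0)))

    def test_bad_stage_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(stage="anaphase").validate()

    def test_overfull_volume_raises_packing_error(self):
        spec = PhantomSpec(
            image_shape=(30, 60, 60),
            n_chromosomes=20,
            total_volume_um3=500.0,
            seed=0,
        )
        with pytest.raises(PackingError):
            generate_phantom(spec)

    def test_explicit_tube_outside_image_rejected(self):
        tube = Tube.straight((1.0, 1.0, 1.0), (1.0, 1.0, 50.0), 1.0)
        spec = PhantomSpec(
            image_shape=(40, 90, 90), n_chromosomes=1, tubes=(tube,), seed=0
        )
        with pytest.raises(PackingError):
            generate_phantom(spec)


class TestIntensityTable:
    def test_block_mass_shares_recovered(self):
        table = generate_intensity_table(600, n_experiments=24, seed=0)
        shares = proteomics.mass_fraction_by_group(table)
        assert shares["histone"] == pytest.approx(20.0, abs=1.0)
        assert shares["periphery"] == pytest.approx(33.0, abs=1.0)
        assert shares["other"] == pytest.approx(47.0, abs=1.0)

    def test_within_block_correlation_monte_carlo(self):
        # 10k pairwise draws: mean sample correlation within 0.05 of rho
        blocks = (ProteinBlock("a", 0.5, rho=0.9), ProteinBlock("b", 0.5, rho=0.9))
        table = generate_intensity_table(300, blocks=blocks, n_experiments=50, seed=1)
        logs = proteomics.log_transform(table).values
        groups = table.groups.values
        cors = []
        rng = np.random.default_rng(2)
        for name in ("a", "b"):
            idx = np.flatnonzero(groups == name)
            for _ in range(5000):
                i, j = rng.choice(idx, size=2, replace=False)
                cors.append(np.corrcoef(logs[i], logs[j])[0, 1])
        assert abs(float(np.mean(cors)) - 0.9) < 0.05

    def test_cross_block_correlation_near_zero(self):
        blocks = (ProteinBlock("a", 0.5, rho=0.9), ProteinBlock("b", 0.5, rho=0.9))
        table = generate_intensity_table(100, blocks=blocks, n_experiments=50, seed=3)
        logs = proteomics.log_transform(table).values
        groups = table.groups.values
        ia = np.flatnonzero(groups == "a")[:30]
        ib = np.flatnonzero(groups == "b")[:30]
        cors = [np.corrcoef(logs[i], logs[j])[0, 1] for i in ia for j in ib]
        assert abs(float(np.mean(cors))) < 0.1

    def test_block_sizes_and_ids(self):
        table = generate_intensity_table(10, n_experiments=4, seed=0)
        assert len(table.intensities) == 10
        assert set(table.groups.unique()) == {"histone", "periphery", "other"}

    def test_too_few_experiments_rejected(self):
        with pytest.raises(ValueError):
            generate_intensity_table(10, n_experiments=2, seed=0)

    def test_overcommitted_fractions_rejected(self):
        blocks = (ProteinBlock("a", 0.7), ProteinBlock("b", 0.7))
        with pytest.raises(ValueError):
            generate_intensity_table(10, blocks=blocks, seed=0)
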