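"""Geometry recovery: surface, axis, positions, contacts, contrast."""

import numpy as np
import pytest

from chromovol import morphometry
from chromovol.phantom import PhantomSpec, Tube, generate_phantom
from chromovol.volume_io import LabelVolume, VoxelGrid


def ball_labels(radius_um=1.0, spacing_nm=(60.0, 60.0, 60.0), pad_vox=4):
    spacing_um = np.asarray(spacing_nm) / 1000.0
    n = (2 * np.ceil(radius_um / spacing_um) + 2 * pad_vox).astype(int)
    zz, yy, xx = np.indices(tuple(n))
    c = (n - 1) / 2.0
    r2 = ((zz - c[0]) * spacing_um[0]) ** 2 + ((yy - c[1]) * spacing_um[1]) ** 2 + (
        (xx - c[2]) * spacing_um[2]
    ) ** 2
    lab = (r2 <= radius_um**2).astype(np.int32)
    return LabelVolume(labels=lab, spacing_nm=tuple(spacing_nm))


def oriented_tube_labels(direction, length_um=5.0, diameter_um=1.0,
                         spacing_nm=(60.0, 24.0, 24.0)):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    extent = np.array([7.2, 7.2, 7.2])
    shape = tuple((extent * 1000 / np.asarray(spacing_nm)).astype(int))
    center = extent / 2.0
    tube = Tube.straight(center - d * length_um / 2, center + d * length_um / 2, diameter_um)
    spec = PhantomSpec(
        image_shape=shape, spacing_nm=spacing_nm, n_chromosomes=1, tubes=(tube,),
        periphery_thickness_nm=0.0, noise_sd=0.0, seed=0,
    )
    _, truth = generate_phantom(spec)
    return truth.labels


class TestSurface:
    def test_sphere_area_within_3_percent(self):
        lv = ball_labels(radius_um=1.0)
        area = morphometry.measure_surface(lv, smoothing_level=6)[0]
        assert area == pytest.approx(4 * np.pi * 1.0**2, rel=0.03)

    def test_area_decreases_with_smoothing_level(self):
        lv = ball_labels(radius_um=0.8)
        a0, a3, a6 = (morphometry.measure_surface(lv, smoothing_level=s)[0] for s in (0, 3, 6))
        assert a0 > a3 > a6

    def test_rotation_isotropy_in_plane(self):
        lv = oriented_tube_labels([0.2, 1.0, 0.4], spacing_nm=(60.0, 24.0, 24.0))
        rot = LabelVolume(
            labels=np.ascontiguousarray(np.rot90(lv.labels, axes=(1, 2))),
            spacing_nm=lv.spacing_nm,
        )
        a = morphometry.measure_surface(lv, smoothing_level=6)[0]
        b = morphometry.measure_surface(rot, smoothing_level=6)[0]
        assert b == pytest.approx(a, rel=0.02)

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            morphometry.measure_surface(ball_labels(0.5), smoothing_level=11)


class TestVolume:
    def test_additivity_is_exact(self, rng):
        lab = rng.integers(0, 4, size=(15, 15, 15)).astype(np.int32)
        lab[0, 0, :4] = [1, 2, 3, 0]  # guarantee contiguity
        lv = LabelVolume(labels=lab, spacing_nm=(120.0, 48.0, 48.0))
        vols = morphometry.measure_volume(lv)
        assert vols.sum() == pytest.approx((lab > 0).sum() * lv.voxel_volume_um3, rel=1e-12)


class TestAxis:
    def test_straight_tube_axis_aligned(self):
        lv = oriented_tube_labels([0.0, 0.0, 1.0])
        length, diam, mid, degen = morphometry.measure_axis(lv, 1)
        assert not degen
        assert length == pytest.approx(5.0, rel=0.05)
        assert diam == pytest.approx(1.0, rel=0.05)
        assert np.allclose(mid, [3.6, 3.6, 3.6], atol=0.25)

    @pytest.mark.parametrize("k", range(20))
    def test_twenty_seeded_orientations_within_5_percent(self, k):
        d = np.random.default_rng(100 + k).standard_normal(3)
        lv = oriented_tube_labels(d)
        length, diam, _, degen = morphometry.measure_axis(lv, 1)
        assert not degen
        assert length == pytest.approx(5.0, rel=0.05)
        assert diam == pytest.approx(1.0, rel=0.05)

    def test_ball_is_degenerate(self):
        lv = ball_labels(radius_um=1.0, spacing_nm=(120.0, 48.0, 48.0))
        length, diam, _, degen = morphometry.measure_axis(lv, 1)
        assert degen
        assert length == pytest.approx(2.0, rel=0.1)
        assert diam == pytest.approx(2.0, rel=0.1)


class TestPositions:
    def test_radial_distance_is_pythagorean(self):
        r = morphometry.radial_positions(np.array([[0.0, 3.0, 4.0]]), [0.0, 0.0, 0.0])
        assert r[0] == pytest.approx(5.0)

    def test_mass_centroid_of_symmetric_object(self):
        lv = ball_labels(radius_um=0.6, spacing_nm=(100.0, 100.0, 100.0))
        c_geom = (np.asarray(lv.labels.shape) - 1) / 2.0 * 0.1
        assert np.allclose(morphometry.mass_centroid(lv), c_geom, atol=0.05)

    def test_explicit_layout_recovers_group_radii(self):
        # two rings of four z-parallel tubes at radii 6.2 and 3.1 um from
        # the field center; by symmetry the centroid is the center
        spacing = (120.0, 48.0, 48.0)
        center = np.array([3.6, 7.2, 7.2])
        tubes = []
        for radius in (6.2, 3.1):
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                y, x = center[1] + dy * radius, center[2] + dx * radius
                tubes.append(Tube.straight((2.1, y, x), (5.1, y, x), 0.6))
        spec = PhantomSpec(
            image_shape=(60, 300, 300), spacing_nm=spacing, n_chromosomes=8,
            tubes=tuple(tubes), periphery_thickness_nm=0.0, noise_sd=0.0, seed=0,
        )
        _, truth = generate_phantom(spec)
        records = morphometry.measure_all(truth.labels, smoothing_level=0)
        radial = np.array([r.radial_distance_um for r in records])
        assert np.mean(radial[:4]) == pytest.approx(6.2, rel=0.10)
        assert np.mean(radial[4:]) == pytest.approx(3.1, rel=0.10)


class TestEnvelopeContacts:
    def test_distant_object_has_zero_contacts(self):
        lab = np.zeros((20, 9, 9), dtype=np.int32)
        lab[8:12, 3:6, 3:6] = 1
        lv = LabelVolume(labels=lab, spacing_nm=(100.0, 100.0, 100.0))
        env = np.zeros_like(lab, dtype=bool)
        env[0] = True
        assert morphometry.envelope_contacts(lv, env)[0] == 0

    def test_tube_bridging_two_planes_has_two_contacts(self):
        lab = np.zeros((20, 9, 9), dtype=np.int32)
        lab[3:17, 4, 4] = 1
        lv = LabelVolume(labels=lab, spacing_nm=(100.0, 100.0, 100.0))
        env = np.zeros_like(lab, dtype=bool)
        env[2] = env[17] = True
        assert morphometry.envelope_contacts(lv, env)[0] == 2

    def test_empty_envelope_warns_and_returns_zeros(self):
        lv = ball_labels(0.4, spacing_nm=(100.0, 100.0, 100.0))
        counts = morphometry.envelope_contacts(lv, np.zeros(lv.labels.shape, dtype=bool))
        assert (counts == 0).all()

    def test_prophase_truth_objects_touch_envelope(self, prophase_phantom):
        _, truth = prophase_phantom
        counts = morphometry.envelope_contacts(truth.labels, truth.envelope_mask)
        assert (counts >= 1).sum() >= 42


class TestGrayContrast:
    def test_identical_disjoint_regions_give_zero(self):
        data = np.full((4, 4, 4), 100, dtype=np.uint8)
        grid = VoxelGrid(data=data, spacing_nm=(100.0, 100.0, 100.0))
        a = np.zeros(data.shape, dtype=bool)
        b = np.zeros(data.shape, dtype=bool)
        a[0], b[2] = True, True
        assert morphometry.gray_contrast(grid, a, b) == pytest.approx(0.0)

    def test_64_vs_100_is_36_percent(self):
        data = np.full((4, 4, 4), 100, dtype=np.uint8)
        data[0] = 64
        grid = VoxelGrid(data=data, spacing_nm=(100.0, 100.0, 100.0))
        a = np.zeros(data.shape, dtype=bool)
        b = np.zeros(data.shape, dtype=bool)
        a[0], b[2] = True, True
        assert morphometry.gray_contrast(grid, a, b) == pytest.approx(36.0)

    def test_overlap_rejected(self):
        grid = VoxelGrid(data=np.zeros((3, 3, 3), dtype=np.uint8), spacing_nm=(100.0,) * 3)
        m = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            morphometry.gray_contrast(grid, m, m)

    def test_prophase_chromatin_vs_nucleolus(self, prophase_phantom):
        grid, truth = prophase_phantom
        c = morphometry.gray_contrast(grid, truth.labels.labels > 0, truth.nucleolus_mask)
        assert c == pytest.approx(36.0, abs=2.0)


class TestMeasureAll:
    def test_full_table_on_straight_tube(self):
        lv = oriented_tube_labels([0.0, 0.0, 1.0])
        records = morphometry.measure_all(lv, smoothing_level=6)
        assert len(records) == 1
        rec = records[0]
        assert rec.volume_um3 == pytest.approx(np.pi * 0.25 * 5.0, rel=0.02)
        assert rec.surface_um2 == pytest.approx(2 * np.pi * 0.5 * 5.0 + 2 * np.pi * 0.25, rel=0.05)
        assert rec.length_um == pytest.approx(5.0, rel=0.05)
        assert rec.diameter_um == pytest.approx(1.0, rel=0.05)
        assert not rec.degenerate_axis
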