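import numpy as np
import pytest

from enscircuit.contact import (
    ContactVolume,
    contact_fraction,
    contact_fraction_labeled,
    surface_voxels,
)
from enscircuit.synthetic import SimContactConfig, generate_contact_volume


class TestSurfaceVoxels:
    def test_single_voxel_is_surface(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert surface_voxels(mask).sum() == 1

    def test_3x3x3_cube_has_26_surface_voxels(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        assert surface_voxels(mask).sum() == 26

    def test_empty_mask(self):
        assert surface_voxels(np.zeros((4, 4, 4), bool)).sum() == 0

    def test_volume_edge_counts_as_surface(self):
        mask = np.ones((3, 3, 3), bool)
        assert surface_voxels(mask).sum() == 26  # only the center is interior

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            surface_voxels(np.full((3, 3, 3), 2))


class TestContactFraction:
    def _cube(self, shape=(9, 9, 9)):
        soma = np.zeros(shape, bool)
        soma[3:6, 3:6, 3:6] = True
        return soma

    def test_enveloped_cube_fraction_one(self):
        soma = self._cube()
        shell = np.zeros_like(soma)
        shell[2:7, 2:7, 2:7] = True
        shell &= ~soma
        res = contact_fraction(ContactVolume(soma, shell), distance_vox=1)
        assert res.fraction == 1.0

    def test_no_varicosities_fraction_zero(self):
        soma = self._cube()
        res = contact_fraction(ContactVolume(soma, np.zeros_like(soma)))
        assert res.fraction == 0.0
        assert res.surface_vox == 26

    def test_half_covered_two_voxel_soma(self):
        soma = np.zeros((11, 11, 11), bool)
        soma[5, 5, 5] = soma[5, 5, 6] = True  # both voxels are surface
        vari = np.zeros_like(soma)
        vari[5, 5, 8] = True  # Chebyshev distance 2 and 3
        assert contact_fraction(ContactVolume(soma, vari), 1).fraction == 0.0
        vari[:] = False
        vari[5, 5, 7] = True  # distance 1 to one voxel, 2 to the other
        assert contact_fraction(ContactVolume(soma, vari), 1).fraction == 0.5

    def test_monotone_in_distance(self):
        vol, _ = generate_contact_volume(SimContactConfig(coverage_target=0.2), seed=3)
        fracs = [contact_fraction(vol, d).fraction for d in (0, 1, 2, 3)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_translation_invariance(self):
        soma = self._cube((12, 12, 12))
        vari = np.zeros_like(soma)
        vari[3, 3, 7] = True
        f1 = contact_fraction(ContactVolume(soma, vari)).fraction
        f2 = contact_fraction(
            ContactVolume(np.roll(soma, 2, axis=0), np.roll(vari, 2, axis=0))
        ).fraction
        assert f1 == f2

    def test_empty_soma_rejected(self):
        with pytest.raises(ValueError):
            contact_fraction(ContactVolume(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ContactVolume(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))


class TestLabeledContact:
    def test_per_neuron_mean(self):
        labels = np.zeros((11, 11, 11), np.int32)
        labels[2, 2, 2] = 1  # single-voxel soma, fully contacted
        labels[8, 8, 8] = 2  # single-voxel soma, no contact
        vari = np.zeros(labels.shape, bool)
        vari[2, 2, 3] = True
        res = contact_fraction_labeled(labels, vari, 1)
        assert res.per_label == {1: 1.0, 2: 0.0}
        assert res.fraction == 0.5


class TestPhantomGenerator:
    def test_zero_target_gives_zero(self):
        vol, truth = generate_contact_volume(SimContactConfig(coverage_target=0.0), seed=1)
        assert truth.contact["realized_coverage"] == 0.0
        assert contact_fraction(vol).fraction == 0.0

    def test_full_shell_gives_one(self):
        vol, truth = generate_contact_volume(SimContactConfig(coverage_target=1.0), seed=1)
        assert truth.contact["realized_coverage"] == 1.0
        assert contact_fraction(vol).fraction == 1.0

    def test_masks_disjoint(self):
        vol, _ = generate_contact_volume(SimContactConfig(), seed=2)
        assert not (vol.soma_mask & vol.varicosity_mask).any()

    def test_measured_matches_realized_coverage(self):
        vol, truth = generate_contact_volume(SimContactConfig(coverage_target=0.3), seed=5)
        res = contact_fraction(vol, distance_vox=1)
        assert res.fraction == pytest.approx(truth.contact["realized_coverage"], abs=0.1)

    def test_soma_must_fit(self):
        with pytest.raises(ValueError):
            generate_contact_volume(
                SimContactConfig(shape=(32, 32, 32), soma_radius_vox=20.0), seed=1
            )

    def test_seed_determinism(self):
        a, _ = generate_contact_volume(SimContactConfig(), seed=6)
        b, _ = generate_contact_volume(SimContactConfig(), seed=6)
        assert np.array_equal(a.varicosity_mask, b.varicosity_mask)
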