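"""Phantoms, CBCT simulation, known deformations, evaluation metrics."""

import numpy as np
import pytest

from edgereg.errors import LatticeMismatchError
from edgereg.image import DisplacementField, ScalarImage
from edgereg.synthetic import CbctSimSpec, DiskPhantomSpec, \
    KnownDeformationSpec, checkerboard, deformation_difference, \
    known_deformation_preset, make_known_deformation, make_phantom, \
    simulate_cbct, thorax_phantom_spec


class TestPhantom:
    def test_single_disk_values(self):
        spec = DiskPhantomSpec(shape=(64, 64),
                               disks=(((32.0, 32.0), 16.0, 100.0),))
        img = make_phantom(spec)
        assert img.data[32, 32] == 100.0
        assert img.data[0, 0] == 0.0

    def test_nested_disks_add(self):
        spec = DiskPhantomSpec(shape=(64, 64),
                               disks=(((32.0, 32.0), 24.0, 80.0),
                                      ((32.0, 32.0), 8.0, 80.0)))
        img = make_phantom(spec)
        assert img.data[32, 32] == 160.0
        assert img.data[32, 12] == 80.0

    def test_rasterized_area_near_continuum(self):
        r = 16.0
        spec = DiskPhantomSpec(shape=(64, 64), disks=(((32., 32.), r, 1.0),))
        area = make_phantom(spec).data.sum()
        assert area == pytest.approx(np.pi * r ** 2, rel=0.02)

    def test_out_of_bounds_rejected(self):
        spec = DiskPhantomSpec(shape=(32, 32), disks=(((2.0, 2.0), 8.0, 1.0),))
        with pytest.raises(ValueError):
            make_phantom(spec)

    def test_determinism(self):
        spec = thorax_phantom_spec(shape=(32, 32, 4), seed=9)
        assert np.array_equal(make_phantom(spec).data,
                              make_phantom(spec).data)


class TestCbctSimulation:
    def test_noise_free_identity(self, rng):
        img = ScalarImage(rng.normal(size=(16, 16)))
        out = simulate_cbct(img, CbctSimSpec(a=1.0, b=0.0, sigma=0.0,
                                             sp_fraction=0.0))
        assert np.array_equal(out.data, img.data)

    def test_linear_gray_transform(self):
        img = ScalarImage(np.full((8, 8), 5.0))
        out = simulate_cbct(img, CbctSimSpec(a=2.0, b=10.0, sigma=0.0,
                                            sp_fraction=0.0))
        assert np.allclose(out.data, 20.0)

    def test_salt_pepper_exact_count(self):
        img = ScalarImage(np.full((100, 100), 0.5))
        spec = CbctSimSpec(a=1.0, b=0.0, sigma=0.0, sp_fraction=0.1,
                           sp_low=0.0, sp_high=1.0, seed=3)
        out = simulate_cbct(img, spec)
        assert int(((out.data == 0.0) | (out.data == 1.0)).sum()) == 1000

    def test_seeded_reproducibility(self, rng):
        img = ScalarImage(rng.normal(size=(32, 32)))
        spec = CbctSimSpec(seed=11)
        assert np.array_equal(simulate_cbct(img, spec).data,
                              simulate_cbct(img, spec).data)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            CbctSimSpec(sp_fraction=1.0)


class TestKnownDeformation:
    @pytest.fixture
    def lattice(self):
        return ScalarImage(np.zeros((48, 48, 6)), spacing=(1.0, 1.0, 3.0))

    def test_zero_amplitude_gives_zero_field(self, lattice):
        spec = KnownDeformationSpec(target_max_mm=0.0, seed=1)
        fld = make_known_deformation(spec, lattice)
        assert np.all(fld.vectors == 0.0)

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_presets_capped_and_strictly_ordered(self, lattice, seed):
        mags = {}
        for name in ("D1", "D2", "D3"):
            fld = known_deformation_preset(name, lattice, seed=seed)
            m = fld.magnitude()
            assert m.max() <= 10.0 + 1e-9
            mags[name] = m.mean()
        assert mags["D1"] < mags["D2"] < mags["D3"]

    def test_slicewise_field_is_in_plane_and_z_constant(self, lattice):
        fld = known_deformation_preset("D2", lattice, seed=5)
        assert np.all(fld.vectors[..., 2] == 0.0)
        assert np.allclose(fld.vectors[:, :, 0], fld.vectors[:, :, 3])

    def test_cap_violation_rejected(self):
        with pytest.raises(ValueError):
            KnownDeformationSpec(target_max_mm=12.0, cap_mm=10.0)


class TestDeformationDifference:
    def test_identical_fields_zero(self, rng):
        v = rng.normal(size=(5, 5, 2))
        f = DisplacementField(v)
        assert deformation_difference(f, f) == 0.0

    def test_constant_offset(self, rng):
        v = rng.normal(size=(5, 5, 2))
        k = DisplacementField(v)
        w = DisplacementField(v + np.array([1.0, 0.0]))
        assert deformation_difference(w, k) == pytest.approx(1.0)

    def test_matches_double_loop(self, rng):
        a = rng.normal(size=(4, 4, 2))
        b = rng.normal(size=(4, 4, 2))
        ref = np.mean([np.linalg.norm(a[i, j] - b[i, j])
                       for i in range(4) for j in range(4)])
        got = deformation_difference(DisplacementField(a),
                                     DisplacementField(b))
        assert got == pytest.approx(ref, abs=1e-12)

    def test_lattice_mismatch(self, rng):
        a = DisplacementField(rng.normal(size=(4, 4, 2)))
        b = DisplacementField(rng.normal(size=(4, 4, 2)), spacing=2.0)
        with pytest.raises(LatticeMismatchError):
            deformation_difference(a, b)


class TestCheckerboard:
    def test_identical_inputs(self, rng):
        a = ScalarImage(rng.normal(size=(8, 8)))
        assert np.array_equal(checkerboard(a, a, 4).data, a.data)

    def test_single_tile_returns_first(self, rng):
        a = ScalarImage(rng.normal(size=(8, 8)))
        b = ScalarImage(rng.normal(size=(8, 8)))
        assert np.array_equal(checkerboard(a, b, 1).data, a.data)

    def test_parity_rule_exhaustive(self, rng):
        a = ScalarImage(np.zeros((8, 8)))
        b = ScalarImage(np.ones((8, 8)))
        out = checkerboard(a, b, 4).data  # tile size 2
        for i in range(8):
            for j in range(8):
                expect = 0.0 if (i // 2 + j // 2) % 2 == 0 else 1.0
                assert out[i, j] == expect
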