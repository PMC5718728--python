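"""TV-L1 energy, solver, and the hierarchical scale space.

The geometric contracts under test: a disk of radius r survives the
decomposition iff lambda > 2/r (independent of its contrast); nested
structures are peeled strictly by size as lambda decreases; and
cartoon + texture reconstructs the input exactly at every level.
"""

import itertools

import numpy as np
import pytest

from edgereg.errors import LatticeMismatchError
from edgereg.image import ScalarImage
from edgereg.tvl1 import LambdaSchedule, build_scale_space, \
    neighborhood_structure, solve_tvl1, tvl1_energy

from conftest import disk_image


def brute_energy(candidate, input_image, lam):
    """Independent double-loop evaluator of the discrete TV-L1 energy."""
    u = candidate.data
    structure = neighborhood_structure(u.ndim, candidate.spacing)
    tv = 0.0
    for (off, w) in structure:
        for idx in np.ndindex(*u.shape):
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= v < s for v, s in zip(nb, u.shape)):
                tv += w * abs(u[idx] - u[nb])
    vox = float(np.prod(candidate.spacing))
    return tv + lam * vox * float(np.abs(u - input_image.data).sum())


class TestEnergy:
    def test_candidate_equal_input_has_no_residual(self, disk128):
        e = tvl1_energy(disk128, disk128, lam=5.0)
        zero = disk128.with_data(np.zeros_like(disk128.data))
        assert e == pytest.approx(tvl1_energy(disk128, disk128, lam=0.0))
        assert e < tvl1_energy(zero, disk128, lam=5.0)

    def test_zero_candidate_on_disk_approaches_continuum(self, disk128):
        # E(0) = lam * c1 * area; rasterized area is within 2% of pi r^2
        lam, c1, r = 0.1, 100.0, 16.0
        zero = disk128.with_data(np.zeros_like(disk128.data))
        e = tvl1_energy(zero, disk128, lam)
        assert e == pytest.approx(lam * c1 * np.pi * r ** 2, rel=0.02)

    def test_matches_brute_force_on_small_images(self, rng):
        for _ in range(5):
            cand = ScalarImage(rng.integers(0, 2, (3, 3)).astype(float),
                               spacing=(1.0, 1.3))
            inp = ScalarImage(rng.normal(size=(3, 3)), spacing=(1.0, 1.3))
            lam = float(rng.uniform(0, 2))
            assert tvl1_energy(cand, inp, lam) == \
                pytest.approx(brute_energy(cand, inp, lam), abs=1e-12)

    def test_lattice_mismatch(self, rng):
        a = ScalarImage(rng.normal(size=(4, 4)))
        b = ScalarImage(rng.normal(size=(4, 4)), spacing=2.0)
        with pytest.raises(LatticeMismatchError):
            tvl1_energy(a, b, 1.0)


class TestDiskLaw:
    """Analytic solution regimes for disk phantoms (thresholds at 2/r,
    tested with >= 20% margin on both sides)."""

    def test_below_threshold_removes_disk(self, disk128):
        res = solve_tvl1(disk128, lam=0.08)  # 2/r = 0.125
        assert np.abs(res.cartoon.data).mean() < 2.0

    def test_above_threshold_keeps_disk(self, disk128):
        res = solve_tvl1(disk128, lam=0.25)
        err = np.abs(res.cartoon.data - disk128.data).sum() \
            / np.abs(disk128.data).sum()
        assert err < 0.05

    def test_two_disk_scale_selection(self):
        n = 128
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rr = (xx - 64) ** 2 + (yy - 64) ** 2
        big = (rr <= 24 ** 2) * 80.0
        small = (rr <= 8 ** 2) * 80.0
        img = ScalarImage(big + small)
        # 2/r1 ~ 0.083 < lam < 2/r2 = 0.25: large disk only
        res = solve_tvl1(img, lam=0.12)
        inner = rr <= 8 ** 2
        assert np.abs(res.cartoon.data - big)[inner].mean() < 0.05 * 80.0
        assert np.abs(res.cartoon.data - big).sum() / big.sum() < 0.05

    def test_contrast_scaling_leaves_geometry(self, disk128):
        # the survival threshold depends on r, not on the amplitude
        sup_ref = solve_tvl1(disk128, 0.25).cartoon.data > 50.0
        scaled = disk128.with_data(disk128.data * 7.0)
        sup_scaled = solve_tvl1(scaled, 0.25).cartoon.data > 350.0
        assert np.array_equal(sup_ref, sup_scaled)

    def test_lambda_zero_returns_median(self, rng):
        img = ScalarImage(rng.normal(size=(10, 10)))
        res = solve_tvl1(img, 0.0)
        assert np.allclose(res.cartoon.data, np.median(img.data))
        assert np.allclose(res.cartoon.data + res.texture.data, img.data)

    def test_negative_lambda_rejected(self, disk128):
        with pytest.raises(ValueError):
            solve_tvl1(disk128, -0.1)


class TestSolverOptimality:
    def test_cut_solution_attains_enumerated_minimum(self, rng):
        """On random binary 3x3 instances the graph solution's energy equals
        the exhaustive minimum over all binary candidates."""
        cands = [np.array(c, float).reshape(3, 3)
                 for c in itertools.product([0, 1], repeat=9)]
        for lam in (0.4, 1.0):
            for _ in range(12):
                f = ScalarImage(rng.integers(0, 2, (3, 3)).astype(float))
                res = solve_tvl1(f, lam, levels=2)
                e_sol = tvl1_energy(res.cartoon, f, lam)
                e_min = min(tvl1_energy(ScalarImage(c), f, lam)
                            for c in cands)
                assert e_sol == pytest.approx(e_min, abs=1e-9)

    def test_energy_not_above_trivial_candidates(self, rng):
        # the solver is optimal over the quantized candidates; the
        # quantization half-step bounds the gap to off-grid constants
        img = ScalarImage(rng.uniform(0, 1, (24, 24)))
        lam, levels = 0.5, 64
        res = solve_tvl1(img, lam, levels=levels)
        e_sol = tvl1_energy(res.cartoon, img, lam)
        assert e_sol <= tvl1_energy(img, img, lam) + 1e-9
        rng_i = img.data.max() - img.data.min()
        quant_slack = lam * img.data.size * rng_i / (levels - 1) / 2.0
        for const in (0.0, 0.5, float(np.median(img.data))):
            cand = img.with_data(np.full_like(img.data, const))
            assert e_sol <= tvl1_energy(cand, img, lam) + quant_slack

    def test_exact_additivity(self, rng):
        img = ScalarImage(rng.normal(size=(20, 20)) * 50)
        res = solve_tvl1(img, 0.3, levels=64)
        # texture is exactly the residual; re-summing may differ by 1 ulp
        assert np.array_equal(res.texture.data,
                              img.data - res.cartoon.data)
        assert np.allclose(res.cartoon.data + res.texture.data, img.data,
                           atol=1e-10)


class TestPrimalDualFallback:
    def test_disk_recovery_approximate(self, disk128):
        res = solve_tvl1(disk128, 0.25, solver="primal_dual")
        err = np.abs(res.cartoon.data - disk128.data).sum() \
            / disk128.data.sum()
        assert err < 0.10
        assert np.array_equal(res.cartoon.data + res.texture.data,
                              disk128.data)

    def test_auto_falls_back_above_node_cap(self, disk128):
        res = solve_tvl1(disk128, 0.25, max_graph_nodes=100)
        err = np.abs(res.cartoon.data - disk128.data).sum() \
            / disk128.data.sum()
        assert err < 0.10


class TestScaleSpace:
    def test_single_level_equals_solve(self, disk128):
        pyr = build_scale_space(disk128, (0.25,))
        res = solve_tvl1(disk128, 0.25)
        assert np.array_equal(pyr.cartoon(0).data, res.cartoon.data)

    def test_two_disk_hierarchy(self):
        n = 128
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rr = (xx - 64) ** 2 + (yy - 64) ** 2
        big = (rr <= 24 ** 2) * 80.0
        img = ScalarImage(big + (rr <= 8 ** 2) * 80.0)
        pyr = build_scale_space(img, (0.5, 0.12))
        # level 0 keeps both disks, level 1 keeps only the large one
        assert np.abs(pyr.cartoon(0).data - img.data).sum() \
            / img.data.sum() < 0.05
        assert np.abs(pyr.cartoon(1).data - big).sum() / big.sum() < 0.05

    def test_scale_nesting(self):
        """Structures removed at a scale stay removed at coarser scales."""
        n = 128
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rr = (xx - 64) ** 2 + (yy - 64) ** 2
        img = ScalarImage((rr <= 24 ** 2) * 80.0 + (rr <= 8 ** 2) * 80.0)
        pyr = build_scale_space(img, (0.12, 0.1))
        inner = rr <= 8 ** 2
        for lvl in range(2):
            assert np.abs(pyr.cartoon(lvl).data - 80.0)[inner].max() < 4.0

    def test_telescoping_reconstruction(self, rng):
        img = ScalarImage(disk_image().data + rng.normal(0, 5, (128, 128)))
        levels = 64
        pyr = build_scale_space(img, (0.5, 0.3, 0.15, 0.08), levels=levels)
        step = (img.data.max() - img.data.min()) / (levels - 1)
        assert np.abs(pyr.reconstruct() - img.data).max() <= step

    def test_non_monotone_schedule_rejected(self, disk128):
        with pytest.raises(ValueError):
            build_scale_space(disk128, (0.1, 0.2))
        with pytest.raises(ValueError):
            LambdaSchedule((0.3, 0.3))


def test_schedule_presets():
    assert LambdaSchedule.preset("ct").values[0] == 0.7
    assert LambdaSchedule.preset("soft").values == \
        (0.26, 0.17, 0.1, 0.08, 0.06, 0.04)
    assert len(LambdaSchedule.preset("ct", levels=3)) == 3
    with pytest.raises(ValueError):
        LambdaSchedule.preset("bone")
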