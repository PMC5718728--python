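"""Rigid transforms, the offset metric, and automated lambda selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgereg.image import ScalarImage
from edgereg.lambda_est import LambdaCache, LambdaCandidateGrid, \
    OffsetWeights, RigidParams, apply_rigid, estimate_lambda, implant_rigid, \
    offset, rigid_register
from edgereg.synthetic import CbctSimSpec, DiskPhantomSpec, make_phantom, \
    simulate_cbct
from edgereg.tvl1 import LambdaSchedule


class TestOffset:
    def test_identical_params_zero(self):
        p = RigidParams(1.0, -2.0, 0.5, 0.1, -0.2, 0.3)
        assert offset(p, p) == 0.0

    def test_one_mm_translation(self):
        assert offset(RigidParams(), RigidParams(tx=1.0)) \
            == pytest.approx(1.0)

    def test_one_degree_rotation_equals_one_mm(self):
        est = RigidParams(theta1=math.pi / 180.0)
        assert offset(RigidParams(), est) == pytest.approx(1.0)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            OffsetWeights((1.0, 1.0))
        with pytest.raises(ValueError):
            OffsetWeights((1, 1, 1, 1, 1, -1))

    @given(st.lists(st.floats(-5, 5), min_size=18, max_size=18))
    @settings(max_examples=50, deadline=None)
    def test_weighted_l1_metric_axioms(self, vals):
        p, q, r = (RigidParams(*vals[i:i + 3], *[v / 10 for v in
                                                 vals[i + 3:i + 6]])
                   for i in (0, 6, 12))
        assert offset(p, q) == pytest.approx(offset(q, p), abs=1e-9)
        assert offset(p, r) <= offset(p, q) + offset(q, r) + 1e-9
        assert offset(p, p) == 0.0


class TestApplyRigid:
    def test_identity_params_unchanged(self, rng):
        img = ScalarImage(rng.normal(size=(16, 16)))
        out = apply_rigid(img, RigidParams())
        assert np.allclose(out.data, img.data, atol=1e-12)

    def test_translation_inverse_composition(self, rng):
        img = ScalarImage(np.pad(rng.normal(size=(12, 12)), 6))
        fwd = apply_rigid(img, RigidParams(tx=2.0, ty=-1.0))
        back = apply_rigid(fwd, RigidParams(tx=-2.0, ty=1.0))
        inner = (slice(8, 16), slice(8, 16))
        assert np.allclose(back.data[inner], img.data[inner], atol=1e-9)

    def test_matches_matrix_transform_oracle(self, rng):
        from scipy import ndimage
        img = ScalarImage(rng.normal(size=(20, 18)), spacing=(1.0, 1.5),
                          origin=(-4.0, 2.0))
        p = RigidParams(tx=1.5, ty=-2.0, theta3=0.3)
        out = apply_rigid(img, p)
        c = np.array(img.origin) + (np.array(img.shape) - 1) / 2.0 \
            * np.array(img.spacing)
        R = np.array([[math.cos(p.theta3), -math.sin(p.theta3)],
                      [math.sin(p.theta3), math.cos(p.theta3)]])
        for idx in [(3, 4), (10, 9), (17, 2)]:
            x = img.voxel_to_world(idx)
            y = R @ (x - c) + c + np.array([p.tx, p.ty])
            cij = (y - np.array(img.origin)) / np.array(img.spacing)
            ref = ndimage.map_coordinates(img.data, cij[:, None], order=1,
                                          cval=0.0)[0]
            assert abs(out.data[idx] - ref) < 1e-8

    def test_implant_then_register_recovers_params(self, rng):
        spec = DiskPhantomSpec(shape=(96, 96),
                               disks=(((47.5, 47.5), 30.0, 100.0),
                                      ((38.0, 40.0), (10.0, 12.0), 60.0),
                                      ((60.0, 58.0), 6.0, -50.0)),
                               texture_amplitude=15.0, seed=3)
        img = make_phantom(spec)
        kt = RigidParams(tx=3.0, ty=-2.0)
        est = rigid_register(img, implant_rigid(img, kt))
        assert offset(kt, est) < 0.5


class TestEstimateLambda:
    def _training_pair(self):
        spec = DiskPhantomSpec(shape=(128, 128),
                               disks=(((63.5, 63.5), 24.0, 100.0),))
        ref = make_phantom(spec)
        flo = simulate_cbct(ref, CbctSimSpec(a=1.0, b=0.0, sigma=1.0,
                                             sp_fraction=0.002, seed=5))
        return ref, flo

    def test_single_candidate_returned_unchanged(self):
        ref, flo = self._training_pair()
        res = estimate_lambda([(ref, flo)], [RigidParams(tx=4.0)],
                              [(0.2,)], quant_levels=32)
        assert res.schedule.values == (0.2,)

    def test_candidates_straddling_disk_threshold(self):
        """Below 2/r the cartoon loses the disk and rigid recovery fails;
        the estimator must return the exhaustively-minimal candidate."""
        ref, flo = self._training_pair()
        res = estimate_lambda([(ref, flo)], [RigidParams(tx=5.0)],
                              [(0.05, 0.2)], quant_levels=32)
        scores = res.scores[0]
        assert set(scores) == {0.05, 0.2}
        assert res.schedule.values[0] == min(scores, key=scores.get)
        assert res.schedule.values[0] == 0.2  # 2/r = 1/12 < 0.2
        assert scores[0.2] < scores[0.05]

    def test_empty_inputs_rejected(self):
        ref, flo = self._training_pair()
        with pytest.raises(ValueError):
            estimate_lambda([], [RigidParams()], [(0.1,)])
        with pytest.raises(ValueError):
            estimate_lambda([(ref, flo)], [], [(0.1,)])
        with pytest.raises(ValueError):
            LambdaCandidateGrid(((0.1, -0.2),))


class TestLambdaCache:
    def test_lookup_before_optimize(self, tmp_path):
        cache = LambdaCache(tmp_path / "lambdas.json")
        calls = []

        def estimator():
            calls.append(1)
            return LambdaSchedule((0.3, 0.1))

        first = cache.get_or_estimate("cbct", "lung", "m", estimator)
        second = cache.get_or_estimate("cbct", "lung", "m", estimator)
        assert first.values == second.values == (0.3, 0.1)
        assert len(calls) == 1
        # persisted to disk: a fresh cache reads it back without estimating
        other = LambdaCache(tmp_path / "lambdas.json")
        assert other.lookup("CBCT", "Lung", "M").values == (0.3, 0.1)

    def test_distinct_keys_estimated_separately(self, tmp_path):
        cache = LambdaCache(tmp_path / "c.json")
        cache.store("cbct", "lung", "m", LambdaSchedule((0.5,)))
        assert cache.lookup("cbct", "liver", "m") is None
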