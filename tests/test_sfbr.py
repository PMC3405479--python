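import numpy as np
import pytest
from scipy import ndimage

from dirprop.core import ImageVolume
from dirprop.sfbr import (
    Correspondence,
    SFBRParams,
    SalientFeature,
    apply_tps,
    detect_salient_features,
    fit_tps,
    match_feature,
    sfbr_register,
)


def _gaussian_blob(dims, spacing, center_mm, sigma_mm, amplitude=100.0):
    idx = np.stack(np.meshgrid(*(np.arange(n) for n in dims), indexing="ij"), axis=-1)
    world = idx * np.asarray(spacing, dtype=float)
    d2 = np.sum((world - np.asarray(center_mm)) ** 2, axis=-1)
    return amplitude * np.exp(-d2 / (2 * sigma_mm**2))


class TestDetect:
    def test_uniform_volume_empty(self):
        vol = ImageVolume(np.full((20, 20, 20), 3.0))
        assert detect_salient_features(vol) == []

    def test_single_blob_detected(self):
        spacing = (2.0, 2.0, 2.0)
        data = _gaussian_blob((32, 32, 32), spacing, (32.0, 32.0, 32.0), 4.0)
        vol = ImageVolume(data, spacing)
        feats = detect_salient_features(vol)
        assert len(feats) >= 1
        top = feats[0]
        assert np.linalg.norm(np.asarray(top.center) - 32.0) <= 2.0 * np.sqrt(3)

    def test_two_blobs(self):
        spacing = (2.0, 2.0, 2.0)
        data = _gaussian_blob((40, 40, 20), spacing, (20.0, 20.0, 20.0), 4.0)
        data += _gaussian_blob((40, 40, 20), spacing, (60.0, 60.0, 20.0), 4.0)
        vol = ImageVolume(data, spacing)
        feats = detect_salient_features(vol)
        centers = np.asarray([f.center for f in feats[:6]])
        d_a = np.linalg.norm(centers - np.array([20.0, 20.0, 20.0]), axis=1).min()
        d_b = np.linalg.norm(centers - np.array([60.0, 60.0, 20.0]), axis=1).min()
        assert d_a <= 4.0 and d_b <= 4.0

    def test_deterministic_ordering(self, default_case):
        f1 = detect_salient_features(default_case.planning)
        f2 = detect_salient_features(default_case.planning)
        assert [(f.center, f.scale, f.response) for f in f1] == [
            (f.center, f.scale, f.response) for f in f2
        ]
        responses = [abs(f.response) for f in f1]
        assert responses == sorted(responses, reverse=True)


class TestMatchFeature:
    def _textured(self, rng, dims=(40, 40, 40), spacing=(2.0, 2.0, 2.0)):
        return ImageVolume(
            ndimage.gaussian_filter(rng.normal(0, 1, dims), 1.5) * 60, spacing
        )

    def test_self_match(self, rng):
        vol = self._textured(rng)
        f = SalientFeature((40.0, 40.0, 40.0), 4.0, 1.0)
        c = match_feature(f, vol, vol)
        assert c is not None
        assert c.correlation >= 0.999
        assert np.linalg.norm(np.asarray(c.p_target) - np.asarray(c.p_source)) < 0.5

    def test_translation_recovered(self, rng):
        vol = self._textured(rng)
        shifted = ImageVolume(np.roll(vol.data, 3, axis=0), vol.spacing)  # +6 mm
        f = SalientFeature((40.0, 40.0, 40.0), 4.0, 1.0)
        c = match_feature(f, vol, shifted)
        assert c is not None
        disp = np.asarray(c.p_target) - np.asarray(c.p_source)
        np.testing.assert_allclose(disp, [6.0, 0.0, 0.0], atol=1.0)

    def test_noise_discarded(self):
        n_kept = 0
        trials = 100
        for seed in range(trials):
            r = np.random.default_rng(seed)
            src = self._textured(r)
            tgt = self._textured(np.random.default_rng(10_000 + seed))
            f = SalientFeature((40.0, 40.0, 40.0), 4.0, 1.0)
            if match_feature(f, src, tgt) is not None:
                n_kept += 1
        assert n_kept <= 2  # discarded with probability ~ 1

    def test_window_outside_discarded(self, rng):
        vol = self._textured(rng)
        f = SalientFeature((0.0, 0.0, 0.0), 4.0, 1.0)
        assert match_feature(f, vol, vol) is None

    def test_never_below_threshold(self, rng, default_case):
        params = SFBRParams()
        feats = detect_salient_features(default_case.planning, params)[:100]
        for f in feats:
            c = match_feature(f, default_case.planning, default_case.per_treatment, params)
            if c is not None:
                assert c.correlation >= params.reliability_threshold


class TestTPS:
    def _corrs(self, src, dst):
        return [Correspondence(tuple(s), tuple(d), 1.0) for s, d in zip(src, dst)]

    def test_pure_translation(self, rng):
        src = rng.uniform(0, 100, (20, 3))
        dst = src + np.array([5.0, -3.0, 2.0])
        t = fit_tps(self._corrs(src, dst))
        probes = rng.uniform(0, 100, (50, 3))
        np.testing.assert_allclose(
            apply_tps(t, probes), probes + np.array([5.0, -3.0, 2.0]), atol=1e-6
        )

    def test_general_affine_reproduced(self, rng):
        A = np.eye(3) + rng.normal(0, 0.1, (3, 3))
        b = rng.normal(0, 10, 3)
        src = rng.uniform(0, 100, (30, 3))
        dst = src @ A.T + b
        t = fit_tps(self._corrs(src, dst))
        probes = rng.uniform(0, 100, (100, 3))
        np.testing.assert_allclose(apply_tps(t, probes), probes @ A.T + b, atol=1e-6)

    def test_interpolation_at_anchors(self, rng):
        src = rng.uniform(0, 100, (25, 3))
        dst = src + rng.normal(0, 4, (25, 3))
        t = fit_tps(self._corrs(src, dst), regularization=0.0)
        residual = np.abs(apply_tps(t, src) - dst).max()
        assert residual < 1e-6

    def test_side_conditions(self, rng):
        src = rng.uniform(0, 100, (15, 3))
        dst = src + rng.normal(0, 4, (15, 3))
        t = fit_tps(self._corrs(src, dst))
        P = np.hstack([np.ones((15, 1)), src])
        np.testing.assert_allclose(P.T @ t.weights, 0.0, atol=1e-8)

    def test_coplanar_errors(self, rng):
        src = rng.uniform(0, 100, (10, 3))
        src[:, 2] = 5.0
        with pytest.raises(ValueError, match="degenerate|coplanar"):
            fit_tps(self._corrs(src, src))

    def test_duplicate_anchor_errors(self, rng):
        src = rng.uniform(0, 100, (8, 3))
        src[3] = src[0]
        with pytest.raises(ValueError, match="duplicate"):
            fit_tps(self._corrs(src, src + 1.0))

    def test_too_few_anchors(self):
        with pytest.raises(ValueError):
            fit_tps(self._corrs(np.zeros((3, 3)), np.zeros((3, 3))))

    def test_apply_matches_double_loop_oracle(self, rng):
        src = rng.uniform(0, 50, (12, 3))
        dst = src + rng.normal(0, 3, (12, 3))
        t = fit_tps(self._corrs(src, dst))
        probes = rng.uniform(0, 50, (7, 3))
        got = apply_tps(t, probes)
        for i, p in enumerate(probes):
            expected = t.translation + t.affine @ p
            for j, a in enumerate(t.anchors):
                expected = expected + t.weights[j] * np.linalg.norm(p - a)
            np.testing.assert_allclose(got[i], expected, atol=1e-9)

    def test_serialization_round_trip(self, rng):
        src = rng.uniform(0, 50, (10, 3))
        t = fit_tps(self._corrs(src, src + 2.0))
        t2 = type(t).from_dict(t.to_dict())
        probes = rng.uniform(0, 50, (5, 3))
        np.testing.assert_allclose(apply_tps(t2, probes), apply_tps(t, probes))


class TestSFBRRegister:
    def test_self_registration_near_identity(self, default_case):
        tps, retained = sfbr_register(default_case.planning, default_case.planning)
        assert retained >= 10
        probes = np.array([[95.0, 95.0, 70.0], [60.0, 100.0, 40.0], [130.0, 90.0, 100.0]])
        moved = apply_tps(tps, probes)
        assert np.linalg.norm(moved - probes, axis=1).max() < 0.5

    def test_phantom_probe_error(self, default_case, sfbr_result):
        from dirprop.phantom import analytic_displacement

        tps, retained = sfbr_result
        assert retained >= 10
        # probe in feature-rich regions: vertebral column neighbourhood
        probes = np.array(
            [[95.0, 120.0, 60.0], [95.0, 145.0, 90.0], [80.0, 120.0, 45.0]]
        )
        mapped = apply_tps(tps, probes)
        target = probes.copy()
        for _ in range(40):  # solve x + u(x) = p for the true forward map
            target = probes - analytic_displacement(target, default_case.deform)
        assert np.linalg.norm(mapped - target, axis=1).max() < 2.0

    def test_pure_noise_insufficient_anchors(self):
        r1, r2 = np.random.default_rng(1), np.random.default_rng(2)
        a = ImageVolume(r1.normal(0, 50, (32, 32, 16)), (2.0, 2.0, 3.0))
        b = ImageVolume(r2.normal(0, 50, (32, 32, 16)), (2.0, 2.0, 3.0))
        with pytest.raises(ValueError, match="insufficient"):
            sfbr_register(a, b)
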