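"""First-order features and GLCM against independent brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrocad import CTImage, ROIMask, extract_first_order, glcm_features, \
    histogram_probabilities
from conftest import roi_from_values


def oracle_first_order(values, p):
    """Naive one-pass reference implementation of the six features."""
    values = list(map(float, values))
    n = len(values)
    e = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    u = sum(pi ** 2 for pi in p)
    m = sum(values) / n
    sd = math.sqrt(sum((a - m) ** 2 for a in values) / (n - 1))
    if sd == 0:
        return e, u, m, sd, 0.0, 0.0
    s = n / ((n - 1) * (n - 2)) * sum(((a - m) / sd) ** 3 for a in values)
    k = (n * (n + 1) / ((n - 1) * (n - 2) * (n - 3))
         * sum(((a - m) / sd) ** 4 for a in values)
         - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return e, u, m, sd, k, s


class TestHistogram:
    def test_constant_roi_single_occupied_bin(self):
        h = histogram_probabilities(roi_from_values([5.0] * 9), n_bins=8)
        assert h.p[0] == 1.0 and h.p[1:].sum() == 0.0

    def test_two_bins_half_half(self):
        h = histogram_probabilities(roi_from_values([0, 0, 1, 1]), n_bins=2)
        assert np.allclose(h.p, [0.5, 0.5])

    def test_rightmost_bin_closed(self):
        h = histogram_probabilities(roi_from_values([0, 1, 2, 3]), n_bins=3)
        assert h.p.sum() == pytest.approx(1.0)

    def test_uniform_values_binomial_bound(self, rng):
        vals = rng.uniform(0, 1, 1000)
        h = histogram_probabilities(roi_from_values(vals), n_bins=10)
        sigma = math.sqrt(0.1 * 0.9 / 1000)
        assert np.all(np.abs(h.p - 0.1) < 5 * sigma + 1e-3)

    def test_bad_bin_count(self):
        with pytest.raises(ValueError):
            histogram_probabilities(roi_from_values([1, 2]), n_bins=1)

    def test_probabilities_sum_to_one(self, rng):
        vals = rng.normal(50, 20, 333)
        h = histogram_probabilities(roi_from_values(vals), n_bins=256)
        assert abs(h.p.sum() - 1.0) < 1e-9


class TestFirstOrder:
    def test_constant_roi(self):
        fv = extract_first_order(roi_from_values([100.0] * 9))
        assert (fv.e, fv.u, fv.m, fv.sd, fv.s, fv.k) == (0.0, 1.0, 100.0, 0.0, 0.0, 0.0)
        assert fv.degenerate

    def test_symmetric_small_sample(self):
        fv = extract_first_order(roi_from_values([1, 2, 3, 2]))
        assert fv.m == pytest.approx(2.0)
        assert fv.s == pytest.approx(0.0)

    def test_kurtosis_exact_arithmetic_1234(self):
        # direct exact-arithmetic evaluation of the printed formula for {1,2,3,4}
        vals = [1, 2, 3, 4]
        n = 4
        m = Fraction(sum(vals), n)
        var = sum((Fraction(a) - m) ** 2 for a in vals) / (n - 1)
        z4 = sum(((Fraction(a) - m) ** 2) ** 2 for a in vals) / var ** 2
        k_exact = (Fraction(n * (n + 1), (n - 1) * (n - 2) * (n - 3)) * z4
                   - Fraction(3 * (n - 1) ** 2, (n - 2) * (n - 3)))
        assert k_exact == Fraction(-6, 5)
        fv = extract_first_order(roi_from_values(vals))
        assert fv.k == pytest.approx(float(k_exact), abs=1e-12)

    def test_two_equal_mass_bins(self):
        fv = extract_first_order(roi_from_values([0, 0, 1, 1]), n_bins=2)
        assert fv.e == pytest.approx(1.0)
        assert fv.u == pytest.approx(0.5)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError, match="4"):
            extract_first_order(roi_from_values([1, 2, 3]))

    def test_matches_naive_oracle_on_random_rois(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            vals = rng.normal(rng.uniform(-100, 200), rng.uniform(1, 60), n)
            hist = histogram_probabilities(roi_from_values(vals), n_bins=32)
            fv = extract_first_order(roi_from_values(vals), hist=hist)
            e, u, m, sd, k, s = oracle_first_order(vals, hist.p)
            assert np.allclose([fv.e, fv.u, fv.m, fv.sd, fv.k, fv.s],
                               [e, u, m, sd, k, s], atol=1e-9, rtol=1e-9)

    def test_entropy_zero_iff_uniformity_one(self, rng):
        for _ in range(20):
            vals = rng.normal(0, rng.uniform(0, 2), 50)
            fv = extract_first_order(roi_from_values(vals), n_bins=16)
            assert (fv.e == 0.0) == (fv.u == 1.0)

    def test_uniform_histogram_extremes(self):
        # k equal-mass bins maximize entropy (= log2 k) and minimize uniformity
        vals = np.repeat(np.arange(8) + 0.5, 10)
        fv = extract_first_order(roi_from_values(vals), n_bins=8)
        assert fv.e == pytest.approx(3.0)
        assert fv.u == pytest.approx(1 / 8)

    @given(shift=st.floats(-500, 500), scale=st.floats(0.1, 50))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariances(self, shift, scale):
        base = np.array([3.0, -1.0, 7.0, 2.5, 0.0, 11.0, 4.0, -2.0])
        fv0 = extract_first_order(roi_from_values(base))
        fv1 = extract_first_order(roi_from_values(scale * base + shift))
        assert fv1.m == pytest.approx(scale * fv0.m + shift, rel=1e-9, abs=1e-6)
        assert fv1.sd == pytest.approx(scale * fv0.sd, rel=1e-9, abs=1e-9)
        assert fv1.s == pytest.approx(fv0.s, rel=1e-6, abs=1e-6)
        assert fv1.k == pytest.approx(fv0.k, rel=1e-6, abs=1e-6)

    def test_order_invariance(self, rng):
        vals = rng.normal(0, 10, 60)
        fv0 = extract_first_order(roi_from_values(vals))
        fv1 = extract_first_order(roi_from_values(rng.permutation(vals)))
        for a, b in zip(fv0.as_dict().values(), fv1.as_dict().values()):
            assert a == pytest.approx(b, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------

def oracle_glcm(pixels, inside, levels, offsets):
    """Brute-force pair counting + textbook Haralick formulas."""
    vals = pixels[inside]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        quant = np.zeros_like(pixels, dtype=int)
    else:
        quant = np.clip(np.floor((pixels - lo) / (hi - lo) * levels), 0,
                        levels - 1).astype(int)
    cm = np.zeros((levels, levels))
    rows, cols = pixels.shape
    for r in range(rows):
        for c in range(cols):
            if not inside[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and inside[r2, c2]:
                    cm[quant[r, c], quant[r2, c2]] += 1
    cm = cm + cm.T
    p = cm / cm.sum()
    lv = np.arange(levels)
    pi = p.sum(axis=1)
    mu = (lv * pi).sum()
    sig2 = (((lv - mu) ** 2) * pi).sum()
    out = {}
    out["angular_second_moment"] = (p ** 2).sum()
    out["entropy"] = -sum(p[i, j] * math.log2(p[i, j])
                          for i in range(levels) for j in range(levels)
                          if p[i, j] > 0)
    out["contrast"] = sum((i - j) ** 2 * p[i, j]
                          for i in range(levels) for j in range(levels))
    out["inertia"] = out["contrast"]
    out["inverse_difference_moment"] = sum(p[i, j] / (1 + (i - j) ** 2)
                                           for i in range(levels)
                                           for j in range(levels))
    out["correlation"] = (sum((i - mu) * (j - mu) * p[i, j]
                              for i in range(levels) for j in range(levels))
                          / sig2) if sig2 > 0 else 1.0
    ps = np.zeros(2 * levels - 1)
    pd = np.zeros(levels)
    for i in range(levels):
        for j in range(levels):
            ps[i + j] += p[i, j]
            pd[abs(i - j)] += p[i, j]
    ks = np.arange(2 * levels - 1)
    kd = np.arange(levels)
    out["sum_average"] = (ks * ps).sum()
    out["sum_entropy"] = -sum(v * math.log2(v) for v in ps if v > 0)
    out["sum_variance"] = ((ks - out["sum_average"]) ** 2 * ps).sum()
    out["variance"] = sig2
    out["difference_average"] = (kd * pd).sum()
    out["difference_variance"] = ((kd - out["difference_average"]) ** 2 * pd).sum()
    out["difference_entropy"] = -sum(v * math.log2(v) for v in pd if v > 0)
    return out


class TestGLCM:
    def test_constant_roi(self):
        img = CTImage(pixels=np.full((5, 5), 80.0))
        feats = glcm_features(img, ROIMask(inside=np.ones((5, 5))), levels=8)
        assert feats["angular_second_moment"] == pytest.approx(1.0)
        assert feats["contrast"] == 0.0
        assert feats["entropy"] == 0.0

    def test_checkerboard_single_offset(self):
        board = (np.indices((6, 6)).sum(axis=0) % 2).astype(float)
        img = CTImage(pixels=board)
        feats = glcm_features(img, ROIMask(inside=np.ones((6, 6))), levels=2,
                              offsets=((0, 1),))
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["angular_second_moment"] == pytest.approx(0.5)

    def test_contrast_inertia_alias(self, rng):
        img = CTImage(pixels=rng.uniform(0, 100, (8, 8)))
        feats = glcm_features(img, ROIMask(inside=np.ones((8, 8))))
        assert feats["contrast"] == feats["inertia"]
        assert len(feats) == 13

    def test_random_roi_matches_pair_counting_oracle(self, rng):
        for _ in range(5):
            px = rng.uniform(-50, 250, (8, 8))
            inside = rng.uniform(size=(8, 8)) > 0.3
            inside[3:5, 3:5] = True
            offsets = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
            got = glcm_features(CTImage(pixels=px), ROIMask(inside=inside),
                                levels=6, offsets=offsets)
            want = oracle_glcm(px, inside, 6, offsets)
            for name, v in want.items():
                assert got[name] == pytest.approx(v, abs=1e-9), name

    def test_pairs_require_both_pixels_inside(self):
        # two inside pixels never adjacent for offset (0,1) -> no pair
        inside = np.zeros((4, 4), bool)
        inside[0, 0] = inside[2, 2] = True
        img = CTImage(pixels=np.arange(16, dtype=float).reshape(4, 4))
        with pytest.raises(ValueError, match="pair"):
            glcm_features(img, ROIMask(inside=inside), levels=4, offsets=((0, 1),))
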