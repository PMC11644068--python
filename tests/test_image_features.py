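"""Zonal statistics, vegetation-index bank, GLCM texture and canopy cover."""

import datetime as dt
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from shapely.geometry import box

from agbfusion import image_features as feat
from agbfusion.image_features import (
    GLCM_STAT_NAMES,
    VI_NAMES,
    canopy_cover,
    compute_vis,
    extract_band_means,
    extract_features,
    glcm_features,
    glcm_features_patch,
    glcm_matrix,
)
from agbfusion.synthetic_scene import (
    BAND_ROLES,
    GroundTruth,
    render_plot_image,
)


def _stack(ms, rgb=None):
    from agbfusion.synthetic_scene import BandStack

    if rgb is None:
        rgb = np.clip(ms[..., [3, 1, 0]] * 255, 0, 255)
    return BandStack(ms=ms, rgb=rgb, band_roles=dict(BAND_ROLES),
                     plot_id="p", flight_date=dt.date(2023, 7, 15))


class TestBandMeans:
    def test_constant_image(self):
        ms = np.full((20, 20, 6), 0.3)
        bm = extract_band_means(_stack(ms), box(0, 0, 20, 20))
        assert all(v == pytest.approx(0.3) for v in bm.means.values())

    def test_half_polygon_of_two_valued_image(self):
        ms = np.zeros((20, 20, 6))
        ms[:, 10:, :] = 1.0  # right half bright
        bm = extract_band_means(_stack(ms), box(5, 0, 15, 20))
        assert all(v == pytest.approx(0.5) for v in bm.means.values())

    def test_matches_per_pixel_loop_oracle(self, rng):
        from shapely.geometry import Point

        ms = rng.random((32, 32, 6))
        poly = box(3.2, 4.7, 28.9, 27.1)
        bm = extract_band_means(_stack(ms), poly)
        # brute-force oracle: explicit double loop with center-point test
        for slot, role in BAND_ROLES.items():
            total, count = 0.0, 0
            for i in range(32):
                for j in range(32):
                    if poly.covers(Point(j + 0.5, i + 0.5)):
                        total += ms[i, j, int(slot[-1]) - 1]
                        count += 1
            assert bm[role] == pytest.approx(total / count, abs=1e-12)

    def test_empty_intersection_rejected(self):
        ms = np.full((20, 20, 6), 0.3)
        with pytest.raises(ValueError, match="polygon"):
            extract_band_means(_stack(ms), box(100, 100, 120, 120))


class TestVegetationIndices:
    MEANS = {"nir": 0.5, "red": 0.1, "green": 0.2, "red_edge": 0.3,
             "blue": 0.05, "pan": 0.15}

    def test_bank_has_14_indices(self):
        assert len(VI_NAMES) == 14
        assert set(compute_vis(self.MEANS)) == set(VI_NAMES)

    def test_optional_grndvi_is_a_15th(self):
        out = compute_vis(self.MEANS, include_grndvi=True)
        assert len(out) == 15
        assert out["GRNDVI"] == pytest.approx((0.5 - 0.3) / (0.5 + 0.3))

    @pytest.mark.parametrize(
        "name,value",
        [("NDVI", 0.4 / 0.6), ("SR", 5.0), ("GCI", 1.5),
         ("RECI", 0.5 / 0.3 - 1), ("NDRE", 0.25)],
    )
    def test_worked_values(self, name, value):
        assert compute_vis(self.MEANS)[name] == pytest.approx(value, abs=5e-5)

    def test_equal_nir_and_red(self):
        m = dict(self.MEANS, nir=0.3, red=0.3)
        out = compute_vis(m)
        assert out["NDVI"] == 0.0
        assert out["WDRVI"] < 0  # (0.1 NIR - R) is negative at NIR = R

    def test_zero_denominator_flagged_missing(self):
        m = dict(self.MEANS, green=0.0)
        assert math.isnan(compute_vis(m)["GRVI"])

    def test_depends_only_on_band_means(self, rng):
        """Indices are invariant to pixel arrangement: same means, same VIs."""
        ms = rng.random((16, 16, 6))
        shuffled = ms.reshape(-1, 6)[rng.permutation(256)].reshape(16, 16, 6)
        poly = box(0, 0, 16, 16)
        a = compute_vis(extract_band_means(_stack(ms), poly))
        b = compute_vis(extract_band_means(_stack(shuffled), poly))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestGlcmMatrix:
    def test_hand_enumerated_2x2(self):
        P = glcm_matrix(np.array([[0.0, 0.0], [1.0, 1.0]]), levels=2,
                        offset=(1, 0.0))
        # horizontal pairs: (0,0) and (1,1), symmetric-normalized to 0.5 each
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 1] == pytest.approx(0.5)
        assert P[0, 1] == 0.0

    def test_constant_patch_single_entry(self):
        P = glcm_matrix(np.full((5, 5), 3.7), levels=8)
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        patch=hnp.arrays(
            float, hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=8),
            elements=st.floats(0, 1, allow_nan=False, width=32),
        ),
        angle_idx=st.integers(0, 3),
    )
    def test_normalized_and_symmetric(self, patch, angle_idx):
        angle = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4][angle_idx]
        P = glcm_matrix(patch, levels=4, offset=(1, angle))
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(P, P.T, atol=1e-15)

    def test_matches_skimage_counting(self, rng):
        """Independent co-occurrence oracle: skimage graycomatrix."""
        from skimage.feature import graycomatrix

        levels = 6
        q = rng.integers(0, levels, (12, 12))
        for angle in (0.0, np.pi / 2):
            ours = glcm_matrix(q.astype(float) * (levels - 1) / levels, levels,
                               (1, angle))
            # feed identical integer image to skimage
            theirs = graycomatrix(
                q.astype(np.uint8), [1], [angle], levels=levels,
                symmetric=True, normed=True,
            )[..., 0, 0]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            glcm_matrix(np.ones((1, 5)), levels=4)
        with pytest.raises(ValueError):
            glcm_matrix(np.ones((4, 4)), levels=1)


def _loop_oracle(P):
    """Literal double-loop implementation of the eight texture statistics."""
    L = P.shape[0]
    mu = sum(i * P[i, j] for i in range(L) for j in range(L))
    va = sum((i - mu) ** 2 * P[i, j] for i in range(L) for j in range(L))
    out = {
        "ME": mu,
        "VA": va,
        "DI": sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L)),
        "CON": sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        "HO": sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)),
        "SE": sum(P[i, j] ** 2 for i in range(L) for j in range(L)),
        "COR": (
            sum((i - mu) * (j - mu) * P[i, j] for i in range(L) for j in range(L)) / va
            if va > 0 else 1.0
        ),
        "EN": -sum(
            P[i, j] * math.log(P[i, j])
            for i in range(L) for j in range(L) if P[i, j] > 0
        ),
    }
    return out


class TestGlcmFeatures:
    def test_single_entry_matrix_degenerate_texture(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = glcm_features(P)
        assert f["HO"] == 1.0 and f["SE"] == 1.0
        assert f["CON"] == 0.0 and f["EN"] == 0.0

    def test_uniform_matrix_closed_form(self):
        L = 5
        f = glcm_features(np.full((L, L), 1 / L**2))
        assert f["SE"] == pytest.approx(1 / L**2)
        assert f["EN"] == pytest.approx(2 * math.log(L))

    def test_matches_loop_oracle_on_random_matrix(self, rng):
        M = rng.random((6, 6))
        M = M + M.T
        P = M / M.sum()
        got = glcm_features(P)
        want = _loop_oracle(P)
        for k in GLCM_STAT_NAMES:
            assert got[k] == pytest.approx(want[k], abs=1e-12), k

    def test_eight_statistics(self):
        assert len(GLCM_STAT_NAMES) == 8

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(np.ones((3, 3)))

    def test_invariant_to_additive_shift_of_patch(self, rng):
        patch = rng.random((10, 10))
        a = glcm_features_patch(patch, levels=8)
        b = glcm_features_patch(patch + 5.0, levels=8)
        for k in GLCM_STAT_NAMES:
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestCanopyCover:
    def _render(self, cc, seed=0, size=(128, 128)):
        truth = GroundTruth("p", dt.date(2023, 7, 15), 2.0, cc, "S2")
        return render_plot_image(truth, size=size, seed=seed)

    def test_all_soil_plot(self):
        stack = self._render(0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = canopy_cover(stack, box(0, 0, 128, 128))
        assert got.cc <= 0.05

    def test_all_vegetation_plot(self):
        stack = self._render(1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = canopy_cover(stack, box(0, 0, 128, 128))
        assert got.cc >= 0.95

    def test_half_cover_recovered(self):
        stack = self._render(0.5)
        got = canopy_cover(stack, box(0, 0, 128, 128))
        assert abs(got.cc - 0.5) <= 0.05

    def test_threshold_scale_invariance(self):
        """Otsu is equivariant to positive scaling of the index image."""
        stack = self._render(0.4, seed=2)
        base = canopy_cover(stack, box(0, 0, 128, 128))
        scaled = stack
        scaled.rgb = stack.rgb * 3.0
        rescored = canopy_cover(scaled, box(0, 0, 128, 128))
        assert rescored.cc == pytest.approx(base.cc)

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            canopy_cover(self._render(0.5), box(0, 0, 128, 128), index="savi")

    def test_ndvi_route_agrees_with_exg(self):
        stack = self._render(0.6, seed=4)
        poly = box(0, 0, 128, 128)
        a = canopy_cover(stack, poly, index="exg")
        b = canopy_cover(stack, poly, index="ndvi")
        assert abs(a.cc - b.cc) <= 0.02


class TestExtractFeatures:
    def test_row_has_namespaced_groups(self):
        stack = render_plot_image(
            GroundTruth("p", dt.date(2023, 7, 15), 2.0, 0.5, "S2"), seed=0
        )
        row = extract_features(stack, box(0, 0, 64, 64))
        vis = [k for k in row if k.startswith("vi.")]
        tex = [k for k in row if k.startswith("tex.")]
        assert len(vis) == 14
        assert len(tex) == 8 * 6  # 8 statistics per multispectral band
        assert "cc" in row
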