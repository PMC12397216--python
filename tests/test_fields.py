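import numpy as np
import pytest

import devatlas as da
from devatlas.fields import round_half_down
from devatlas.synthetic import make_analytic_field

SHAPE = (32, 32, 32)
INTERIOR = (slice(8, -8),) * 3


def spaces(age_src=56, age_tgt=28, shape=SHAPE):
    return da.make_space(age_src, shape), da.make_space(age_tgt, shape)


def brute_force_trilinear(values, coords):
    """Independent trilinear sampler (zero fill outside) used as the warp
    oracle; written against the mathematical definition, not the package."""
    out = np.zeros(coords.shape[1:])
    x, y, z = coords
    x0, y0, z0 = np.floor(x).astype(int), np.floor(y).astype(int), np.floor(z).astype(int)
    fx, fy, fz = x - x0, y - y0, z - z0

    def at(i, j, k):
        inside = ((i >= 0) & (i < values.shape[0]) & (j >= 0)
                  & (j < values.shape[1]) & (k >= 0) & (k < values.shape[2]))
        v = np.zeros_like(out)
        v[inside] = values[i[inside], j[inside], k[inside]]
        return v

    for di, wx in ((0, 1 - fx), (1, fx)):
        for dj, wy in ((0, 1 - fy), (1, fy)):
            for dk, wz in ((0, 1 - fz), (1, fz)):
                out += wx * wy * wz * at(x0 + di, y0 + dj, z0 + dk)
    return out


class TestWarpVolume:
    def test_zero_field_is_identity(self, gaussian_blob):
        src, tgt = spaces(gaussian_blob.space.age, 4)
        field = da.zero_field(gaussian_blob.space, tgt)
        out = da.warp_volume(gaussian_blob, field)
        assert np.array_equal(out.values, gaussian_blob.values)

    def test_constant_field_shifts_impulse(self):
        src, tgt = spaces()
        vol = np.zeros(SHAPE)
        vol[10, 5, 5] = 1.0
        field = make_analytic_field("translation", {"offset": (2.0, 0, 0)},
                                    source=src, target=tgt)
        out = da.warp_volume(da.IntensityVolume(space=src, values=vol), field)
        assert out.values[8, 5, 5] == 1.0
        assert out.values.sum() == 1.0

    def test_sinusoidal_warp_matches_brute_force(self, gaussian_blob):
        src = gaussian_blob.space
        field = make_analytic_field(
            "sinusoidal", {"amplitude": 2.0, "frequency": 0.15},
            source=src, target=da.make_space(14, SHAPE))
        out = da.warp_volume(gaussian_blob, field, mode="linear")
        coords = (np.indices(SHAPE, dtype=float)
                  + np.moveaxis(field.displacement, -1, 0))
        expected = brute_force_trilinear(gaussian_blob.values, coords)
        assert np.max(np.abs(out.values - expected)) < 1e-6

    def test_space_mismatch_names_both_ages(self, gaussian_blob):
        field = da.zero_field(da.make_space(7, SHAPE), da.make_space(4, SHAPE))
        with pytest.raises(da.SpaceMismatchError, match="P7"):
            da.warp_volume(gaussian_blob, field)

    def test_linear_mode_on_labels_rejected(self):
        src, tgt = spaces()
        labels = da.LabelVolume(space=src,
                                labels=np.ones(SHAPE, dtype=np.int32))
        field = da.zero_field(src, tgt)
        with pytest.raises(ValueError, match="nearest"):
            da.warp_volume(labels, field, mode="linear")

    def test_nearest_warp_never_invents_labels(self):
        rng = np.random.default_rng(7)
        src, tgt = spaces()
        labels = da.LabelVolume(
            space=src, labels=rng.integers(0, 5, SHAPE, dtype=np.int32))
        field = make_analytic_field("centred_scaling", {"factor": 1.3},
                                    source=src, target=tgt)
        out = da.warp_volume(labels, field)
        assert out.label_set() <= labels.label_set()

    def test_out_of_domain_samples_become_background(self):
        src, tgt = spaces()
        field = make_analytic_field("translation", {"offset": (40.0, 0, 0)},
                                    source=src, target=tgt)
        vol = da.IntensityVolume(space=src, values=np.ones(SHAPE))
        assert np.all(da.warp_volume(vol, field).values == 0)
        labels = da.LabelVolume(space=src, labels=np.ones(SHAPE, np.int32))
        assert np.all(da.warp_volume(labels, field).labels == 0)


class TestRoundingTieRule:
    def test_half_rounds_toward_smaller_index(self):
        assert round_half_down(np.array([2.5, 2.6, 2.4, -0.5])).tolist() == \
            [2, 3, 2, -1]


class TestMapPoints:
    def test_zero_and_constant_fields(self):
        src, tgt = spaces()
        pts = da.PointSet(space=tgt, points=np.array([[5., 6., 7.]]))
        assert np.array_equal(
            da.map_points(pts, da.zero_field(src, tgt)).points, pts.points)
        field = make_analytic_field("translation", {"offset": (1., 2., 3.)},
                                    source=src, target=tgt)
        assert np.allclose(da.map_points(pts, field).points,
                           [[6., 8., 10.]])

    def test_linear_scaling_closed_form(self):
        src, tgt = spaces()
        a, c = 1.2, (np.asarray(SHAPE) - 1) / 2.0
        field = make_analytic_field("centred_scaling", {"factor": a},
                                    source=src, target=tgt)
        pts = np.array([[10.0, 12.0, 20.0], [15.5, 15.5, 15.5]])
        out = da.map_points(da.PointSet(space=tgt, points=pts), field)
        assert np.max(np.abs(out.points - (c + a * (pts - c)))) < 1e-6

    def test_out_of_domain_flagged_not_dropped(self):
        src, tgt = spaces()
        field = make_analytic_field("translation", {"offset": (30.0, 0, 0)},
                                    source=src, target=tgt)
        out = da.map_points(
            da.PointSet(space=tgt, points=np.array([[5., 5., 5.]])), field)
        assert len(out) == 1 and out.out_of_domain().all()


class TestInvertField:
    def test_zero_field_inverts_to_zero(self):
        src, tgt = spaces()
        inv = da.invert_field(da.zero_field(src, tgt))
        assert np.all(inv.displacement == 0)
        assert (inv.source.age, inv.target.age) == (tgt.age, src.age)

    def test_constant_field_inverts_exactly(self):
        src, tgt = spaces()
        field = make_analytic_field("translation", {"offset": (1.5, -2., 0.5)},
                                    source=src, target=tgt)
        inv = da.invert_field(field)
        assert np.allclose(inv.displacement, [-1.5, 2., -0.5])
        assert inv.metadata["inverse_residual"] < 1e-9

    def test_scaling_inverse_matches_closed_form(self):
        src, tgt = spaces()
        field = make_analytic_field("centred_scaling", {"factor": 1.25},
                                    source=src, target=tgt)
        inv = da.invert_field(field, tol=0.05)
        ana = field.metadata["analytic_inverse"]
        err = np.abs(inv.displacement[INTERIOR] - ana.displacement[INTERIOR])
        assert err.max() < 0.05

    def test_double_inversion_recovers_field(self):
        src, tgt = spaces()
        field = make_analytic_field(
            "sinusoidal", {"amplitude": 1.5, "frequency": 0.2},
            source=src, target=tgt)
        twice = da.invert_field(da.invert_field(field, tol=0.01), tol=0.01)
        err = np.abs(twice.displacement[INTERIOR]
                     - field.displacement[INTERIOR])
        assert err.max() < 0.02  # 2 * tol

    def test_point_round_trip_through_inverse(self):
        src, tgt = spaces()
        field = make_analytic_field(
            "sinusoidal", {"amplitude": 1.5, "frequency": 0.2},
            source=src, target=tgt)
        inv = da.invert_field(field, tol=0.01)
        rng = np.random.default_rng(0)
        pts = da.PointSet(space=tgt,
                          points=rng.uniform(8, 23, size=(50, 3)))
        fwd = da.map_points(pts, field)
        back = da.map_points(da.PointSet(space=field.source,
                                         points=fwd.points), inv)
        assert np.max(np.abs(back.points - pts.points)) < 0.02

    def test_large_residual_warns_not_fails(self):
        src, tgt = spaces()
        # self-coupled sinusoid with |A k| = 2.5: folds, so the fixed-point
        # iteration cannot settle and the residual stays large
        U = np.zeros(SHAPE + (3,))
        grid0 = np.indices(SHAPE, dtype=float)[0]
        U[..., 0] = 5.0 * np.sin(0.5 * grid0)
        field = da.DisplacementField(source=src, target=tgt, displacement=U)
        with pytest.warns(RuntimeWarning, match="residual"):
            inv = da.invert_field(field, tol=0.001, max_iter=5)
        assert "inverse_warning" in inv.metadata


class TestComposeFields:
    def test_identity_element(self):
        src, tgt = spaces()
        field = make_analytic_field(
            "sinusoidal", {"amplitude": 1.0, "frequency": 0.2},
            source=src, target=tgt)
        ident_inner = da.zero_field(tgt, da.make_space(tgt.age, SHAPE))
        composed = da.compose_fields(outer=field, inner=ident_inner)
        assert np.allclose(composed.displacement, field.displacement)
        ident_outer = da.zero_field(da.make_space(src.age, SHAPE), src)
        composed2 = da.compose_fields(outer=ident_outer, inner=field)
        assert np.allclose(composed2.displacement, field.displacement)

    def test_translations_add(self):
        s56, s28 = spaces()
        s14 = da.make_space(14, SHAPE)
        outer = make_analytic_field("translation", {"offset": (1., 2., 0.)},
                                    source=s56, target=s28)
        inner = make_analytic_field("translation", {"offset": (0.5, 0., 3.)},
                                    source=s28, target=s14)
        composed = da.compose_fields(outer=outer, inner=inner)
        assert np.allclose(composed.displacement, [1.5, 2., 3.])
        assert (composed.source.age, composed.target.age) == (56, 14)

    def test_centred_scalings_multiply(self):
        s56, s28 = spaces()
        s14 = da.make_space(14, SHAPE)
        outer = make_analytic_field("centred_scaling", {"factor": 1.1},
                                    source=s56, target=s28)
        inner = make_analytic_field("centred_scaling", {"factor": 1.15},
                                    source=s28, target=s14)
        composed = da.compose_fields(outer=outer, inner=inner)
        expected = make_analytic_field("centred_scaling",
                                       {"factor": 1.1 * 1.15},
                                       source=s56, target=s14)
        err = np.abs(composed.displacement[INTERIOR]
                     - expected.displacement[INTERIOR])
        assert err.max() < 1e-4

    def test_associativity_on_smooth_fields(self):
        ages = [56, 28, 21, 14]
        sps = [da.make_space(a, SHAPE) for a in ages]
        f1 = make_analytic_field("sinusoidal",
                                 {"amplitude": 0.8, "frequency": 0.15},
                                 source=sps[0], target=sps[1])
        f2 = make_analytic_field("centred_scaling", {"factor": 1.05},
                                 source=sps[1], target=sps[2])
        f3 = make_analytic_field("translation", {"offset": (0.5, 0.5, 0)},
                                 source=sps[2], target=sps[3])
        left = da.compose_fields(outer=da.compose_fields(outer=f1, inner=f2),
                                 inner=f3)
        right = da.compose_fields(outer=f1,
                                  inner=da.compose_fields(outer=f2, inner=f3))
        err = np.abs(left.displacement[INTERIOR]
                     - right.displacement[INTERIOR])
        assert err.max() < 5e-3  # trilinear interpolation error bound

    def test_chain_mismatch_names_ages(self):
        s56, s28 = spaces()
        s14 = da.make_space(14, SHAPE)
        f1 = da.zero_field(s56, s28)
        f3 = da.zero_field(s14, da.make_space(7, SHAPE))
        with pytest.raises(da.SpaceMismatchError, match="P14"):
            da.compose_fields(outer=f1, inner=f3)


class TestScaleField:
    @pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 2.0),
                                                   (0.5, 1.0)])
    def test_linearity_on_constant(self, fraction, expected):
        src, tgt = spaces()
        field = make_analytic_field("translation", {"offset": (2., 0., 0.)},
                                    source=src, target=tgt)
        out = da.scale_field(field, fraction)
        assert np.allclose(out.displacement[..., 0], expected)

    def test_fraction_out_of_bounds_rejected(self):
        src, tgt = spaces()
        field = da.zero_field(src, tgt)
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                da.scale_field(field, bad)


class TestWarpRoundTrip:
    def test_volume_round_trip_within_tolerance(self, gaussian_blob):
        src = gaussian_blob.space
        tgt = da.make_space(14, SHAPE)
        field = make_analytic_field(
            "sinusoidal", {"amplitude": 1.5, "frequency": 0.2},
            source=src, target=tgt)
        inv = da.invert_field(field, tol=0.01)
        warped = da.warp_volume(gaussian_blob, field, mode="linear")
        back = da.warp_volume(
            da.IntensityVolume(space=field.target, values=warped.values),
            inv, mode="linear")
        rng_ = gaussian_blob.values.max() - gaussian_blob.values.min()
        err = np.abs(back.values[INTERIOR] - gaussian_blob.values[INTERIOR])
        assert err.max() < 0.02 * rng_
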