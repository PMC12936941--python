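import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from auxleak import neighborhood as nb
from conftest import make_track


def frame_table(cells):
    """One-frame table from (track_id, cell_type, x, y, area) tuples."""
    return pd.DataFrame(
        {
            "replicate_id": "R1",
            "chamber_id": "C1",
            "frame": 0,
            "time_h": 0.0,
            "track_id": [c[0] for c in cells],
            "cell_type": [c[1] for c in cells],
            "x_um": [c[2] for c in cells],
            "y_um": [c[3] for c in cells],
            "length_um": [c[4] for c in cells],
            "area_um2": [c[4] for c in cells],
        }
    )


class TestLocalFraction:
    def test_only_aux_inside_radius(self):
        t = frame_table(
            [(0, "WT", 10, 10, 1.0), (1, "AUX", 12, 10, 1.5), (2, "WT", 18, 10, 2.0)]
        )
        assert nb.local_aux_fraction(t, 0, "R1", "C1", 0, radius_um=5) == 1.0

    def test_area_weighting(self):
        t = frame_table(
            [(0, "WT", 10, 10, 1.0), (1, "AUX", 12, 10, 2.0), (2, "WT", 8, 10, 6.0)]
        )
        assert nb.local_aux_fraction(t, 0, "R1", "C1", 0, radius_um=5) == 0.25

    def test_no_neighbors_is_missing(self):
        t = frame_table([(0, "WT", 10, 10, 1.0), (1, "AUX", 30, 30, 1.0)])
        assert np.isnan(nb.local_aux_fraction(t, 0, "R1", "C1", 0, radius_um=5))

    def test_absent_focal_errors(self):
        t = frame_table([(0, "WT", 10, 10, 1.0)])
        with pytest.raises(ValueError):
            nb.local_aux_fraction(t, 0, "R1", "C1", 99, radius_um=5)

    def test_focal_cell_excluded_from_its_own_neighborhood(self):
        # focal is AUX but only its WT neighbor counts
        t = frame_table([(0, "AUX", 10, 10, 5.0), (1, "WT", 11, 10, 1.0)])
        assert nb.local_aux_fraction(t, 0, "R1", "C1", 0, radius_um=5) == 0.0


class TestRasterized:
    def test_single_aux_disc(self):
        shapes = [
            {"kind": "disc", "x": 10, "y": 10, "radius": 0.5, "is_aux": False},
            {"kind": "disc", "x": 11, "y": 10, "radius": 0.5, "is_aux": True},
        ]
        assert nb.rasterized_aux_fraction(shapes, 0, radius_um=5) == 1.0

    def test_equal_rectangles_half(self):
        shapes = [
            {"kind": "rect", "x": 10, "y": 10, "width": 1, "height": 2, "is_aux": False},
            {"kind": "rect", "x": 12, "y": 10, "width": 1, "height": 2, "is_aux": True},
            {"kind": "rect", "x": 8, "y": 10, "width": 1, "height": 2, "is_aux": False},
        ]
        # equal-size rectangles, so equal pixel counts up to grid alignment
        got = nb.rasterized_aux_fraction(shapes, 0, radius_um=5)
        assert got == pytest.approx(0.5, abs=0.02)
        finer = nb.rasterized_aux_fraction(shapes, 0, radius_um=5, um_per_pixel=0.01)
        assert abs(finer - 0.5) <= abs(got - 0.5) + 1e-12

    def test_straddling_rectangle_matches_pixel_enumeration(self):
        px = 0.065
        shapes = [
            {"kind": "rect", "x": 10, "y": 10, "width": 1, "height": 1, "is_aux": False},
            {"kind": "rect", "x": 14.3, "y": 10, "width": 2, "height": 3, "is_aux": True},
            {"kind": "rect", "x": 11, "y": 11, "width": 1, "height": 1, "is_aux": False},
        ]
        got = nb.rasterized_aux_fraction(shapes, 0, radius_um=5, um_per_pixel=px)

        def brute_count(sh):  # exhaustive global-grid enumeration
            n = 0
            k0x, k1x = int(np.floor(6 / px)), int(np.ceil(18 / px))
            for kx in range(k0x, k1x):
                cx = (kx + 0.5) * px
                if abs(cx - sh["x"]) > sh["width"] / 2:
                    continue
                for ky in range(int(np.floor(6 / px)), int(np.ceil(14 / px))):
                    cy = (ky + 0.5) * px
                    if abs(cy - sh["y"]) > sh["height"] / 2:
                        continue
                    if (cx - 10) ** 2 + (cy - 10) ** 2 <= 25:
                        n += 1
            return n

        counts = [brute_count(sh) for sh in shapes[1:]]
        assert got == counts[0] / (counts[0] + counts[1])

    def test_zero_area_shape_errors(self):
        shapes = [
            {"kind": "rect", "x": 0, "y": 0, "width": 1, "height": 1, "is_aux": False},
            {"kind": "rect", "x": 1, "y": 0, "width": 0, "height": 1, "is_aux": True},
        ]
        with pytest.raises(ValueError):
            nb.rasterized_aux_fraction(shapes, 0, radius_um=5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_centroid_and_raster_rules_agree_on_separated_layouts(self, seed):
        # with small cells far from the circle boundary the two area rules
        # agree; discretization error shrinks with pixel size
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 7)
        xs = rng.uniform(8, 12, n)
        ys = rng.uniform(8, 12, n)
        aux = rng.random(n) < 0.5
        side = 0.4
        shapes = [
            {"kind": "rect", "x": x, "y": y, "width": side, "height": side, "is_aux": bool(a)}
            for x, y, a in zip(xs, ys, aux)
        ]
        t = frame_table(
            [(i, "AUX" if a else "WT", x, y, side * side) for i, (x, y, a) in enumerate(zip(xs, ys, aux))]
        )
        centroid = nb.local_aux_fraction(t, 0, "R1", "C1", 0, radius_um=6)
        raster = nb.rasterized_aux_fraction(shapes, 0, radius_um=6, um_per_pixel=0.01)
        if np.isnan(centroid):
            assert np.isnan(raster)
        else:
            assert raster == pytest.approx(centroid, abs=0.02)


class TestLifetimeFraction:
    def test_constant_composition(self):
        t = pd.concat(
            [
                make_track(0, [2.0, 2.1], x=10, y=10, cell_type="WT"),
                make_track(1, [1.0, 1.0], x=12, y=10, cell_type="AUX"),
            ],
            ignore_index=True,
        )
        rec = nb.lifetime_fraction(t, radius_um=5).set_index("track_id")
        # focal 1's only neighbor is track 0 (WT) at both frames
        assert rec.loc[1, "aux_fraction"] == 0.0
        assert rec.loc[1, "n_frames_defined"] == 2

    def test_mean_of_defined_frames(self):
        # frame 0: AUX/total = 1/2; frame 1: only WT neighbor -> 0
        rows = pd.concat(
            [
                make_track(0, [2.0, 2.0], x=10, y=10),
                make_track(1, [2.0], frames=[0], x=12, y=10, cell_type="AUX"),
                make_track(2, [2.0, 2.0], x=8, y=10),
            ],
            ignore_index=True,
        )
        rec = nb.lifetime_fraction(rows, radius_um=5).set_index("track_id")
        assert rec.loc[0, "aux_fraction"] == pytest.approx((0.5 + 0.0) / 2)

    def test_matches_per_frame_recomputation(self, fast_chamber):
        tracks, _ = fast_chamber
        sub = tracks[tracks["frame"] < 12]
        rec = nb.lifetime_fraction(sub, radius_um=5).set_index("track_id")
        rng = np.random.default_rng(0)
        for tid in rng.choice(rec.index.to_numpy(), 8, replace=False):
            vals = []
            for fr in sub.loc[sub["track_id"] == tid, "frame"]:
                vals.append(nb.local_aux_fraction(sub, fr, "R1", "C1", tid, 5.0))
            expect = np.nanmean(vals) if not np.all(np.isnan(vals)) else np.nan
            got = rec.loc[tid, "aux_fraction"]
            assert got == pytest.approx(expect, nan_ok=True, abs=1e-12)


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.arange(10.0)
        assert nb.spearman_rho(x, np.exp(x)) == 1.0
        assert nb.spearman_rho(x, -x) == -1.0

    def test_tied_example_hand_computed(self):
        # x=(1,2,3,4), y=(2,2,3,1): mid-ranks y=(2.5,2.5,4,1)
        # Pearson of ranks: cov=1.0? compute directly from the formula
        rx = np.array([1.0, 2.0, 3.0, 4.0])
        ry = np.array([2.5, 2.5, 4.0, 1.0])
        expect = np.corrcoef(rx, ry)[0, 1]
        assert nb.spearman_rho([1, 2, 3, 4], [2, 2, 3, 1]) == pytest.approx(expect, abs=1e-15)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        y[:10] = y[0]  # introduce ties
        assert nb.spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = nb.spearman_rho(x, y)
        assert nb.spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert nb.spearman_rho(x, y**3) == pytest.approx(base, abs=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            nb.spearman_rho([1, 2], [3, 4])
        with pytest.raises(ValueError):
            nb.spearman_rho([1, 1, 1], [1, 2, 3])


class TestPermutation:
    def test_monotone_pairs_highly_significant(self):
        x = np.arange(20.0)
        rho, p = nb.permutation_pvalue(x, 2 * x + 1, n_perm=10_000, seed=0)
        assert rho == 1.0
        # under shuffling only 2 of 20! orderings reach |rho| = 1
        assert p < 0.001

    def test_resolution_limit(self):
        rho, p = nb.permutation_pvalue(np.arange(10.0), np.arange(10.0) ** 2, n_perm=1, seed=0)
        assert p in (0.0, 1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert nb.permutation_pvalue(x, y, 500, seed=11) == nb.permutation_pvalue(
            x, y, 500, seed=11
        )

    def test_requires_seed(self):
        with pytest.raises(ValueError):
            nb.permutation_pvalue([1, 2, 3], [1, 2, 3], 10, seed=None)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(300):
            x, y = rng.normal(size=40), rng.normal(size=40)
            ps.append(nb.permutation_pvalue(x, y, n_perm=200, seed=rng)[1])
        # binomial 99.9% band around 0.05 for 300 draws
        rej = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= rej <= 0.10
        assert 0.4 < np.mean(ps) < 0.6


class TestRadiusSweep:
    def test_coupling_radius_strongest(self, fast_config):
        from auxleak.growth import apply_r2_filter, filter_tracks, fit_growth
        from auxleak.simulate import generate_replicates

        tracks = generate_replicates(fast_config, seed=10)
        filtered, _ = filter_tracks(tracks)
        rec = apply_r2_filter(fit_growth(filtered))
        sweep = nb.radius_sweep(rec, tracks, radii=(5.0, 13.0), n_perm=200, seed=2)
        aux = sweep[sweep.cell_type == "AUX"].set_index("radius_um")
        assert aux.loc[5.0, "rho"] < 0
        assert abs(aux.loc[5.0, "rho"]) >= abs(aux.loc[13.0, "rho"])

    def test_duplicate_radius_rejected(self):
        with pytest.raises(ValueError):
            nb.radius_sweep(pd.DataFrame(), pd.DataFrame(), radii=(5, 5))


class TestBinning:
    def test_fixed_width_edges(self):
        rec = pd.DataFrame({"aux_fraction": np.linspace(0, 1, 50), "mu_h": np.zeros(50)})
        out = nb.bin_growth_by_fraction(rec, mode="fixed_width", k=4)
        assert np.allclose(out["bin_left"], [0, 0.25, 0.5, 0.75])

    def test_quartile_counts(self):
        rec = pd.DataFrame({"aux_fraction": np.arange(8) / 8.0, "mu_h": np.arange(8.0)})
        out = nb.bin_growth_by_fraction(rec, mode="quartile")
        assert out["n"].tolist() == [2, 2, 2, 2]

    def test_monotone_relation_gives_monotone_medians(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0, 1, 400)
        rec = pd.DataFrame({"aux_fraction": f, "mu_h": 0.33 - 0.5 * 0.7 * f})
        out = nb.bin_growth_by_fraction(rec, mode="quartile")
        med = out["median_mu_h"].to_numpy()
        assert np.all(np.diff(med) < 0)

    def test_identical_fractions_error_in_quartile_mode(self):
        rec = pd.DataFrame({"aux_fraction": np.full(10, 0.3), "mu_h": np.arange(10.0)})
        with pytest.raises(ValueError):
            nb.bin_growth_by_fraction(rec, mode="quartile")
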