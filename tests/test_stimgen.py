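import math

import numpy as np
import pytest

import radialcontrast as rc
from radialcontrast import stimgen
from radialcontrast.stimgen import StimulusSpec, landolt_c, render, vernier

GEOM = rc.ViewingGeometry(57.0, 0.282)  # ~35.3 px/deg


def spec(family, **kw):
    base = dict(
        family=family,
        geometry=GEOM,
        eccentricity_deg=5.0,
        canvas_deg=2.0,
        target_params={},
        flanker_params={},
        target_level=0.0,
        flanker_level=0.0,
        background_level=0.5,
        supersample=1,
    )
    base.update(kw)
    return StimulusSpec(**base)


def ink_count(img, bg):
    return int(np.sum(img.intensities != bg))


class TestRenderDeterminism:
    def test_identical_specs_give_bit_identical_images(self):
        s = spec(
            "concentric_cs",
            canvas_deg=4.0,
            target_params=dict(diameter_deg=1.0),
            flanker_params=dict(count=2, ring_step_deg=0.4),
            supersample=2,
        )
        a, b = render(s), render(s)
        assert np.array_equal(a.intensities, b.intensities)

    def test_oversized_stimulus_rejected(self):
        s = spec(
            "concentric_cs",
            canvas_deg=1.0,
            target_params=dict(diameter_deg=0.9),
            flanker_params=dict(count=3, ring_step_deg=0.5),
        )
        with pytest.raises(ValueError):
            render(s)


class TestLetterArray:
    def test_isolated_target_has_two_intensity_levels(self):
        s = spec(
            "letter_array",
            target_params=dict(letter="r", height_deg=0.4),
            flanker_params=dict(count=0),
            target_level=0.5,
            background_level=1.0,
        )
        img = render(s)
        assert set(np.unique(img.intensities)) == {0.5, 1.0}

    def test_flankers_add_ink(self):
        kw = dict(
            target_params=dict(letter="r", height_deg=0.3),
            target_level=0.5,
            flanker_level=0.5,
            background_level=1.0,
        )
        alone = render(spec("letter_array", flanker_params=dict(count=0), **kw))
        four = render(
            spec(
                "letter_array",
                flanker_params=dict(count=4, distance_deg=0.5, letter="a"),
                **kw,
            )
        )
        assert ink_count(four, 1.0) > ink_count(alone, 1.0)

    def test_edge_convention_moves_flankers_outward(self):
        kw = dict(
            target_params=dict(letter="r", height_deg=0.3),
            target_level=0.5,
            flanker_level=0.5,
            background_level=1.0,
        )
        center = render(
            spec(
                "letter_array",
                flanker_params=dict(count=2, distance_deg=0.5, convention="center"),
                **kw,
            )
        )
        edge = render(
            spec(
                "letter_array",
                flanker_params=dict(count=2, distance_deg=0.5, convention="edge"),
                **kw,
            )
        )
        # edge-separated flankers reach farther from the centre
        cols_center = np.where((center.intensities != 1.0).any(axis=0))[0]
        cols_edge = np.where((edge.intensities != 1.0).any(axis=0))[0]
        assert cols_edge.max() > cols_center.max()


class TestLandoltC:
    def test_gap_removes_ink(self):
        gapped = landolt_c(50.0, 0.0)
        gapless = landolt_c(50.0, 0.0, gapless=True)
        assert gapped.sum() < gapless.sum()

    def test_ink_area_matches_annulus_minus_slot(self):
        d = 50.0
        glyph = landolt_c(d, 0.0, supersample=4)
        r_out, r_in = d / 2.0, d / 2.0 - d / 5.0
        analytic = math.pi * (r_out**2 - r_in**2) - (d / 5.0) ** 2
        assert glyph.sum() == pytest.approx(analytic, rel=0.10)

    def test_gap_rotation_preserves_ink_area(self):
        a = landolt_c(40.0, 0.0)
        b = landolt_c(40.0, 90.0)
        assert a.sum() == b.sum()

    def test_sub_resolution_diameter_rejected(self):
        with pytest.raises(ValueError):
            landolt_c(4.0, 0.0)


class TestLandoltBars:
    def test_bars_separated_from_target_at_large_distance(self):
        geom = rc.ViewingGeometry(2300.0, 0.282, 1423.4770)
        s = spec(
            "landolt_bars",
            canvas_deg=16.0 / 60.0,
            target_params=dict(diameter_arcmin=4.0, gap_orientation_deg=90.0),
            flanker_params=dict(count=4, distance_arcmin=3.0, length_arcmin=2.0,
                                width_arcmin=0.8),
        )
        s = StimulusSpec(**{**s.__dict__, "geometry": geom})
        img = render(s)
        # probe midway between the C's outer edge and the bar: pure background
        mid = img.shape[0] // 2
        px_per_arcmin = geom.pixels_per_degree / 60.0
        probe = int(round((2.0 + 1.5) * px_per_arcmin))  # r_out + half the gap
        assert img.intensities[mid - probe, mid] == 0.5

    def test_flanker_count_zero_is_target_alone(self):
        kw = dict(
            canvas_deg=1.5,
            target_params=dict(diameter_arcmin=20.0),
        )
        alone = render(spec("landolt_bars", flanker_params=dict(count=0), **kw))
        flanked = render(
            spec("landolt_bars", flanker_params=dict(count=4, distance_arcmin=5.0), **kw)
        )
        assert ink_count(flanked, 0.5) > ink_count(alone, 0.5)


class TestVernier:
    def test_mirrored_offsets_are_mirror_images(self):
        kw = dict(eccentricity_deg=3.88, flanker_count=4, canvas_deg=2.0)
        left = vernier(GEOM, offset_direction="left_top", **kw)
        right = vernier(GEOM, offset_direction="right_top", **kw)
        assert np.array_equal(left.intensities, np.fliplr(right.intensities))

    def test_ink_monotone_in_flanker_count(self):
        counts = [2, 4, 8, 16]
        inks = [
            ink_count(vernier(GEOM, flanker_count=n, canvas_deg=3.2, supersample=4), 0.0)
            for n in counts
        ]
        assert all(a < b for a, b in zip(inks, inks[1:]))

    def test_taller_flankers_double_ink_rows(self):
        one = vernier(GEOM, flanker_count=2, flanker_height_factor=1.0, canvas_deg=3.2)
        two = vernier(GEOM, flanker_count=2, flanker_height_factor=2.0, canvas_deg=3.2)
        # count ink rows in a flanker column (away from the central vernier)
        def flank_rows(img):
            cols = np.where((img.intensities != 0.0).any(axis=0))[0]
            return int((img.intensities[:, cols[0]] != 0.0).sum())

        r1, r2 = flank_rows(one), flank_rows(two)
        assert abs(r2 - 2 * r1) <= 1

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            vernier(GEOM, flanker_count=3)

    def test_overlapping_flankers_rejected(self):
        s = spec(
            "vernier_lines",
            target_params=dict(offset_arcmin=30.0, width_arcmin=10.0),
            flanker_params=dict(count=2, spacing_arcmin=10.0),
            target_level=1.0,
            flanker_level=1.0,
            background_level=0.0,
        )
        with pytest.raises(ValueError):
            render(s)


class TestConcentricCs:
    def test_more_rings_more_ink(self):
        def img(n):
            return render(
                spec(
                    "concentric_cs",
                    canvas_deg=6.0,
                    target_params=dict(diameter_deg=1.0),
                    flanker_params=dict(count=n, ring_step_deg=0.4),
                )
            )

        assert ink_count(img(5), 0.5) > ink_count(img(1), 0.5)

    def test_gapless_rings_have_more_ink(self):
        def img(gapless):
            return render(
                spec(
                    "concentric_cs",
                    canvas_deg=5.0,
                    target_params=dict(diameter_deg=1.0),
                    flanker_params=dict(count=2, ring_step_deg=0.4, gapless=gapless),
                )
            )

        assert ink_count(img(True), 0.5) > ink_count(img(False), 0.5)


class TestContrastPipelineComposition:
    def test_letter_contrast_dips_only_under_encroachment(self, pl_run):
        """Letter-array contrast is approximately flat once flankers are
        clear of the target and falls as they encroach on it."""
        config, points = pl_run
        frame = rc.curve_frame(points)
        for ecc, grp in frame.groupby("eccentricity_deg"):
            grp = grp.set_index("flank_distance_deg")["contrast_energy"]
            plateau = grp.loc[0.2:]
            assert plateau.max() / plateau.min() < 1.10
            assert grp.loc[0.05] < plateau.min()

    def test_five_rings_exceed_one_ring_contrast(self, pa_runs):
        (cfg1, pts1), (cfg5, pts5) = pa_runs
        f1 = rc.curve_frame(pts1).set_index(["ring_step_deg", "gapless"])
        f5 = rc.curve_frame(pts5).set_index(["ring_step_deg", "gapless"])
        assert (
            f5["contrast_energy"] > f1.loc[f5.index, "contrast_energy"]
        ).all()
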