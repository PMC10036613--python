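"""Scanpath-image encoding: layout geometry, colour rules, raster exactness."""

import io

import numpy as np
import pytest

from gazestrat.render import (
    OUT,
    SEQUENTIAL_LUT,
    AOILayout,
    RenderSpec,
    assign_aoi,
    build_layout,
    fixation_color,
    read_layout,
    render_scanpath,
    render_to_array,
    saccade_color,
    write_layout,
)
from gazestrat.synth import Fixation, SaccadeEvent, ScanpathRecord
from gazestrat.truncate import TruncationSpec, truncate_record


def record_with_fixations(layout, positions, dur=200.0, gap=30.0):
    fixations, saccades = [], []
    t = 0.0
    for i, (x, y) in enumerate(positions):
        fixations.append(Fixation(x=x, y=y, start=t, end=t + dur))
        t += dur
        if i < len(positions) - 1:
            saccades.append(
                SaccadeEvent((x, y), positions[i + 1], start_time=t, end_time=t + gap)
            )
            t += gap
    return ScanpathRecord("P0", "G0", tuple(fixations), tuple(saccades),
                          chosen="Top", rt=max(t, 1.0))


class TestLayout:
    def test_default_layout_has_18_paired_aois(self, layout):
        assert len(layout.aois) == 18
        assert sum(a.role == "own" for a in layout.aois) == 9
        assert sum(a.role == "other" for a in layout.aois) == 9
        for r in range(3):
            for c in range(3):
                roles = {a.role for a in layout.aois if a.cell == (r, c)}
                assert roles == {"own", "other"}

    def test_own_is_bottom_left_of_other_within_each_cell(self, layout):
        for r in range(3):
            for c in range(3):
                own = next(a for a in layout.aois if a.cell == (r, c) and a.role == "own")
                oth = next(a for a in layout.aois if a.cell == (r, c) and a.role == "other")
                assert own.center[0] < oth.center[0]  # left of
                assert own.center[1] > oth.center[1]  # below (y grows downward)

    def test_oversized_radius_raises_overlap_error(self):
        with pytest.raises(ValueError, match="overlap"):
            build_layout(aoi_radius=120.0)

    def test_layout_json_round_trip(self, tmp_path, layout):
        write_layout(layout, tmp_path / "layout.json")
        assert read_layout(tmp_path / "layout.json") == layout


class TestAssignAoi:
    def test_centre_is_inside(self, layout):
        a = layout.aois[0]
        assert assign_aoi(*a.center, layout) == a.aoi_id

    def test_boundary_point_is_inside_closed_disc(self):
        # integer-friendly geometry so centre + radius is exact in floats
        lay = build_layout(matrix_size=(720, 600), aoi_radius=45.0)
        a = lay.aois[0]
        assert assign_aoi(a.center[0] + a.radius, a.center[1], lay) == a.aoi_id

    def test_far_corner_is_out(self, layout):
        assert assign_aoi(1.0, 1.0, layout) == OUT


class TestFixationColor:
    def test_single_fixation_is_the_darkest_ramp_entry(self):
        assert fixation_color(1) == tuple(SEQUENTIAL_LUT[0])
        assert sum(fixation_color(1)) < 30  # near-black

    def test_counts_at_or_above_cap_share_one_colour(self):
        assert fixation_color(20) == fixation_color(35) == tuple(SEQUENTIAL_LUT[255])

    def test_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            fixation_color(0)

    def test_perceptual_lightness_is_monotone_in_count(self):
        from skimage.color import rgb2lab

        lightness = [
            rgb2lab(np.array(fixation_color(k), float)[None, None] / 255.0)[0, 0, 0]
            for k in range(1, 21)
        ]
        assert all(b >= a for a, b in zip(lightness, lightness[1:]))


class TestSaccadeColor:
    def test_first_saccade_is_dark_blue(self):
        assert saccade_color(0, 10) == (0, 0, 255)

    def test_single_saccade_takes_the_start_colour(self):
        assert saccade_color(0, 1) == (0, 0, 255)

    def test_midpoint_interpolates_channelwise(self):
        spec = RenderSpec()
        mid = saccade_color(1, 3, spec)
        expect = tuple(
            round((a + b) / 2)
            for a, b in zip(spec.saccade_start_rgb, spec.saccade_end_rgb)
        )
        assert mid == expect

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            saccade_color(3, 3)


class TestRenderScanpath:
    def test_empty_record_shows_only_the_aoi_circles(self, layout):
        rec = ScanpathRecord("P", "G", (), (), chosen="Top", rt=1.0)
        arr = render_to_array(rec, layout)
        spec = RenderSpec()
        colours = {tuple(c) for c in arr.reshape(-1, 3)}
        assert colours == {
            spec.background_rgb, spec.own_circle_rgb, spec.other_circle_rgb
        }

    def test_repeated_renders_are_byte_identical(self, layout, small_cohort):
        rec = small_cohort[0]
        bufs = []
        for _ in range(2):
            buf = io.BytesIO()
            render_scanpath(rec, layout).save(buf, format="PNG")
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_aoi_centre_pixel_encodes_the_fixation_count(self, layout):
        spec = RenderSpec()
        own = next(a for a in layout.aois if a.role == "own")
        for k in (1, 3, 12):
            rec = record_with_fixations(layout, [own.center] * k)
            arr = render_to_array(rec, layout, spec)
            sx = spec.image_size[0] / layout.screen[0]
            sy = spec.image_size[1] / layout.screen[1]
            px = arr[round(own.center[1] * sy), round(own.center[0] * sx)]
            assert tuple(px) == fixation_color(k, spec)

    def test_single_own_fixation_draws_a_near_black_triangle(self, layout):
        own = next(a for a in layout.aois if a.role == "own")
        rec = record_with_fixations(layout, [own.center])
        arr = render_to_array(rec, layout)
        assert tuple(SEQUENTIAL_LUT[0]) in {tuple(c) for c in arr.reshape(-1, 3)}

    def test_first_saccade_segment_contains_dark_blue_pixels(self, layout):
        a = next(x for x in layout.aois if x.cell == (0, 0) and x.role == "own")
        b = next(x for x in layout.aois if x.cell == (2, 2) and x.role == "own")
        rec = record_with_fixations(layout, [a.center, b.center, a.center])
        arr = render_to_array(rec, layout)
        assert (0, 0, 255) in {tuple(c) for c in arr.reshape(-1, 3)}

    def test_out_of_aoi_fixation_draws_a_fuchsia_dot(self, layout):
        rec = record_with_fixations(layout, [(5.0, 5.0)])
        arr = render_to_array(rec, layout)
        assert (255, 0, 255) in {tuple(c) for c in arr.reshape(-1, 3)}

    def test_off_screen_event_rejected(self, layout):
        rec = record_with_fixations(layout, [(-10.0, 5.0)])
        with pytest.raises(ValueError, match="outside screen"):
            render_to_array(rec, layout)

    def test_rendering_commutes_with_truncation(self, layout, small_cohort):
        """A truncated record renders identically to a record built from
        only the surviving events."""
        from dataclasses import replace

        rec = small_cohort[1]
        cut = truncate_record(rec, TruncationSpec("percent", 0.5))
        rebuilt = replace(rec, fixations=cut.fixations, saccades=cut.saccades)
        assert np.array_equal(
            render_to_array(cut, layout), render_to_array(rebuilt, layout)
        )


class TestRenderSpecValidation:
    def test_bad_colour_rejected(self):
        with pytest.raises(ValueError):
            RenderSpec(out_dot_rgb=(300, 0, 0))

    def test_bad_dot_ratio_rejected(self):
        with pytest.raises(ValueError):
            RenderSpec(out_dot_ratio=1.5)

    def test_spec_dict_round_trip(self):
        spec = RenderSpec(fixation_cap=15)
        assert RenderSpec.from_dict(spec.to_dict()) == spec
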