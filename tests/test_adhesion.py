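"""Adhesion-assay rules: overlap fraction, adherence calls, well summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from plexiquant import SynthFieldParams, generate_coculture_field
from plexiquant.adhesion import (
    AdhesionConfig,
    WellResult,
    classify_adherent,
    overlap_fraction,
    quantify_field,
    quantify_well,
    size_frequency,
    summarize_condition,
)
from plexiquant.micrograph import Micrograph

from conftest import brute_force_overlap, make_mask, make_object


class TestOverlapFraction:
    def test_half_overlap_example(self):
        tcell = make_object([(1, 1), (1, 2)])
        glia = np.zeros((4, 4), dtype=bool)
        glia[1, 2] = glia[2, 2] = True
        assert overlap_fraction(tcell, make_mask(glia)) == 0.5

    def test_disjoint_masks_zero(self):
        tcell = make_object([(0, 0), (0, 1)])
        glia = np.zeros((4, 4), dtype=bool)
        glia[3, 3] = True
        assert overlap_fraction(tcell, make_mask(glia)) == 0.0

    def test_subset_gives_one(self):
        pixels = [(1, 1), (1, 2), (2, 1)]
        glia = np.zeros((4, 4), dtype=bool)
        for r, c in pixels:
            glia[r, c] = True
        assert overlap_fraction(make_object(pixels), make_mask(glia)) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pixel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (12, 12)
        glia = rng.random(shape) < 0.4
        pixels = np.argwhere(rng.random(shape) < 0.3)
        if pixels.shape[0] == 0:
            pixels = np.array([[0, 0]])
        obj = make_object(pixels)
        assert overlap_fraction(obj, make_mask(glia)) == pytest.approx(
            brute_force_overlap(pixels, glia)
        )

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            make_object(np.empty((0, 2)))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        mask=hnp.arrays(bool, (10, 10)),
        pixels=st.lists(
            st.tuples(st.integers(0, 9), st.integers(0, 9)),
            min_size=1,
            max_size=30,
            unique=True,
        ),
    )
    def test_overlap_bounded_and_matches_oracle(self, mask, pixels):
        obj = make_object(pixels)
        frac = overlap_fraction(obj, make_mask(mask))
        assert 0.0 <= frac <= 1.0
        assert frac == pytest.approx(brute_force_overlap(np.asarray(pixels), mask))


class TestClassifyAdherent:
    def _setup(self, area_px, overlap_px, pixel_size_um=1.0):
        pixels = [(0, c) for c in range(area_px)]
        glia = np.zeros((2, area_px + 1), dtype=bool)
        for c in range(overlap_px):
            glia[0, c] = True
        return (
            make_object(pixels, pixel_size_um=pixel_size_um),
            make_mask(glia, pixel_size_um=pixel_size_um),
        )

    def test_exact_five_percent_overlap_is_adherent(self):
        # 60 px of 1 um^2 each, 3 overlapping -> overlap exactly 0.05
        obj, glia = self._setup(60, 3)
        calls = classify_adherent([obj], glia)
        assert calls == [(obj, True)]

    def test_just_below_five_percent_is_not_adherent(self):
        # 1000 px object with 49 overlapping -> 0.049
        obj, glia = self._setup(1000, 49, pixel_size_um=0.5)
        assert obj.area_um2 >= 50
        calls = classify_adherent([obj], glia)
        assert calls == [(obj, False)]

    def test_small_object_excluded_entirely(self):
        obj, glia = self._setup(40, 36)  # 40 um^2, overlap 0.9
        assert classify_adherent([obj], glia) == []

    def test_exact_area_threshold_inclusive(self):
        obj, glia = self._setup(50, 25)
        assert classify_adherent([obj], glia) == [(obj, True)]

    def test_monotonicity_in_thresholds(self, rng):
        glia = rng.random((30, 30)) < 0.5
        objects = []
        for i in range(15):
            r, c = rng.integers(0, 22, size=2)
            block = [(r + dr, c + dc) for dr in range(8) for dc in range(8)]
            objects.append(make_object(block, object_id=i + 1))
        mask = make_mask(glia)

        def n_adherent(min_overlap, min_area):
            return sum(
                flag
                for _, flag in classify_adherent(
                    objects, mask, min_area_um2=min_area, min_overlap=min_overlap
                )
            )

        for lo, hi in [(0.01, 0.05), (0.05, 0.2), (0.2, 0.8)]:
            assert n_adherent(lo, 50) >= n_adherent(hi, 50)
        for lo, hi in [(10, 50), (50, 63), (63, 65)]:
            assert n_adherent(0.05, lo) >= n_adherent(0.05, hi)


class TestWellSummaries:
    def test_density_arithmetic(self):
        # 3 adherent cells over 0.5 mm^2 of S100B -> 6 cells/mm^2
        well = WellResult("w", n_fields=81, n_adherent_tcells=3, s100b_area_um2=5e5)
        assert well.density_per_mm2 == pytest.approx(6.0)

    def test_zero_tcells_zero_density(self):
        params = SynthFieldParams(seed=0, n_tcells=0)
        micrograph, _ = generate_coculture_field(params)
        well = quantify_well([micrograph])
        assert well.n_adherent_tcells == 0
        assert well.density_per_mm2 == 0.0

    def test_no_glial_surface_raises(self):
        params = SynthFieldParams(seed=0, n_tcells=0, glia_coverage=0.0)
        micrograph, _ = generate_coculture_field(params)
        with pytest.raises(ValueError, match="glial surface"):
            quantify_well([micrograph])

    def test_median_and_percent_of_control(self):
        def wells(densities):
            return [
                WellResult(f"w{i}", 1, int(d), 1e6) for i, d in enumerate(densities)
            ]

        result = summarize_condition(wells([10, 12, 14]), wells([10, 10, 10]), "LPS")
        assert result.median_density == 12
        assert result.pct_of_control == pytest.approx(120.0)
        identity = summarize_condition(wells([10, 10, 10]), wells([10, 10, 10]))
        assert identity.pct_of_control == pytest.approx(100.0)
        robust = summarize_condition(wells([5, 50, 8]), wells([10, 10, 10]))
        assert robust.median_density == 8

    def test_zero_control_median_raises(self):
        wells = [WellResult("w", 1, 0, 1e6)]
        with pytest.raises(ValueError, match="control median"):
            summarize_condition(wells, wells)


class TestGroundTruthRecovery:
    def test_noiseless_field_recovers_truth_exactly(self, coculture_field):
        micrograph, truth = coculture_field
        calls, _ = quantify_field(micrograph)
        truth_cells = truth.of_kind("tcell")
        assert len(calls) == len(truth_cells)
        by_pos = {
            (round(o.centroid_px[0]), round(o.centroid_px[1])): o.adherent
            for o in truth_cells
        }
        for obj, adherent in calls:
            r, c = obj.centroid
            key = min(
                by_pos, key=lambda k: max(abs(k[0] - r), abs(k[1] - c))
            )
            assert max(abs(key[0] - r), abs(key[1] - c)) <= 2
            assert adherent == by_pos[key]

    def test_density_invariant_under_field_split(self):
        # same pixels, fixed threshold: one field vs four quadrants
        params = SynthFieldParams(seed=11, n_tcells=6)
        micrograph, truth = generate_coculture_field(params)
        labels = truth.labels["tcell"]
        n = labels.shape[0]
        clear_rows = [
            r for r in range(40, n - 40) if labels[r - 20 : r + 21].sum() == 0
        ]
        clear_cols = [
            c for c in range(40, n - 40) if labels[:, c - 20 : c + 21].sum() == 0
        ]
        assert clear_rows and clear_cols, "field has no clean split line"
        r0, c0 = clear_rows[len(clear_rows) // 2], clear_cols[len(clear_cols) // 2]
        config = AdhesionConfig(method="fixed", threshold=0.6, smooth_sigma_um=0)
        quadrants = []
        for rs, cs in [
            (slice(None, r0), slice(None, c0)),
            (slice(None, r0), slice(c0, None)),
            (slice(r0, None), slice(None, c0)),
            (slice(r0, None), slice(c0, None)),
        ]:
            quadrants.append(
                Micrograph(
                    channels={k: v[rs, cs].copy() for k, v in micrograph.channels.items()},
                    pixel_size_um=micrograph.pixel_size_um,
                )
            )
        whole = quantify_well([micrograph], config)
        split = quantify_well(quadrants, config)
        assert split.n_adherent_tcells == whole.n_adherent_tcells
        assert split.s100b_area_um2 == pytest.approx(whole.s100b_area_um2)
        assert split.density_per_mm2 == pytest.approx(whole.density_per_mm2)


class TestSizeFrequency:
    def test_single_bin_gets_all_mass(self):
        hist = size_frequency(np.array([60.0, 70.0, 80.0]), [50, 100])
        assert hist.frequencies.tolist() == [1.0]

    def test_two_bin_split(self):
        hist = size_frequency(np.array([55.0, 65.0, 120.0]), [50, 100, 150])
        assert hist.frequencies == pytest.approx([2 / 3, 1 / 3])

    def test_shift_moves_mass(self):
        areas = np.array([55.0, 65.0, 120.0])
        before = size_frequency(areas, [50, 100, 150]).frequencies
        after = size_frequency(areas + 45.0, [50, 100, 150]).frequencies
        assert before == pytest.approx([2 / 3, 1 / 3])
        assert after == pytest.approx([0.0, 1.0])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            size_frequency(np.array([]), [0, 10])
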