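import dataclasses

import numpy as np
import pytest

from retinaquant.morphometry import (
    MorphoConfig,
    binarize_class,
    clean_mask,
    connected_domains,
    count_ganglion_cells,
    measure_layer,
    profile_section,
)
from retinaquant.schema import CELL, INL, IPL, OPL, RNFL
from retinaquant.synthgen import generate_section

NO_FILTER = MorphoConfig(erosion_iters=0, min_layer_area_frac=0.0)


def flood_fill_components(mask):
    """Independent 8-connectivity component oracle (explicit BFS)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                stack = [(si, sj)]
                seen[si, sj] = True
                pixels = []
                while stack:
                    i, j = stack.pop()
                    pixels.append((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (0 <= ni < h and 0 <= nj < w
                                    and mask[ni, nj] and not seen[ni, nj]):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                comps.append(frozenset(pixels))
    return comps


class TestBinarize:
    def test_absent_class_all_false(self):
        labels = np.zeros((5, 5), int)
        assert not binarize_class(labels, CELL).any()

    def test_probability_boundary_inclusive(self):
        probs = np.full((6, 4, 4), 0.5)
        assert binarize_class(probs, 2).all()

    def test_matches_per_pixel_oracle(self, rng):
        labels = rng.integers(0, 6, size=(16, 16))
        mask = binarize_class(labels, IPL)
        for i in range(16):
            for j in range(16):
                assert mask[i, j] == (labels[i, j] == IPL)

    def test_invalid_class(self):
        with pytest.raises(ValueError):
            binarize_class(np.zeros((2, 2), int), 9)


class TestCleanMask:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not clean_mask(mask, MorphoConfig(erosion_iters=1)).any()

    def test_solid_square_restored(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        opened = clean_mask(mask, MorphoConfig(erosion_iters=1))
        # opening with a 3x3 square element restores the solid square exactly
        assert np.array_equal(opened, mask)

    def test_empty_mask(self):
        assert not clean_mask(np.zeros((5, 5), bool)).any()

    def test_zero_iters_identity(self, rng):
        mask = rng.random((12, 12)) > 0.5
        assert np.array_equal(clean_mask(mask, NO_FILTER), mask)


class TestConnectedDomains:
    def test_diagonal_pixels_one_component(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        doms = connected_domains(mask, CELL, NO_FILTER)
        assert len(doms) == 1
        assert doms[0].pixel_count == 2

    def test_five_disjoint_squares(self):
        mask = np.zeros((30, 30), bool)
        for k in range(5):
            mask[2:5, 2 + 5 * k:5 + 5 * k] = True
        doms = connected_domains(mask, CELL, NO_FILTER)
        assert len(doms) == 5
        assert all(d.pixel_count == 9 for d in doms)

    def test_matches_flood_fill_oracle(self, rng):
        mask = rng.random((64, 64)) > 0.7
        doms = connected_domains(mask, CELL, NO_FILTER)
        oracle = flood_fill_components(mask)
        assert len(doms) == len(oracle)
        assert sorted(d.pixel_count for d in doms) == \
            sorted(len(c) for c in oracle)

    def test_bounding_box_half_open(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 3:7] = True
        d = connected_domains(mask, CELL, NO_FILTER)[0]
        assert d.bounding_box == (2, 3, 5, 7)
        assert d.width == 4 and d.height == 3
        assert d.pixel_count <= d.width * d.height

    def test_erosion_survival_flag(self):
        mask = np.zeros((12, 12), bool)
        mask[1, 1] = True            # speck: dies
        mask[4:9, 4:9] = True        # 5x5 block: survives
        doms = connected_domains(mask, CELL, MorphoConfig(erosion_iters=1))
        flags = sorted((d.pixel_count, d.survives_erosion) for d in doms)
        assert flags == [(1, False), (25, True)]


class TestCountGanglionCells:
    def test_five_discs(self):
        mask = np.zeros((40, 80), bool)
        yy, xx = np.mgrid[0:40, 0:80]
        area = 0
        for k in range(5):
            cx = 8 + 15 * k
            disc = (yy - 20) ** 2 + (xx - cx) ** 2 <= 16
            mask |= disc
            area += disc.sum()
        a, s_a, _ = count_ganglion_cells(mask, MorphoConfig(erosion_iters=1))
        assert a == 5
        assert s_a == area

    def test_clump_split_by_aspect_ratio(self):
        mask = np.zeros((20, 50), bool)
        mask[5:15, 5:35] = True      # box 30 wide x 10 high, r = 3.0
        a, _, _ = count_ganglion_cells(mask, MorphoConfig(erosion_iters=1))
        assert a == 3

    def test_max_split_cap(self):
        mask = np.zeros((6, 100), bool)
        mask[2:4, 2:98] = True       # r = 48
        a, _, _ = count_ganglion_cells(
            mask, MorphoConfig(erosion_iters=0, max_split=6))
        assert a == 6

    def test_speck_filtered_area_excluded(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        mask[2, 2] = True
        a, s_a, _ = count_ganglion_cells(mask, MorphoConfig(erosion_iters=1))
        assert a == 1
        assert s_a == 100  # speck excluded; block counted pre-erosion

    def test_empty_mask(self):
        a, s_a, detail = count_ganglion_cells(np.zeros((5, 5), bool))
        assert a == 0 and s_a == 0 and detail == []

    def test_erosion_monotonicity(self, rng):
        mask = rng.random((60, 60)) > 0.6
        counts = [count_ganglion_cells(mask, MorphoConfig(erosion_iters=i))[0]
                  for i in range(3)]
        assert counts[0] >= counts[1] >= counts[2]


class TestMeasureLayer:
    def test_flat_band(self):
        mask = np.zeros((60, 200), bool)
        mask[10:30, :] = True
        s, h, empty = measure_layer(mask, NO_FILTER)
        assert (s, h, empty) == (4000.0, 20.0, False)

    def test_sinusoidal_band_constant_thickness(self):
        cols = np.arange(200)
        offset = np.rint(6 * np.sin(2 * np.pi * cols / 80)).astype(int)
        mask = np.zeros((60, 200), bool)
        for j, off in enumerate(offset):
            mask[20 + off:40 + off, j] = True
        s, h, _ = measure_layer(mask, NO_FILTER)
        assert h == 20.0          # vertical column counts unaffected
        assert s == 4000.0

    def test_speck_filtered_by_area_threshold(self):
        mask = np.zeros((50, 100), bool)
        mask[10:20, :] = True          # 1000 px band
        mask[40, 3:6] = True           # 3 px speck
        cfg = MorphoConfig(erosion_iters=0, min_layer_area_frac=0.001)
        s, h, _ = measure_layer(mask, cfg)   # threshold = 5 px
        assert s == 1000.0
        assert h == 10.0

    def test_empty_flagged(self):
        s, h, empty = measure_layer(np.zeros((10, 10), bool), NO_FILTER)
        assert (s, h, empty) == (0.0, 0.0, True)

    def test_area_threshold_monotonicity(self, rng):
        mask = rng.random((64, 64)) > 0.55
        areas = []
        for frac in (0.0, 0.001, 0.005, 0.02):
            cfg = MorphoConfig(erosion_iters=0, min_layer_area_frac=frac)
            areas.append(measure_layer(mask, cfg)[0])
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_scale_equivariance(self):
        mask = np.zeros((40, 40), bool)
        mask[10:25, 5:35] = True
        s1, h1, _ = measure_layer(mask, NO_FILTER)
        big = np.kron(mask, np.ones((2, 2), bool))
        s2, h2, _ = measure_layer(big, NO_FILTER)
        assert s2 == 4 * s1
        assert h2 == 2 * h1


class TestProfileSection:
    def test_identity_on_clean_truth(self, flat_section):
        prof = profile_section(flat_section.labels, NO_FILTER)
        assert prof.as_dict() == flat_section.truth_profile.as_dict()

    def test_identity_with_curvature_and_vacuoles(self, flat_spec):
        spec = dataclasses.replace(flat_spec, curvature_amplitude_px=5.0,
                                   vacuole_density=0.5, seed=21)
        sec = generate_section(spec)
        prof = profile_section(sec.labels, NO_FILTER)
        assert prof.as_dict() == sec.truth_profile.as_dict()

    def test_all_background_all_zero(self):
        prof = profile_section(np.zeros((32, 32), int), NO_FILTER)
        assert all(v == 0 for v in prof.as_dict().values())
        assert set(prof.empty_layers) == {"RNFL", "IPL", "INL", "OPL"}

    def test_cohort_thinning_ratio(self, flat_spec):
        from retinaquant.synthgen import generate_cohort
        msg = dataclasses.replace(flat_spec, condition="msg_like",
                                  thinning_factor=0.6)
        cohort = generate_cohort(10, flat_spec, msg, seed=2, jitter_cv=0.05)
        profs = [profile_section(s.labels, NO_FILTER) for s in cohort]
        h_c = np.mean([p.h_ipl for p, s in zip(profs, cohort)
                       if s.group == "control"])
        h_m = np.mean([p.h_ipl for p, s in zip(profs, cohort)
                       if s.group == "model"])
        assert h_m / h_c == pytest.approx(0.6, abs=0.08)

    def test_probability_stack_input(self, flat_section):
        k = 6
        labels = flat_section.labels
        probs = np.zeros((k,) + labels.shape)
        for c in range(k):
            probs[c] = (labels == c).astype(float)
        prof = profile_section(probs, NO_FILTER)
        assert prof.as_dict() == flat_section.truth_profile.as_dict()

    def test_band_area_thickness_consistency(self):
        # on a vertically convex band, S = H x occupied columns exactly
        mask = np.zeros((60, 150), bool)
        mask[12:30, 10:140] = True
        s, h, _ = measure_layer(mask, NO_FILTER)
        assert s == h * 130


class TestMorphoConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"prob_threshold": 0.0},
        {"prob_threshold": 1.0},
        {"struct_elem": "diamond"},
        {"erosion_iters": -1},
        {"adherence_ratio": 0.5},
        {"max_split": 0},
    ])
    def test_rejects_bad_values(self, kwargs):
        with pytest.raises(ValueError):
            MorphoConfig(**kwargs)
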