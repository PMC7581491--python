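"""Boundary errors, Dice overlap, ETDRS statistics, Bland-Altman."""

import numpy as np
import pytest

from octseg.metrics import (EtdrsGrid, SUBFIELDS, bland_altman,
                            boundary_errors, dice_overlap, etdrs_stats,
                            thickness_map)
from octseg.phantom import (BoundarySet, PhantomConfig,
                            generate_boundary_surfaces,
                            ground_truth_boundaries, gt_macular_volume_mm3)


def _bset(ilm, rpe, W=10):
    return BoundarySet(np.full(W, float(ilm)), np.full(W, float(rpe)))


class TestBoundaryErrors:
    def test_identical_boundaries_zero_error(self):
        b = _bset(10, 40)
        rep = boundary_errors(b, b).set_index("boundary")
        assert (rep["mae_px"] == 0).all() and (rep["me_px"] == 0).all()

    def test_prediction_below_truth_is_positive(self):
        truth = _bset(10, 40)
        pred = _bset(11, 41)  # one row lower on the image
        rep = boundary_errors(pred, truth).set_index("boundary")
        assert (rep["mae_px"] == 1).all()
        assert (rep["me_px"] == 1).all()

    def test_mixed_errors_cancel_in_me_not_mae(self):
        truth = _bset(10, 40, W=10)
        ilm = np.full(10, 10.0)
        ilm[:5] += 1
        ilm[5:] -= 1
        pred = BoundarySet(ilm, np.full(10, 40.0))
        rep = boundary_errors(pred, truth).set_index("boundary")
        assert rep.loc["ILM", "mae_px"] == 1.0
        assert rep.loc["ILM", "me_px"] == 0.0

    def test_swap_flips_me_keeps_mae(self):
        a, b = _bset(10, 40), _bset(12, 39)
        r1 = boundary_errors(a, b).set_index("boundary")
        r2 = boundary_errors(b, a).set_index("boundary")
        assert np.allclose(r1["mae_px"], r2["mae_px"])
        assert np.allclose(r1["me_px"], -r2["me_px"])

    def test_restricted_to_valid_range(self):
        truth = BoundarySet(np.full(10, 10.0), np.full(10, 40.0),
                            valid_start=2, valid_end=7)
        ilm = np.full(10, 10.0)
        ilm[0] = 25.0  # outside the valid range; must be ignored
        pred = BoundarySet(ilm, np.full(10, 40.0))
        rep = boundary_errors(pred, truth).set_index("boundary")
        assert rep.loc["ILM", "mae_px"] == 0.0
        assert rep.loc["ILM", "n_columns"] == 6

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            boundary_errors(_bset(1, 2, W=5), _bset(1, 2, W=6))


class TestDiceOverlap:
    def test_identical_maps_are_100(self):
        lab = np.array([[0, 1], [2, 1]])
        assert dice_overlap(lab, lab)["overall"] == 100.0

    def test_disjoint_classes_are_0(self):
        a = np.zeros((2, 2), dtype=int)
        b = np.ones((2, 2), dtype=int)
        d = dice_overlap(a, b)
        assert d["class_0"] == 0.0 and d["class_1"] == 0.0
        assert d["class_2"] == 100.0  # empty in both

    def test_half_overlap_hand_case(self):
        a = np.array([[1, 1], [0, 0]])
        b = np.array([[1, 0], [1, 0]])
        assert dice_overlap(a, b)["class_1"] == pytest.approx(50.0)


class TestThicknessMap:
    def test_pixel_to_micron_conversion(self):
        b = _bset(10, 110, W=4)  # 100 px
        tm = thickness_map([b], 3.9, 5.7, 119.0)
        assert np.allclose(tm.values_um, 390.0)

    def test_zero_thickness_allowed(self):
        tm = thickness_map([_bset(12, 12, W=4)], 3.9, 5.7, 119.0)
        assert np.all(tm.values_um == 0)

    def test_matches_generator_ground_truth(self):
        cfg = PhantomConfig()
        surf = generate_boundary_surfaces(cfg, rng_seed=3)
        bnds = [ground_truth_boundaries(surf, s) for s in range(cfg.n_slices)]
        tm = thickness_map(bnds, cfg.axial_res_um, cfg.lateral_res_um,
                           cfg.scan_spacing_um)
        assert np.allclose(tm.values_um,
                           surf.thickness_px * cfg.axial_res_um)


class TestEtdrs:
    @pytest.fixture
    def const_tmap(self):
        cfg = PhantomConfig()
        W, n = cfg.width_px, cfg.n_slices
        vals = np.full((n, W), 100.0)
        return thickness_map([BoundarySet(np.zeros(W),
                                          np.full(W, 100.0 / cfg.axial_res_um))
                              for _ in range(n)],
                             cfg.axial_res_um, cfg.lateral_res_um,
                             cfg.scan_spacing_um), vals

    def test_constant_thickness_every_subfield_mean(self, const_tmap):
        tm, _ = const_tmap
        st = etdrs_stats(tm).set_index("subfield")
        for sf in SUBFIELDS:
            assert st.loc[sf, "mean_thickness_um"] == pytest.approx(100.0)

    def test_constant_thickness_disc_volume(self, const_tmap):
        tm, _ = const_tmap
        st = etdrs_stats(tm).set_index("subfield")
        analytic = 0.1 * np.pi * 3.0 ** 2  # t * pi * r^2
        assert st.loc["total", "volume_mm3"] == pytest.approx(analytic,
                                                              rel=0.01)

    def test_central_subfield_area(self, const_tmap):
        tm, _ = const_tmap
        st = etdrs_stats(tm).set_index("subfield")
        area = st.loc["central", "n_cells"] * tm.cell_area_mm2
        assert area == pytest.approx(np.pi * 0.5 ** 2, rel=0.05)

    def test_subfield_volumes_partition_disc(self, const_tmap):
        tm, _ = const_tmap
        st = etdrs_stats(tm).set_index("subfield")
        parts = st.loc[list(SUBFIELDS), "volume_mm3"].sum()
        assert parts == pytest.approx(st.loc["total", "volume_mm3"], abs=1e-12)
        assert st.loc[list(SUBFIELDS), "n_cells"].sum() == \
            st.loc["total", "n_cells"]

    def test_insufficient_coverage_rejected(self):
        tm = thickness_map([_bset(0, 10, W=8) for _ in range(4)],
                           3.9, 5.7, 119.0)
        with pytest.raises(ValueError, match="cover"):
            etdrs_stats(tm)

    def test_laterality_swaps_nasal_temporal(self):
        g_od = EtdrsGrid(laterality="OD")
        g_os = EtdrsGrid(laterality="OS")
        assert g_od.subfields(1.0, 0.0) == "inner_nasal"
        assert g_os.subfields(1.0, 0.0) == "inner_temporal"
        assert g_od.subfields(0.0, -1.0) == "inner_superior"

    def test_gt_volume_reproduced_from_boundaries(self):
        cfg = PhantomConfig(atrophy_severity=0.4)
        surf = generate_boundary_surfaces(cfg, rng_seed=9)
        bnds = [ground_truth_boundaries(surf, s) for s in range(cfg.n_slices)]
        tm = thickness_map(bnds, cfg.axial_res_um, cfg.lateral_res_um,
                           cfg.scan_spacing_um)
        st = etdrs_stats(tm).set_index("subfield")
        assert st.loc["total", "volume_mm3"] == pytest.approx(
            gt_macular_volume_mm3(surf, cfg), rel=0.01)


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff == 0 and r.loa_lower == 0 and r.loa_upper == 0

    def test_constant_offset(self):
        r = bland_altman(np.arange(5) + 5.0, np.arange(5).astype(float))
        assert r.mean_diff == pytest.approx(5.0)
        assert r.loa_lower == pytest.approx(5.0)

    def test_hand_computed_limits(self):
        # d = {-1, +1}: mean 0, SD (n-1) = sqrt(2), LoA = +-1.96*sqrt(2)
        r = bland_altman([0.0, 2.0], [1.0, 1.0])
        assert r.mean_diff == pytest.approx(0.0)
        assert r.loa_upper == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert r.loa_lower == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)

    def test_invariant_lower_le_mean_le_upper(self, rng):
        a, b = rng.random(30), rng.random(30)
        r = bland_altman(a, b)
        assert r.loa_lower <= r.mean_diff <= r.loa_upper

    def test_rejects_single_pair(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])
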