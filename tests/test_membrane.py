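import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimerscope.membrane import (
    LipidFrame,
    MembraneError,
    annular_shells,
    interface_mismatch,
    order_map,
    order_parameter,
    thickness_map,
)
from dimerscope.synth.bilayer import (
    MembraneModel,
    ThicknessSector,
    generate_lipid_frames,
)

BOX = (20.0, 20.0)


def _flat_frames(n_frames=2, **model_kw):
    model = MembraneModel(**model_kw)
    return model, generate_lipid_frames(model, BOX, n_frames=n_frames, seed=5)


class TestOrderParameter:
    def test_parallel_bonds_give_one(self):
        assert order_parameter([0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_in_plane_bonds_give_minus_half(self):
        assert order_parameter([90.0] * 7) == pytest.approx(-0.5)

    def test_isotropic_average_zero(self, rng):
        # theta from an isotropic sphere: cos(theta) uniform on [-1, 1]
        cos = rng.uniform(-1, 1, 200000)
        s = order_parameter(np.degrees(np.arccos(cos)))
        assert abs(s) < 0.01

    def test_empty_rejected(self):
        with pytest.raises(MembraneError):
            order_parameter([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 180.0), min_size=1, max_size=40))
    def test_bounds_never_violated(self, angles):
        assert -0.5 - 1e-12 <= order_parameter(angles) <= 1.0 + 1e-12

    def test_matches_literal_formula(self, rng):
        angles = rng.uniform(0, 180, 500)
        lit = 0.5 * (3.0 * np.mean(np.cos(np.radians(angles)) ** 2) - 1.0)
        assert order_parameter(angles) == pytest.approx(lit, abs=1e-12)


class TestOrderMap:
    def test_uniform_tilt_30_deg_everywhere(self):
        model, frames = _flat_frames(bulk_tilt_deg=30.0)
        m = order_map(frames, window="all")
        expected = 0.5 * (3 * np.cos(np.radians(30.0)) ** 2 - 1)  # 0.625
        vals = m.values[~np.isnan(m.values)]
        np.testing.assert_allclose(vals, expected, atol=1e-9)
        assert expected == pytest.approx(0.625)

    def test_unsampled_cells_masked_not_zero(self):
        model, frames = _flat_frames()
        m = order_map(frames, grid_cell=0.2, window="all")
        assert m.mask.any()
        assert np.isnan(m.values[m.mask]).all()

    def test_grid_refinement_preserves_weighted_mean(self):
        model, frames = _flat_frames(bulk_tilt_deg=28.0)
        coarse = order_map(frames, grid_cell=1.0, window="all")
        fine = order_map(frames, grid_cell=0.4, window="all")

        def wmean(m):
            ok = ~np.isnan(m.values)
            return np.average(m.values[ok], weights=m.counts[ok])

        assert wmean(coarse) == pytest.approx(wmean(fine), abs=1e-9)

    def test_annular_order_perturbation_strongest_near_protein(self):
        model = MembraneModel(order_shell_deltas=[-0.15, -0.08, -0.03],
                              shell_width=0.5, annulus_radius=2.0)
        frames = generate_lipid_frames(model, BOX,
                                       protein_centers=[(10.0, 10.0)],
                                       footprint_radius=2.3, n_frames=2,
                                       seed=6)
        m = order_map(frames, window="all")
        shells = annular_shells(m, [(10.0, 10.0)], 2.3, shell_width=0.5)
        devs = (shells["mean"] - model.bulk_order).to_numpy()
        assert abs(devs[0]) > abs(devs[2])
        far = shells[shells["distance_nm"] > 3.0]["mean"]
        np.testing.assert_allclose(far, model.bulk_order, atol=0.02)

    def test_empty_window_rejected(self):
        with pytest.raises(MembraneError):
            order_map([], window="all")


class TestThicknessMap:
    def test_flat_bilayer_uniform_thickness(self):
        model, frames = _flat_frames(bulk_thickness=4.0)
        m = thickness_map(frames, window="all", bulk=4.0)
        vals = m.values[~np.isnan(m.values)]
        np.testing.assert_allclose(vals, 4.0, atol=0.02)
        assert (vals > 0).all()

    def test_planted_thinning_recovered_within_interpolation_error(self):
        center = (10.0, 10.0)
        model = MembraneModel(thickness_sectors=[
            ThicknessSector(center, 0.0, 360.0, -0.4)])
        frames = generate_lipid_frames(model, BOX, protein_centers=[center],
                                       footprint_radius=2.3, n_frames=4,
                                       seed=7, position_jitter=0.02)
        m = thickness_map(frames, window="all", bulk=model.bulk_thickness)
        x, y = m.cell_centers()
        xx, yy = np.meshgrid(x, y)
        dist_fp = np.hypot(xx - center[0], yy - center[1]) - 2.3
        planted = -0.4 * np.clip(1.0 - np.clip(dist_fp, 0, None)
                                 / model.annulus_radius, 0.0, None)
        sel = (dist_fp > 0) & ~np.isnan(m.deviation)
        err = np.abs(m.deviation[sel] - planted[sel])
        assert err.mean() < 0.05

    def test_balanced_perturbations_cancel_in_deviation(self):
        center = (10.0, 10.0)
        model = MembraneModel(thickness_sectors=[
            ThicknessSector(center, 0.0, 180.0, +0.3),
            ThicknessSector(center, 180.0, 360.0, -0.3)])
        frames = generate_lipid_frames(model, BOX, protein_centers=[center],
                                       footprint_radius=2.3, n_frames=2,
                                       seed=8)
        m = thickness_map(frames, window="all", bulk=model.bulk_thickness)
        assert abs(np.nanmean(m.deviation)) < 0.02

    def test_translation_invariance(self):
        model, frames = _flat_frames(bulk_thickness=4.2)
        shifted = [LipidFrame(leaflet=f.leaflet,
                              head_positions=f.head_positions + [3.0, -2.0, 0],
                              tail_positions=f.tail_positions + [3.0, -2.0, 0],
                              time_us=f.time_us) for f in frames]
        a = thickness_map(frames, window="all")
        b = thickness_map(shifted, window="all")
        ok_a = a.values[~np.isnan(a.values)]
        ok_b = b.values[~np.isnan(b.values)]
        assert np.nanmean(ok_a) == pytest.approx(np.nanmean(ok_b), abs=1e-6)
        assert a.bulk == pytest.approx(b.bulk, abs=1e-6)

    def test_single_leaflet_rejected(self):
        model, frames = _flat_frames()
        upper_only = [LipidFrame(
            leaflet=f.leaflet[f.leaflet > 0],
            head_positions=f.head_positions[f.leaflet > 0],
            tail_positions=f.tail_positions[f.leaflet > 0],
        ) for f in frames]
        with pytest.raises(MembraneError):
            thickness_map(upper_only, window="all")


class TestAnnularShells:
    def test_uniform_map_all_shells_equal(self):
        model, frames = _flat_frames(bulk_tilt_deg=25.0)
        m = order_map(frames, window="all")
        shells = annular_shells(m, [(10.0, 10.0)], 2.0, shell_width=1.0)
        np.testing.assert_allclose(shells["mean"], shells["mean"].iloc[0],
                                   atol=1e-9)

    def test_perturbation_confined_to_first_shell(self):
        model = MembraneModel(order_shell_deltas=[-0.2], shell_width=0.5,
                              annulus_radius=0.5)
        frames = generate_lipid_frames(model, BOX,
                                       protein_centers=[(10.0, 10.0)],
                                       footprint_radius=2.0, n_frames=2,
                                       seed=9)
        m = order_map(frames, window="all")
        shells = annular_shells(m, [(10.0, 10.0)], 2.0, shell_width=0.5)
        outer = shells[shells["shell"] >= 3]["mean"]
        np.testing.assert_allclose(outer, model.bulk_order, atol=0.02)


class TestInterfaceMismatch:
    def _map_with_halves(self, dev_a, dev_b):
        from dimerscope.membrane import ThicknessMap
        vals = np.full((20, 20), 4.0)
        vals[:, :10] += dev_a   # left = protomer A side
        vals[:, 10:] += dev_b
        return ThicknessMap(values=vals, counts=np.ones((20, 20)),
                            origin=(0.0, 0.0), cell=0.5, bulk=4.0,
                            deviation=vals - 4.0)

    def test_opposite_signs_positive_score(self):
        m = self._map_with_halves(+0.3, -0.3)
        score = interface_mismatch(m, (2.0, 5.0), (8.0, 5.0))
        assert score == pytest.approx(0.09, abs=1e-9)

    def test_matched_signs_negative_score(self):
        m = self._map_with_halves(+0.3, +0.3)
        assert interface_mismatch(m, (2.0, 5.0), (8.0, 5.0)) == pytest.approx(
            -0.09, abs=1e-9)

    def test_zero_deviation_zero_score(self):
        m = self._map_with_halves(0.0, 0.0)
        assert interface_mismatch(m, (2.0, 5.0), (8.0, 5.0)) == 0.0

    def test_coincident_centers_rejected(self):
        m = self._map_with_halves(0.1, 0.2)
        with pytest.raises(MembraneError):
            interface_mismatch(m, (5.0, 5.0), (5.0, 5.0))

    def test_mismatched_transient_exceeds_matched_stable(self):
        """Planted transient-dimer mismatch beats the stable-dimer signature.

        Footprints 4 nm apart with a 1 nm perturbation annulus keep the two
        planted sectors disjoint, so each side of the interface carries one
        protomer's signature only."""
        ca, cb = (6.0, 10.0), (14.0, 10.0)
        mism = MembraneModel(annulus_radius=1.0, thickness_sectors=[
            ThicknessSector(ca, -90.0, 90.0, +0.35),
            ThicknessSector(cb, 90.0, 270.0, -0.35)])
        match = MembraneModel(annulus_radius=1.0, thickness_sectors=[
            ThicknessSector(ca, -90.0, 90.0, +0.35),
            ThicknessSector(cb, 90.0, 270.0, +0.35)])
        scores = {}
        for name, model in (("transient", mism), ("stable", match)):
            frames = generate_lipid_frames(model, BOX,
                                           protein_centers=[ca, cb],
                                           footprint_radius=2.0, n_frames=3,
                                           seed=10)
            m = thickness_map(frames, window="all",
                              bulk=model.bulk_thickness)
            scores[name] = interface_mismatch(m, ca, cb, sector_radius=2.5)
        assert scores["transient"] > 0
        assert scores["stable"] < 0
        assert scores["transient"] > scores["stable"]


class TestLipidFrameValidation:
    def test_leaflet_sign_consistency_enforced(self):
        with pytest.raises(MembraneError):
            LipidFrame(leaflet=[1], head_positions=[[0, 0, -2.0]],
                       tail_positions=[[[0, 0, -1.5], [0, 0, -1.0]]])

    def test_minimum_tail_beads(self):
        with pytest.raises(MembraneError):
            LipidFrame(leaflet=[1], head_positions=[[0, 0, 2.0]],
                       tail_positions=[[[0, 0, 1.5]]])
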