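import numpy as np
import pandas as pd
import pytest

from dimerscope.contacts import (
    ContactError,
    bundle_screen,
    expected_random_encounters,
    filter_contacts,
    helix_pairing_orientation,
    interface_periodicity,
    interface_summary,
    min_distance_brute,
    min_distance_series,
    residue_contact_map,
    screen_summary,
)
from dimerscope.synth import EnsembleConfig, InteractionMap, generate_daft_ensemble


@pytest.fixture(scope="module")
def static_dimer(template12):
    """Duration-0 ensemble pinned at the start separation."""
    cfg = EnsembleConfig(n_replicates=3, duration_us=0.0, seed=4)
    return generate_daft_ensemble(template12, InteractionMap(attractors=[]), cfg)


class TestMinDistance:
    def test_duration_zero_constant_and_far(self, static_dimer):
        s = min_distance_series(static_dimer, 0)
        assert len(s) == 1
        assert s["min_distance_nm"].iloc[0] > 2.0

    def test_matches_brute_force(self, small_ensemble, rng):
        for _ in range(25):
            r = int(rng.integers(small_ensemble.n_replicates))
            fi = int(rng.integers(small_ensemble.n_frames))
            a, b = small_ensemble.bead_coords(r, fi)
            series = min_distance_series(small_ensemble, r)
            assert series["min_distance_nm"].iloc[fi] == pytest.approx(
                min_distance_brute(a, b), abs=1e-12)

    def test_overlapping_beads_zero(self):
        a = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert min_distance_brute(a, a[:1]) == 0.0


class TestContactMap:
    def test_far_apart_all_zero(self, template12, static_dimer):
        cmap = residue_contact_map(static_dimer, template12, window_us=0.0,
                                   n_frames=1)
        assert cmap.total == 0

    def test_homodimer_symmetry_exact(self, template12, small_ensemble):
        cmap = residue_contact_map(small_ensemble, template12)
        np.testing.assert_array_equal(cmap.counts, cmap.counts.T)

    def test_frame_doubling_linearity(self, template12, small_ensemble):
        """Static-window linearity: the same frame counted twice doubles
        every entry."""
        one = residue_contact_map(small_ensemble, template12, n_frames=1,
                                  window_us=0.0)
        # degenerate window: both requested frames resolve to the final one
        with pytest.raises(ContactError):
            residue_contact_map(small_ensemble, template12, n_frames=2,
                                window_us=0.0)
        # doubling via explicit replicate duplication instead
        two = residue_contact_map(small_ensemble, template12, n_frames=1,
                                  window_us=0.0,
                                  replicates=list(range(small_ensemble.n_replicates)) * 2)
        np.testing.assert_array_equal(two.counts, 2 * one.counts)

    def test_window_outside_trajectory_raises(self, template12, static_dimer):
        with pytest.raises(ContactError):
            residue_contact_map(static_dimer, template12, window_us=5.0)

    def test_helix_block_partition(self, template12, small_ensemble):
        """Helix-pair blocks partition the full map total."""
        cmap = residue_contact_map(small_ensemble, template12)
        helices = sorted({template12.helix_of_residue[int(r)]
                          for r in cmap.residues})
        total = sum(cmap.helix_block(template12, ha, hb).sum()
                    for ha in helices for hb in helices)
        assert total == pytest.approx(cmap.total)

    def test_bundle_rows_nearly_empty_on_default_ensemble(
            self, template12, small_ensemble):
        cmap = residue_contact_map(small_ensemble, template12)
        if cmap.total == 0:
            pytest.skip("no contacts formed in the small ensemble")
        bundle = set(template12.bundle_residues())
        idx = [i for i, r in enumerate(cmap.residues) if int(r) in bundle]
        bundle_count = cmap.counts[idx, :].sum() + cmap.counts[:, idx].sum()
        assert bundle_count / (2 * cmap.total) < 0.01


class TestFilter:
    def _map(self, template12, counts):
        from dimerscope.contacts import ContactMap
        return ContactMap(counts=counts, residues=template12.residues,
                          n_frames_per_replicate=5, window_us=(0.0, 0.1))

    def test_strictly_greater_than_five(self, template12):
        n = len(template12.residues)
        counts = np.zeros((n, n))
        counts[0, 1] = counts[1, 0] = 5
        counts[2, 3] = counts[3, 2] = 6
        out = filter_contacts(self._map(template12, counts), min_count=5)
        assert len(out) == 2  # the 6-count pair in both labelings
        assert set(out["count"]) == {6.0}

    def test_all_below_threshold_empty(self, template12):
        n = len(template12.residues)
        out = filter_contacts(self._map(template12, np.full((n, n), 3.0)))
        assert out.empty

    def test_transpose_invariant(self, template12, rng):
        n = len(template12.residues)
        counts = rng.integers(0, 12, (n, n)).astype(float)
        counts = counts + counts.T
        a = filter_contacts(self._map(template12, counts))
        b = filter_contacts(self._map(template12, counts.T))
        pd.testing.assert_frame_equal(a, b)


class TestHelixPairing:
    def _map_with_band(self, template12, ha, hb, antidiag=False, random=None):
        from dimerscope.contacts import ContactMap
        n = len(template12.residues)
        counts = np.zeros((n, n))
        ra = template12.residues_of_helix(ha)
        rb = template12.residues_of_helix(hb)
        idx = {int(r): i for i, r in enumerate(template12.residues)}
        m = min(len(ra), len(rb))
        if random is not None:
            for i, j in zip(random.integers(0, len(ra), 12),
                            random.integers(0, len(rb), 12)):
                counts[idx[int(ra[i])], idx[int(rb[j])]] += 1
        else:
            for k in range(m):
                jj = (m - 1 - k) if antidiag else k
                counts[idx[int(ra[k])], idx[int(rb[jj])]] = 10
        return ContactMap(counts=counts, residues=template12.residues,
                          n_frames_per_replicate=5, window_us=(0.0, 0.1))

    def test_parallel_band(self, template12):
        cmap = self._map_with_band(template12, "TMH9", "TMH9")
        verdict, extent = helix_pairing_orientation(cmap, template12,
                                                    "TMH9", "TMH9")
        assert verdict == "parallel"
        assert extent >= 6

    def test_antiparallel_band(self, template12):
        cmap = self._map_with_band(template12, "TMH9", "TMH9", antidiag=True)
        verdict, _ = helix_pairing_orientation(cmap, template12, "TMH9", "TMH9")
        assert verdict == "antiparallel"

    def test_random_scatter_none(self, template12):
        hits = 0
        for s in range(5):
            cmap = self._map_with_band(template12, "TMH9", "TMH9",
                                       random=np.random.default_rng(s))
            verdict, _ = helix_pairing_orientation(cmap, template12,
                                                   "TMH9", "TMH9")
            hits += verdict == "none"
        assert hits >= 3  # isotropic scatter rarely shows 2:1 anisotropy

    def test_too_few_cells_none(self, template12):
        from dimerscope.contacts import ContactMap
        n = len(template12.residues)
        counts = np.zeros((n, n))
        counts[0, 0] = 5
        cmap = ContactMap(counts=counts, residues=template12.residues,
                          n_frames_per_replicate=5, window_us=(0.0, 0.1))
        assert helix_pairing_orientation(cmap, template12, "TMH9", "TMH9")[0] \
            == "none"


class TestPeriodicity:
    def test_heptad_spacing_near_three_and_a_half(self):
        helix = np.arange(100, 130)
        iface = [100, 103, 107, 110, 114, 117, 121, 124, 128]  # 3,4,3,4,...
        period, flag = interface_periodicity(iface, helix)
        assert flag == "ok"
        assert period == pytest.approx(3.5, abs=0.15)

    def test_planted_period_four(self):
        helix = np.arange(50, 80)
        iface = list(range(50, 80, 4))
        period, flag = interface_periodicity(iface, helix)
        assert flag == "ok"
        assert period == pytest.approx(4.0, abs=0.1)

    def test_every_residue_flagged_flat(self):
        helix = np.arange(10, 40)
        period, flag = interface_periodicity(list(helix), helix)
        assert flag == "flat" and period is None

    def test_too_few_residues(self):
        period, flag = interface_periodicity([1, 2], np.arange(1, 30))
        assert flag == "too_few_residues" and period is None


class TestBundleScreen:
    def test_paper_counts_percentage(self):
        assert screen_summary(7, 512).percentage == 1.4

    def test_threshold_zero_flags_every_contacting_replicate(
            self, template12, small_ensemble):
        zero = bundle_screen(small_ensemble, template12,
                             bundle_fraction_threshold=0.0, persistence=1)
        # every replicate that ever had >=1 contact frame is flagged
        expected = 0
        for r in range(small_ensemble.n_replicates):
            s = min_distance_series(small_ensemble, r)
            expected += (s["min_distance_nm"] < 0.5).any()
        assert zero.count == expected

    def test_monotone_in_threshold(self, template12, small_ensemble):
        counts = [bundle_screen(small_ensemble, template12,
                                bundle_fraction_threshold=th).count
                  for th in (0.0, 0.25, 0.5, 0.75, 1.01)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_default_ensemble_rarely_bundle_centered(
            self, template12, small_ensemble):
        res = bundle_screen(small_ensemble, template12)
        assert res.count / res.n_replicates < 0.1
        flagged = res.flags[res.flags["flagged"]]
        assert (flagged["lifetime_us"] >= 0).all()
        assert (flagged["separation_us"] >= flagged["first_contact_us"]).all()


class TestExpectedEncounters:
    def test_zero_fraction(self):
        assert expected_random_encounters(512, 1.0, 0.0) == 0

    def test_paper_upper_bound(self):
        assert expected_random_encounters(512, 0.625, 0.125) == pytest.approx(40.0)

    def test_bounds_validated(self):
        with pytest.raises(ContactError):
            expected_random_encounters(10, 1.5, 0.5)
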