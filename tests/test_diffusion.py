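"""Distance fields, tortuosity, path lengthening, airspace conductance."""

import warnings

import numpy as np
import pytest

import leafgas as lg
from leafgas.volume import DEFAULT_LABELS, LabeledVolume

from conftest import dijkstra_geodesic, small_phantom_params

L = DEFAULT_LABELS


def open_slab(depth=30, ny=30, nx=30):
    return lg.slab_phantom(mesophyll_depth=depth, ny=ny, nx=nx, epidermis=3)


class TestDistanceFields:
    def test_matches_dijkstra_oracle_on_phantoms(self):
        """Production geodesic equals exact Dijkstra on the 26-neighbour
        voxel graph at every reachable voxel (three random phantoms; the
        acceptance suite runs twenty)."""
        for seed in range(3):
            vol, truth = lg.generate_leaf_volume(small_phantom_params(seed=seed))
            fields = lg.distance_fields(vol, truth.stomate_centers)
            oracle = dijkstra_geodesic(vol.mask("ias"), fields.seeds, vol.voxel_size_um)
            ias = vol.mask("ias")
            both = ias & np.isfinite(fields.l_geo) & np.isfinite(oracle)
            assert np.array_equal(np.isfinite(fields.l_geo[ias]), np.isfinite(oracle[ias]))
            rel = np.abs(fields.l_geo[both] - oracle[both]) / np.maximum(oracle[both], 1e-9)
            assert np.nanmax(rel) < 0.02

    def test_ordering_invariant(self, small_phantom):
        """L_geo >= L_Euc >= L_epi wherever defined (stomata on the
        abaxial epidermis)."""
        _, vol, truth = small_phantom
        f = lg.distance_fields(vol, truth.stomate_centers)
        ias = vol.mask("ias") & np.isfinite(f.l_geo)
        assert np.all(f.l_geo[ias] >= f.l_euc[ias] - 1e-9)
        assert np.all(f.l_euc[ias] >= f.l_epi[ias] - 1e-9)

    def test_adjacent_seed_distance_is_one_pitch(self):
        slab = open_slab()
        seed = np.array([[32, 15, 15]])
        f = lg.distance_fields(slab, seed)
        assert f.l_geo[31, 15, 15] == pytest.approx(1.0)
        assert f.l_euc[31, 15, 15] == pytest.approx(1.0)

    def test_wall_with_gap_matches_hand_path(self):
        """A solid wall with one gap: the geodesic detours through the
        gap; checked against the exact graph oracle."""
        slab = open_slab(depth=20, ny=21, nx=21)
        labels = slab.labels.copy()
        wall_z = 13
        labels[wall_z, :, :] = L["mesophyll_cell"]
        labels[wall_z, 10, 10] = L["ias"]  # single gap
        vol = LabeledVolume(labels, 1.0)
        seed = np.array([[22, 2, 2]])
        f = lg.distance_fields(vol, seed)
        oracle = dijkstra_geodesic(vol.mask("ias"), seed, 1.0)
        target = (5, 18, 18)  # other side of the wall
        assert np.isfinite(f.l_geo[target])
        assert f.l_geo[target] == pytest.approx(oracle[target], rel=1e-9)
        assert f.l_geo[target] > f.l_euc[target]  # forced detour

    def test_seed_in_solid_tissue_rejected(self, small_phantom):
        _, vol, _ = small_phantom
        with pytest.raises(ValueError, match="not an IAS voxel"):
            lg.distance_fields(vol, np.array([[0, 0, 0]]))

    def test_no_seeds_rejected(self, small_phantom):
        _, vol, _ = small_phantom
        with pytest.raises(ValueError):
            lg.distance_fields(vol, np.empty((0, 3), int))

    def test_detected_stomata_match_truth(self, small_phantom):
        _, vol, truth = small_phantom
        seeds = lg.detect_stomata(vol)
        # every recorded stomate center is among the detected pore voxels
        detected = {tuple(s) for s in seeds}
        for c in truth.stomate_centers:
            assert tuple(c) in detected


class TestTortuosity:
    def test_open_slab_is_unity(self):
        slab = open_slab()
        seed = np.array([[32, 15, 15]])  # bottom mesophyll row
        f = lg.distance_fields(slab, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau = lg.leaf_tortuosity(f, slab)
        assert tau == pytest.approx(1.0, abs=0.02)

    def test_never_below_one_on_random_phantoms(self):
        for seed in range(5):
            vol, truth = lg.generate_leaf_volume(small_phantom_params(seed=seed))
            f = lg.distance_fields(vol, truth.stomate_centers)
            assert lg.leaf_tortuosity(f, vol) >= 1.0

    def test_obstacles_increase_tortuosity(self):
        """Adding an impermeable baffle never decreases tau."""
        slab = open_slab(depth=24, ny=24, nx=24)
        labels = slab.labels.copy()
        labels[10:12, 2:22, 2:22] = L["mesophyll_cell"]  # pierced floor
        labels[10:12, 11:13, 11:13] = L["ias"]
        open_vol = LabeledVolume(slab.labels, 1.0)
        walled = LabeledVolume(labels, 1.0)
        seed = np.array([[26, 12, 12]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau_open = lg.leaf_tortuosity(lg.distance_fields(open_vol, seed), open_vol)
        tau_wall = lg.leaf_tortuosity(lg.distance_fields(walled, seed), walled)
        assert tau_wall > tau_open


class TestPathLengthening:
    def test_full_coverage_is_unity(self):
        slab = open_slab()
        nz = slab.shape[0]
        seeds = np.array(
            [[nz - 4, y, x] for y in range(30) for x in range(30)]
        )  # stomata tiling the abaxial surface
        f = lg.distance_fields(slab, seeds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = lg.leaf_path_lengthening(f, slab)
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_single_stomate_in_wide_leaf(self):
        slab = open_slab(depth=10, ny=50, nx=50)
        seed = np.array([[12, 25, 25]])
        f = lg.distance_fields(slab, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = lg.leaf_path_lengthening(f, slab)
        assert lam > 2.0

    def test_fewer_stomata_increase_lambda(self):
        """Halving stomatal density raises lateral path lengthening, the
        direction seen across species with contrasting densities."""
        vol, truth = lg.generate_leaf_volume(
            small_phantom_params(seed=8, stomatal_density_mm2=600.0)
        )
        seeds = truth.stomate_centers
        half = seeds[: max(1, len(seeds) // 2)]
        lam_full = lg.leaf_path_lengthening(lg.distance_fields(vol, seeds), vol)
        lam_half = lg.leaf_path_lengthening(lg.distance_fields(vol, half), vol)
        assert lam_half > lam_full
        assert lam_full >= 1.0


class TestGIas:
    def test_worked_value(self):
        """theta=0.3, Dm=1.54e-5 m2/s, Lmes=200 um, tau=1.5, lambda=1.2
        at 298 K and 1 bar gives ~1.04 mol m-2 s-1 bar-1 (hand-computed
        porous-slab conductance times ideal-gas molar density)."""
        g = lg.g_ias(0.3, 1.5, 1.2, 200e-6, d_m=1.54e-5, temperature=298.0)
        assert g == pytest.approx(1.036, abs=0.01)

    def test_scaling_laws(self):
        base = lg.g_ias(0.3, 1.5, 1.2, 200e-6)
        assert lg.g_ias(0.6, 1.5, 1.2, 200e-6) == pytest.approx(2 * base, rel=1e-12)
        assert lg.g_ias(0.3, 1.5, 1.2, 400e-6) == pytest.approx(base / 2, rel=1e-12)
        assert lg.g_ias(0.3, 3.0, 1.2, 200e-6) == pytest.approx(base / 2, rel=1e-12)
        assert lg.g_ias(0.3, 1.5, 2.4, 200e-6) == pytest.approx(base / 2, rel=1e-12)

    def test_free_slab_limit(self):
        """tau = lambda = theta = 1 reduces to the free-air slab
        conductance Dm/(0.5 Lmes) times P/(RT)."""
        g = lg.g_ias(1.0, 1.0, 1.0, 200e-6, d_m=1.54e-5, temperature=298.15)
        expected = 1.54e-5 / (0.5 * 200e-6) * 1e5 / (8.31446 * 298.15)
        assert g == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            lg.g_ias(0.0, 1.5, 1.2, 200e-6)


class TestGiasContribution:
    def test_limits_and_arithmetic(self):
        assert lg.gias_contribution(0.1, 1e9) == pytest.approx(0.0, abs=1e-9)
        assert lg.gias_contribution(0.5, 0.5) == pytest.approx(1.0)
        assert lg.gias_contribution(0.22, 1.0) == pytest.approx(0.22)

    def test_gm_exceeding_gias_rejected(self):
        with pytest.raises(ValueError, match="series"):
            lg.gias_contribution(1.0, 0.5)
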