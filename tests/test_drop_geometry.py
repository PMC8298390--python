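"""Droplet geometries: voxelisation, substrate placement, collision model."""

import numpy as np
import pytest

from dropmix.drop_geometry import (CollisionParams, DropSpec,
                                   apply_pei_initial_condition, apportion,
                                   build_mass_flow_model, discretize_sphere,
                                   weber_number)
from dropmix.errors import PlacementError, ValidationError


class TestDropSpec:
    def test_diameter_derived_from_volume(self):
        # 4 nL sphere: d = (6V/pi)^(1/3) ~ 197 µm
        assert DropSpec(4000.0).diameter == pytest.approx(196.95, abs=0.1)

    def test_inconsistent_diameter_rejected(self):
        with pytest.raises(ValidationError, match="disagree"):
            DropSpec(4000.0, diameter_um=150.0)

    def test_consistent_diameter_accepted(self):
        d = DropSpec(4000.0).diameter
        assert DropSpec(4000.0, diameter_um=d).diameter == d


class TestDiscretizeSphere:
    def test_volume_conserved_within_tolerance(self):
        lat = discretize_sphere(4.0, 20.0)
        assert lat.total_volume_pL == pytest.approx(4000.0, rel=0.05)
        assert lat.meta["diameter_um"] == pytest.approx(196.95, abs=0.1)

    def test_halving_spacing_multiplies_compartments_by_about_eight(self):
        coarse = discretize_sphere(4.0, 20.0).n_compartments
        fine = discretize_sphere(4.0, 10.0).n_compartments
        assert 5.0 < fine / coarse < 10.0

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(ValidationError):
            discretize_sphere(4.0, 90.0)  # < 3 voxels across

    def test_spacing_larger_than_radius_rejected(self):
        with pytest.raises(ValidationError):
            discretize_sphere(0.004, 50.0)

    def test_uniform_concentration_is_stationary_flux_balance(self):
        # k_ij * V_i = k_ji * V_j must hold edge by edge (partial voxels)
        lat = discretize_sphere(0.5, 12.0)
        key = {}
        for e in range(lat.edge_src.size):
            key[(lat.edge_src[e], lat.edge_dst[e])] = lat.edge_rates[e, 0]
        for (i, j), k_ij in key.items():
            assert k_ij * lat.volumes_pL[i] == pytest.approx(
                key[(j, i)] * lat.volumes_pL[j], rel=1e-9)


class TestWeberNumber:
    def test_direct_evaluation(self):
        p = CollisionParams(1000.0, 1.5, 200e-6, 0.072)
        assert weber_number(p) == pytest.approx(6.25)

    def test_quadratic_in_velocity(self):
        p1 = CollisionParams(1000.0, 1.0, 200e-6, 0.072)
        p2 = CollisionParams(1000.0, 2.0, 200e-6, 0.072)
        assert weber_number(p2) == pytest.approx(4 * weber_number(p1))

    def test_large_surface_tension_limit(self):
        p = CollisionParams(1000.0, 1.5, 200e-6, 1e9)
        assert weber_number(p) < 1e-6

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValidationError):
            CollisionParams(1000.0, 0.0, 200e-6, 0.072)


class TestApportion:
    def test_conserves_total_and_tracks_weights(self):
        out = apportion(1000, [1.0, 2.0, 3.0, 4.0])
        assert out.sum() == 1000
        assert np.allclose(out, [100, 200, 300, 400])

    def test_remainders_distributed(self):
        out = apportion(10, [1.0, 1.0, 1.0])
        assert out.sum() == 10


class TestPeiPlacement:
    def test_surface_caps_hold_all_substrate(self):
        # 3 x 60 pL at 100 mM -> 18 pmol of substrate
        lat = discretize_sphere(4.0, 20.0)
        pei = DropSpec(60.0, 3)
        scale = 18e-12 / 1e4
        init = apply_pei_initial_condition(lat, pei, 0.1, mode="surface_caps",
                                           particle_scale=scale)
        i_ca = lat.species.index("Ca")
        total = init.state.counts[:, i_ca].sum()
        assert total == round(18e-12 / scale)
        # interior (original voxels) holds nothing at t = 0
        assert init.state.counts[:lat.n_compartments, i_ca].sum() == 0
        assert init.lattice.n_compartments == lat.n_compartments + 3
        # appended caps carry the injector drop volume
        assert init.lattice.total_volume_pL == pytest.approx(
            lat.total_volume_pL + 180.0, rel=1e-9)

    def test_cone_jets_place_substrate_in_interior(self):
        lat = discretize_sphere(4.18, 20.0)
        pei = DropSpec(60.0, 3)
        scale = 18e-12 / 1e4
        init = apply_pei_initial_condition(lat, pei, 0.1, mode="cone_jets",
                                           particle_scale=scale)
        i_ca = lat.species.index("Ca")
        assert init.lattice.n_compartments == lat.n_compartments
        # amount conserved: 3 x 60 pL x 100 mM = 18 pmol, scaled
        assert init.state.counts[:, i_ca].sum() == round(18e-12 / scale)
        # substrate sits inside the (voxel-clipped) sphere, and the cones
        # reach well below the surface shell
        r = np.linalg.norm(lat.centroids_um[init.substrate_compartments], axis=1)
        h = lat.meta["h_um"]
        assert np.all(r < lat.meta["radius_um"] + h)
        assert r.min() < lat.meta["radius_um"] - 2 * h

    def test_zero_cone_depth_degenerates_to_surface_distribution(self):
        lat = discretize_sphere(4.18, 20.0)
        pei = DropSpec(60.0, 3)
        init = apply_pei_initial_condition(lat, pei, 0.1, mode="cone_jets",
                                           particle_scale=18e-12 / 1e4,
                                           cone_depth_fraction=0.0)
        r = np.linalg.norm(lat.centroids_um[init.substrate_compartments], axis=1)
        h = lat.meta["h_um"]
        assert np.all(r >= lat.meta["radius_um"] - 2 * h)

    def test_overlapping_sites_raise_placement_error(self):
        lat = discretize_sphere(4.0, 20.0)
        with pytest.raises(PlacementError):
            apply_pei_initial_condition(lat, DropSpec(60.0, 12), 0.1,
                                        particle_scale=1e-16)

    def test_total_pei_volume_must_fit(self):
        lat = discretize_sphere(0.06, 5.0)
        with pytest.raises(ValidationError):
            apply_pei_initial_condition(lat, DropSpec(60.0, 3), 0.1,
                                        particle_scale=1e-16)


class TestMassFlowModel:
    def test_transfer_rate_is_velocity_over_mixing_length(self):
        # 200 µm drop split in two: L_mix = 100 µm; v = 1.5 m/s -> 1.5e4 /s
        ade = DropSpec(np.pi * 200.0**3 / 6.0 / 1e3)
        lat = build_mass_flow_model(ade, DropSpec(60.0, 3), 1.5, 2)
        assert lat.meta["transfer_rate_s"] == pytest.approx(1.5e4)
        assert np.allclose(lat.edge_rates, 1.5e4)

    def test_merged_volume_conserved(self):
        ade, pei = DropSpec(4000.0), DropSpec(60.0, 3)
        lat = build_mass_flow_model(ade, pei, 1.5, 10)
        assert lat.total_volume_pL == pytest.approx(4180.0, rel=1e-9)

    @pytest.mark.parametrize("v", [1.0, 1.5, 2.0])
    def test_reported_collision_velocities_accepted(self, v):
        build_mass_flow_model(DropSpec(4000.0), DropSpec(60.0, 3), v, 4)

    def test_unphysical_velocity_rejected(self):
        with pytest.raises(ValidationError):
            build_mass_flow_model(DropSpec(4000.0), DropSpec(60.0, 3), 50.0, 4)

    def test_chain_needs_at_least_two_compartments(self):
        with pytest.raises(ValidationError):
            build_mass_flow_model(DropSpec(4000.0), DropSpec(60.0, 3), 1.5, 1)
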