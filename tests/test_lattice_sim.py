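"""Stochastic engine: hop rates, exactness, conservation, oracles."""

import numpy as np
import pytest

from dropmix.errors import ValidationError
from dropmix.lattice_sim import (Lattice, SimState, diffusion_hop_rate, simulate_ssa,
                                 simulate_wellmixed_ode)
from dropmix.mixing_pipeline import MixingConfig, equilibration_time, run_regime
from dropmix.reaction_model import (Reaction, ReactionNetwork, Species,
                                    build_dye_network, equilibrium_state)

#: association rate used in engine tests; binding still equilibrates far
#: faster than transport at these concentrations while keeping the
#: bind/unbind event rate tractable
KON_TEST = 1e6


def single_compartment(species, volume_pL=1.0):
    return Lattice(np.zeros((1, 3)), np.array([volume_pL]),
                   np.zeros(0, int), np.zeros(0, int),
                   np.zeros((0, len(species))), species=list(species))


def two_compartments(species, rate=1.0, volume_pL=1.0):
    S = len(species)
    return Lattice(np.array([[0.0, 0, 0], [10.0, 0, 0]]),
                   np.array([volume_pL, volume_pL]),
                   np.array([0, 1]), np.array([1, 0]),
                   np.full((2, S), rate), species=list(species))


class TestHopRate:
    def test_direct_evaluation(self):
        assert diffusion_hop_rate(7.9e-10, 10e-6) == pytest.approx(7.9)

    def test_halving_spacing_quadruples_rate(self):
        assert diffusion_hop_rate(4e-10, 5e-6) == pytest.approx(
            4 * diffusion_hop_rate(4e-10, 10e-6))

    @pytest.mark.parametrize("D,h", [(0.0, 1e-6), (1e-10, 0.0), (-1e-10, 1e-6)])
    def test_nonpositive_inputs_rejected(self, D, h):
        with pytest.raises(ValidationError):
            diffusion_hop_rate(D, h)


def _dye_state(lattice, net, ca_M, dye_M, n_ca=100_000):
    """Counts for Ca + Fluo-5N in every compartment at equal concentration."""
    v_L = lattice.volumes_pL * 1e-12
    scale = ca_M * v_L.sum() / n_ca
    counts = np.zeros((lattice.n_compartments, 5), dtype=np.int64)
    i_ca = net.species_names.index("Ca")
    i_fluo = net.species_names.index("FluoFree")
    counts[:, i_ca] = np.round(ca_M * v_L / scale).astype(np.int64)
    counts[:, i_fluo] = np.round(dye_M * v_L / scale).astype(np.int64)
    return SimState(counts, scale)


class TestSSA:
    def test_pure_diffusion_keeps_volume_average_constant(self):
        net = ReactionNetwork((Species("A"),), (), ())
        lat = two_compartments(["A"], rate=5.0)
        counts = np.array([[500], [500]], dtype=np.int64)
        traj = simulate_ssa(lat, net, SimState(counts, 1e-18), 2.0,
                            np.linspace(0, 2, 40)[1:], seed=3)
        assert np.all(traj.averaged_M == traj.averaged_M[0])

    def test_single_particle_splits_time_evenly(self):
        # stationary distribution of the symmetric two-state chain is 1/2
        net = ReactionNetwork((Species("A"),), (), ())
        lat = two_compartments(["A"], rate=1.0)
        counts = np.array([[1], [0]], dtype=np.int64)
        traj = simulate_ssa(lat, net, SimState(counts, 1e-18), 4000.0,
                            np.arange(1.0, 4000.0), seed=5,
                            record_compartments=True)
        occupancy = traj.per_compartment[:, 0, 0].mean()
        assert occupancy == pytest.approx(0.5, abs=0.03)

    def test_long_time_binding_matches_equilibrium_oracle(self):
        net = build_dye_network(kon_fura=KON_TEST, kon_fluo=KON_TEST)
        lat = single_compartment(net.species_names)
        st = _dye_state(lat, net, ca_M=1.5e-3, dye_M=1.0e-3)
        traj = simulate_ssa(lat, net, st, 0.1, np.linspace(0, 0.1, 60)[1:], seed=9)
        eq = equilibrium_state(net, {"Ca": 1.5e-3, "Fluo": 1.0e-3})
        late = traj.concentration("FluoBound")[-15:]
        se = late.std(ddof=1) / np.sqrt(len(late))
        assert abs(late.mean() - eq["FluoBound"]) < 3 * se + 3e-7
        assert eq["FluoBound"] == pytest.approx(8.742566e-4, rel=1e-5)

    def test_conserved_moieties_exact_on_every_snapshot(self):
        net = build_dye_network(kon_fura=KON_TEST, kon_fluo=KON_TEST)
        lat = two_compartments(net.species_names, rate=2.0)
        st = _dye_state(lat, net, ca_M=2e-3, dye_M=1e-3, n_ca=20_000)
        ca0 = st.counts[:, 0].sum()
        fluo0 = st.counts[:, 3].sum() + st.counts[:, 4].sum()
        traj = simulate_ssa(lat, net, st, 0.05, np.linspace(0, 0.05, 30)[1:],
                            seed=13, record_compartments=True)
        per = traj.per_compartment
        names = net.species_names
        ca = per[:, :, names.index("Ca")].sum(axis=1) \
            + per[:, :, names.index("FuraBound")].sum(axis=1) \
            + per[:, :, names.index("FluoBound")].sum(axis=1)
        fluo = per[:, :, names.index("FluoFree")].sum(axis=1) \
            + per[:, :, names.index("FluoBound")].sum(axis=1)
        assert np.all(ca == ca0)
        assert np.all(fluo == fluo0)

    def test_identical_seed_gives_bit_identical_trajectory(self):
        net = build_dye_network(kon_fura=KON_TEST, kon_fluo=KON_TEST)
        lat = two_compartments(net.species_names, rate=2.0)
        st = _dye_state(lat, net, ca_M=1e-3, dye_M=1e-3, n_ca=10_000)
        rec = np.linspace(0, 0.02, 20)[1:]
        a = simulate_ssa(lat, net, st.copy(), 0.02, rec, seed=21)
        b = simulate_ssa(lat, net, st.copy(), 0.02, rec, seed=21)
        c = simulate_ssa(lat, net, st.copy(), 0.02, rec, seed=22)
        assert np.array_equal(a.averaged_M, b.averaged_M)
        assert not np.array_equal(a.averaged_M, c.averaged_M)

    def test_exhausted_system_flags_absorbed(self):
        net = ReactionNetwork((Species("A"), Species("B")),
                              (Reaction((("A", 1),), (("B", 1),), 50.0),), ())
        lat = single_compartment(["A", "B"])
        counts = np.array([[200, 0]], dtype=np.int64)
        traj = simulate_ssa(lat, net, SimState(counts, 1e-18), 100.0,
                            np.linspace(0, 100, 20)[1:], seed=1)
        assert traj.absorbed
        assert traj.averaged_M[-1, 0] == 0.0

    def test_ssa_matches_ode_within_three_standard_errors(self):
        # law of large numbers: >=1e4 particles per species, 10 replicates
        net = build_dye_network(kon_fura=KON_TEST, kon_fluo=KON_TEST)
        lat = single_compartment(net.species_names)
        rec = np.linspace(0, 0.05, 20)[1:]
        init = {"Ca": 1.5e-3, "FluoFree": 1.2e-3, "FuraFree": 3e-4}
        ode = simulate_wellmixed_ode(net, init, 0.05, rec)
        runs = []
        for seed in range(10):
            v_L = 1e-12
            scale = 1.5e-3 * v_L / 30_000
            counts = np.zeros((1, 5), dtype=np.int64)
            for name, c in init.items():
                counts[0, net.species_names.index(name)] = round(c * v_L / scale)
            traj = simulate_ssa(lat, net, SimState(counts, scale), 0.05, rec,
                                seed=100 + seed)
            runs.append(traj.concentration("FluoBound"))
        runs = np.array(runs)
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
        ref = ode.concentration("FluoBound")
        assert np.all(np.abs(mean - ref) < 3 * se + 1e-3 * ref.max())


class TestWellMixedODE:
    def test_zero_rate_constants_give_constant_solution(self):
        net = ReactionNetwork((Species("A"), Species("B")),
                              (Reaction((("A", 1),), (("B", 1),), 0.0),), ())
        traj = simulate_wellmixed_ode(net, {"A": 1e-3}, 1.0)
        assert np.allclose(traj.concentration("A"), 1e-3, rtol=1e-9)

    def test_long_time_endpoint_matches_equilibrium(self):
        net = build_dye_network()
        totals = {"Ca": 2e-3, "Fura": 1e-3, "Fluo": 1e-3}
        traj = simulate_wellmixed_ode(
            net, {"Ca": 2e-3, "FuraFree": 1e-3, "FluoFree": 1e-3}, 1.0)
        eq = equilibrium_state(net, totals)
        for sp in ("FuraBound", "FluoBound", "Ca"):
            assert traj.concentration(sp)[-1] == pytest.approx(eq[sp], rel=1e-5)

    def test_moiety_conservation_along_trajectory(self):
        net = build_dye_network()
        traj = simulate_wellmixed_ode(
            net, {"Ca": 2e-3, "FuraFree": 1e-3, "FluoFree": 1e-3}, 0.5)
        ca = (traj.concentration("Ca") + traj.concentration("FuraBound")
              + traj.concentration("FluoBound"))
        assert np.allclose(ca, 2e-3, rtol=1e-7)


class TestSpatialConvergence:
    def test_halving_spacing_changes_equilibration_below_20_percent(self):
        """Grid-refinement stability of the diffusive mixing time.

        A scaled-down drop (0.5 nL, one 20 pL surface drop) so both
        resolutions run quickly; the association rate is reduced, keeping
        binding much faster than transport.
        """
        times = []
        for h in (12.0, 6.0):
            cfg = MixingConfig(regime="diffusion_only", ade_volume_nL=0.5,
                               pei_volume_pL=20.0, n_pei_drops=1,
                               kon_M_s=KON_TEST, h_um=h, t_end_s=4.0,
                               target_particles=2e4, record_points=200, seed=31)
            res = run_regime(cfg)
            assert res.bound_total_time.reached
            times.append(res.bound_total_time.time_s)
        coarse, fine = times
        assert abs(coarse - fine) / fine < 0.20
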