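"""Compartmental stochastic reaction–diffusion engine and its deterministic oracle.

The state is a set of compartments (voxels of a droplet, appended surface
drops, or a mass-flow chain) each holding integer particle counts per
species. Events are elementary reactions inside a compartment and
per-particle transfers along couplings (Fickian hops or inertial mass
flow); the exact Gillespie direct method samples the chemical master
equation, compiled with numba (see :mod:`dropmix._kernel`).

Real drops hold ~1e12 molecules; simulations use scaled particle counts
(``particle_scale`` = moles per simulated particle). Concentrations and
mean dynamics are unchanged by the scaling; relative fluctuations are
inflated by sqrt(scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import units
from ._kernel import ssa_run
from .errors import NumericalError, ValidationError
from .reaction_model import ReactionNetwork


def diffusion_hop_rate(D, h) -> float:
    """Per-particle hop rate [1/s] to one neighbour: D / h**2.

    ``D`` in m^2/s, ``h`` (compartment spacing) in metres; tagged strings
    accepted for ``h``.
    """
    D = float(D)
    h = units.metres(h)
    units.require_positive(D=D, h=h)
    return D / h**2


@dataclass
class Lattice:
    """Compartment geometry plus per-species transfer couplings.

    Couplings are directed: particle ``s`` leaves ``edge_src[e]`` for
    ``edge_dst[e]`` at per-particle rate ``edge_rates[e, s]`` [1/s].
    Symmetric diffusion between equal voxels appears as two directed edges
    of equal rate; edges between compartments of unequal volume carry
    rates satisfying k_ij * V_i = k_ji * V_j so that a uniform
    concentration is stationary.
    """

    centroids_um: np.ndarray  # (C, 3)
    volumes_pL: np.ndarray  # (C,)
    edge_src: np.ndarray  # (E,) int
    edge_dst: np.ndarray  # (E,) int
    edge_rates: np.ndarray  # (E, S) per-particle 1/s
    species: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        self.volumes_pL = np.asarray(self.volumes_pL, dtype=float)
        self.edge_src = np.asarray(self.edge_src, dtype=np.int64)
        self.edge_dst = np.asarray(self.edge_dst, dtype=np.int64)
        self.edge_rates = np.asarray(self.edge_rates, dtype=float)
        C = self.n_compartments
        if np.any(self.volumes_pL <= 0):
            raise ValidationError("all compartment volumes must be > 0")
        if self.edge_src.size and (self.edge_src.max() >= C or self.edge_dst.max() >= C
                                   or self.edge_src.min() < 0 or self.edge_dst.min() < 0):
            raise ValidationError("couplings reference non-existent compartments")
        if np.any(self.edge_rates < 0):
            raise ValidationError("hop rates must be non-negative")

    @property
    def n_compartments(self) -> int:
        return self.volumes_pL.shape[0]

    @property
    def total_volume_pL(self) -> float:
        return float(self.volumes_pL.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n_compartments),
            "x_um": self.centroids_um[:, 0],
            "y_um": self.centroids_um[:, 1],
            "z_um": self.centroids_um[:, 2],
            "volume_pL": self.volumes_pL,
        })


@dataclass
class SimState:
    """Integer particle counts per (compartment, species) at a time point."""

    counts: np.ndarray  # (C, S) int64
    particle_scale: float  # moles per simulated particle
    time: float = 0.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("particle counts must be non-negative")
        units.require_positive(particle_scale=self.particle_scale)

    def copy(self) -> "SimState":
        return SimState(self.counts.copy(), self.particle_scale, self.time)


@dataclass
class Trajectory:
    """Volume-averaged species concentrations over time.

    ``averaged_M[t, s]`` is total moles of species ``s`` divided by the
    combined volume of all compartments (molar). Optional per-compartment
    snapshots are particle counts.
    """

    times: np.ndarray  # (T,) s, strictly increasing
    species: list[str]
    averaged_M: np.ndarray  # (T, S)
    per_compartment: np.ndarray | None = None  # (T, C, S) counts
    absorbed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.averaged_M = np.asarray(self.averaged_M, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")
        if np.any(self.averaged_M < 0):
            raise ValidationError("concentrations must be non-negative")

    def concentration(self, species: str) -> np.ndarray:
        return self.averaged_M[:, self.species.index(species)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.averaged_M, columns=self.species)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _build_reaction_arrays(network: ReactionNetwork):
    names = network.species_names
    idx = {n: i for i, n in enumerate(names)}
    R, S = len(network.reactions), len(names)
    sp1 = np.full(R, -1, dtype=np.int64)
    sp2 = np.full(R, -1, dtype=np.int64)
    k = np.zeros(R)
    delta = np.zeros((R, S), dtype=np.int64)
    for r, rx in enumerate(network.reactions):
        if rx.order > 2:
            raise ValidationError("engine supports at most bimolecular reactions")
        flat = []
        for name, st in rx.reactants:
            flat.extend([idx[name]] * st)
            delta[r, idx[name]] -= st
        for name, st in rx.products:
            delta[r, idx[name]] += st
        sp1[r] = flat[0]
        if len(flat) == 2:
            sp2[r] = flat[1]
        k[r] = rx.rate_constant
    return sp1, sp2, k, delta


def _edges_csr(lattice: Lattice):
    C = lattice.n_compartments
    order = np.argsort(lattice.edge_src, kind="stable")
    src = lattice.edge_src[order]
    eidx = order.astype(np.int64)
    eptr = np.zeros(C + 1, dtype=np.int64)
    np.add.at(eptr, src + 1, 1)
    eptr = np.cumsum(eptr)
    return eptr, eidx


def simulate_ssa(lattice: Lattice, network: ReactionNetwork, initial: SimState,
                 t_end: float, record_times, seed: int,
                 record_compartments: bool = False) -> Trajectory:
    """Exact stochastic simulation of the compartmental master equation.

    The trajectory is recorded at ``record_times`` (state just before each
    requested time). Identical ``seed`` and inputs give bit-identical
    output. If total propensity hits zero before ``t_end`` the system is
    absorbed and the remaining samples repeat the final state
    (``Trajectory.absorbed`` is set).
    """
    units.require_positive(t_end=t_end)
    record_times = np.asarray(record_times, dtype=float)
    if record_times.ndim != 1 or record_times.size == 0:
        raise ValidationError("record_times must be a non-empty 1-D sequence")
    if np.any(np.diff(record_times) <= 0):
        raise ValidationError("record_times must be strictly increasing")
    C, S = initial.counts.shape
    if C != lattice.n_compartments:
        raise ValidationError(
            f"initial counts have {C} compartments, lattice has {lattice.n_compartments}")
    if lattice.edge_rates.shape[1] != S:
        raise ValidationError("lattice couplings and state disagree on species count")
    names = network.species_names
    if len(names) != S:
        raise ValidationError("network and state disagree on species count")

    sp1, sp2, k, delta = _build_reaction_arrays(network)
    eptr, eidx = _edges_csr(lattice)
    counts = initial.counts.copy()
    volumes_L = lattice.volumes_pL * 1e-12
    rec, comp_rec, t_final, absorbed = ssa_run(
        counts, volumes_L, initial.particle_scale,
        lattice.edge_dst, lattice.edge_rates, eptr, eidx,
        sp1, sp2, k, delta,
        float(initial.time), float(t_end), record_times, int(seed),
        bool(record_compartments),
    )
    v_tot_L = lattice.total_volume_pL * 1e-12
    averaged = rec.astype(float) * initial.particle_scale / v_tot_L
    return Trajectory(
        times=record_times,
        species=names,
        averaged_M=averaged,
        per_compartment=comp_rec if record_compartments else None,
        absorbed=bool(absorbed),
        meta={"seed": int(seed), "t_end": float(t_end),
              "particle_scale": initial.particle_scale, "t_final": float(t_final)},
    )


def simulate_wellmixed_ode(network: ReactionNetwork, initial: dict, t_end: float,
                           t_eval=None, rtol: float = 1e-8) -> Trajectory:
    """Deterministic mass-action rate equations for a single well-mixed volume.

    ``initial`` maps species name to molar concentration (tagged strings
    accepted). Serves as the large-count oracle for :func:`simulate_ssa`.
    """
    units.require_positive(t_end=t_end)
    names = network.species_names
    idx = {n: i for i, n in enumerate(names)}
    y0 = np.zeros(len(names))
    for name, c in initial.items():
        c = units.molar(c)
        units.require_non_negative(**{name: c})
        y0[idx[name]] = c
    sp1, sp2, k, delta = _build_reaction_arrays(network)

    def rhs(_t, y):
        rates = np.empty(len(k))
        for r in range(len(k)):
            rate = k[r] * y[sp1[r]]
            if sp2[r] >= 0:
                rate *= y[sp2[r]]
            rates[r] = rate
        return rates @ delta

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 200)[1:]
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=1e-16)
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)
    return Trajectory(times=sol.t, species=names, averaged_M=y,
                      meta={"method": "LSODA", "rtol": rtol})
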