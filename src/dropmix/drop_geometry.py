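"""Droplet geometries for the three mixing regimes.

* diffusion-only: a voxelised sphere (the nanoliter acoustic-ejection
  drop) with picoliter injector drops appended as surface compartments,
  coupled by Fickian diffusion;
* cone-jet: the same sphere with the injector drops replaced by conical
  volumes extending inward from the contact sites — the partial-mix
  structure formed within milliseconds of impact;
* mass-flow: a chain of compartments spanning the merged volume with
  proportional inertial transfer at per-particle rate v_rel / L_mix, the
  lower-bound-on-mixing-time idealisation of a droplet collision.

Also computes the Weber number rho * v^2 * L / sigma governing the
collision regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .errors import PlacementError, ValidationError
from .lattice_sim import Lattice, SimState, diffusion_hop_rate

#: literature free-solution diffusion coefficients [m^2/s]
DEFAULT_DIFFUSION = {
    "Ca": 7.9e-10,
    "FuraFree": 4.0e-10,
    "FuraBound": 4.0e-10,
    "FluoFree": 4.0e-10,
    "FluoBound": 4.0e-10,
}


def sphere_diameter_um(volume_pL: float) -> float:
    """Diameter [µm] of a sphere of the given volume [pL]; 1 pL = 1e3 µm^3."""
    return (6.0 * volume_pL * 1e3 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DropSpec:
    """A dispensed drop population: volume per drop and drop count."""

    volume_pL: float
    count: int = 1
    diameter_um: float | None = None

    def __post_init__(self):
        units.require_positive(volume_pL=self.volume_pL)
        if self.count < 0:
            raise ValidationError(f"count must be >= 0, got {self.count}")
        if self.diameter_um is not None:
            implied = math.pi * self.diameter_um**3 / 6.0 / 1e3  # pL
            if abs(implied - self.volume_pL) > 1e-3 * self.volume_pL:
                raise ValidationError(
                    f"volume {self.volume_pL} pL and diameter {self.diameter_um} µm "
                    f"disagree beyond 0.1% (diameter implies {implied:.4g} pL)")

    @property
    def diameter(self) -> float:
        """Diameter [µm], derived from volume when not given."""
        if self.diameter_um is not None:
            return self.diameter_um
        return sphere_diameter_um(self.volume_pL)

    @property
    def total_volume_pL(self) -> float:
        return self.volume_pL * self.count


@dataclass(frozen=True)
class CollisionParams:
    """Inputs to the Weber number: all SI."""

    density: float  # kg/m^3
    velocity: float  # m/s
    length: float  # m
    surface_tension: float  # N/m

    def __post_init__(self):
        units.require_positive(density=self.density, velocity=self.velocity,
                               length=self.length, surface_tension=self.surface_tension)


def weber_number(p: CollisionParams) -> float:
    """We = rho * v^2 * L / sigma (inertial vs. capillary forces)."""
    return p.density * p.velocity**2 * p.length / p.surface_tension


@dataclass
class InitialState:
    """A SimState plus the provenance of substrate placement."""

    lattice: Lattice
    state: SimState
    regime: str
    sites_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    substrate_compartments: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


def apportion(total: int, weights) -> np.ndarray:
    """Split ``total`` integer particles over bins proportionally to ``weights``.

    Largest-remainder rounding; deterministic, conserves the total exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0 or np.any(weights < 0) or weights.sum() <= 0:
        raise ValidationError("apportion needs total >= 0 and positive weight sum")
    ideal = total * weights / weights.sum()
    base = np.floor(ideal).astype(np.int64)
    short = int(total - base.sum())
    if short:
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:short]] += 1
    return base


def discretize_sphere(volume_nL: float, h_um: float,
                      diffusion: dict[str, float] | None = None) -> Lattice:
    """Voxelise a sphere of the given volume into cubic compartments.

    Cubic voxels of edge ``h_um`` are clipped to the sphere: boundary
    voxels keep the partial volume estimated by 4x4x4 sub-sampling, so the
    summed compartment volume tracks the requested volume closely (it must
    land within 5%, the documented tolerance). 6-neighbour couplings carry
    per-species hop rate D/h^2, corrected by h^3/V_src for partial voxels
    so that k_ij * V_i = k_ji * V_j and a uniform concentration is
    stationary. Fewer than 3 voxels across the diameter is rejected.
    """
    units.require_positive(volume_nL=volume_nL, h_um=h_um)
    diffusion = dict(DEFAULT_DIFFUSION if diffusion is None else diffusion)
    species = list(diffusion)
    d_um = sphere_diameter_um(volume_nL * 1e3)
    radius = d_um / 2.0
    if h_um >= radius:
        raise ValidationError(f"spacing h={h_um} µm must be smaller than the "
                              f"sphere radius {radius:.1f} µm")
    if d_um / h_um < 3:
        raise ValidationError(
            f"h={h_um} µm too coarse: {d_um / h_um:.1f} voxels across the "
            f"{d_um:.0f} µm diameter (need >= 3)")

    n_half = int(math.ceil(radius / h_um))
    axis = (np.arange(-n_half, n_half + 1)) * h_um  # voxel centres
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    # occupancy fraction of each voxel by 4^3 sub-sampling
    sub = (np.arange(4) + 0.5) / 4.0 - 0.5  # offsets in voxel units
    frac = np.zeros(X.shape)
    for dx in sub:
        for dy in sub:
            for dz in sub:
                frac += ((X + dx * h_um) ** 2 + (Y + dy * h_um) ** 2
                         + (Z + dz * h_um) ** 2) <= radius**2
    frac /= len(sub) ** 3
    inside = frac > 0
    ii, jj, kk = np.nonzero(inside)
    centroids = np.stack([X[inside], Y[inside], Z[inside]], axis=1)
    volumes = frac[inside] * h_um**3 / 1e3  # pL

    total = volumes.sum()
    requested = volume_nL * 1e3
    if abs(total - requested) > 0.05 * requested:
        raise ValidationError(
            f"voxelised volume {total:.1f} pL deviates from requested "
            f"{requested:.1f} pL by more than 5%; refine h")

    index = {}
    for cid, (a, b, c) in enumerate(zip(ii, jj, kk)):
        index[(a, b, c)] = cid
    base = np.array([diffusion_hop_rate(diffusion[s], h_um * 1e-6) for s in species])
    full_pL = h_um**3 / 1e3
    src, dst, rates = [], [], []
    for (a, b, c), cid in index.items():
        for da, db, dc in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = index.get((a + da, b + db, c + dc))
            if nb is not None:
                src.extend((cid, nb))
                dst.extend((nb, cid))
                rates.append(base * (full_pL / volumes[cid]))
                rates.append(base * (full_pL / volumes[nb]))
    rates = np.array(rates).reshape(len(src), len(species))
    return Lattice(
        centroids_um=centroids,
        volumes_pL=volumes,
        edge_src=np.array(src, dtype=np.int64),
        edge_dst=np.array(dst, dtype=np.int64),
        edge_rates=rates,
        species=species,
        meta={"h_um": h_um, "radius_um": radius, "diameter_um": d_um,
              "diffusion": diffusion, "requested_volume_nL": volume_nL},
    )


def _boundary_mask(lattice: Lattice) -> np.ndarray:
    """Voxels within one spacing of the sphere surface."""
    h = lattice.meta["h_um"]
    radius = lattice.meta["radius_um"]
    r = np.linalg.norm(lattice.centroids_um, axis=1)
    return r >= radius - h


def contact_sites(radius_um: float, n_sites: int, polar_deg: float = 45.0) -> np.ndarray:
    """Evenly spaced sites on a latitude ring ``polar_deg`` from the top pole."""
    theta = math.radians(polar_deg)
    phis = 2.0 * math.pi * np.arange(n_sites) / max(n_sites, 1)
    return radius_um * np.stack([
        np.sin(theta) * np.cos(phis),
        np.sin(theta) * np.sin(phis),
        np.full(n_sites, np.cos(theta)),
    ], axis=1)


def apply_pei_initial_condition(lattice: Lattice, pei: DropSpec, c_substrate,
                                mode: str = "surface_caps", substrate: str = "Ca",
                                particle_scale: float | None = None,
                                cone_depth_fraction: float = 0.5,
                                polar_deg: float = 45.0) -> InitialState:
    """Place the substrate carried by the injector drops at time zero.

    ``surface_caps``: one cap compartment per drop is appended at distinct
    upper-hemisphere contact sites (45° latitude ring by default), holding
    all substrate; diffusion couplings to the nearby surface voxels use
    D*A/(d*V) rates so a uniform concentration is stationary.

    ``cone_jets``: cones of volume equal to each drop extend inward from
    the contact sites (depth = ``cone_depth_fraction`` x sphere radius,
    base radius fixed by volume conservation); the substrate is spread
    uniformly over the voxels inside each cone. Depth below one voxel
    degenerates to a surface distribution at the sites.
    """
    c_substrate = units.molar(c_substrate)
    units.require_positive(c_substrate=c_substrate)
    if pei.count < 1:
        raise ValidationError("pei.count must be >= 1")
    if mode not in ("surface_caps", "cone_jets"):
        raise ValidationError(f"unknown placement mode {mode!r}")
    if substrate not in lattice.species:
        raise ValidationError(f"substrate {substrate!r} not among lattice species")
    ade_volume_pL = lattice.total_volume_pL
    if pei.total_volume_pL >= ade_volume_pL:
        raise ValidationError("total injector volume must be below the main drop volume")

    moles = pei.total_volume_pL * 1e-12 * c_substrate
    if particle_scale is None:
        particle_scale = moles / 1e5
    n_particles = int(round(moles / particle_scale))

    radius = lattice.meta["radius_um"]
    h = lattice.meta["h_um"]
    sites = contact_sites(radius, pei.count, polar_deg)
    drop_radius_um = pei.diameter / 2.0
    if pei.count > 1:
        chord = np.linalg.norm(sites[0] - sites[1])
        if chord < 2.0 * drop_radius_um:
            raise PlacementError(
                f"{pei.count} drops of radius {drop_radius_um:.1f} µm overlap on the "
                f"45° ring (site separation {chord:.1f} µm)")

    s_idx = lattice.species.index(substrate)
    S = len(lattice.species)

    if mode == "surface_caps":
        diffusion = lattice.meta["diffusion"]
        C0 = lattice.n_compartments
        cap_centroids = sites * (radius + drop_radius_um) / radius
        cap_volumes = np.full(pei.count, pei.volume_pL)
        boundary = np.nonzero(_boundary_mask(lattice))[0]
        src = [lattice.edge_src]
        dst = [lattice.edge_dst]
        rates = [lattice.edge_rates]
        contact_area_m2 = math.pi * (drop_radius_um * 1e-6) ** 2
        for j in range(pei.count):
            d2 = np.linalg.norm(lattice.centroids_um[boundary] - sites[j], axis=1)
            att = boundary[d2 <= max(drop_radius_um, h)]
            if att.size == 0:
                att = boundary[[int(np.argmin(d2))]]
            area = contact_area_m2 / att.size
            for vox in att:
                dist_m = np.linalg.norm(cap_centroids[j] - lattice.centroids_um[vox]) * 1e-6
                v_cap_m3 = pei.volume_pL * 1e-15
                v_vox_m3 = lattice.volumes_pL[vox] * 1e-15
                row_out = np.array([diffusion[s] * area / (dist_m * v_cap_m3)
                                    for s in lattice.species])
                row_in = np.array([diffusion[s] * area / (dist_m * v_vox_m3)
                                   for s in lattice.species])
                src.append(np.array([C0 + j, vox]))
                dst.append(np.array([vox, C0 + j]))
                rates.append(np.stack([row_out, row_in]))
        new_lat = Lattice(
            centroids_um=np.vstack([lattice.centroids_um, cap_centroids]),
            volumes_pL=np.concatenate([lattice.volumes_pL, cap_volumes]),
            edge_src=np.concatenate(src),
            edge_dst=np.concatenate(dst),
            edge_rates=np.vstack(rates),
            species=list(lattice.species),
            meta=dict(lattice.meta, caps=list(range(C0, C0 + pei.count))),
        )
        counts = np.zeros((new_lat.n_compartments, S), dtype=np.int64)
        counts[C0:C0 + pei.count, s_idx] = apportion(n_particles, cap_volumes)
        target = np.arange(C0, C0 + pei.count)
        return InitialState(new_lat, SimState(counts, particle_scale), "surface_caps",
                            sites, target)

    # cone_jets: substrate goes into interior voxels, lattice unchanged
    depth = cone_depth_fraction * radius
    counts = np.zeros((lattice.n_compartments, S), dtype=np.int64)
    chosen: list[np.ndarray] = []
    if depth < h:  # degenerate: surface distribution at the sites
        base_r = max(drop_radius_um, h)
        boundary = np.nonzero(_boundary_mask(lattice))[0]
        for j in range(pei.count):
            d2 = np.linalg.norm(lattice.centroids_um[boundary] - sites[j], axis=1)
            sel = boundary[d2 <= base_r]
            if sel.size == 0:
                sel = boundary[[int(np.argmin(d2))]]
            chosen.append(sel)
    else:
        base_r = math.sqrt(3.0 * pei.volume_pL * 1e3 / (math.pi * depth))
        for j in range(pei.count):
            axis_in = -sites[j] / np.linalg.norm(sites[j])  # inward unit vector
            rel = lattice.centroids_um - sites[j]
            s_par = rel @ axis_in
            perp = np.linalg.norm(rel - np.outer(s_par, axis_in), axis=1)
            with np.errstate(invalid="ignore"):
                in_cone = (s_par >= 0) & (s_par <= depth) & \
                    (perp <= base_r * (1.0 - s_par / depth))
            sel = np.nonzero(in_cone)[0]
            if sel.size == 0:
                sel = np.array([int(np.argmin(np.linalg.norm(
                    lattice.centroids_um - sites[j], axis=1)))])
            chosen.append(sel)
    all_sel = np.unique(np.concatenate(chosen))
    counts[all_sel, s_idx] = apportion(n_particles, lattice.volumes_pL[all_sel])
    return InitialState(lattice, SimState(counts, particle_scale), "cone_jets",
                        sites, all_sel)


def build_mass_flow_model(ade: DropSpec, pei: DropSpec, v_rel: float,
                          n_compartments: int,
                          species: list[str] | None = None) -> Lattice:
    """Chain-of-compartments inertial mixing model of the droplet collision.

    The merged volume (main drop + all injector drops) is split into
    ``n_compartments`` equal slabs coupled by proportional mass flow at
    per-particle rate v_rel / L_mix with L_mix = main-drop diameter /
    n_compartments. No Fickian couplings: this is the pure
    hydrodynamic-flow lower bound on mixing time.
    """
    units.require_positive(v_rel=v_rel)
    if not (0.1 <= v_rel <= 10.0):
        raise ValidationError(f"v_rel={v_rel} m/s outside the physical range 0.1-10")
    if n_compartments < 2:
        raise ValidationError("n_compartments must be >= 2")
    species = list(DEFAULT_DIFFUSION) if species is None else list(species)

    total_pL = ade.volume_pL * ade.count + pei.total_volume_pL
    L_mix_m = ade.diameter * 1e-6 / n_compartments
    rate = v_rel / L_mix_m  # 1/s per particle
    n = n_compartments
    centroids = np.zeros((n, 3))
    centroids[:, 0] = (np.arange(n) + 0.5) * L_mix_m * 1e6
    volumes = np.full(n, total_pL / n)
    src, dst = [], []
    for i in range(n - 1):
        src.extend((i, i + 1))
        dst.extend((i + 1, i))
    rates = np.full((len(src), len(species)), rate)
    return Lattice(
        centroids_um=centroids, volumes_pL=volumes,
        edge_src=np.array(src, dtype=np.int64), edge_dst=np.array(dst, dtype=np.int64),
        edge_rates=rates, species=species,
        meta={"model": "mass_flow", "v_rel_m_s": v_rel, "L_mix_m": L_mix_m,
              "transfer_rate_s": rate, "ade_volume_pL": ade.volume_pL * ade.count,
              "pei_volume_pL": pei.total_volume_pL},
    )
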