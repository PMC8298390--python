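"""Chemical species, reversible Ca(II)–dye binding reactions and their equilibria.

The template system is the two-dye calcium-indicator mixture used to
validate drop-on-drop mixing: Fura Red (high affinity, Kd = 400 nM) and
Fluo-5N (low affinity, Kd = 90 µM), both binding free Ca2+ reversibly with
1:1 stoichiometry,

    Ca + Dye_free  <-> Dye_bound      k_on [1/(M s)], k_off = Kd * k_on [1/s].

All quantities are SI internally (molar, seconds); constructors accept
unit-tagged strings (``"400 nM"``) via :mod:`dropmix.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import units
from .errors import NumericalError, ValidationError

ROLES = ("ligand", "dye_free", "dye_bound", "inert")

#: literature dissociation constants of the two calcium indicators [M]
KD_FURA_RED = 4.0e-7
KD_FLUO_5N = 9.0e-5
#: diffusion-influenced default association rate constant [1/(M s)]
DEFAULT_KON = 1.0e8


@dataclass(frozen=True)
class Species:
    """A chemical species tracked by the simulations."""

    name: str
    role: str = "inert"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown species role {self.role!r}; one of {ROLES}")


@dataclass(frozen=True)
class Reaction:
    """Elementary mass-action reaction.

    ``rate_constant`` is per-second for unimolecular and per-molar-per-second
    for bimolecular steps. Stoichiometries are positive integers.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float

    def __post_init__(self):
        for side in (self.reactants, self.products):
            for name, st in side:
                if not (isinstance(st, int) and st > 0):
                    raise ValidationError(
                        f"stoichiometry of {name} must be a positive integer, got {st}"
                    )
        if self.rate_constant < 0:
            raise ValidationError("rate_constant must be non-negative")

    @property
    def order(self) -> int:
        return sum(st for _, st in self.reactants)


@dataclass(frozen=True)
class Dye:
    """Bookkeeping for one reversible 1:1 binder: species names and Kd."""

    name: str
    free_species: str
    bound_species: str
    kd: float  # M
    kon: float  # 1/(M s)

    @property
    def koff(self) -> float:
        return self.kd * self.kon


@dataclass(frozen=True)
class ReactionNetwork:
    """Species + reactions + the dye map used to derive conserved moieties."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    dyes: tuple[Dye, ...]
    ligand: str = "Ca"

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValidationError(f"species names must be unique, got {names}")
        known = set(names)
        for r in self.reactions:
            for name, _ in (*r.reactants, *r.products):
                if name not in known:
                    raise ValidationError(f"reaction references unknown species {name!r}")
        # reversible pairs must satisfy k_off = Kd * k_on
        for dye in self.dyes:
            kon = self._find_rate((self.ligand, dye.free_species), (dye.bound_species,))
            koff = self._find_rate((dye.bound_species,), (self.ligand, dye.free_species))
            if abs(koff - dye.kd * kon) > 1e-9 * max(koff, dye.kd * kon):
                raise ValidationError(
                    f"detailed balance violated for {dye.name}: "
                    f"k_off={koff} != Kd*k_on={dye.kd * kon}"
                )

    def _find_rate(self, reactants, products) -> float:
        for r in self.reactions:
            if (sorted(n for n, _ in r.reactants) == sorted(reactants)
                    and sorted(n for n, _ in r.products) == sorted(products)):
                return r.rate_constant
        raise ValidationError(f"no reaction {reactants} -> {products} in network")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def kd_map(self) -> dict[str, float]:
        return {d.name: d.kd for d in self.dyes}

    def moieties(self) -> dict[str, dict[str, int]]:
        """Conserved moieties as {moiety: {species: multiplicity}}.

        The ligand moiety counts free ligand plus every bound complex; each
        dye moiety counts its free and bound forms.
        """
        out = {self.ligand: {self.ligand: 1}}
        for d in self.dyes:
            out[self.ligand][d.bound_species] = 1
            out[d.name] = {d.free_species: 1, d.bound_species: 1}
        return out

    # -- declarative config round trip -------------------------------------
    def to_config(self) -> dict:
        return {
            "ligand": self.ligand,
            "species": [{"name": s.name, "role": s.role} for s in self.species],
            "dyes": [
                {
                    "name": d.name,
                    "free": d.free_species,
                    "bound": d.bound_species,
                    "kd": f"{d.kd} M",
                    "kon": d.kon,
                }
                for d in self.dyes
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ReactionNetwork":
        dyes = [
            Dye(d["name"], d["free"], d["bound"], units.molar(d["kd"]), float(d["kon"]))
            for d in cfg["dyes"]
        ]
        species = tuple(Species(s["name"], s.get("role", "inert")) for s in cfg["species"])
        ligand = cfg.get("ligand", "Ca")
        reactions = []
        for d in dyes:
            reactions.append(Reaction(((ligand, 1), (d.free_species, 1)),
                                      ((d.bound_species, 1),), d.kon))
            reactions.append(Reaction(((d.bound_species, 1),),
                                      ((ligand, 1), (d.free_species, 1)), d.koff))
        return cls(species, tuple(reactions), tuple(dyes), ligand)


def build_dye_network(kd_fura=KD_FURA_RED, kd_fluo=KD_FLUO_5N,
                      kon_fura=DEFAULT_KON, kon_fluo=DEFAULT_KON) -> ReactionNetwork:
    """Five-species competitive two-dye calcium binding network.

    Species: Ca, FuraFree/FuraBound, FluoFree/FluoBound; four reactions
    (two associations, two dissociations with k_off = Kd * k_on).
    Arguments accept molar floats or tagged strings (``"400 nM"``).
    """
    kd_fura = units.molar(kd_fura)
    kd_fluo = units.molar(kd_fluo)
    kon_fura = float(kon_fura)
    kon_fluo = float(kon_fluo)
    units.require_positive(kd_fura=kd_fura, kd_fluo=kd_fluo,
                           kon_fura=kon_fura, kon_fluo=kon_fluo)
    species = (
        Species("Ca", "ligand"),
        Species("FuraFree", "dye_free"),
        Species("FuraBound", "dye_bound"),
        Species("FluoFree", "dye_free"),
        Species("FluoBound", "dye_bound"),
    )
    dyes = (
        Dye("Fura", "FuraFree", "FuraBound", kd_fura, kon_fura),
        Dye("Fluo", "FluoFree", "FluoBound", kd_fluo, kon_fluo),
    )
    reactions = []
    for d in dyes:
        reactions.append(Reaction((("Ca", 1), (d.free_species, 1)),
                                  ((d.bound_species, 1),), d.kon))
        reactions.append(Reaction(((d.bound_species, 1),),
                                  (("Ca", 1), (d.free_species, 1)), d.koff))
    return ReactionNetwork(species, tuple(reactions), dyes)


@dataclass(frozen=True)
class EquilibriumState:
    """Non-negative equilibrium of the competitive binding system."""

    concentrations: dict[str, float] = field(default_factory=dict)  # M per species
    totals: dict[str, float] = field(default_factory=dict)  # M per moiety

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]


def equilibrium_state(network: ReactionNetwork, totals: dict) -> EquilibriumState:
    """Solve the conservation + Kd equations for the unique equilibrium.

    ``totals`` maps moiety names (the ligand, e.g. ``"Ca"``, and dye names,
    e.g. ``"Fura"``) to total concentrations; values may be tagged strings.

    The free-ligand conservation residual

        g(x) = x + sum_d D_d * x / (Kd_d + x) - Ca_tot

    is strictly increasing in x, so the root is bracketed on [0, Ca_tot]
    and found by Brent's method to 1e-9 relative on free Ca.
    """
    tot = {k: units.molar(v) for k, v in totals.items()}
    for k, v in tot.items():
        units.require_non_negative(**{k: v})
    ca_tot = tot.get(network.ligand, 0.0)
    dye_tot = {d.name: tot.get(d.name, 0.0) for d in network.dyes}

    def bound(d: Dye, x: float) -> float:
        return dye_tot[d.name] * x / (d.kd + x) if d.kd + x > 0 else 0.0

    def g(x: float) -> float:
        return x + sum(bound(d, x) for d in network.dyes) - ca_tot

    if ca_tot == 0.0:
        x = 0.0
    else:
        try:
            x = brentq(g, 0.0, ca_tot, xtol=1e-30, rtol=1e-15, maxiter=200)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover
            raise NumericalError(f"equilibrium solve failed: {exc}", residual=g(ca_tot))

    conc = {network.ligand: x}
    bound_sum = 0.0
    for d in network.dyes:
        b = bound(d, x)
        bound_sum += b
        conc[d.bound_species] = b
        conc[d.free_species] = dye_tot[d.name] - b
    # enforce the ligand mass balance exactly
    conc[network.ligand] = ca_tot - bound_sum
    # sanity: Kd relation
    for d in network.dyes:
        if conc[d.bound_species] > 0:
            resid = abs(conc[network.ligand] * conc[d.free_species]
                        / conc[d.bound_species] - d.kd) / d.kd
            if resid > 1e-6:
                raise NumericalError(
                    f"Kd residual {resid:.2e} for {d.name} exceeds 1e-6", residual=resid
                )
    return EquilibriumState(conc, {network.ligand: ca_tot, **dye_tot})
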