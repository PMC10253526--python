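"""Species, reactions and the water-radiolysis (+O2) reaction network.

The ten evolving species are grouped into the three observable categories:
(i) primary radiolysis products (OH, H3O+, H, e_aq-), (ii) intra-track
recombination molecules (H2, H2O2, OH-) and (iii) oxygen-reaction products
(HO2, O2-, HO2-).  Dissolved molecular oxygen is a *continuum* solute: it
enters reaction rates as one uniform, fixed molarity and is never evolved
as a field.

All constants live in a bundled, editable table
(``radchemxt/data/default_network.yaml``); nothing in the engine hard-codes
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .constants import DEFAULT_HENRY_O2, K_SI_TO_INTERNAL

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ConfigurationError",
    "build_default_network",
    "load_network",
    "o2_concentration_from_po2",
    "validate_network",
    "CATEGORIES",
]

#: Category membership of the ten standard species.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "i": ("OH", "H3O+", "H", "e_aq-"),
    "ii": ("H2", "H2O2", "OH-"),
    "iii": ("HO2", "O2-", "HO2-"),
}

VALID_CATEGORIES = ("i", "ii", "iii", "other")


class ConfigurationError(ValueError):
    """Raised for invalid network/config input."""


@dataclass(frozen=True)
class Species:
    """A tracked chemical entity.

    ``diffusion_coefficient`` is in nm^2/ns (1 nm^2/ns == 1e-9 m^2/s).
    ``n_h``/``n_o`` give the elemental composition used for balance checks;
    leave them ``None`` for exotic user species to skip the check.
    """

    name: str
    diffusion_coefficient: float
    category: str = "other"
    charge: int = 0
    n_h: int | None = None
    n_o: int | None = None

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ConfigurationError(
                f"species {self.name!r}: negative diffusion coefficient"
            )
        if self.category not in VALID_CATEGORIES:
            raise ConfigurationError(
                f"species {self.name!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction with 1-2 reactants and 0-3 products.

    ``rate_constant`` is per-M per-ns for bimolecular reactions (per-ns for
    unimolecular ones).  For same-species reactions A + A -> P the stored
    constant is the *event* rate: d[A]/dt = -2 k [A]^2, d[P]/dt = +k [A]^2.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2:
            raise ConfigurationError(f"reaction {self.key}: need 1-2 reactants")
        if len(self.products) > 3:
            raise ConfigurationError(f"reaction {self.key}: more than 3 products")
        # negative rate constants are left to validate_network so that broken
        # networks can be constructed and diagnosed

    @property
    def key(self) -> str:
        """Canonical identifier, e.g. ``'OH+OH->H2O2'``."""
        return "+".join(self.reactants) + "->" + "+".join(self.products)

    @property
    def is_same_species(self) -> bool:
        return len(self.reactants) == 2 and self.reactants[0] == self.reactants[1]


@dataclass
class ReactionNetwork:
    """Ordered species, reactions and continuum-solute concentrations."""

    species: list[Species]
    reactions: list[Reaction]
    continuum_concentrations: dict[str, float] = field(default_factory=dict)
    continuum_species: dict[str, Species] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names in network")
        overlap = set(names) & set(self.continuum_species)
        if overlap:
            raise ConfigurationError(
                f"continuum solutes also listed as evolving species: {sorted(overlap)}"
            )

    # -- lookup helpers -------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        if name in self.continuum_species:
            return self.continuum_species[name]
        raise KeyError(name)

    def is_continuum(self, name: str) -> bool:
        return name in self.continuum_species

    def find_reaction(self, key: str) -> Reaction:
        for r in self.reactions:
            if r.key == key:
                return r
        raise KeyError(key)


def o2_concentration_from_po2(
    po2: float, henry_constant: float = DEFAULT_HENRY_O2
) -> float:
    """Dissolved-O2 molarity from its partial pressure via Henry's law.

    Parameters
    ----------
    po2 : fraction of 1 atm (0.21 = air-saturated).
    henry_constant : solubility in M/atm.
    """
    if po2 < 0 or po2 > 1:
        raise ConfigurationError(f"po2 must be within [0, 1], got {po2}")
    if henry_constant <= 0:
        raise ConfigurationError("henry_constant must be positive")
    return po2 * henry_constant


def _parse_species_entry(entry: dict) -> Species:
    try:
        return Species(
            name=str(entry["name"]),
            diffusion_coefficient=float(entry["D_nm2_per_ns"]),
            category=str(entry.get("category", "other")),
            charge=int(entry.get("charge", 0)),
            n_h=entry.get("n_H"),
            n_o=entry.get("n_O"),
        )
    except KeyError as exc:  # pragma: no cover - schema guard
        raise ConfigurationError(f"species entry missing field {exc}") from exc


def load_network(source: str | Path | dict) -> ReactionNetwork:
    """Load a network from a YAML/JSON-compatible file or a parsed mapping.

    Rate constants are given as ``k_per_M_per_s`` (or ``k_per_s`` for
    unimolecular steps) and converted to the internal per-ns units.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    species = [_parse_species_entry(e) for e in doc.get("species", [])]
    continuum = {}
    for e in doc.get("continuum", []):
        continuum[str(e["name"])] = Species(
            name=str(e["name"]),
            diffusion_coefficient=0.0,
            category="other",
            charge=int(e.get("charge", 0)),
            n_h=e.get("n_H"),
            n_o=e.get("n_O"),
        )
    known = {s.name for s in species} | set(continuum)
    reactions = []
    for e in doc.get("reactions", []):
        reactants = tuple(str(x) for x in e["reactants"])
        products = tuple(str(x) for x in e.get("products", []))
        for name in reactants + products:
            if name not in known:
                raise ConfigurationError(
                    f"reaction references unknown species {name!r}"
                )
        if "k_per_M_per_s" in e:
            k = float(e["k_per_M_per_s"]) * K_SI_TO_INTERNAL
        elif "k_per_s" in e:
            k = float(e["k_per_s"]) * K_SI_TO_INTERNAL
        else:
            raise ConfigurationError(
                f"reaction {'+'.join(reactants)}: missing rate constant"
            )
        reactions.append(Reaction(reactants, products, k))
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        continuum_concentrations={name: 0.0 for name in continuum},
        continuum_species=continuum,
    )


_OVERRIDE_KEYS = {"rate_constants", "diffusion_coefficients", "po2",
                  "henry_constant", "o2_molarity"}


def build_default_network(
    config_overrides: dict | None = None,
    *,
    po2: float = 0.0,
    henry_constant: float = DEFAULT_HENRY_O2,
) -> ReactionNetwork:
    """Construct the bundled 10-species network plus continuum O2.

    ``config_overrides`` may contain:

    * ``rate_constants``: mapping reaction key (e.g. ``'e_aq-+O2->O2-'``)
      to a new constant in M^-1 s^-1;
    * ``diffusion_coefficients``: mapping species name to nm^2/ns;
    * ``po2`` / ``henry_constant`` / ``o2_molarity``: oxygen model inputs
      (``o2_molarity`` wins over the Henry's-law product).
    """
    with resources.files("radchemxt.data").joinpath("default_network.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    net = load_network(doc)

    overrides = dict(config_overrides or {})
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown override keys: {sorted(unknown)}")
    po2 = overrides.get("po2", po2)
    henry_constant = overrides.get("henry_constant", henry_constant)
    o2 = overrides.get("o2_molarity")
    if o2 is None:
        o2 = o2_concentration_from_po2(po2, henry_constant)
    net.continuum_concentrations["O2"] = float(o2)

    for key, k_si in overrides.get("rate_constants", {}).items():
        try:
            old = net.find_reaction(key)
        except KeyError:
            raise ConfigurationError(f"unknown reaction key {key!r}") from None
        net.reactions[net.reactions.index(old)] = Reaction(
            old.reactants, old.products, float(k_si) * K_SI_TO_INTERNAL
        )
    for name, d in overrides.get("diffusion_coefficients", {}).items():
        found = False
        for i, s in enumerate(net.species):
            if s.name == name:
                net.species[i] = Species(s.name, float(d), s.category, s.charge,
                                         s.n_h, s.n_o)
                found = True
        if not found:
            raise ConfigurationError(f"unknown species {name!r} in D override")
    return net


def _balance_violation(reaction: Reaction, net: ReactionNetwork) -> str | None:
    """Check H/O balance modulo implied H2O on either side, plus charge.

    A reaction is balanced iff integer water counts w_r, w_p >= 0 exist with
    H_r + 2 w_r == H_p + 2 w_p and O_r + w_r == O_p + w_p, i.e.
    (H_r - H_p) == 2 (O_r - O_p).  Charge must balance exactly (water is
    neutral).
    """
    def totals(names):
        h = o = q = 0
        for n in names:
            sp = net.get_species(n)
            if sp.n_h is None or sp.n_o is None:
                return None
            h += sp.n_h
            o += sp.n_o
            q += sp.charge
        return h, o, q

    tr, tp = totals(reaction.reactants), totals(reaction.products)
    if tr is None or tp is None:
        return None  # composition unknown -> skip
    dh, do, dq = tr[0] - tp[0], tr[1] - tp[1], tr[2] - tp[2]
    if dq != 0:
        return f"{reaction.key}: charge imbalance ({dq:+d})"
    if dh != 2 * do:
        return f"{reaction.key}: H/O imbalance (dH={dh}, dO={do})"
    return None


def validate_network(net: ReactionNetwork) -> list[str]:
    """Return a list of human-readable violations (empty iff valid)."""
    violations: list[str] = []
    known = set(net.species_names) | set(net.continuum_species)
    for sp in net.species:
        if sp.diffusion_coefficient < 0 or not math.isfinite(sp.diffusion_coefficient):
            violations.append(f"species {sp.name}: bad diffusion coefficient")
    for r in net.reactions:
        if r.rate_constant < 0 or not math.isfinite(r.rate_constant):
            violations.append(f"{r.key}: bad rate constant")
        for name in r.reactants + r.products:
            if name not in known:
                violations.append(f"{r.key}: unknown species {name!r}")
                break
        else:
            n_cont = sum(net.is_continuum(n) for n in r.reactants)
            if n_cont > 1:
                violations.append(f"{r.key}: more than one continuum reactant")
            msg = _balance_violation(r, net)
            if msg:
                violations.append(msg)
    for name, c in net.continuum_concentrations.items():
        if c < 0:
            violations.append(f"continuum {name}: negative concentration")
    return violations
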