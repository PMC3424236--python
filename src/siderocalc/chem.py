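"""Chemical model declarations: components, species and cumulative formation constants.

A :class:`ChemicalModel` is the thermodynamic ground truth for every computation in
this package.  It lists the *components* (free building blocks: a metal such as
Fe3+, a ligand L, the proton H+ and optionally a protein P) and the *species*
assembled from them.  Each species carries a cumulative formation constant
``log_beta`` = log10 of

    beta_pqr = [M_p L_q H_r] / ([M]^p [L]^q [H]^r)

on the molar concentration scale.  Constants are conditional (valid at the ionic
strength and temperature of their source); no activity corrections are applied.
Hydroxide-containing species are encoded with negative proton stoichiometry, the
standard speciation-software convention, with the water autoprotolysis constant
``kw`` (default log Kw = -13.997 at 25 C, I = 0.1 M) configurable per model.

Packaged model files under ``siderocalc/data`` cover ferric hydrolysis and the
catechol, 2,3-DHBA, gentisate (2,5-DHBA), salicylate and enterobactin ligand
systems.  Their constants are reconstructions from the cited literature, not
asserted ground truth; every constant carries a mandatory provenance string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Component",
    "Species",
    "ChemicalModel",
    "Condition",
    "ModelError",
    "load_model",
    "write_model",
    "add_protein_binding",
    "packaged_model",
    "packaged_model_names",
    "parse_concentration",
]

ROLES = ("metal", "ligand", "proton", "protein")

DEFAULT_LOG_KW = -13.997

#: multipliers for concentration unit tags accepted in config files
_UNIT = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class ModelError(ValueError):
    """Raised when a model definition or condition violates the schema."""


def parse_concentration(value) -> float:
    """Convert a concentration to molar units.

    Accepts a bare number (already molar) or a string with an explicit unit
    tag, e.g. ``"20 uM"`` or ``"100nM"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    for unit, mult in sorted(_UNIT.items(), key=lambda kv: -len(kv[0])):
        if text.endswith(unit):
            return float(text[: -len(unit)].strip()) * mult
    try:
        return float(text)
    except ValueError as exc:
        raise ModelError(f"cannot parse concentration {value!r}") from exc


@dataclass(frozen=True)
class Component:
    """A free building block of the equilibrium system."""

    name: str
    charge: int = 0
    role: str = "ligand"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ModelError(f"component {self.name!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Species:
    """A complex assembled from free components.

    ``stoich`` maps component name -> signed integer coefficient; a negative
    proton count encodes hydroxide / deprotonated water.  ``log_beta`` is the
    cumulative log10 formation constant from the free components.
    """

    label: str
    stoich: Mapping[str, int]
    log_beta: float
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "stoich", dict(self.stoich))
        if not any(v != 0 for v in self.stoich.values()):
            raise ModelError(f"species {self.label!r} has all-zero stoichiometry")
        if not math.isfinite(self.log_beta):
            raise ModelError(f"species {self.label!r}: log_beta must be finite")

    def stoich_key(self) -> tuple:
        return tuple(sorted((k, v) for k, v in self.stoich.items() if v != 0))


@dataclass(frozen=True)
class ChemicalModel:
    """Components plus species with cumulative formation constants."""

    components: tuple
    species: tuple
    kw: float = DEFAULT_LOG_KW
    name: str = ""
    ionic_strength_note: str = ""
    temperature_note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "species", tuple(self.species))
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ModelError("duplicate component names")
        declared = set(names)
        seen_stoich = set()
        seen_labels = set(names)
        for sp in self.species:
            unknown = set(sp.stoich) - declared
            if unknown:
                raise ModelError(
                    f"species {sp.label!r} references undeclared component(s) "
                    f"{sorted(unknown)}"
                )
            key = sp.stoich_key()
            if key in seen_stoich:
                raise ModelError(f"duplicate species stoichiometry: {sp.label!r}")
            seen_stoich.add(key)
            if sp.label in seen_labels:
                raise ModelError(f"duplicate species label {sp.label!r}")
            seen_labels.add(sp.label)
        protons = [c for c in self.components if c.role == "proton"]
        if len(protons) > 1:
            raise ModelError("more than one proton component declared")

    # -- lookups ---------------------------------------------------------

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise ModelError(f"no component named {name!r}")

    def component_by_role(self, role: str):
        """Return the unique component with ``role``, or None if absent."""
        hits = [c for c in self.components if c.role == role]
        if not hits:
            return None
        if len(hits) > 1:
            raise ModelError(f"multiple components with role {role!r}")
        return hits[0]

    @property
    def proton(self):
        return self.component_by_role("proton")

    def species_by_label(self, label: str) -> Species:
        for sp in self.species:
            if sp.label == label:
                return sp
        raise ModelError(f"no species labelled {label!r}")

    def species_by_stoich(self, stoich: Mapping[str, int]):
        key = tuple(sorted((k, v) for k, v in stoich.items() if v != 0))
        for sp in self.species:
            if sp.stoich_key() == key:
                return sp
        return None

    def with_species(self, *extra: Species) -> "ChemicalModel":
        return replace(self, species=self.species + tuple(extra))


@dataclass(frozen=True)
class Condition:
    """Analytical totals (molar) and, optionally, a clamped pH.

    When ``ph`` is given the free proton concentration is fixed at 10**-pH and
    the proton mass balance is dropped from the solve (titration against pH).
    """

    totals: Mapping[str, float]
    ph: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "totals", {k: float(v) for k, v in self.totals.items()})
        for name, tot in self.totals.items():
            if tot < 0:
                raise ModelError(f"negative total for {name!r}: {tot}")
        if self.ph is not None and not 0.0 <= self.ph <= 14.0:
            raise ModelError(f"pH {self.ph} outside [0, 14]")


# ---------------------------------------------------------------------------
# Config I/O


def _species_from_config(entry: Mapping, declared: set) -> Species:
    try:
        label = entry["label"]
        stoich = {str(k): int(v) for k, v in entry["stoich"].items()}
    except KeyError as exc:
        raise ModelError(f"species entry missing field {exc}") from exc
    if "log_beta" not in entry:
        raise ModelError(f"species {label!r}: missing log_beta")
    unknown = set(stoich) - declared
    if unknown:
        raise ModelError(
            f"species {label!r} references undeclared component(s) {sorted(unknown)}"
        )
    return Species(
        label=label,
        stoich=stoich,
        log_beta=float(entry["log_beta"]),
        provenance=str(entry.get("provenance", "")),
    )


def load_model(source) -> ChemicalModel:
    """Load and validate a :class:`ChemicalModel` from structured config.

    ``source`` may be a mapping (already-parsed config), a path to a YAML file,
    or an open text stream.  Schema::

        name: <str>                      # optional
        kw: <float>                      # optional, default -13.997
        components: [{name, charge, role}, ...]
        species: [{label, stoich: {comp: int, ...}, log_beta, provenance}, ...]
    """
    if isinstance(source, Mapping):
        cfg = source
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    else:  # open stream
        cfg = yaml.safe_load(source)
    if not isinstance(cfg, Mapping) or "components" not in cfg:
        raise ModelError("model config must be a mapping with a 'components' list")
    comps = tuple(
        Component(
            name=str(c["name"]),
            charge=int(c.get("charge", 0)),
            role=str(c.get("role", "ligand")),
        )
        for c in cfg["components"]
    )
    declared = {c.name for c in comps}
    species = tuple(
        _species_from_config(e, declared) for e in cfg.get("species", [])
    )
    return ChemicalModel(
        components=comps,
        species=species,
        kw=float(cfg.get("kw", DEFAULT_LOG_KW)),
        name=str(cfg.get("name", "")),
        ionic_strength_note=str(cfg.get("ionic_strength_note", "")),
        temperature_note=str(cfg.get("temperature_note", "")),
    )


def model_to_config(model: ChemicalModel) -> dict:
    return {
        "name": model.name,
        "kw": model.kw,
        "ionic_strength_note": model.ionic_strength_note,
        "temperature_note": model.temperature_note,
        "components": [
            {"name": c.name, "charge": c.charge, "role": c.role}
            for c in model.components
        ],
        "species": [
            {
                "label": sp.label,
                "stoich": dict(sp.stoich),
                "log_beta": float(sp.log_beta),
                "provenance": sp.provenance,
            }
            for sp in model.species
        ],
    }


def write_model(model: ChemicalModel, path) -> None:
    """Write a model as YAML such that :func:`load_model` round-trips exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_config(model), fh, sort_keys=False)


def packaged_model_names() -> list:
    """Names of the ligand systems shipped with the package."""
    pkg = resources.files("siderocalc") / "data"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def packaged_model(name: str) -> ChemicalModel:
    """Load one of the packaged ligand systems (e.g. ``"dhba23"``, ``"gentisate"``)."""
    ref = resources.files("siderocalc") / "data" / f"{name}.yaml"
    if not ref.is_file():
        raise ModelError(
            f"no packaged model {name!r}; available: {packaged_model_names()}"
        )
    with ref.open("r", encoding="utf-8") as fh:
        return load_model(fh)


# ---------------------------------------------------------------------------
# Protein binding


def add_protein_binding(
    model: ChemicalModel,
    bound_species: Mapping[str, int],
    log_k_assoc: float,
    label: str | None = None,
    provenance: str = "",
) -> ChemicalModel:
    """Extend a model with a protein adduct from a stepwise association constant.

    ``bound_species`` is the stoichiometry of the adduct *including* the protein
    component (coefficient >= 1).  The remainder (adduct minus protein) must be
    either a declared species (its core complex) or a single free component; the
    adduct's cumulative log beta is the core's log beta plus ``log_k_assoc``,
    by additivity of cumulative constants.

    Example: adding P + FeL3 = P.FeL3 with log K = 10 to a model whose FeL3 has
    log beta = 40 yields a species with log beta = 50.
    """
    protein = model.component_by_role("protein")
    if protein is None:
        raise ModelError("model has no protein component")
    stoich = {k: int(v) for k, v in bound_species.items() if int(v) != 0}
    n_prot = stoich.get(protein.name, 0)
    if n_prot < 1:
        raise ModelError(
            f"bound species must include the protein component {protein.name!r}"
        )
    core = {k: v for k, v in stoich.items() if k != protein.name}
    if not core:
        raise ModelError("bound species contains nothing but protein")
    core_sp = model.species_by_stoich(core)
    if core_sp is not None:
        core_log_beta = core_sp.log_beta
        core_label = core_sp.label
    elif len(core) == 1 and next(iter(core.values())) == 1:
        # the core is a free component: implicit species, log beta = 0
        name = next(iter(core))
        model.component(name)  # raises if undeclared
        core_log_beta = 0.0
        core_label = name
    else:
        # no declared core: the constant is cumulative from the free components
        # (e.g. a P + 2L = PL2 candidate in a model with no L2 species)
        core_log_beta = 0.0
        core_label = "".join(
            f"{k}{v}" if v > 1 else k for k, v in sorted(core.items())
        )
    if label is None:
        label = protein.name * n_prot + core_label if n_prot > 1 else f"{protein.name}{core_label}"
    return model.with_species(
        Species(
            label=label,
            stoich=stoich,
            log_beta=core_log_beta + float(log_k_assoc),
            provenance=provenance or f"stepwise log K = {log_k_assoc} on {core_label}",
        )
    )
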