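"""Lipid nomenclature, taxonomy and species-identity parsing.

Shotgun lipidomics reports species at *sum composition* level: a class
token plus the summed carbon and double-bond counts over all radyl chains
(and the long-chain base for sphingolipids), e.g. ``PC 34:1`` or
``LPC O-18:1``.  This module owns the grammar for those names and the
class -> category taxonomy shared by every downstream stage.

Categories follow the organelle-lipidomics convention of splitting the
glycerophospholipids by chain architecture: ``diacylGPL`` (acyl-acyl),
``etherGPL`` (alkyl/alkenyl-acyl, the "O-" classes) and ``lysoGPL``
(single chain), alongside ``FA``, ``GL``, ``SL`` and ``St``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

CATEGORIES = ("FA", "GL", "diacylGPL", "etherGPL", "lysoGPL", "SL", "St")

#: organelle-marker roles understood by the purity metrics
MARKER_LYSOSOME = "lysosome"
MARKER_MITOCHONDRION = "mitochondrion"


class UnknownClassError(KeyError):
    """A species name used a class token absent from the taxonomy."""


class MalformedNameError(ValueError):
    """A species name does not follow ``<CLASS>[ O-]<C>:<D>[;h]``."""


@dataclass(frozen=True)
class LipidSpecies:
    """A sum-composition lipid species identity.

    ``carbons`` and ``double_bonds`` are summed over all chains and the
    long-chain base; ``hydroxyls`` records an optional ``;n`` suffix that
    is carried along but ignored in carbon/double-bond arithmetic.
    """

    name: str
    lipid_class: str
    category: str
    carbons: int
    double_bonds: int
    ether: bool
    hydroxyls: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise MalformedNameError(f"{self.name}: carbons must be >= 1")
        if not 0 <= self.double_bonds <= self.carbons:
            raise MalformedNameError(
                f"{self.name}: double bonds must lie in [0, carbons]"
            )


@dataclass(frozen=True)
class ClassInfo:
    category: str
    chains: int
    ether: bool
    standard_group: str
    marker: str | None = None
    fixed_composition: tuple[int, int] | None = None


@dataclass
class Taxonomy:
    """Mapping lipid class -> (category, chains, ether, standard group)."""

    entries: dict[str, ClassInfo]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, info in self.entries.items():
            if info.category not in CATEGORIES:
                raise ValueError(
                    f"class {cls!r}: unknown category {info.category!r}"
                )
        for alias, target in self.aliases.items():
            if target not in self.entries:
                raise ValueError(f"alias {alias!r} points to unknown class {target!r}")

    # -- lookups ---------------------------------------------------------
    def resolve(self, lipid_class: str) -> str:
        """Canonical class key, resolving aliases; raises on unknown token."""
        if lipid_class in self.entries:
            return lipid_class
        if lipid_class in self.aliases:
            return self.aliases[lipid_class]
        raise UnknownClassError(f"unknown lipid class token: {lipid_class!r}")

    def info(self, lipid_class: str) -> ClassInfo:
        return self.entries[self.resolve(lipid_class)]

    def category_of(self, lipid_class: str) -> str:
        return self.info(lipid_class).category

    def standard_group_of(self, lipid_class: str) -> str:
        return self.info(lipid_class).standard_group

    @property
    def classes(self) -> list[str]:
        return list(self.entries)

    @property
    def standard_groups(self) -> list[str]:
        return sorted({i.standard_group for i in self.entries.values()})

    def marker_classes(self, role: str | None = None) -> list[str]:
        return [
            c
            for c, i in self.entries.items()
            if i.marker is not None and (role is None or i.marker == role)
        ]

    # -- parsing ---------------------------------------------------------
    _CHAIN_RE = re.compile(r"^(O-)?(\d+):(\d+)(?:;(\d+))?$")

    def parse_species(self, name: str) -> LipidSpecies:
        """Parse a sum-composition species name.

        Grammar: ``<CLASS> [O-]<carbons>:<double_bonds>[;<hydroxyls>]``
        where the ``O-`` prefix of the chain descriptor is part of the
        class identity (ether-linked classes).  Classes with a fixed
        composition (cholesterol) are written bare, e.g. ``Chol``.
        """
        name = name.strip()
        head, _, tail = name.rpartition(" ")
        if not head:
            # bare name: only valid for fixed-composition classes
            cls = self.resolve(name)
            info = self.entries[cls]
            if info.fixed_composition is None:
                raise MalformedNameError(
                    f"{name!r}: missing chain descriptor for class {cls!r}"
                )
            c, d = info.fixed_composition
            return LipidSpecies(name, cls, info.category, c, d, info.ether)
        m = self._CHAIN_RE.match(tail)
        if m is None:
            raise MalformedNameError(
                f"{name!r}: chain descriptor {tail!r} does not match "
                "'[O-]<carbons>:<double_bonds>[;<hydroxyls>]'"
            )
        ether_tag, carbons, dbonds, hydroxyls = m.groups()
        cls_token = head + " O-" if ether_tag else head
        cls = self.resolve(cls_token)
        info = self.entries[cls]
        if info.ether != bool(ether_tag):
            raise MalformedNameError(
                f"{name!r}: ether designation inconsistent with class {cls!r}"
            )
        return LipidSpecies(
            name=self.format_name(cls, int(carbons), int(dbonds), int(hydroxyls or 0)),
            lipid_class=cls,
            category=info.category,
            carbons=int(carbons),
            double_bonds=int(dbonds),
            ether=info.ether,
            hydroxyls=int(hydroxyls or 0),
        )

    def format_name(
        self, lipid_class: str, carbons: int | None = None,
        double_bonds: int | None = None, hydroxyls: int = 0,
    ) -> str:
        """Canonical name for a species of this taxonomy."""
        cls = self.resolve(lipid_class)
        info = self.entries[cls]
        if info.fixed_composition is not None:
            return cls
        suffix = f";{hydroxyls}" if hydroxyls else ""
        if info.ether:
            base = cls[: -len(" O-")]
            return f"{base} O-{carbons}:{double_bonds}{suffix}"
        return f"{cls} {carbons}:{double_bonds}{suffix}"

    def format(self, species: LipidSpecies) -> str:
        info = self.entries[self.resolve(species.lipid_class)]
        if info.fixed_composition is not None:
            return species.lipid_class
        return self.format_name(
            species.lipid_class, species.carbons, species.double_bonds,
            species.hydroxyls,
        )

    # -- serialisation ---------------------------------------------------
    @classmethod
    def from_mapping(cls, data: dict) -> "Taxonomy":
        entries = {}
        for key, raw in data["classes"].items():
            fixed = raw.get("fixed_composition")
            if fixed is not None:
                c, d = str(fixed).split(":")
                fixed = (int(c), int(d))
            entries[str(key)] = ClassInfo(
                category=raw["category"],
                chains=int(raw["chains"]),
                ether=bool(raw.get("ether", False)),
                standard_group=str(raw.get("standard_group", key)),
                marker=raw.get("marker"),
                fixed_composition=fixed,
            )
        aliases = {str(k): str(v) for k, v in (data.get("aliases") or {}).items()}
        return cls(entries=entries, aliases=aliases)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Taxonomy":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Taxonomy":
        """The packaged 28-class taxonomy."""
        ref = resources.files("lysopipe.data").joinpath("taxonomy.yaml")
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


def parse_species(name: str, taxonomy: Taxonomy | None = None) -> LipidSpecies:
    """Module-level convenience: parse against the default taxonomy."""
    return (taxonomy or Taxonomy.default()).parse_species(name)


def category_of(lipid_class: str, taxonomy: Taxonomy | None = None) -> str:
    """Working category (one of seven) for a lipid class."""
    return (taxonomy or Taxonomy.default()).category_of(lipid_class)
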