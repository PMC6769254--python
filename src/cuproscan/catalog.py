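"""Signature catalog: copper-related protein types and their matching rules.

The catalog is data, not code. Each entry names one protein type, the Table-style
section it belongs to (cuproprotein / homeostasis / chaperone), its category
memberships (dual-membership types such as multicopper oxidases carry two), the
matching mode the classifier applies, the Pfam domain identifiers involved and,
for architecture-defined types, the domain-organization patterns.

Pattern notation: a ``same_protein`` pattern lists domains that must co-occur,
ordered N-terminus to C-terminus, on a single polypeptide; a ``split_complex``
pattern lists domains carried by distinct polypeptides encoded within a short
locus window (multi-subunit enzymes such as two-chain multicopper oxidases or
cytochrome oxidase complexes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

CATEGORIES = ("cuproprotein", "homeostasis", "chaperone")
MATCH_MODES = (
    "single_domain",
    "architecture",
    "complex",
    "transporter_disambiguation",
    "csp_cytoplasmic",
    "csp_extracytoplasmic",
)


class CatalogError(ValueError):
    """Raised when a catalog file violates the schema or its invariants."""


@dataclass(frozen=True)
class DomainId:
    """A profile-HMM domain identity: Pfam name plus accession."""

    name: str
    accession: str


@dataclass(frozen=True)
class ArchPattern:
    """One domain-organization pattern.

    elements are domain names; scope is 'same_protein' or 'split_complex'.
    Longer patterns are more specific and are evaluated first.
    """

    elements: tuple[str, ...]
    scope: str

    def __post_init__(self) -> None:
        if not self.elements:
            raise CatalogError("pattern with no elements")
        if self.scope not in ("same_protein", "split_complex"):
            raise CatalogError(f"unknown pattern scope {self.scope!r}")
        if self.scope == "split_complex" and len(self.elements) < 2:
            raise CatalogError("split_complex pattern needs >= 2 elements")

    @property
    def specificity_rank(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class SignatureType:
    """One catalog entry: a copper-related protein type and its match rule."""

    type_name: str
    section: str
    categories: frozenset[str]
    match_mode: str
    domain_ids: tuple[DomainId, ...]
    patterns: tuple[ArchPattern, ...] = ()
    params: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.section not in CATEGORIES:
            raise CatalogError(f"{self.type_name}: unknown section {self.section!r}")
        if self.match_mode not in MATCH_MODES:
            raise CatalogError(
                f"{self.type_name}: unknown match_mode {self.match_mode!r}"
            )
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise CatalogError(f"{self.type_name}: unknown categories {sorted(bad)}")
        if self.section not in self.categories:
            raise CatalogError(
                f"{self.type_name}: categories {sorted(self.categories)} do not "
                f"contain section {self.section!r}"
            )
        if self.match_mode not in ("architecture", "complex") and self.patterns:
            raise CatalogError(f"{self.type_name}: patterns on non-architecture type")

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.domain_ids)

    def matches_domain(self, name_or_accession: str) -> bool:
        return any(
            name_or_accession in (d.name, d.accession) for d in self.domain_ids
        )


class Catalog:
    """A validated, ordered collection of :class:`SignatureType` entries."""

    def __init__(self, types: Iterable[SignatureType], version: str = "1.0"):
        self.types: tuple[SignatureType, ...] = tuple(types)
        self.version = version
        names = [t.type_name for t in self.types]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise CatalogError(f"duplicate type_name(s): {sorted(dupes)}")
        self._by_name = {t.type_name: t for t in self.types}

    def __len__(self) -> int:
        return len(self.types)

    def __iter__(self):
        return iter(self.types)

    def __contains__(self, type_name: str) -> bool:
        return type_name in self._by_name

    def __getitem__(self, type_name: str) -> SignatureType:
        try:
            return self._by_name[type_name]
        except KeyError:
            raise CatalogError(f"unknown type_name {type_name!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, Catalog) and self.types == other.types

    @property
    def type_names(self) -> tuple[str, ...]:
        return tuple(t.type_name for t in self.types)

    def patterns_for(self, type_name: str) -> tuple[ArchPattern, ...]:
        """Domain-organization patterns of a type (empty for single-domain types)."""
        return self[type_name].patterns

    def types_in_category(self, category: str) -> tuple[SignatureType, ...]:
        """All types whose category memberships include *category* (dual counted)."""
        if category not in CATEGORIES:
            raise CatalogError(f"unknown category {category!r}")
        return tuple(t for t in self.types if category in t.categories)

    def types_in_section(self, section: str) -> tuple[SignatureType, ...]:
        if section not in CATEGORIES:
            raise CatalogError(f"unknown section {section!r}")
        return tuple(t for t in self.types if t.section == section)

    def types_with_mode(self, match_mode: str) -> tuple[SignatureType, ...]:
        return tuple(t for t in self.types if t.match_mode == match_mode)

    def all_domain_names(self) -> frozenset[str]:
        return frozenset(d.name for t in self.types for d in t.domain_ids)

    def all_domain_ids(self) -> frozenset[str]:
        return frozenset(
            x for t in self.types for d in t.domain_ids for x in (d.name, d.accession)
        )

    def types_for_domain(self, name_or_accession: str) -> tuple[SignatureType, ...]:
        return tuple(t for t in self.types if t.matches_domain(name_or_accession))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "types": [
                {
                    "type_name": t.type_name,
                    "section": t.section,
                    "categories": sorted(t.categories),
                    "match_mode": t.match_mode,
                    "domain_ids": [
                        {"name": d.name, "accession": d.accession}
                        for d in t.domain_ids
                    ],
                    "patterns": [
                        {"elements": list(p.elements), "scope": p.scope}
                        for p in t.patterns
                    ],
                    "params": dict(t.params),
                }
                for t in self.types
            ],
        }

    def serialize(self, path: Optional[Union[str, Path]] = None) -> str:
        """Canonical YAML serialization; stable bytes for a given catalog."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _parse_type(raw: Mapping) -> SignatureType:
    missing = {"type_name", "section", "categories", "match_mode"} - set(raw)
    if missing:
        raise CatalogError(f"catalog entry missing fields {sorted(missing)}: {raw!r}")
    domain_ids = tuple(
        DomainId(name=str(d["name"]), accession=str(d.get("accession", d["name"])))
        for d in raw.get("domain_ids", [])
    )
    patterns = tuple(
        ArchPattern(elements=tuple(p["elements"]), scope=p["scope"])
        for p in raw.get("patterns") or []
    )
    return SignatureType(
        type_name=str(raw["type_name"]),
        section=str(raw["section"]),
        categories=frozenset(raw["categories"]),
        match_mode=str(raw["match_mode"]),
        domain_ids=domain_ids,
        patterns=patterns,
        params={str(k): str(v) for k, v in (raw.get("params") or {}).items()},
    )


def load_catalog(path: Optional[Union[str, Path, io.TextIOBase]] = None) -> Catalog:
    """Load and validate a signature catalog.

    With no argument, loads the default catalog shipped with the package
    (31 copper-related protein types). Validation failures raise
    :class:`CatalogError`.
    """
    if path is None:
        text = files("cuproscan.data").joinpath("catalog.yaml").read_text()
    elif isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping) or "types" not in raw:
        raise CatalogError("catalog file must be a mapping with a 'types' list")
    types = [_parse_type(t) for t in raw["types"]]
    return Catalog(types, version=str(raw.get("version", "1.0")))
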