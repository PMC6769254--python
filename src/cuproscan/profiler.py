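"""Per-species copper-related proteome (CuRP) statistics.

A species profile is the 31-vector of type counts plus lifestyle and proteome
size. CuRP statistics express the copper-related proteome as a percentage of
the whole proteome and split it into functional-category shares. Category
accounting is "dual" by default: a dual-membership type (multicopper oxidases:
cuproprotein + homeostasis; cytoplasmic copper-storage proteins: homeostasis +
chaperone) contributes fully to both of its categories, so the three shares
may sum above 100%. An alternative "exclusive" accounting assigns each type
only to its section.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .annotation_io import SpeciesMeta
from .catalog import Catalog
from .classifier import TypeCall

ACCOUNTING_MODES = ("dual", "exclusive")


@dataclass
class SpeciesProfile:
    """Counts of each copper-related type in one species."""

    species_id: str
    lifestyle: str
    proteome_size: int
    counts: dict[str, int] = field(default_factory=dict)

    def count(self, type_name: str) -> int:
        return self.counts.get(type_name, 0)


@dataclass(frozen=True)
class CuRPStats:
    """Copper-related proteome summary for one species.

    Shares are percentages of the copper-related proteome; with dual
    accounting they may sum above 100.
    """

    species_id: str
    curp_count: int
    curp_percent: float
    share_cuproprotein: float
    share_homeostasis: float
    share_chaperone: float


def build_profile(
    calls: Sequence[TypeCall],
    meta: SpeciesMeta,
    catalog: Catalog,
    species_id: Optional[str] = None,
    per_subunit: bool = False,
) -> SpeciesProfile:
    """Aggregate type calls into a species profile.

    Complexes count once each (``per_subunit=True`` counts their members
    instead). Calls for types absent from the catalog are an error.
    """
    counts = {t: 0 for t in catalog.type_names}
    for call in calls:
        if call.type_name not in counts:
            raise ValueError(f"call for unknown type {call.type_name!r}")
        counts[call.type_name] += (
            len(call.member_protein_ids) if per_subunit else 1
        )
    return SpeciesProfile(
        species_id=species_id or meta.species_id,
        lifestyle=meta.lifestyle,
        proteome_size=meta.proteome_size,
        counts=counts,
    )


def curp_stats(
    profile: SpeciesProfile, catalog: Catalog, accounting: str = "dual"
) -> CuRPStats:
    """CuRP size and functional-category shares for one species.

    curp_percent = 100 * (number of copper-related proteins and complexes) /
    proteome size. Each share = 100 * (counts of types belonging to that
    category) / curp_count; all shares are defined as 0 when the species has
    no copper-related proteins.
    """
    if accounting not in ACCOUNTING_MODES:
        raise ValueError(f"unknown accounting mode {accounting!r}")
    if profile.proteome_size <= 0:
        raise ValueError(f"{profile.species_id}: proteome_size must be positive")
    curp_count = sum(profile.counts.values())
    curp_percent = 100.0 * curp_count / profile.proteome_size

    def share(category: str) -> float:
        if curp_count == 0:
            return 0.0
        if accounting == "dual":
            members = catalog.types_in_category(category)
        else:
            members = catalog.types_in_section(category)
        total = sum(profile.count(t.type_name) for t in members)
        return 100.0 * total / curp_count

    return CuRPStats(
        species_id=profile.species_id,
        curp_count=curp_count,
        curp_percent=curp_percent,
        share_cuproprotein=share("cuproprotein"),
        share_homeostasis=share("homeostasis"),
        share_chaperone=share("chaperone"),
    )


def lifestyle_medians(
    profiles: Sequence[SpeciesProfile],
    stat: str,
    catalog: Catalog,
    accounting: str = "dual",
) -> dict[str, float]:
    """Median of a per-species statistic within each lifestyle group.

    ``stat`` is one of curp_percent / curp_count / share_cuproprotein /
    share_homeostasis / share_chaperone, or a catalog type name (per-type
    copy number). Median is the standard middle value (mean of the two middle
    values for even group sizes); lifestyles with no species are omitted.
    """
    stat_fields = {
        "curp_percent",
        "curp_count",
        "share_cuproprotein",
        "share_homeostasis",
        "share_chaperone",
    }
    values: dict[str, list[float]] = {}
    for p in profiles:
        if stat in stat_fields:
            v = float(getattr(curp_stats(p, catalog, accounting), stat))
        elif stat in catalog:
            v = float(p.count(stat))
        else:
            raise ValueError(f"unknown statistic {stat!r}")
        values.setdefault(p.lifestyle, []).append(v)
    return {ls: statistics.median(vs) for ls, vs in values.items()}


def count_species_with_type(
    profiles: Sequence[SpeciesProfile],
    type_name: str,
    catalog: Catalog,
    min_count: int = 1,
) -> int:
    """Number of species carrying at least ``min_count`` copies of a type."""
    if type_name not in catalog:
        raise ValueError(f"unknown type {type_name!r}")
    return sum(1 for p in profiles if p.count(type_name) >= min_count)


def stats_table(
    profiles: Sequence[SpeciesProfile], catalog: Catalog, accounting: str = "dual"
):
    """Per-species CuRP statistics as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for p in profiles:
        s = curp_stats(p, catalog, accounting)
        rows.append(
            {
                "species_id": p.species_id,
                "lifestyle": p.lifestyle,
                "proteome_size": p.proteome_size,
                "curp_count": s.curp_count,
                "curp_percent": round(s.curp_percent, 2),
                "share_cuproprotein": round(s.share_cuproprotein, 2),
                "share_homeostasis": round(s.share_homeostasis, 2),
                "share_chaperone": round(s.share_chaperone, 2),
            }
        )
    return pd.DataFrame(rows)
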