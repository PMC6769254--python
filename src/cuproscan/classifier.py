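"""Assign proteins and protein complexes to copper-related types.

Each protein of a species contributes to at most one type call
(single-assignment). Evaluation order, fixed for determinism:

1. multi-subunit complexes (cytochrome oxidase complexes first — the FixO
   subunit defines cbb3-type oxidases, then COX1+COX2 pairs resolved by
   TIGRFAM-style flags — then split-subunit architecture patterns);
2. per-protein domain architectures, longest pattern first;
3. transporter disambiguation of P-type ATPases and RND transporters against
   a labeled transporter-reference hit table;
4. copper-storage-protein (CSP) compartment assignment via twin-arginine
   (Tat) signal detection;
5. single-domain types, in catalog order.

Overlapping hits of the same domain on one protein are collapsed to a greedy
non-overlapping set by descending bit score before matching, so repeated or
fragmented reporting of one domain cannot double-count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .annotation_io import DomainHit, ProteinRecord, SimilarityHit
from .catalog import ArchPattern, Catalog, SignatureType

DEFAULT_TAT_MOTIF = r"[ST]RR.[FGAVML][LITMVF]"
DEFAULT_TAT_SEARCH_LEN = 35
DEFAULT_COMPLEX_WINDOW = 5
# blast prints E-value underflow as 0.0; "E value 0.0" selection is
# implemented as evalue <= this bound
DEFAULT_EVALUE_ZERO = 1e-180

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class TypeCall:
    """One classified copper-related protein or complex."""

    type_name: str
    member_protein_ids: tuple[str, ...]
    evidence: str  # single_domain | architecture | complex | similarity | csp_motif
    details: str = ""

    def __post_init__(self) -> None:
        if not self.member_protein_ids:
            raise ValueError("TypeCall with no members")
        if len(self.member_protein_ids) > 1 and self.evidence != "complex":
            raise ValueError("multi-member call requires complex evidence")


@dataclass(frozen=True)
class TransporterDecision:
    protein_id: str
    candidate_family: str  # P_type_ATPase | RND
    verdict: str  # copper_ATPase | RND_HME | excluded_biogenesis_ATPase | unclassified
    best_hit: Optional[SimilarityHit] = None

    def __post_init__(self) -> None:
        if self.verdict == "copper_ATPase" and self.candidate_family != "P_type_ATPase":
            raise ValueError("copper_ATPase verdict requires P_type_ATPase family")
        if self.verdict == "RND_HME" and self.candidate_family != "RND":
            raise ValueError("RND_HME verdict requires RND family")


@dataclass
class ClassifyOptions:
    """Tunable classification parameters."""

    complex_window: int = DEFAULT_COMPLEX_WINDOW
    e_max: float = DEFAULT_EVALUE_ZERO
    tat_motif: str = DEFAULT_TAT_MOTIF
    tat_search_len: int = DEFAULT_TAT_SEARCH_LEN


# ---------------------------------------------------------------------------
# hit hygiene

def collapse_hits(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy non-overlapping subset per domain name, best bit score first.

    Hits of *different* domains may overlap (e.g. nested annotations); only
    same-domain overlaps are collapsed.
    """
    kept: list[DomainHit] = []
    by_domain: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_domain.setdefault(h.domain_name, []).append(h)
    for name in by_domain:
        chosen: list[DomainHit] = []
        for h in sorted(
            by_domain[name], key=lambda h: (-h.bit_score, h.ali_start, h.ali_end)
        ):
            if all(
                h.ali_end < c.ali_start or h.ali_start > c.ali_end for c in chosen
            ):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.ali_start, h.ali_end, h.domain_name))
    return kept


def _retained_domain_string(record: ProteinRecord) -> tuple[str, ...]:
    return tuple(h.domain_name for h in collapse_hits(record.domains))


# ---------------------------------------------------------------------------
# per-protein matchers

def match_single_domain(
    record: ProteinRecord, sig: SignatureType
) -> Optional[TypeCall]:
    """One call per protein iff any retained hit matches the signature's domains."""
    if sig.match_mode != "single_domain":
        raise ValueError(f"{sig.type_name} is not a single_domain signature")
    for h in collapse_hits(record.domains):
        if sig.matches_domain(h.domain_name) or sig.matches_domain(h.domain_accession):
            return TypeCall(
                type_name=sig.type_name,
                member_protein_ids=(record.protein_id,),
                evidence="single_domain",
                details=f"domain={h.domain_name}",
            )
    return None


def _is_subsequence(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    it = iter(haystack)
    return all(elem in it for elem in needle)


def match_architecture(
    record: ProteinRecord, patterns: Sequence[ArchPattern]
) -> Optional[ArchPattern]:
    """Longest same-protein pattern whose elements appear as an ordered
    (not necessarily contiguous) subsequence of the protein's domain string."""
    if any(p.scope != "same_protein" for p in patterns):
        raise ValueError("match_architecture takes same_protein patterns only")
    dstring = _retained_domain_string(record)
    best: Optional[ArchPattern] = None
    for p in patterns:
        if _is_subsequence(p.elements, dstring):
            if best is None or p.specificity_rank > best.specificity_rank:
                best = p
    return best


# ---------------------------------------------------------------------------
# complexes

def _carries(record: ProteinRecord, domain: str) -> bool:
    return domain in _retained_domain_string(record)


def _matches_any_same_protein_pattern(
    record: ProteinRecord, catalog: Catalog
) -> bool:
    for sig in catalog.types_with_mode("architecture"):
        same = [p for p in sig.patterns if p.scope == "same_protein"]
        if same and match_architecture(record, same) is not None:
            return True
    return False


def assemble_complexes(
    records: Sequence[ProteinRecord],
    catalog: Catalog,
    window: int = DEFAULT_COMPLEX_WINDOW,
    tigrfam_flags: Optional[Mapping[str, str]] = None,
    override: Optional[Mapping[str, str]] = None,
    audit: Optional[list] = None,
) -> tuple[list[TypeCall], set[str]]:
    """Group subunits of multi-protein complexes within a locus window.

    Greedy left-to-right by locus: each anchor subunit pairs with the nearest
    unconsumed partner within ``window`` loci; each protein joins at most one
    complex. Returns the calls and the set of consumed protein ids (including
    subunits of complexes excluded from the profile, e.g. QoxB-flagged pairs
    overridden as nitric oxide reductases).
    """
    if window < 1:
        raise ValueError(f"complex window must be >= 1, got {window}")
    tigrfam_flags = tigrfam_flags or {}
    override = override or {}
    audit = audit if audit is not None else []

    records = sorted(records, key=lambda r: (r.locus_index, r.protein_id))
    consumed: set[str] = set()
    calls: list[TypeCall] = []

    def pair_up(anchor_dom: str, partner_dom: str, skip_self_arch: bool):
        """Yield (anchor, partner) pairs, greedily, nearest partner first."""
        pairs = []
        for rec in records:
            if rec.protein_id in consumed or not _carries(rec, anchor_dom):
                continue
            if skip_self_arch and _matches_any_same_protein_pattern(rec, catalog):
                continue
            best = None
            for other in records:
                if other.protein_id in consumed or other.protein_id == rec.protein_id:
                    continue
                if not _carries(other, partner_dom):
                    continue
                if skip_self_arch and _matches_any_same_protein_pattern(other, catalog):
                    continue
                gap = abs(other.locus_index - rec.locus_index)
                if gap > window:
                    continue
                key = (gap, other.locus_index, other.protein_id)
                if best is None or key < best[0]:
                    best = (key, other)
            if best is not None:
                consumed.add(rec.protein_id)
                consumed.add(best[1].protein_id)
                pairs.append((rec, best[1]))
        return pairs

    # 1. cbb3-type cytochrome C oxidases: COX1 + FixO (FixO is diagnostic)
    for a, b in pair_up("COX1", "FixO", skip_self_arch=False):
        calls.append(
            TypeCall(
                "Cyto_C_cbb3",
                (a.protein_id, b.protein_id),
                "complex",
                f"loci={a.locus_index},{b.locus_index}",
            )
        )

    # 2. COX1 + COX2 pairs -> bo / aa3 / unresolved, via flags and override
    for a, b in pair_up("COX1", "COX2", skip_self_arch=False):
        name = resolve_complex_identity(
            (a.protein_id, b.protein_id), tigrfam_flags, override
        )
        if name in ("Cyto_bo", "Cyto_C_aa3"):
            calls.append(
                TypeCall(
                    name,
                    (a.protein_id, b.protein_id),
                    "complex",
                    f"loci={a.locus_index},{b.locus_index}",
                )
            )
        else:
            audit.append(
                {
                    "stage": "complex",
                    "protein_id": ",".join((a.protein_id, b.protein_id)),
                    "outcome": name,
                    "reason": "COX1+COX2 pair not assigned to the profile",
                }
            )

    # 3. split-subunit architecture patterns (catalog order: nitrite
    #    reductase before multicopper oxidase). Proteins that satisfy a
    #    same-protein pattern on their own are not available as subunits.
    for sig in catalog.types_with_mode("architecture"):
        for pat in sig.patterns:
            if pat.scope != "split_complex":
                continue
            anchor, partner = pat.elements[0], pat.elements[1]
            for a, b in pair_up(anchor, partner, skip_self_arch=True):
                calls.append(
                    TypeCall(
                        sig.type_name,
                        (a.protein_id, b.protein_id),
                        "complex",
                        f"pattern={'//'.join(pat.elements)};"
                        f"loci={a.locus_index},{b.locus_index}",
                    )
                )
    return calls, consumed


def resolve_complex_identity(
    complex_members: Sequence[str],
    tigrfam_flags: Optional[Mapping[str, str]] = None,
    override: Optional[Mapping[str, str]] = None,
) -> str:
    """Identify a COX1/COX2 complex from per-protein flags.

    CyoB-flagged subunit -> cytochrome bo ubiquinol oxidase; QoxB-flagged ->
    aa3-type cytochrome C oxidase, unless the override labels a subunit as a
    nitric oxide reductase (these share the QoxB signature and are excluded).
    No flag -> 'unresolved_COX' (audit channel, not part of the 31-type
    profile). Contradictory flags on one complex are an error.
    """
    tigrfam_flags = tigrfam_flags or {}
    override = override or {}
    flags = {tigrfam_flags[m] for m in complex_members if m in tigrfam_flags}
    unknown = flags - {"CyoB", "QoxB"}
    if unknown:
        raise ValueError(f"unknown TIGRFAM flag(s) {sorted(unknown)}")
    if flags == {"CyoB", "QoxB"}:
        raise ValueError(
            f"contradictory CyoB and QoxB flags on complex {list(complex_members)}"
        )
    if "CyoB" in flags:
        return "Cyto_bo"
    if "QoxB" in flags:
        if any(override.get(m) == "NOR" for m in complex_members):
            return "excluded_NOR"
        return "Cyto_C_aa3"
    return "unresolved_COX"


# ---------------------------------------------------------------------------
# transporters

def disambiguate_transporter(
    record: ProteinRecord,
    family: str,
    hits: Sequence[SimilarityHit],
    e_max: float = DEFAULT_EVALUE_ZERO,
) -> TransporterDecision:
    """Decide whether a P-type ATPase / RND transporter is copper-specific.

    Only hits at effectively zero E-value (``evalue <= e_max``) qualify.
    P-type ATPases: copper-resistance verdict requires a qualifying hit in
    the copper-resistance reference category ("3.A.3.5") with no
    better-scoring qualifying hit in the cuproenzyme-biogenesis category
    ("3.A.3.27", excluded from the analysis). RND transporters require the
    heavy-metal-efflux category ("2.A.6.1").
    """
    if family not in ("P_type_ATPase", "RND"):
        raise ValueError(f"unknown transporter family {family!r}")
    qualifying = sorted(
        (h for h in hits if h.evalue <= e_max),
        key=lambda h: (-h.bit_score, h.evalue, h.subject_id),
    )
    if not qualifying:
        return TransporterDecision(record.protein_id, family, "unclassified")
    if family == "RND":
        best = qualifying[0]
        if best.subject_label == "2.A.6.1":
            return TransporterDecision(record.protein_id, family, "RND_HME", best)
        return TransporterDecision(record.protein_id, family, "unclassified", best)
    # P-type ATPase
    copper = [h for h in qualifying if h.subject_label == "3.A.3.5"]
    biogenesis = [h for h in qualifying if h.subject_label == "3.A.3.27"]
    if copper and (not biogenesis or biogenesis[0].bit_score <= copper[0].bit_score):
        return TransporterDecision(
            record.protein_id, family, "copper_ATPase", copper[0]
        )
    if biogenesis:
        return TransporterDecision(
            record.protein_id, family, "excluded_biogenesis_ATPase", biogenesis[0]
        )
    return TransporterDecision(record.protein_id, family, "unclassified", qualifying[0])


# ---------------------------------------------------------------------------
# CSP compartment

def detect_tat_signal(
    sequence: str,
    search_len: int = DEFAULT_TAT_SEARCH_LEN,
    motif: str = DEFAULT_TAT_MOTIF,
) -> bool:
    """Twin-arginine export signal detection on the N-terminal window.

    True iff the first ``search_len`` residues contain the twin-arginine
    consensus motif (default ``[ST]RR.[FGAVML][LITMVF]``), a documented
    sequence-motif surrogate for dedicated Tat-signal predictors.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return re.search(motif, seq[:search_len]) is not None


def classify_csp(
    record: ProteinRecord,
    sequence: Optional[str] = None,
    options: Optional[ClassifyOptions] = None,
    audit: Optional[list] = None,
) -> TypeCall:
    """Split a copper-storage protein by compartment.

    Tat-positive -> extracytoplasmic (Csp1/2_Ecsp); otherwise cytoplasmic
    (Csp3_Ccsp). A missing sequence falls back to cytoplasmic with an audit
    warning.
    """
    options = options or ClassifyOptions()
    sequence = sequence if sequence is not None else record.sequence
    if sequence is None:
        if audit is not None:
            audit.append(
                {
                    "stage": "csp",
                    "protein_id": record.protein_id,
                    "outcome": "Csp3_Ccsp",
                    "reason": "no sequence available; cytoplasmic by fallback",
                }
            )
        return TypeCall(
            "Csp3_Ccsp", (record.protein_id,), "csp_motif", "no-sequence fallback"
        )
    tat = detect_tat_signal(sequence, options.tat_search_len, options.tat_motif)
    name = "Csp1/2_Ecsp" if tat else "Csp3_Ccsp"
    return TypeCall(
        name, (record.protein_id,), "csp_motif", f"tat={'+' if tat else '-'}"
    )


# ---------------------------------------------------------------------------
# species-level pipeline

def classify_species(
    records: Sequence[ProteinRecord],
    catalog: Catalog,
    similarity_hits: Optional[Iterable[SimilarityHit]] = None,
    tigrfam_flags: Optional[Mapping[str, str]] = None,
    override: Optional[Mapping[str, str]] = None,
    options: Optional[ClassifyOptions] = None,
    audit: Optional[list] = None,
) -> list[TypeCall]:
    """Classify all proteins of one species into copper-related type calls.

    Deterministic and invariant to input order; each protein contributes to
    at most one call. See module docstring for the stage order.
    """
    options = options or ClassifyOptions()
    audit = audit if audit is not None else []
    if not records:
        return []
    species = {r.species_id for r in records}
    if len(species) > 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")

    records = sorted(records, key=lambda r: (r.locus_index, r.protein_id))
    sim_by_query: dict[str, list[SimilarityHit]] = {}
    for h in similarity_hits or []:
        sim_by_query.setdefault(h.query_id, []).append(h)

    calls: list[TypeCall] = []

    # stage 1: complexes
    complex_calls, consumed = assemble_complexes(
        records, catalog, options.complex_window, tigrfam_flags, override, audit
    )
    calls.extend(complex_calls)

    def available():
        return [r for r in records if r.protein_id not in consumed]

    # stage 2: per-protein architectures, longest pattern wins across types;
    # ties broken by catalog order
    arch_sigs = catalog.types_with_mode("architecture")
    for rec in available():
        best_sig, best_pat = None, None
        for sig in arch_sigs:
            same = [p for p in sig.patterns if p.scope == "same_protein"]
            if not same:
                continue
            pat = match_architecture(rec, same)
            if pat is None:
                continue
            if best_pat is None or pat.specificity_rank > best_pat.specificity_rank:
                best_sig, best_pat = sig, pat
        if best_sig is not None:
            consumed.add(rec.protein_id)
            calls.append(
                TypeCall(
                    best_sig.type_name,
                    (rec.protein_id,),
                    "architecture",
                    f"pattern={'/'.join(best_pat.elements)}",
                )
            )

    # stage 3: transporter disambiguation (candidates consumed whatever the
    # verdict, so accessory domains are not re-counted downstream)
    for sig in catalog.types_with_mode("transporter_disambiguation"):
        family = sig.params.get("family", "P_type_ATPase")
        for rec in available():
            if not any(_carries(rec, d.name) for d in sig.domain_ids):
                continue
            decision = disambiguate_transporter(
                rec, family, sim_by_query.get(rec.protein_id, []), options.e_max
            )
            consumed.add(rec.protein_id)
            if decision.verdict in ("copper_ATPase", "RND_HME"):
                calls.append(
                    TypeCall(
                        sig.type_name,
                        (rec.protein_id,),
                        "similarity",
                        f"verdict={decision.verdict};"
                        f"label={decision.best_hit.subject_label if decision.best_hit else 'NA'}",
                    )
                )
            else:
                audit.append(
                    {
                        "stage": "transporter",
                        "protein_id": rec.protein_id,
                        "outcome": decision.verdict,
                        "reason": f"family={family}",
                    }
                )

    # stage 4: CSP compartment split
    csp_domains = {
        d.name
        for mode in ("csp_cytoplasmic", "csp_extracytoplasmic")
        for sig in catalog.types_with_mode(mode)
        for d in sig.domain_ids
    }
    for rec in available():
        if not any(_carries(rec, d) for d in csp_domains):
            continue
        consumed.add(rec.protein_id)
        calls.append(classify_csp(rec, options=options, audit=audit))

    # stage 5: single-domain types, catalog order
    single_sigs = catalog.types_with_mode("single_domain")
    for rec in available():
        for sig in single_sigs:
            call = match_single_domain(rec, sig)
            if call is not None:
                consumed.add(rec.protein_id)
                calls.append(call)
                break

    return calls
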