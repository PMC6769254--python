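"""Readers and writers for the pipeline's external formats.

Supported inputs
----------------
* HMMER3 per-domain tabular output (``--domtblout``): whitespace-delimited,
  '#'-prefixed comment lines, one row per domain hit.
* A simplified tab-separated domain-hit dialect with an explicit header
  (columns: protein_id, species_id, locus_index, domain_name, domain_accession,
  ali_start, ali_end, i_evalue, bit_score; coordinates 1-based inclusive).
* 12-column blast-tabular similarity hit tables plus a subject->label map
  (transporter reference categories).
* Protein metadata TSV (protein_id, species_id, locus_index, length),
  species metadata TSV (species_id, proteome_size, lifestyle, taxon_order),
  per-species profile matrices, FASTA sequences.

Ingestion applies a configurable per-domain inclusion E-value filter
(default 1e-5), an explicit surrogate for upstream hit curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

LIFESTYLES = ("E", "OE", "AP", "PP", "OC", "C", "S", "EnP", "EnS")

DEFAULT_IEVALUE_MAX = 1e-5

SIMPLE_TSV_COLUMNS = (
    "protein_id",
    "species_id",
    "locus_index",
    "domain_name",
    "domain_accession",
    "ali_start",
    "ali_end",
    "i_evalue",
    "bit_score",
)


class ParseError(ValueError):
    """Raised for malformed rows; the message carries the 1-based line number."""


@dataclass(frozen=True)
class DomainHit:
    """One profile-domain match on one protein (1-based inclusive coordinates)."""

    protein_id: str
    domain_name: str
    domain_accession: str
    ali_start: int
    ali_end: int
    i_evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.ali_start < 1:
            raise ValueError(f"{self.protein_id}: ali_start {self.ali_start} < 1")
        if self.ali_end < self.ali_start:
            raise ValueError(
                f"{self.protein_id}: ali_end {self.ali_end} < ali_start {self.ali_start}"
            )
        if self.i_evalue < 0:
            raise ValueError(f"{self.protein_id}: negative i_evalue")


@dataclass
class ProteinRecord:
    """A protein with its ordered domain hits and position along the replicon."""

    protein_id: str
    species_id: str
    locus_index: int
    length: Optional[int] = None
    domains: list[DomainHit] = field(default_factory=list)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda h: (h.ali_start, h.ali_end))

    @property
    def domain_string(self) -> tuple[str, ...]:
        """Domain names ordered N->C by alignment start."""
        return tuple(h.domain_name for h in self.domains)


@dataclass(frozen=True)
class SimilarityHit:
    """One similarity-search hit against the labeled transporter reference."""

    query_id: str
    subject_id: str
    evalue: float
    bit_score: float
    subject_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative evalue")


@dataclass(frozen=True)
class SpeciesMeta:
    """Species-level metadata: proteome size and lifestyle code."""

    species_id: str
    proteome_size: int
    lifestyle: str
    taxon_order: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(
                f"{self.species_id}: lifestyle {self.lifestyle!r} not one of {LIFESTYLES}"
            )
        if self.proteome_size < 0:
            raise ValueError(f"{self.species_id}: negative proteome_size")


# ---------------------------------------------------------------------------
# domain tables

# domtblout column indices (hmmsearch: target = protein, query = profile)
_DT_TARGET, _DT_QNAME, _DT_QACC = 0, 3, 4
_DT_IEVALUE, _DT_SCORE = 12, 13
_DT_ALIFROM, _DT_ALITO = 17, 18
_DT_MIN_COLS = 22


def _parse_domtblout_line(line: str, lineno: int) -> DomainHit:
    parts = line.split()
    if len(parts) < _DT_MIN_COLS:
        raise ParseError(
            f"line {lineno}: expected >= {_DT_MIN_COLS} columns, got {len(parts)}"
        )
    try:
        return DomainHit(
            protein_id=parts[_DT_TARGET],
            domain_name=parts[_DT_QNAME],
            domain_accession=parts[_DT_QACC].split(".")[0],
            ali_start=int(parts[_DT_ALIFROM]),
            ali_end=int(parts[_DT_ALITO]),
            i_evalue=float(parts[_DT_IEVALUE]),
            bit_score=float(parts[_DT_SCORE]),
        )
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def _parse_simple_tsv_line(
    parts: Sequence[str], colidx: Mapping[str, int], lineno: int
) -> DomainHit:
    try:
        return DomainHit(
            protein_id=parts[colidx["protein_id"]],
            domain_name=parts[colidx["domain_name"]],
            domain_accession=parts[colidx["domain_accession"]],
            ali_start=int(parts[colidx["ali_start"]]),
            ali_end=int(parts[colidx["ali_end"]]),
            i_evalue=float(parts[colidx["i_evalue"]]),
            bit_score=float(parts[colidx["bit_score"]]),
        )
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_domain_table(
    path: Union[str, Path], i_evalue_max: float = DEFAULT_IEVALUE_MAX
) -> list[DomainHit]:
    """Read a per-domain hit table (domtblout or simplified TSV dialect).

    Rows with per-domain independent E-value above ``i_evalue_max`` are
    filtered out (and the count logged). Malformed rows raise
    :class:`ParseError` with their line number; an empty file yields an
    empty list.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    n_filtered = 0
    colidx: Optional[dict[str, int]] = None
    dialect: Optional[str] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect is None:
                header = line.split("\t")
                if "protein_id" in header:
                    missing = set(SIMPLE_TSV_COLUMNS) - set(header)
                    if missing:
                        raise ParseError(
                            f"line {lineno}: simplified TSV header missing "
                            f"columns {sorted(missing)}"
                        )
                    colidx = {c: header.index(c) for c in SIMPLE_TSV_COLUMNS}
                    dialect = "simple_tsv"
                    continue
                dialect = "domtblout"
            if dialect == "simple_tsv":
                assert colidx is not None
                hit = _parse_simple_tsv_line(line.split("\t"), colidx, lineno)
            else:
                hit = _parse_domtblout_line(line, lineno)
            if hit.i_evalue <= i_evalue_max:
                hits.append(hit)
            else:
                n_filtered += 1
    if n_filtered:
        logger.info(
            "read_domain_table(%s): filtered %d hits with i_evalue > %g",
            path.name,
            n_filtered,
            i_evalue_max,
        )
    return hits


def write_domain_table(
    hits: Iterable[DomainHit],
    path: Union[str, Path],
    protein_meta: Optional[pd.DataFrame] = None,
) -> None:
    """Write hits in the simplified TSV dialect (1-based inclusive coordinates)."""
    meta_idx = None
    if protein_meta is not None:
        meta_idx = protein_meta.set_index("protein_id")
    with Path(path).open("w") as fh:
        fh.write("# cuproscan simplified domain-hit table; ali coords 1-based inclusive\n")
        fh.write("\t".join(SIMPLE_TSV_COLUMNS) + "\n")
        for h in hits:
            if meta_idx is not None and h.protein_id in meta_idx.index:
                row = meta_idx.loc[h.protein_id]
                species, locus = str(row["species_id"]), int(row["locus_index"])
            else:
                species, locus = "", 0
            fh.write(
                "\t".join(
                    [
                        h.protein_id,
                        species,
                        str(locus),
                        h.domain_name,
                        h.domain_accession,
                        str(h.ali_start),
                        str(h.ali_end),
                        repr(h.i_evalue),
                        repr(h.bit_score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# protein / species metadata

PROTEIN_META_COLUMNS = ("protein_id", "species_id", "locus_index", "length")


def read_protein_meta(path: Union[str, Path]) -> pd.DataFrame:
    """Protein metadata TSV. Missing locus_index falls back to file order."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    if "protein_id" not in df.columns or "species_id" not in df.columns:
        raise ParseError(f"{path}: protein metadata needs protein_id and species_id")
    if "locus_index" not in df.columns:
        df["locus_index"] = range(len(df))
    if "length" not in df.columns:
        df["length"] = pd.NA
    return df[list(PROTEIN_META_COLUMNS)]


def write_protein_meta(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[list(PROTEIN_META_COLUMNS)].to_csv(path, sep="\t", index=False)


def assemble_records(
    hits: Iterable[DomainHit],
    meta: pd.DataFrame,
    sequences: Optional[Mapping[str, str]] = None,
) -> list[ProteinRecord]:
    """Group hits per protein into :class:`ProteinRecord` objects.

    Proteins with zero hits are retained: they count toward the proteome,
    never toward copper types. A hit whose protein_id is absent from *meta*
    is an error.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    known = set(meta["protein_id"].astype(str))
    unknown = set(by_protein) - known
    if unknown:
        raise ValueError(
            f"domain hits reference unknown protein(s): {sorted(unknown)[:5]}"
        )
    records = []
    for row in meta.itertuples(index=False):
        pid = str(row.protein_id)
        length = None if pd.isna(row.length) else int(row.length)
        records.append(
            ProteinRecord(
                protein_id=pid,
                species_id=str(row.species_id),
                locus_index=int(row.locus_index),
                length=length,
                domains=by_protein.get(pid, []),
                sequence=sequences.get(pid) if sequences else None,
            )
        )
    return records


def read_species_meta(path: Union[str, Path]) -> list[SpeciesMeta]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"species_id", "proteome_size", "lifestyle"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: species metadata missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        taxon = row.get("taxon_order")
        if pd.isna(taxon) or taxon == "":
            taxon = None
        out.append(
            SpeciesMeta(
                species_id=str(row["species_id"]),
                proteome_size=int(row["proteome_size"]),
                lifestyle=str(row["lifestyle"]),
                taxon_order=taxon,
            )
        )
    return out


def write_species_meta(metas: Iterable[SpeciesMeta], path: Union[str, Path]) -> None:
    rows = [
        {
            "species_id": m.species_id,
            "proteome_size": m.proteome_size,
            "lifestyle": m.lifestyle,
            "taxon_order": m.taxon_order or "",
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# similarity tables (12-column blast-tabular)

def read_label_map(path: Union[str, Path]) -> dict[str, str]:
    """Two-column TSV: subject_id -> transporter category label."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["subject_id", "label"],
        dtype=str,
    )
    return dict(zip(df["subject_id"], df["label"]))


def read_similarity_table(
    path: Union[str, Path],
    label_map: Union[str, Path, Mapping[str, str]],
) -> list[SimilarityHit]:
    """Read a 12-column blast-tabular hit table, annotating subject labels.

    Subjects absent from the label map get the label "unknown".
    """
    if not isinstance(label_map, Mapping):
        label_map = read_label_map(label_map)
    hits: list[SimilarityHit] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                evalue = float(parts[10])
                bit_score = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            hits.append(
                SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    evalue=evalue,
                    bit_score=bit_score,
                    subject_label=label_map.get(parts[1], "unknown"),
                )
            )
    return hits


def write_similarity_table(
    hits: Iterable[SimilarityHit], path: Union[str, Path]
) -> None:
    """Write hits as 12-column blast-tabular (unused columns zero-filled)."""
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, "100.00", "0", "0", "0",
                        "0", "0", "0", "0", repr(h.evalue), repr(h.bit_score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for pid in sequences:
            fh.write(f">{pid}\n{sequences[pid]}\n")


# ---------------------------------------------------------------------------
# profile matrices

def write_profile_matrix(profiles, path: Union[str, Path], catalog) -> None:
    """Write per-species profiles as TSV: one row per species, one column per
    catalog type (catalog order), plus proteome_size and lifestyle."""
    rows = []
    for p in profiles:
        row = {"species_id": p.species_id, "lifestyle": p.lifestyle,
               "proteome_size": p.proteome_size}
        for t in catalog.type_names:
            row[t] = p.counts.get(t, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profile_matrix(path: Union[str, Path], catalog) -> list:
    """Read a profile matrix TSV back into SpeciesProfile objects.

    Column order on disk is irrelevant (named columns); a count column that is
    not a catalog type is an error.
    """
    from .profiler import SpeciesProfile  # deferred: avoid import cycle

    df = pd.read_csv(path, sep="\t", comment="#")
    fixed = {"species_id", "lifestyle", "proteome_size"}
    missing = fixed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: profile matrix missing columns {sorted(missing)}")
    count_cols = [c for c in df.columns if c not in fixed]
    unknown = [c for c in count_cols if c not in catalog]
    if unknown:
        raise ParseError(f"{path}: unknown type column(s) {unknown}")
    profiles = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        counts = {t: int(d.get(t, 0)) for t in catalog.type_names}
        profiles.append(
            SpeciesProfile(
                species_id=str(d["species_id"]),
                lifestyle=str(d["lifestyle"]),
                proteome_size=int(d["proteome_size"]),
                counts=counts,
            )
        )
    return profiles
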