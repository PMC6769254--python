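"""Synthetic multi-species proteome annotations with planted ground truth.

The generator emulates the study design the pipeline targets: per-species
domain-hit tables over a set of bacterial species whose copper-protein
complements are conditioned on lifestyle. Each lifestyle archetype carries a
Poisson rate per copper-related type; planted proteins instantiate the type's
domain organization (complex subunits at adjacent loci), decoy proteins carry
non-copper domains, and configurable noise (domain dropout, spurious hits)
degrades the tables. A truth file records every planted protein and count, so
recovery can be checked exactly.

Environmental archetypes are parameterized with roughly one third of planted
copper-related proteins in each functional category and a total expectation
close to 0.7% of the proteome; host-restricted archetypes shed homeostasis
systems and endosymbionts retain little beyond respiratory cuproproteins.
Dropout decisions are coupled across noise levels (one latent uniform per
planted hit), so raising the dropout probability can only remove hits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .annotation_io import (
    DomainHit,
    ProteinRecord,
    SimilarityHit,
    SpeciesMeta,
    write_domain_table,
    write_fasta,
    write_protein_meta,
    write_similarity_table,
    write_species_meta,
)
from .catalog import Catalog, load_catalog

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_R = AA20.replace("R", "")

# decoy vocabulary is disjoint from every catalog domain, so noise-free
# recovery is exact by construction
DECOY_DOMAINS = (
    ("ABC_tran", "PF99001"),
    ("Response_reg", "PF99002"),
    ("HTH_1", "PF99003"),
    ("GGDEF", "PF99004"),
    ("PAS", "PF99005"),
    ("HAMP", "PF99006"),
    ("TonB_dep_Rec", "PF99007"),
    ("MFS_1", "PF99008"),
    ("Peptidase_S8", "PF99009"),
    ("Glycos_transf_2", "PF99010"),
    ("AAA", "PF99011"),
    ("SBP_bac_5", "PF99012"),
)

_MIN_LOCUS_GAP = 12  # keeps planted instances outside each other's complex window


@dataclass(frozen=True)
class ArchetypeSpec:
    """Lifestyle archetype: proteome size distribution and per-type rates."""

    lifestyle: str
    proteome_size_mean: float
    proteome_size_sd: float
    lam: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.lam.values()):
            raise ValueError(f"{self.lifestyle}: negative Poisson rate")


@dataclass
class NoiseSpec:
    """Noise knobs: per-hit dropout probability and spurious hits per species."""

    p_drop: float = 0.0
    spurious_rate: float = 0.0


@dataclass
class SyntheticTruth:
    seed: int
    planted_counts: dict[str, dict[str, int]]  # species -> type -> count
    planted_proteins: dict[str, dict]  # protein_id -> {species, type, domains}
    noise: dict


@dataclass
class SimulatedDataset:
    """In-memory view of a simulated study plus its ground truth."""

    species_meta: list[SpeciesMeta]
    records: dict[str, list[ProteinRecord]]  # species_id -> records
    similarity_hits: list[SimilarityHit]
    label_map: dict[str, str]
    tigrfam_flags: dict[str, str]
    sequences: dict[str, str]
    truth: SyntheticTruth


def _lam(**rates: float) -> dict[str, float]:
    return dict(rates)


def default_archetypes() -> list[ArchetypeSpec]:
    """One archetype per lifestyle code, qualitatively mirroring the trends the
    pipeline is meant to expose: environmental species carry rich homeostasis
    complements; host-restricted groups progressively shed them; endosymbionts
    keep little beyond respiratory electron-transfer cuproproteins."""
    env_cupro = dict(
        **{"Nitrite reductase": 0.4, "Nitrous oxide Reductase": 0.4},
        Nnrs=1.5, Cu_amine_oxid=0.3, DUF386=0.2, Monooxygenase_B=0.3,
        Sod_Cu=1.2, Tyrosinase=0.2, Cyto_bo=0.8, Cyto_C_aa3=1.2, Cyto_C_cbb3=1.2,
    )
    env_cupro["Copper-bind"] = 1.5
    env_cupro["Cu-oxidase_4"] = 0.9
    env_cupro["Cupredoxin_1"] = 0.9
    env_homeo = {
        "MCOs": 1.8, "Cu ATPases": 2.0, "RNDs HME": 2.5, "CopB": 0.5,
        "CopC": 1.2, "CopD": 1.2, "CopK": 0.3, "CutA1": 0.5, "CutC": 0.5,
    }
    env_chap = {
        "Csp3_Ccsp": 0.8, "CusF_EC": 1.2, "HMA": 2.2, "PCuAC": 1.2,
        "SCO1-SenC": 1.2, "Csp1/2_Ecsp": 0.2, "CtaG_COX11": 1.0, "NosL": 0.4,
    }

    def scaled(base: Mapping[str, float], factor: float) -> dict[str, float]:
        return {k: round(v * factor, 3) for k, v in base.items()}

    E = {**env_cupro, **env_homeo, **env_chap}
    OE = {**scaled(env_cupro, 1.05), **scaled(env_homeo, 0.75), **scaled(env_chap, 0.9)}
    AP = {
        "Nnrs": 1.0, "Copper-bind": 0.8, "Sod_Cu": 0.8, "Cupredoxin_1": 0.3,
        "Cyto_C_aa3": 1.2, "Cyto_C_cbb3": 1.2, "Cyto_bo": 0.3,
        "MCOs": 0.3, "Cu ATPases": 1.2, "RNDs HME": 0.2,
        "Csp3_Ccsp": 0.3, "CusF_EC": 0.8, "HMA": 1.2, "PCuAC": 1.0,
        "SCO1-SenC": 1.0, "CtaG_COX11": 0.8,
    }
    PP = {
        **scaled(env_cupro, 0.8),
        "MCOs": 1.0, "Cu ATPases": 1.5, "RNDs HME": 1.0, "CopC": 0.8, "CopD": 0.7,
        **scaled(env_chap, 0.75),
    }
    OC = {
        "Nnrs": 0.8, "Copper-bind": 0.6, "Sod_Cu": 0.6, "Cyto_C_aa3": 1.0,
        "Cyto_C_cbb3": 0.8, "MCOs": 0.2, "Cu ATPases": 0.8,
        "CusF_EC": 0.5, "HMA": 1.0, "PCuAC": 0.8, "SCO1-SenC": 0.8,
        "CtaG_COX11": 0.6,
    }
    C = {
        "Nnrs": 0.6, "Copper-bind": 0.5, "Cyto_C_aa3": 0.8, "Cyto_C_cbb3": 0.6,
        "Cu ATPases": 0.5, "HMA": 0.8, "PCuAC": 0.6, "SCO1-SenC": 0.6,
        "CtaG_COX11": 0.5,
    }
    S = {
        "Nnrs": 0.5, "Cyto_C_aa3": 0.7, "Cyto_C_cbb3": 0.7, "Cu ATPases": 0.3,
        "HMA": 0.6, "PCuAC": 0.5, "SCO1-SenC": 0.5, "CtaG_COX11": 0.4,
    }
    EnP = {
        **scaled(env_cupro, 0.7),
        "MCOs": 0.8, "Cu ATPases": 1.2, "RNDs HME": 0.8, "CopC": 0.6,
        **scaled(env_chap, 0.7),
    }
    EnS = {
        "Nnrs": 0.2, "Cyto_C_aa3": 0.5, "Cyto_C_cbb3": 1.2,
        "Cu ATPases": 0.05, "HMA": 0.15, "PCuAC": 0.3, "SCO1-SenC": 0.3,
    }
    return [
        ArchetypeSpec("E", 4200, 700, E),
        ArchetypeSpec("OE", 5200, 900, OE),
        ArchetypeSpec("AP", 3800, 800, AP),
        ArchetypeSpec("PP", 5000, 800, PP),
        ArchetypeSpec("OC", 3200, 600, OC),
        ArchetypeSpec("C", 2500, 500, C),
        ArchetypeSpec("S", 3000, 600, S),
        ArchetypeSpec("EnP", 4800, 700, EnP),
        ArchetypeSpec("EnS", 400, 120, EnS),
    ]


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def tat_positive_sequence(
    rng: np.random.Generator, length: int = 120, motif_start: Optional[int] = None
) -> str:
    """A sequence carrying a twin-arginine motif within the first 35 residues."""
    motif = (
        rng.choice(list("ST"))
        + "RR"
        + rng.choice(list(AA_NO_R))
        + rng.choice(list("FGAVML"))
        + rng.choice(list("LITMVF"))
    )
    if motif_start is None:
        motif_start = int(rng.integers(2, 20))
    if motif_start + len(motif) > 35:
        raise ValueError(
            f"Tat motif at residue {motif_start} would fall outside the "
            f"35-residue search window"
        )
    prefix = "M" + _random_seq(rng, AA_NO_R, motif_start - 1)
    tail = _random_seq(rng, AA20, max(length - motif_start - len(motif), 10))
    return prefix + motif + tail


def tat_negative_sequence(rng: np.random.Generator, length: int = 120) -> str:
    """No arginine at all in the first 35 residues: provably no RR pair there."""
    head = "M" + _random_seq(rng, AA_NO_R, 34)
    tail = _random_seq(rng, AA20, max(length - 35, 10))
    return head + tail


def emit_csp_sequences(
    n_tat_positive: int,
    n_tat_negative: int,
    seed: int,
    length: int = 120,
    motif_start: Optional[int] = None,
    path: Optional[Union[str, Path]] = None,
) -> dict[str, str]:
    """Copper-storage-protein sequences with a known compartment split."""
    if n_tat_positive < 0 or n_tat_negative < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for i in range(n_tat_positive):
        seqs[f"csp_pos_{i + 1:03d}"] = tat_positive_sequence(rng, length, motif_start)
    for i in range(n_tat_negative):
        seqs[f"csp_neg_{i + 1:03d}"] = tat_negative_sequence(rng, length)
    if path is not None:
        write_fasta(seqs, path)
    return seqs


# ---------------------------------------------------------------------------
# species generation

class _SpeciesBuilder:
    def __init__(self, species_id: str, rng: np.random.Generator):
        self.species_id = species_id
        self.rng = rng
        self.records: list[ProteinRecord] = []
        self.similarity: list[SimilarityHit] = []
        self.label_map: dict[str, str] = {}
        self.flags: dict[str, str] = {}
        self.sequences: dict[str, str] = {}
        self.planted: dict[str, dict] = {}
        self._locus = 0
        self._serial = 0

    def _next_protein_id(self) -> str:
        self._serial += 1
        return f"{self.species_id}_p{self._serial:04d}"

    def _advance_locus(self, adjacent: bool = False) -> int:
        self._locus += 1 if adjacent else int(self.rng.integers(_MIN_LOCUS_GAP, 30))
        return self._locus

    def add_protein(
        self,
        domains: Sequence[tuple[str, str]],
        truth_type: Optional[str],
        adjacent: bool = False,
        sequence: Optional[str] = None,
    ) -> ProteinRecord:
        pid = self._next_protein_id()
        locus = self._advance_locus(adjacent)
        hits = []
        pos = 10
        for name, acc in domains:
            span = int(self.rng.integers(80, 160))
            hits.append(
                DomainHit(
                    protein_id=pid,
                    domain_name=name,
                    domain_accession=acc,
                    ali_start=pos,
                    ali_end=pos + span,
                    i_evalue=float(10.0 ** -self.rng.uniform(10, 50)),
                    bit_score=float(np.round(self.rng.uniform(80, 400), 1)),
                )
            )
            pos += span + int(self.rng.integers(5, 40))
        rec = ProteinRecord(
            protein_id=pid,
            species_id=self.species_id,
            locus_index=locus,
            length=pos + 30,
            domains=hits,
            sequence=sequence,
        )
        self.records.append(rec)
        if sequence is not None:
            self.sequences[pid] = sequence
        if truth_type is not None:
            self.planted[pid] = {
                "species_id": self.species_id,
                "type": truth_type,
                "domains": [name for name, _ in domains],
            }
        return rec

    def add_similarity(self, pid: str, label: str, tag: str) -> None:
        subject = f"TCDB_{label}_{tag}"
        self.label_map[subject] = label
        self.similarity.append(
            SimilarityHit(
                query_id=pid,
                subject_id=subject,
                evalue=0.0,
                bit_score=float(np.round(self.rng.uniform(700, 1200), 1)),
                subject_label=label,
            )
        )


def _domain_pair(catalog: Catalog, name: str) -> tuple[str, str]:
    for t in catalog:
        for d in t.domain_ids:
            if d.name == name:
                return (d.name, d.accession)
    raise ValueError(f"domain {name!r} not in catalog")


def _plant_instance(
    b: _SpeciesBuilder, sig, catalog: Catalog, rng: np.random.Generator
) -> None:
    name = sig.type_name
    if sig.match_mode == "single_domain":
        b.add_protein([(sig.domain_ids[0].name, sig.domain_ids[0].accession)], name)
    elif sig.match_mode == "architecture":
        pat = sig.patterns[int(rng.integers(0, len(sig.patterns)))]
        doms = [_domain_pair(catalog, e) for e in pat.elements]
        if pat.scope == "same_protein":
            b.add_protein(doms, name)
        else:
            b.add_protein([doms[0]], name)
            for d in doms[1:]:
                b.add_protein([d], name, adjacent=True)
    elif sig.match_mode == "complex":
        doms = [_domain_pair(catalog, e) for e in sig.patterns[0].elements]
        first = b.add_protein([doms[0]], name)
        for d in doms[1:]:
            b.add_protein([d], name, adjacent=True)
        flag = sig.params.get("required_flag")
        if flag:
            b.flags[first.protein_id] = flag
    elif sig.match_mode == "transporter_disambiguation":
        rec = b.add_protein(
            [(sig.domain_ids[0].name, sig.domain_ids[0].accession)], name
        )
        b.add_similarity(
            rec.protein_id, sig.params["target_label"], rec.protein_id[-4:]
        )
    elif sig.match_mode == "csp_cytoplasmic":
        b.add_protein(
            [(sig.domain_ids[0].name, sig.domain_ids[0].accession)],
            name,
            sequence=tat_negative_sequence(rng),
        )
    elif sig.match_mode == "csp_extracytoplasmic":
        b.add_protein(
            [(sig.domain_ids[0].name, sig.domain_ids[0].accession)],
            name,
            sequence=tat_positive_sequence(rng),
        )
    else:  # pragma: no cover - catalog validation forbids this
        raise ValueError(f"unhandled match_mode {sig.match_mode}")


def simulate(
    archetypes: Optional[Sequence[ArchetypeSpec]] = None,
    n_species_per_archetype: int = 5,
    noise: Optional[NoiseSpec] = None,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
    catalog: Optional[Catalog] = None,
    n_decoys: int = 25,
    n_decoy_transporters: int = 1,
) -> SimulatedDataset:
    """Generate a multi-species dataset with planted copper-protein truth.

    Per species, counts of each type are Poisson draws from the archetype
    rates; planted proteins instantiate the type's domain organization
    (split complexes at adjacent loci); decoy proteins carry non-copper
    domains; a decoy cuproenzyme-biogenesis ATPase (reference label 3.A.3.27)
    exercises the transporter exclusion path. Identical seed and configuration
    reproduce the dataset byte for byte.
    """
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    noise = noise or NoiseSpec()
    catalog = catalog or load_catalog()
    if n_species_per_archetype < 1:
        raise ValueError("n_species_per_archetype must be >= 1")
    for a in archetypes:
        from .annotation_io import LIFESTYLES

        if a.lifestyle not in LIFESTYLES:
            raise ValueError(f"invalid lifestyle code {a.lifestyle!r}")
        unknown = set(a.lam) - set(catalog.type_names)
        if unknown:
            raise ValueError(f"{a.lifestyle}: rates for unknown types {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    # separate stream for noise so that structure is identical across noise
    # settings and dropout is coupled (monotone in p_drop)
    rng_noise = np.random.default_rng(seed + 2**20)

    species_meta: list[SpeciesMeta] = []
    records: dict[str, list[ProteinRecord]] = {}
    similarity: list[SimilarityHit] = []
    label_map: dict[str, str] = {}
    flags: dict[str, str] = {}
    sequences: dict[str, str] = {}
    planted_counts: dict[str, dict[str, int]] = {}
    planted_proteins: dict[str, dict] = {}

    for arch in archetypes:
        for i in range(n_species_per_archetype):
            sid = f"{arch.lifestyle}{i + 1:02d}"
            b = _SpeciesBuilder(sid, rng)
            counts = {t: 0 for t in catalog.type_names}
            for sig in catalog:
                lam = arch.lam.get(sig.type_name, 0.0)
                k = int(rng.poisson(lam)) if lam > 0 else 0
                counts[sig.type_name] = k
                for _ in range(k):
                    _plant_instance(b, sig, catalog, rng)
            for _ in range(n_decoy_transporters):
                rec = b.add_protein([("E1-E2_ATPases", "PF00122")], None)
                b.add_similarity(rec.protein_id, "3.A.3.27", rec.protein_id[-4:])
            for _ in range(n_decoys):
                name, acc = DECOY_DOMAINS[int(rng.integers(0, len(DECOY_DOMAINS)))]
                b.add_protein([(name, acc)], None)

            # noise: coupled dropout on planted copper-domain hits, then
            # spurious hits on random proteins
            for rec in b.records:
                if rec.protein_id in b.planted:
                    kept = []
                    for h in rec.domains:
                        if float(rng_noise.uniform()) >= noise.p_drop:
                            kept.append(h)
                    rec.domains = kept
            n_spurious = int(rng_noise.poisson(noise.spurious_rate))
            all_domains = sorted(catalog.all_domain_names()) + [
                d for d, _ in DECOY_DOMAINS
            ]
            for _ in range(n_spurious):
                target = b.records[int(rng_noise.integers(0, len(b.records)))]
                dom = all_domains[int(rng_noise.integers(0, len(all_domains)))]
                start = int(rng_noise.integers(1, 200))
                target.domains = sorted(
                    target.domains
                    + [
                        DomainHit(
                            protein_id=target.protein_id,
                            domain_name=dom,
                            domain_accession=dom,
                            ali_start=start,
                            ali_end=start + 90,
                            i_evalue=1e-8,
                            bit_score=60.0,
                        )
                    ],
                    key=lambda h: (h.ali_start, h.ali_end),
                )

            proteome_size = max(
                len(b.records),
                int(round(rng.normal(arch.proteome_size_mean, arch.proteome_size_sd))),
            )
            species_meta.append(
                SpeciesMeta(
                    species_id=sid,
                    proteome_size=proteome_size,
                    lifestyle=arch.lifestyle,
                )
            )
            records[sid] = b.records
            similarity.extend(b.similarity)
            label_map.update(b.label_map)
            flags.update(b.flags)
            sequences.update(b.sequences)
            planted_counts[sid] = counts
            planted_proteins.update(b.planted)

    truth = SyntheticTruth(
        seed=seed,
        planted_counts=planted_counts,
        planted_proteins=planted_proteins,
        noise={"p_drop": noise.p_drop, "spurious_rate": noise.spurious_rate},
    )
    ds = SimulatedDataset(
        species_meta=species_meta,
        records=records,
        similarity_hits=similarity,
        label_map=label_map,
        tigrfam_flags=flags,
        sequences=sequences,
        truth=truth,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SimulatedDataset, out_dir: Union[str, Path]) -> None:
    """Write every pipeline input dialect plus the truth JSON."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_records = [r for sid in ds.records for r in ds.records[sid]]
    meta = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "species_id": r.species_id,
                "locus_index": r.locus_index,
                "length": r.length,
            }
            for r in all_records
        ]
    )
    write_protein_meta(meta, out / "proteins.tsv")
    hits = [h for r in all_records for h in r.domains]
    write_domain_table(hits, out / "domains.tsv", protein_meta=meta)
    write_species_meta(ds.species_meta, out / "species.tsv")
    write_similarity_table(ds.similarity_hits, out / "similarity.tsv")
    with (out / "tcdb_labels.tsv").open("w") as fh:
        for subject in sorted(ds.label_map):
            fh.write(f"{subject}\t{ds.label_map[subject]}\n")
    write_fasta(ds.sequences, out / "sequences.fasta")
    with (out / "flags.tsv").open("w") as fh:
        for pid in sorted(ds.tigrfam_flags):
            fh.write(f"{pid}\t{ds.tigrfam_flags[pid]}\n")
    with (out / "truth.json").open("w") as fh:
        json.dump(
            {
                "seed": ds.truth.seed,
                "noise": ds.truth.noise,
                "planted_counts": ds.truth.planted_counts,
                "planted_proteins": ds.truth.planted_proteins,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
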