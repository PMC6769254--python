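"""End-to-end wiring: classify a dataset, build profiles, cluster, replicate.

The stages compose pure functions from the other modules; everything here is
deterministic for a fixed configuration and input set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import statistics
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import annotation_io as aio
from .catalog import Catalog, load_catalog
from .classifier import ClassifyOptions, TypeCall, classify_species
from .clusterer import cluster_types, subset_cluster, write_newick
from .profiler import (
    SpeciesProfile,
    build_profile,
    count_species_with_type,
    curp_stats,
    lifestyle_medians,
    stats_table,
)
from .synthdata import SimulatedDataset, NoiseSpec, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable run configuration; logged verbatim per run."""

    out_dir: str = "cuproscan_out"
    seed: int = 0
    # inputs; when domains/proteins are unset the pipeline simulates instead
    domains: Optional[str] = None
    proteins: Optional[str] = None
    species: Optional[str] = None
    similarity: Optional[str] = None
    labels: Optional[str] = None
    sequences: Optional[str] = None
    flags: Optional[str] = None
    override: Optional[str] = None
    # simulation
    n_species_per_archetype: int = 5
    p_drop: float = 0.0
    spurious_rate: float = 0.0
    # classifier
    i_evalue_max: float = aio.DEFAULT_IEVALUE_MAX
    complex_window: int = 5
    e_max: float = 1e-180
    tat_motif: str = r"[ST]RR.[FGAVML][LITMVF]"
    tat_search_len: int = 35
    # profiler / clusterer
    accounting: str = "dual"
    linkage: str = "average"
    center: bool = True
    catalog_path: Optional[str] = None

    def classify_options(self) -> ClassifyOptions:
        return ClassifyOptions(
            complex_window=self.complex_window,
            e_max=self.e_max,
            tat_motif=self.tat_motif,
            tat_search_len=self.tat_search_len,
        )


def classify_dataset(
    ds: SimulatedDataset,
    catalog: Optional[Catalog] = None,
    options: Optional[ClassifyOptions] = None,
    audit: Optional[list] = None,
) -> dict[str, list[TypeCall]]:
    """Classify every species of a simulated dataset. Returns species -> calls."""
    catalog = catalog or load_catalog()
    sim_by_species: dict[str, list] = {}
    pid_to_species = {
        r.protein_id: sid for sid in ds.records for r in ds.records[sid]
    }
    for h in ds.similarity_hits:
        sid = pid_to_species.get(h.query_id)
        if sid is not None:
            sim_by_species.setdefault(sid, []).append(h)
    out = {}
    for meta in ds.species_meta:
        out[meta.species_id] = classify_species(
            ds.records[meta.species_id],
            catalog,
            similarity_hits=sim_by_species.get(meta.species_id, []),
            tigrfam_flags=ds.tigrfam_flags,
            options=options,
            audit=audit,
        )
    return out


def profiles_from_dataset(
    ds: SimulatedDataset,
    catalog: Optional[Catalog] = None,
    options: Optional[ClassifyOptions] = None,
    calls: Optional[Mapping[str, Sequence[TypeCall]]] = None,
) -> list[SpeciesProfile]:
    catalog = catalog or load_catalog()
    if calls is None:
        calls = classify_dataset(ds, catalog, options)
    return [
        build_profile(calls[m.species_id], m, catalog) for m in ds.species_meta
    ]


def write_calls(
    calls_by_species: Mapping[str, Sequence[TypeCall]], path: Union[str, Path]
) -> None:
    rows = []
    for sid in calls_by_species:
        for c in calls_by_species[sid]:
            rows.append(
                {
                    "species_id": sid,
                    "type_name": c.type_name,
                    "member_protein_ids": ",".join(c.member_protein_ids),
                    "evidence": c.evidence,
                    "details": c.details,
                }
            )
    pd.DataFrame(
        rows,
        columns=["species_id", "type_name", "member_protein_ids", "evidence", "details"],
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: Union[str, Path]) -> dict[str, list[TypeCall]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, list[TypeCall]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.species_id, []).append(
            TypeCall(
                type_name=row.type_name,
                member_protein_ids=tuple(row.member_protein_ids.split(",")),
                evidence=row.evidence,
                details=row.details,
            )
        )
    return out


def write_audit(audit: Sequence[Mapping], path: Union[str, Path]) -> None:
    pd.DataFrame(
        list(audit), columns=["stage", "protein_id", "outcome", "reason"]
    ).to_csv(path, sep="\t", index=False)


def read_override(path: Union[str, Path]) -> dict[str, str]:
    """Per-protein override TSV (protein_id, label in {NOR, AA3})."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["protein_id", "label"], dtype=str)
    bad = set(df["label"]) - {"NOR", "AA3"}
    if bad:
        raise ValueError(f"override labels must be NOR or AA3, got {sorted(bad)}")
    return dict(zip(df["protein_id"], df["label"]))


def read_flags(path: Union[str, Path]) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["protein_id", "flag"], dtype=str)
    return dict(zip(df["protein_id"], df["flag"]))


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/ingest -> classify -> profile -> cluster; write artifacts.

    Returns a small manifest of the artifacts written. Identical config and
    inputs give identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(config.catalog_path)
    cfg_text = json.dumps(asdict(config), sort_keys=True)
    logger.info(
        "run config (sha1 %s): %s",
        hashlib.sha1(cfg_text.encode()).hexdigest()[:12],
        cfg_text,
    )

    audit: list = []
    options = config.classify_options()

    if config.domains is None:
        ds = simulate(
            n_species_per_archetype=config.n_species_per_archetype,
            noise=NoiseSpec(config.p_drop, config.spurious_rate),
            seed=config.seed,
            out_dir=str(out / "simulated"),
            catalog=catalog,
        )
        calls = classify_dataset(ds, catalog, options, audit)
        metas = ds.species_meta
    else:
        if config.proteins is None:
            raise FileNotFoundError("protein metadata table is required")
        hits = aio.read_domain_table(config.domains, config.i_evalue_max)
        meta_df = aio.read_protein_meta(config.proteins)
        sequences = aio.read_fasta(config.sequences) if config.sequences else None
        records = aio.assemble_records(hits, meta_df, sequences)
        if config.species is None:
            raise FileNotFoundError("species metadata table is required")
        metas = aio.read_species_meta(config.species)
        sim_hits = []
        if config.similarity:
            if not config.labels:
                raise FileNotFoundError("similarity table given without a label map")
            sim_hits = aio.read_similarity_table(config.similarity, config.labels)
        flags = read_flags(config.flags) if config.flags else {}
        override = read_override(config.override) if config.override else {}
        by_species: dict[str, list] = {}
        for r in records:
            by_species.setdefault(r.species_id, []).append(r)
        sim_by_query: dict[str, list] = {}
        for h in sim_hits:
            sim_by_query.setdefault(h.query_id, []).append(h)
        calls = {}
        for m in metas:
            recs = by_species.get(m.species_id, [])
            species_sim = [
                h for r in recs for h in sim_by_query.get(r.protein_id, [])
            ]
            calls[m.species_id] = classify_species(
                recs, catalog, species_sim, flags, override, options, audit
            )

    write_calls(calls, out / "calls.tsv")
    write_audit(audit, out / "audit.tsv")

    profiles = [build_profile(calls[m.species_id], m, catalog) for m in metas]
    aio.write_profile_matrix(profiles, out / "profiles.tsv", catalog)
    stats_table(profiles, catalog, config.accounting).to_csv(
        out / "stats.tsv", sep="\t", index=False
    )
    manifest = {
        "calls": str(out / "calls.tsv"),
        "audit": str(out / "audit.tsv"),
        "profiles": str(out / "profiles.tsv"),
        "stats": str(out / "stats.tsv"),
    }
    if len(profiles) >= 2:
        tree_h = subset_cluster(
            profiles, catalog, "homeostasis_only",
            linkage=config.linkage, center=config.center,
        )
        write_newick(tree_h, out / "species_homeostasis.nwk")
        tree_all = subset_cluster(
            profiles, catalog, "all_copper",
            linkage=config.linkage, center=config.center,
        )
        write_newick(tree_all, out / "species_all_copper.nwk")
        tree_t = cluster_types(profiles, catalog, linkage=config.linkage)
        write_newick(tree_t, out / "type_cooccurrence.nwk")
        manifest.update(
            {
                "species_homeostasis_tree": str(out / "species_homeostasis.nwk"),
                "species_all_copper_tree": str(out / "species_all_copper.nwk"),
                "type_cooccurrence_tree": str(out / "type_cooccurrence.nwk"),
            }
        )
    return manifest


# ---------------------------------------------------------------------------
# replication aggregates over an externally supplied profile matrix

def replicate_sm(
    profiles: Sequence[SpeciesProfile], catalog: Catalog
) -> dict:
    """Recompute the headline aggregates from a per-species profile matrix.

    Intended for externally supplied count tables (one row per species, one
    column per type, plus proteome size and lifestyle). Category shares are
    reported under both accounting modes for dual-membership types.
    """
    out: dict = {}
    out["n_species"] = len(profiles)
    out["median_curp_percent_by_lifestyle"] = {
        k: round(v, 2)
        for k, v in lifestyle_medians(profiles, "curp_percent", catalog).items()
    }
    for mode in ("dual", "exclusive"):
        stats = [curp_stats(p, catalog, mode) for p in profiles]
        out[f"median_share_cuproprotein_{mode}"] = round(
            statistics.median(s.share_cuproprotein for s in stats), 1
        )
        out[f"median_share_homeostasis_{mode}"] = round(
            statistics.median(s.share_homeostasis for s in stats), 1
        )
        out[f"median_share_chaperone_{mode}"] = round(
            statistics.median(s.share_chaperone for s in stats), 1
        )
    out["n_species_with_cu_atpases"] = count_species_with_type(
        profiles, "Cu ATPases", catalog
    )
    out["n_species_with_rnd_hme"] = count_species_with_type(
        profiles, "RNDs HME", catalog
    )
    out["max_curp_percent"] = round(
        max(curp_stats(p, catalog).curp_percent for p in profiles), 2
    )
    out["total_csp_extracytoplasmic"] = sum(p.count("Csp1/2_Ecsp") for p in profiles)
    out["total_csp_cytoplasmic"] = sum(p.count("Csp3_Ccsp") for p in profiles)
    return out
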