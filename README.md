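# cuproscan

Copper is both an essential enzymatic cofactor and a toxin, and bacteria
balance the two with three kinds of proteins: **cuproproteins** (enzymes with
active-site copper, e.g. cytochrome C oxidase subunits, copper nitrite
reductase, Cu/Zn superoxide dismutase), **copper-homeostasis systems**
(P1B-type Cu ATPases, RND heavy-metal-efflux transporters, multicopper
oxidases, periplasmic sequestration proteins) and **copper chaperones**
(HMA/CopZ, CusF, PCuAC, SCO1-SenC, NosL, copper-storage proteins). The
composition of this *copper-related proteome* (CuRP) tracks lifestyle:
environmental bacteria keep rich homeostasis complements, while
host-restricted pathogens, commensals and especially endosymbionts shed them.

`cuproscan` is a pipeline for profiling copper-related proteomes of bacterial
species from protein-domain annotations. It is aimed at comparative
genomicists who already have per-proteome Pfam/profile-HMM domain tables and
want reproducible classification, per-species statistics and clustering
without re-running annotation.

## What it does

* **Signature catalog** — 31 copper-related protein types (14 cuproproteins,
  9 homeostasis systems, 8 chaperones; multicopper oxidases and cytoplasmic
  copper-storage proteins belong to two categories each), shipped as a
  declarative YAML file with per-type matching rules and overridable by the
  user.
* **Classification** — each protein (or multi-protein complex) is assigned to
  at most one type via, in order: locus-window complex assembly (e.g.
  COX1+FixO ⇒ cbb3-type oxidase; COX1+COX2 resolved to bo/aa3 by
  CyoB/QoxB-style flags), domain-architecture patterns matched longest-first
  (e.g. Cu-oxidase_3/Cu-oxidase/Cu-oxidase_2 ⇒ MCO;
  Cu-oxidase_3/Cu-oxidase ⇒ nitrite reductase), transporter disambiguation
  against a labeled reference (copper-resistance ATPases `3.A.3.5`,
  heavy-metal-efflux RND `2.A.6.1`; biogenesis ATPases `3.A.3.27` excluded),
  twin-arginine (Tat) signal detection to split copper-storage proteins by
  compartment, and single-domain rules.
* **Profiling** — per-species CuRP counts,
  `curp_percent = 100 · curp_count / proteome_size`, category shares, and
  lifestyle-group medians.
* **Clustering** — Cluster-3.0-style hierarchical clustering of species and
  of protein types with the uncentered correlation
  `r = Σ x_i y_i / (‖x‖·‖y‖)` (distance `1 − r`), optional median centering
  and MAD scaling, deterministic tie-breaking, Newick export.
* **Synthetic data** — a lifestyle-conditioned generator with planted ground
  truth, so the entire pipeline is testable end to end with no downloads.

## Worked example

Simulate three lifestyle archetypes (environmental `E`, animal pathogen `AP`,
endosymbiont `EnS`), classify, and summarize:

```python
from cuproscan import simulate, load_catalog, profiles_from_dataset, lifestyle_medians
from cuproscan.profiler import stats_table
from cuproscan.synthdata import default_archetypes

catalog = load_catalog()
arche = [a for a in default_archetypes() if a.lifestyle in ("E", "AP", "EnS")]
ds = simulate(arche, n_species_per_archetype=3, seed=17)
profiles = profiles_from_dataset(ds, catalog)
print(stats_table(profiles, catalog).to_string(index=False))
print(lifestyle_medians(profiles, "share_homeostasis", catalog))
```

prints

```
species_id lifestyle  proteome_size  curp_count  curp_percent  share_cuproprotein  share_homeostasis  share_chaperone
       E01         E           4224          18          0.43               50.00              44.44            22.22
       E02         E           4225          35          0.83               45.71              42.86            17.14
       E03         E           4580          29          0.63               55.17              44.83            10.34
      AP01        AP           3728          13          0.35               38.46               7.69            53.85
      AP02        AP           3039          10          0.33               10.00              10.00            80.00
      AP03        AP           3796           7          0.18               57.14              14.29            28.57
     EnS01       EnS            656           3          0.46              100.00               0.00             0.00
     EnS02       EnS            272           4          1.47               75.00               0.00            25.00
     EnS03       EnS            438           1          0.23              100.00               0.00             0.00

{'E': 44.4, 'AP': 10.0, 'EnS': 0.0}
```

Each row is one simulated species: `curp_percent` is the copper-related
fraction of its proteome, and the three shares split the copper-related
proteome by functional category (they can sum above 100% because multicopper
oxidases and cytoplasmic storage proteins count in two categories). The
median homeostasis share falls from environmental species (44%) through
pathogens (10%) to endosymbionts (0%) — the lifestyle gradient the pipeline
is built to expose.

The same flow is available from the shell:

```
cuproscan simulate --seed 17 --out data/
cuproscan classify --domains data/domains.tsv --proteins data/proteins.tsv \
    --species data/species.tsv --similarity data/similarity.tsv \
    --labels data/tcdb_labels.tsv --sequences data/sequences.fasta \
    --flags data/flags.tsv --out run/
cuproscan cluster --profiles run/profiles.tsv --columns homeostasis --out tree.nwk
cuproscan replicate-sm --matrix run/profiles.tsv --out aggregates.json
```

`classify` accepts HMMER `--domtblout` tables or the package's simplified
TSV dialect; `replicate-sm` recomputes headline aggregates (per-lifestyle
CuRP medians, category-share medians under both accounting modes, species
counts per transporter type, maxima, storage-protein totals) from any
externally supplied per-species count matrix.

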