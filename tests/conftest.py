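import numpy as np
import pytest

from cuproscan import load_catalog
from cuproscan.annotation_io import DomainHit, ProteinRecord


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_protein(
    domain_names,
    protein_id="p1",
    species_id="sp1",
    locus_index=0,
    sequence=None,
    accessions=None,
):
    """Build a ProteinRecord with evenly spaced domain hits in the given order."""
    hits = []
    pos = 10
    for i, name in enumerate(domain_names):
        acc = accessions[i] if accessions else name
        hits.append(
            DomainHit(
                protein_id=protein_id,
                domain_name=name,
                domain_accession=acc,
                ali_start=pos,
                ali_end=pos + 100,
                i_evalue=1e-20,
                bit_score=200.0,
            )
        )
        pos += 150
    return ProteinRecord(
        protein_id=protein_id,
        species_id=species_id,
        locus_index=locus_index,
        length=pos + 50,
        domains=hits,
        sequence=sequence,
    )


def subsequence_oracle(needle, haystack):
    """Exhaustive independent check that needle occurs as an ordered
    subsequence of haystack (tries every index combination)."""
    from itertools import combinations

    k = len(needle)
    if k == 0:
        return True
    for idxs in combinations(range(len(haystack)), k):
        if all(haystack[i] == e for i, e in zip(idxs, needle)):
            return True
    return False


def brute_force_agglomerate(dist, linkage="average"):
    """Reference O(n^3) agglomeration computed directly from the definition.

    Inter-cluster distances are recomputed from the original leaf-leaf matrix
    at every step (mean / max / min over all cross pairs), with ties broken by
    the lexicographically smallest pair of cluster indices — independent of
    the Lance-Williams recurrences used by the implementation under test.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n
    agg = {"average": np.mean, "complete": np.max, "single": np.min}[linkage]
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                d = agg([dist[i, j] for i in members[a] for j in members[b]])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merges.append((a, b, d))
        members[next_id] = members[a] + members[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        active.sort()
        next_id += 1
    return merges
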