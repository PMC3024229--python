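"""Cross-strain retention of duplicate genes.

Each duplicate pair's first member ("Orf 1") is searched against the
proteomes of related strains with the same global-alignment thresholds used
for the within-genome census. The per-strain match counts (0 / 1 / 2 / >2)
summarize gene loss and retention; pairs with exactly two qualifying matches
in *every* strain are the "common pairs" carried into the selection analysis.

A count of 2 means two qualifying hits, without requiring that the two hits
be reciprocal duplicates in the target strain; reciprocity is not asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import GeneRecord, GenomeBundle
from .homology import (
    DEFAULT_E_MAX,
    DEFAULT_ID_MIN,
    DuplicatePair,
    ScoringScheme,
    align_global,
    evalue,
)

MATCH_BINS = ("0", "1", "2", ">2")


@dataclass
class MatchProfile:
    pair_id: str
    counts: dict[str, int]           # strain -> match count
    loci: dict[str, list[str]]       # strain -> matched loci, best first


def count_matches(
    query_gene: GeneRecord,
    strain_bundle: GenomeBundle,
    e_max: float = DEFAULT_E_MAX,
    id_min: float = DEFAULT_ID_MIN,
    scoring: ScoringScheme | None = None,
) -> tuple[int, list[str]]:
    """Qualifying hits of one query protein in one strain's proteome.

    Hits must pass both the E-value and identity thresholds; matched loci are
    returned ordered by (E-value, descending score, locus) for determinism.
    """
    scoring = scoring or ScoringScheme()
    rows = []
    for g in strain_bundle.genes:
        res = align_global(query_gene.protein_seq, g.protein_seq, scoring,
                           query_gene.locus_tag, g.locus_tag, keep_alignment=False)
        ev = evalue(res.score, len(query_gene.protein_seq), len(g.protein_seq),
                    scoring.ka)
        if ev <= e_max and res.percent_identity >= id_min:
            rows.append((ev, -res.score, g.locus_tag))
    rows.sort()
    return len(rows), [r[2] for r in rows]


def match_profiles(
    pairs: list[DuplicatePair],
    strains: dict[str, GenomeBundle],
    e_max: float = DEFAULT_E_MAX,
    id_min: float = DEFAULT_ID_MIN,
    scoring: ScoringScheme | None = None,
    query_both_members: bool = False,
) -> list[MatchProfile]:
    """Match counts of each pair's Orf 1 (optionally both members) per strain.

    When both members are queried, a strain's matched locus set is the union
    and the count is its size.
    """
    profiles = []
    for pair in pairs:
        queries = [pair.gene_a] + ([pair.gene_b] if query_both_members else [])
        counts: dict[str, int] = {}
        loci: dict[str, list[str]] = {}
        for name, bundle in strains.items():
            merged: list[str] = []
            for q in queries:
                _, hit_loci = count_matches(q, bundle, e_max, id_min, scoring)
                merged.extend(l for l in hit_loci if l not in merged)
            counts[name] = len(merged)
            loci[name] = merged
        profiles.append(MatchProfile(pair.pair_id, counts, loci))
    return profiles


def match_distribution(
    profiles: list[MatchProfile], strains: list[str]
) -> pd.DataFrame:
    """Strain x {0,1,2,>2} table of match counts; rows sum to the pair count."""
    table = pd.DataFrame(0, index=list(strains), columns=list(MATCH_BINS))
    for p in profiles:
        for s in strains:
            c = p.counts[s]
            key = str(c) if c <= 2 else ">2"
            table.loc[s, key] += 1
    return table


def common_pairs(profiles: list[MatchProfile]) -> list[str]:
    """Pair ids with exactly two qualifying matches in every strain."""
    return [p.pair_id for p in profiles
            if p.counts and all(c == 2 for c in p.counts.values())]
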