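"""COG functional-category statistics for duplicated genes.

Compares the COG distribution of a gene set (typically the duplicated genes)
against genome-wide expectations with a chi-square goodness-of-fit test, at
either the general level (5 classes, 0-4) or the sub-group level (25 letters),
bins amino-acid divergence of duplicate pairs, and detects positional clusters
of duplicated genes sharing a general COG class.

Multi-COG genes contribute one count per category, so tally totals can exceed
the number of genes. Genes with no COG letters fall in general class 0 /
sub-group "-".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import COG_ALPHABET, COG_GENERAL_GROUPS, GeneRecord
from .homology import DuplicatePair

GENERAL_CATEGORIES = ["0", "1", "2", "3", "4"]
SUBGROUP_CATEGORIES = ["-"] + sorted(COG_ALPHABET)


@dataclass
class CogTally:
    counts: dict[str, int]
    level: str  # "general" | "subgroup"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GofResult:
    chi2: float
    df: int
    p: float


@dataclass
class CogCluster:
    replicon_id: str
    window_start: int  # [start, end) in nt
    window_end: int
    category: int  # general COG class
    member_loci: list[str]
    mean_divergence: float


def tally_cogs(genes: list[GeneRecord], level: str = "general") -> CogTally:
    """Count genes per COG category; multi-COG genes count once per category."""
    if level == "general":
        counts = {c: 0 for c in GENERAL_CATEGORIES}
        for g in genes:
            for grp in sorted(g.cog_general_groups):
                counts[str(grp)] += 1
    elif level == "subgroup":
        counts = {c: 0 for c in SUBGROUP_CATEGORIES}
        for g in genes:
            bad = set(g.cogs) - COG_ALPHABET
            if bad:
                raise ValueError(f"{g.locus_tag}: unknown COG letters {sorted(bad)}")
            if not g.cogs:
                counts["-"] += 1
            for c in sorted(g.cogs):
                counts[c] += 1
    else:
        raise ValueError(f"unknown tally level {level!r}")
    return CogTally(counts=counts, level=level)


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < 0 or df < 1:
        raise ValueError("require x >= 0 and df >= 1")
    return float(stats.chi2.sf(x, df))


def chisq_gof(observed: CogTally, expected_props: dict[str, float]) -> GofResult:
    """Chi-square goodness of fit of observed counts against expected proportions.

    The null hypothesis is that the gene set shares the reference (e.g. whole
    genome) category distribution. Categories with zero expectation and zero
    observation are dropped from the statistic and the degrees of freedom;
    a zero expectation with a positive observation is undefined and an error.
    No continuity correction is applied.
    """
    total_prop = sum(expected_props.values())
    if abs(total_prop - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {total_prop}, not 1")
    if observed.total <= 0:
        raise ValueError("observed tally is empty")
    chi2 = 0.0
    n_used = 0
    for cat, obs in observed.counts.items():
        prop = expected_props.get(cat, 0.0)
        if prop == 0.0:
            if obs > 0:
                raise ValueError(f"category {cat!r} observed but expected proportion is 0")
            continue
        exp = observed.total * prop
        chi2 += (obs - exp) ** 2 / exp
        n_used += 1
    df = n_used - 1
    return GofResult(chi2=chi2, df=df, p=chi2_sf(chi2, df))


DIVERGENCE_BIN_EDGES = list(range(0, 101, 10))


def bin_divergence(pairs: list[DuplicatePair], width: int = 10) -> dict[str, int]:
    """Histogram of pair divergences over [0,10), [10,20), ..., [90,100].

    The last bin is closed above so a divergence of exactly 100 is kept.
    """
    edges = list(range(0, 101, width))
    labels = [f"[{lo},{lo + width})" for lo in edges[:-1]]
    labels[-1] = f"[{edges[-2]},100]"
    counts = {lab: 0 for lab in labels}
    for p in pairs:
        d = p.divergence
        if not 0.0 <= d <= 100.0:
            raise ValueError(f"divergence {d} outside [0,100]")
        k = min(int(d // width), len(labels) - 1)
        counts[labels[k]] += 1
    return counts


def find_cog_clusters(
    dup_genes: list[GeneRecord],
    divergence_by_locus: dict[str, float] | None = None,
    window: int = 100_000,
    min_count: int = 3,
) -> list[CogCluster]:
    """Positional clusters of duplicated genes sharing a general COG class.

    Fixed non-overlapping windows are tiled from coordinate 0 on each replicon;
    a cluster is reported for every (window, general class) holding at least
    ``min_count`` duplicated genes of that class. A multi-COG gene can seed
    clusters in each of its classes.
    """
    buckets: dict[tuple[str, int, int], list[GeneRecord]] = {}
    for g in dup_genes:
        w = (g.start - 1) // window
        for grp in g.cog_general_groups:
            buckets.setdefault((g.replicon_id, w, grp), []).append(g)
    clusters: list[CogCluster] = []
    for (rid, w, grp), members in sorted(buckets.items()):
        if len(members) < min_count:
            continue
        if divergence_by_locus:
            divs = [divergence_by_locus[m.locus_tag] for m in members
                    if m.locus_tag in divergence_by_locus]
            mean_div = float(np.mean(divs)) if divs else float("nan")
        else:
            mean_div = float("nan")
        clusters.append(CogCluster(
            replicon_id=rid,
            window_start=w * window,
            window_end=(w + 1) * window,
            category=grp,
            member_loci=sorted(m.locus_tag for m in members),
            mean_divergence=mean_div,
        ))
    return clusters
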