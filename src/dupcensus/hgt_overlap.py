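"""Overlap accounting between predicted HGT intervals and gene annotations.

Horizontal-transfer intervals are produced externally (compositional-bias
scanners emit them per replicon); this module only consumes them: it merges
and clips BED intervals, computes per-replicon coverage, and intersects the
regions with gene coordinates and duplicate-pair membership. A gene counts as
inside a region when it overlaps by at least one nucleotide (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import GeneRecord, GenomeBundle
from .homology import DuplicatePair


@dataclass
class IntervalSet:
    """Per-replicon sorted, merged [start, end) intervals (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def total_bp(self, replicon_id: str) -> int:
        return sum(e - s for s, e in self.intervals.get(replicon_id, []))


def merge_intervals(raw: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/touching half-open intervals (idempotent)."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(raw):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_bed(path: str | Path, bundle: GenomeBundle) -> IntervalSet:
    """Read BED3 intervals, merge them, and clip to replicon bounds."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: not BED3")
            rid, start, end = fields[0], int(fields[1]), int(fields[2])
            if rid not in bundle.replicons:
                raise ValueError(f"{path}:{lineno}: unknown replicon {rid!r}")
            length = bundle.replicons[rid].length
            if end > length:
                warnings.warn(f"{path}:{lineno}: interval end {end} clipped to "
                              f"replicon length {length}")
                end = length
            start = max(start, 0)
            if start < end:
                raw.setdefault(rid, []).append((start, end))
    return IntervalSet({rid: merge_intervals(iv) for rid, iv in raw.items()})


def replicon_coverage(
    intervals: IntervalSet, bundle: GenomeBundle
) -> dict[str, tuple[int, float]]:
    """Per-replicon (nucleotides covered, fraction of replicon length)."""
    out = {}
    for rid, rep in bundle.replicons.items():
        bp = intervals.total_bp(rid)
        out[rid] = (bp, bp / rep.length)
    return out


def genes_in_regions(
    intervals: IntervalSet,
    genes: list[GeneRecord],
    dup_pairs: list[DuplicatePair] | None = None,
    min_overlap: int = 1,
) -> tuple[list[str], list[str]]:
    """Loci overlapping any interval, and the duplicated subset thereof.

    Gene coordinates are 1-based inclusive, intervals half-open; a gene is
    inside when the overlap is at least ``min_overlap`` nucleotides.
    """
    inside: list[str] = []
    for g in genes:
        g0, g1 = g.start - 1, g.end  # half-open
        for s, e in intervals.intervals.get(g.replicon_id, []):
            if min(g1, e) - max(g0, s) >= min_overlap:
                inside.append(g.locus_tag)
                break
    dup_loci = set()
    for p in dup_pairs or []:
        dup_loci.add(p.gene_a.locus_tag)
        dup_loci.add(p.gene_b.locus_tag)
    dup_inside = [l for l in inside if l in dup_loci]
    return inside, dup_inside
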