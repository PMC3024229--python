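import numpy as np
import pytest

from dupcensus import hgt_overlap
from dupcensus.genome_io import GeneRecord, GenomeBundle, Replicon, translate_cds
from dupcensus.homology import DuplicatePair, all_vs_all, build_families, call_duplicate_pairs
from dupcensus.strain_compare import (
    MatchProfile,
    common_pairs,
    count_matches,
    match_distribution,
    match_profiles,
)
from dupcensus.synthetic_data import SimConfig, simulate_cohort


# --- strain comparison -------------------------------------------------------

def test_query_against_own_bundle_hits_self(mini_cohort):
    g = mini_cohort.focal.genes[0]
    n, loci = count_matches(g, mini_cohort.focal)
    assert n >= 1 and g.locus_tag in loci


def test_threshold_monotonicity(mini_cohort):
    g = mini_cohort.focal.genes[0]
    strain = next(iter(mini_cohort.strains.values()))
    strict, _ = count_matches(g, strain, e_max=1e-40, id_min=60.0)
    loose, _ = count_matches(g, strain, e_max=1e-10, id_min=30.0)
    assert loose >= strict


def test_common_pairs_selection_rule():
    mk = lambda pid, counts: MatchProfile(pid, counts, {s: [] for s in counts})
    profiles = [
        mk("p1", {"S1": 2, "S2": 2, "S3": 2}),
        mk("p2", {"S1": 2, "S2": 1, "S3": 2}),
        mk("p3", {"S1": 3, "S2": 2, "S3": 2}),
    ]
    assert common_pairs(profiles) == ["p1"]
    # common pairs are a subset of pairs with >=1 strain at exactly 2 matches
    with_two = {p.pair_id for p in profiles if 2 in p.counts.values()}
    assert set(common_pairs(profiles)) <= with_two


def test_match_distribution_rows_sum_to_pairs():
    mk = lambda pid, counts: MatchProfile(pid, counts, {s: [] for s in counts})
    profiles = [mk("p1", {"S1": 0}), mk("p2", {"S1": 2}), mk("p3", {"S1": 5})]
    table = match_distribution(profiles, ["S1"])
    assert table.loc["S1"].sum() == 3
    assert table.loc["S1", ">2"] == 1
    assert match_distribution([], []).empty


def test_no_copy_loss_makes_every_pair_common():
    cohort = simulate_cohort(SimConfig(
        n_families=8, frac_duplicated=0.5, n_codons=120,
        copy_loss_prob=0.0, n_hgt_intervals=0, master_seed=21))
    hits = all_vs_all(cohort.focal)
    families, _ = build_families(hits)
    pairs = call_duplicate_pairs(families, cohort.focal)
    profiles = match_profiles(pairs, cohort.strains)
    table = match_distribution(profiles, sorted(cohort.strains))
    assert (table["2"] == len(pairs)).all()        # all mass at exactly 2
    assert len(common_pairs(profiles)) == len(pairs)


def test_planted_retention_recovered(mini_cohort, mini_report):
    """Strain match counts equal the number of surviving planted copies."""
    profiles = {p.pair_id: p for p in mini_report.profiles}
    truth = mini_report.truth
    for _, row in truth[truth["duplicated"]].iterrows():
        pid = "|".join(sorted(row["loci"].split(",")))
        if pid not in profiles:
            continue
        for s in ("S1", "S2", "S3"):
            planted = 0 if not row[f"loci_{s}"] else len(row[f"loci_{s}"].split(","))
            assert profiles[pid].counts[s] == planted


# --- HGT overlap -------------------------------------------------------------

def _bundle():
    return GenomeBundle("S", {"c1": Replicon("c1", "chromosome", 1000),
                              "c2": Replicon("c2", "chromosome", 400)}, [])


def test_merge_intervals_and_idempotence():
    merged = hgt_overlap.merge_intervals([(0, 100), (50, 150), (300, 310)])
    assert merged == [(0, 150), (300, 310)]
    assert hgt_overlap.merge_intervals(merged) == merged


def test_read_bed_empty_and_clipping(tmp_path):
    empty = tmp_path / "empty.bed"
    empty.write_text("")
    assert hgt_overlap.read_bed(empty, _bundle()).intervals == {}

    bed = tmp_path / "x.bed"
    bed.write_text("c1\t0\t100\nc1\t50\t150\nc2\t350\t999\n")
    with pytest.warns(UserWarning, match="clipped"):
        iv = hgt_overlap.read_bed(bed, _bundle())
    assert iv.intervals["c1"] == [(0, 150)]
    assert iv.intervals["c2"] == [(350, 400)]

    bad = tmp_path / "bad.bed"
    bad.write_text("nope\t0\t10\n")
    with pytest.raises(ValueError, match="unknown replicon"):
        hgt_overlap.read_bed(bad, _bundle())


def test_replicon_coverage_fractions():
    iv = hgt_overlap.IntervalSet({"c1": [(0, 500)], "c2": [(0, 400)]})
    cov = hgt_overlap.replicon_coverage(iv, _bundle())
    assert cov["c1"] == (500, 0.5)
    assert cov["c2"] == (400, 1.0)


def test_coverage_matches_bitmap_oracle(rng):
    bundle = _bundle()
    raw = [(int(a), int(a) + int(b))
           for a, b in zip(rng.integers(0, 900, 20), rng.integers(1, 100, 20))]
    raw = [(s, min(e, 1000)) for s, e in raw]
    iv = hgt_overlap.IntervalSet({"c1": hgt_overlap.merge_intervals(raw)})
    bitmap = np.zeros(1000, dtype=bool)
    for s, e in raw:
        bitmap[s:e] = True
    assert iv.total_bp("c1") == int(bitmap.sum())


def _gene(locus, start, end, rid="c1"):
    return GeneRecord(locus, "S", rid, "chromosome", start, end, "+",
                      frozenset(), "MA", "ATGGCT")


def test_genes_in_regions_boundary_rules():
    iv = hgt_overlap.IntervalSet({"c1": [(100, 200)]})
    inside = _gene("in", 150, 160)
    abutting = _gene("abut", 201, 210)     # starts exactly at interval end
    one_base = _gene("edge", 200, 205)     # 1-based 200 = 0-based 199, overlaps 1 nt
    genes = [inside, abutting, one_base]
    got, _ = hgt_overlap.genes_in_regions(iv, genes)
    assert got == ["in", "edge"]


def test_duplicated_genes_inside_subset():
    iv = hgt_overlap.IntervalSet({"c1": [(0, 300)]})
    g1, g2, g3 = _gene("a", 10, 20), _gene("b", 30, 40), _gene("c", 500, 600)
    pair = DuplicatePair(g1, g3, 80.0, "CI-CI")
    inside, dup_inside = hgt_overlap.genes_in_regions(iv, [g1, g2, g3], [pair])
    assert inside == ["a", "b"]
    assert dup_inside == ["a"]
    assert set(dup_inside) <= set(inside)


def test_planted_hgt_genes_recovered(mini_cohort):
    iv = hgt_overlap.IntervalSet(mini_cohort.hgt_intervals)
    inside, _ = hgt_overlap.genes_in_regions(iv, mini_cohort.focal.genes)
    planted = set()
    for flags in mini_cohort.truth["hgt_loci"]:
        planted.update(l for l in flags.split(",") if l)
    assert set(inside) == planted
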