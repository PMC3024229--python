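import math
from functools import lru_cache

import numpy as np
import pytest

from dupcensus.genome_io import GeneRecord, GenomeBundle, Replicon, translate_cds
from dupcensus.homology import (
    KarlinAltschulParams,
    ScoringScheme,
    _load_matrix,
    align_global,
    all_vs_all,
    build_families,
    call_duplicate_pairs,
    evalue,
    location_class,
)
from dupcensus.synthetic_data import SimConfig, simulate_cohort


def brute_force_score(a, b, matrix_name="BLOSUM62", open_=11.0, ext=1.0):
    """Exhaustive optimum over all global alignments (gap of length k costs open+k*ext)."""
    alphabet, mat = _load_matrix(matrix_name)
    idx = {c: i for i, c in enumerate(alphabet)}

    @lru_cache(maxsize=None)
    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, mat[idx[a[i]], idx[b[j]]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            best = max(best, -(ext if prev == "X" else open_ + ext) + rec(i + 1, j, "X"))
        if j < len(b):
            best = max(best, -(ext if prev == "Y" else open_ + ext) + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "S")


def test_align_identity_scores_blosum_diagonal():
    r = align_global("MKV", "MKV")
    assert r.percent_identity == 100.0
    assert r.score == 5 + 5 + 4  # BLOSUM62 M,K,V diagonal


def test_align_single_mismatch_column():
    r = align_global("M", "K")
    assert r.aligned_cols == 1
    assert r.percent_identity == 0.0


def test_align_matches_brute_force_on_short_sequences(rng):
    aa = "ACDE"
    for _ in range(60):
        a = "".join(rng.choice(list(aa), rng.integers(1, 7)))
        b = "".join(rng.choice(list(aa), rng.integers(1, 7)))
        assert align_global(a, b).score == pytest.approx(brute_force_score(a, b))


def test_align_ungapping_recovers_inputs(rng):
    aa = "ARNDCQEGHILKMFPSTWYV"
    for _ in range(10):
        a = "".join(rng.choice(list(aa), rng.integers(5, 40)))
        b = "".join(rng.choice(list(aa), rng.integers(5, 40)))
        r = align_global(a, b)
        assert r.aligned_query.replace("-", "") == a
        assert r.aligned_subject.replace("-", "") == b


def test_align_rejects_unknown_symbol():
    with pytest.raises(ValueError, match="absent"):
        align_global("M1K", "MKV")


def test_evalue_closed_form_and_scaling():
    params = KarlinAltschulParams(0.267, 0.041)
    direct = 0.041 * 300 * 300 * math.exp(-0.267 * 100)
    assert evalue(100, 300, 300, params) == pytest.approx(direct, rel=1e-12)
    assert evalue(100, 300, 600, params) == pytest.approx(2 * direct, rel=1e-12)
    assert evalue(1e6, 300, 300, params) == 0.0
    assert evalue(200, 300, 300, params) < evalue(100, 300, 300, params)


def _gene(locus, prot_seq_cds, replicon="chr1", rclass="chromosome"):
    return GeneRecord(locus, "S", replicon, rclass, 1, len(prot_seq_cds), "+",
                      frozenset(), translate_cds(prot_seq_cds), prot_seq_cds)


def _bundle(genes, replicons=None):
    replicons = replicons or {"chr1": Replicon("chr1", "chromosome", 10_000)}
    return GenomeBundle("S", replicons, genes)


def test_all_vs_all_exact_duplicate_both_directions(rng):
    from dupcensus.synthetic_data import CodonEvolver
    ev = CodonEvolver(2.0, 0.2)
    cds = ev.sample_root(150, rng)
    other = ev.sample_root(150, rng)
    bundle = _bundle([_gene("a", cds), _gene("b", cds), _gene("c", other)])
    hits = all_vs_all(bundle)
    directed = {(h.query_id, h.subject_id) for h in hits}
    assert ("a", "b") in directed and ("b", "a") in directed
    assert not any("c" in pair for pair in directed)  # unrelated random protein


def test_all_vs_all_impossible_identity_threshold(rng):
    from dupcensus.synthetic_data import CodonEvolver
    cds = CodonEvolver(2.0, 0.2).sample_root(100, rng)
    bundle = _bundle([_gene("a", cds), _gene("b", cds)])
    assert all_vs_all(bundle, id_min=101) == []


def test_build_families_reciprocal_pair_and_chain():
    from dupcensus.homology import HomologyHit
    mk = lambda q, s: HomologyHit(q, s, 100.0, 50.0, 1e-30)
    fams, hist = build_families([mk("a", "b"), mk("b", "a")])
    assert len(fams) == 1 and fams[0].copy_number == 2
    assert hist == {"2": 1, "3": 0, "4": 0, ">=5": 0}
    # chain rule: a-b and b-c reciprocal, a-c not -> one 3-member component
    fams, hist = build_families(
        [mk("a", "b"), mk("b", "a"), mk("b", "c"), mk("c", "b"), mk("a", "c")])
    assert len(fams) == 1 and fams[0].copy_number == 3
    assert hist["3"] == 1


def test_planted_copy_number_histogram_recovered():
    plan = (2,) * 10 + (3,) * 2 + (5,)
    cohort = simulate_cohort(SimConfig(
        n_families=13, copy_number_plan=plan, n_codons=200,
        strain_names=(), n_hgt_intervals=0, master_seed=3))
    hits = all_vs_all(cohort.focal)
    _, hist = build_families(hits)
    assert hist == {"2": 10, "3": 2, "4": 0, ">=5": 1}


def test_pair_recall_and_precision_on_simulated_cohort():
    """At <=40% planted divergence, every true pair and nothing else is called."""
    cohort = simulate_cohort(SimConfig(
        n_families=20, frac_duplicated=0.5, n_codons=150,
        t_pre_dup=0.2, t_post_dup=0.2, t_species=0.4,
        strain_names=(), n_hgt_intervals=0, master_seed=5))
    hits = all_vs_all(cohort.focal)
    families, _ = build_families(hits)
    pairs = call_duplicate_pairs(families, cohort.focal)
    called = {frozenset(p.pair_id.split("|")) for p in pairs}
    truth = {frozenset(row["loci"].split(","))
             for _, row in cohort.truth.iterrows() if row["duplicated"]}
    assert called == truth  # recall 1.0 and precision 1.0


def test_location_classes():
    reps = {
        "c1": Replicon("c1", "chromosome", 100_000),
        "c2": Replicon("c2", "chromosome", 30_000),
        "p1": Replicon("p1", "plasmid", 10_000),
    }
    g = lambda locus, rid: _gene(locus, "ATGGCT", rid,
                                 "plasmid" if rid.startswith("p") else "chromosome")
    bundle = _bundle([g("a", "c1"), g("b", "c2"), g("c", "p1"), g("d", "c1")],
                     replicons=reps)
    assert location_class(bundle.gene("a"), bundle.gene("d"), bundle) == "CI-CI"
    assert location_class(bundle.gene("a"), bundle.gene("b"), bundle) == "CI-CII"
    assert location_class(bundle.gene("b"), bundle.gene("b"), bundle) == "CII-CII"
    assert location_class(bundle.gene("a"), bundle.gene("c"), bundle) == "C-P"
    assert location_class(bundle.gene("c"), bundle.gene("c"), bundle) == "P-P"


def test_divergence_is_100_minus_identity(mini_report):
    for p in mini_report.pairs:
        assert p.divergence == pytest.approx(100.0 - p.percent_identity)


def test_forced_pairs_and_empty():
    cds1, cds2 = "ATGGCTAAAGCT", "ATGCTGGAAGGG"
    bundle = _bundle([_gene("a", cds1), _gene("b", cds2)])
    assert call_duplicate_pairs([], bundle) == []
    forced = call_duplicate_pairs([], bundle, forced_pairs=[("a", "b")])
    assert len(forced) == 1 and forced[0].forced
    with pytest.raises(ValueError, match="unknown locus"):
        call_duplicate_pairs([], bundle, forced_pairs=[("a", "zz")])
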