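import math

import numpy as np
import pytest

from dupcensus.genome_io import GeneRecord
from dupcensus.homology import DuplicatePair
from dupcensus.quartet_phylo import (
    TOPOLOGIES,
    QuartetResult,
    align_quartet,
    bootstrap_support,
    classify_topology,
    fit_quartet,
    quartet_loglik,
    select_orthologs,
    wag_model,
)
from dupcensus.wag import AA_ORDER


def brute_force_loglik(msa, topology, bl, model):
    """Sum over both internal nodes' state pairs (400 terms per site)."""
    (a, b), (c, d) = topology
    P = [model.p_matrix(t) for t in bl[:4]]
    Pint = model.p_matrix(bl[4])
    idx = {ch: i for i, ch in enumerate(AA_ORDER)}
    total = 0.0
    for site in range(len(msa[0])):
        s = [idx[row[site]] for row in msa]
        like = 0.0
        for x in range(20):
            for y in range(20):
                like += (model.pi[x] * P[a][x, s[a]] * P[b][x, s[b]]
                         * Pint[x, y] * P[c][y, s[c]] * P[d][y, s[d]])
        total += math.log(like)
    return total


def test_wag_generator_properties():
    m = wag_model()
    assert np.abs(m.Q.sum(axis=1)).max() < 1e-12
    flux = m.pi[:, None] * m.Q
    assert np.abs(flux - flux.T).max() < 1e-12       # detailed balance
    assert -float(m.pi @ np.diag(m.Q)) == pytest.approx(1.0)  # unit expected rate


def test_pruning_matches_brute_force(rng):
    m = wag_model()
    for case in range(12):
        msa = ["".join(rng.choice(list(AA_ORDER), 2)) for _ in range(4)]
        bl = rng.uniform(0.01, 2.0, 5)
        topo = TOPOLOGIES[case % 3]
        assert quartet_loglik(msa, topo, bl, m) == pytest.approx(
            brute_force_loglik(msa, topo, bl, m), abs=1e-8)


def test_loglik_invariant_to_rerooting(rng):
    m = wag_model()
    msa = ["".join(rng.choice(list(AA_ORDER), 40)) for _ in range(4)]
    bl = rng.uniform(0.01, 1.5, 5)
    ref = quartet_loglik(msa, ((0, 2), (1, 3)), bl, m)
    for topo in (((2, 0), (3, 1)), ((1, 3), (0, 2)), ((3, 1), (2, 0))):
        assert quartet_loglik(msa, topo, bl, m) == pytest.approx(ref, abs=1e-8)


def test_loglik_degenerate_zero_branches():
    m = wag_model()
    msa = ["MKV"] * 4
    expected = sum(math.log(m.pi[AA_ORDER.index(c)]) for c in "MKV")
    assert quartet_loglik(msa, TOPOLOGIES[0], [0.0] * 5, m) == pytest.approx(expected)


def test_all_gap_column_skipped_with_warning():
    m = wag_model()
    msa = ["M-K", "M-K", "M-K", "M-K"]
    with pytest.warns(UserWarning, match="all-gap"):
        l = quartet_loglik(msa, TOPOLOGIES[0], [0.0] * 5, m)
    expected = sum(math.log(m.pi[AA_ORDER.index(c)]) for c in "MK")
    assert l == pytest.approx(expected)


def test_gaps_are_marginalized_not_penalized():
    m = wag_model()
    full = quartet_loglik(["MK", "MK", "MK", "MK"], TOPOLOGIES[0], [0.1] * 5, m)
    with_gap = quartet_loglik(["MK", "MK", "MK", "M-"], TOPOLOGIES[0], [0.1] * 5, m)
    assert with_gap > full  # one fewer observed state can only raise the likelihood


def test_optimized_branch_lengths_are_local_maximum(rng):
    m = wag_model()
    msa = ["".join(rng.choice(list(AA_ORDER), 60)) for _ in range(2)]
    msa = [msa[0], msa[0], msa[1], msa[1]]
    fit = fit_quartet(msa, m)
    topo = TOPOLOGIES[fit.topology_index]
    for k in range(5):
        for delta in (-1e-3, 1e-3):
            bl = fit.branch_lengths.copy()
            bl[k] = min(max(bl[k] + delta, 1e-8), 10.0)
            assert quartet_loglik(msa, topo, bl, m) <= fit.log_likelihood + 1e-5


def test_identical_sequences_tie_breaks_to_type_a():
    fit = fit_quartet(["MKVA" * 10] * 4)
    assert fit.tied
    assert fit.topology_index == 0  # first Type-A topology wins ties
    assert fit.call == "TypeA"


@pytest.mark.parametrize("topo_index,expected", [(0, "TypeA"), (1, "TypeA"), (2, "TypeB")])
def test_classify_topology_mapping(topo_index, expected):
    r = QuartetResult("p", topo_index, np.zeros(5), 0.0,
                      "TypeB" if topo_index == 2 else "TypeA")
    assert classify_topology(r) == expected


# --- ortholog selection ----------------------------------------------------

def _gene(locus, prot):
    cds = "".join({"M": "ATG", "K": "AAA", "V": "GTT", "A": "GCT", "L": "CTG",
                   "E": "GAA", "D": "GAT", "R": "CGT"}[c] for c in prot)
    return GeneRecord(locus, "S", "c1", "chromosome", 1, len(cds), "+",
                      frozenset(), prot, cds)


def _pair(pa, pb):
    return DuplicatePair(_gene("pa", pa), _gene("pb", pb), 50.0, "CI-CI")


def _db_entry(oid, sp, seq):
    return (oid, sp, seq)


def test_select_orthologs_distinct_best_hits():
    base_a, base_b = "MKVALEDR" * 8, "MKVALEDM" * 8
    db = [_db_entry("x1", "spX", base_a), _db_entry("x2", "spX", base_b)]
    choice = select_orthologs(_pair(base_a, base_b), db, e_max=10.0, id_min=0.0)
    assert choice.resolved and not choice.same_best_resolved
    assert choice.assignments["pa"][0] == "x1"
    assert choice.assignments["pb"][0] == "x2"


def test_select_orthologs_shared_best_triggers_tie_break():
    seq = "MKVALEDR" * 8
    near = "MKVALEDR" * 7 + "MKVALEDM"   # best for both, slightly closer to pa
    far = "MKVALEDM" * 6 + "MKVALEDR" * 2
    db = [_db_entry("best", "spX", seq), _db_entry("alt", "spY", far)]
    choice = select_orthologs(_pair(seq, near), db, e_max=10.0, id_min=0.0)
    assert choice.resolved and choice.same_best_resolved
    assert choice.assignments["pa"][0] == "best"   # stronger paralog keeps the shared hit
    assert choice.assignments["pb"][0] == "alt"


def test_select_orthologs_unresolvable_cases():
    seq = "MKVALEDR" * 8
    assert not select_orthologs(_pair(seq, seq), [], e_max=10.0).resolved
    db = [_db_entry("only", "spX", seq)]
    choice = select_orthologs(_pair(seq, seq), db, e_max=10.0, id_min=0.0)
    assert not choice.resolved and choice.same_best_resolved


# --- quartet alignment -----------------------------------------------------

def test_align_quartet_identical_sequences_gap_free():
    msa = align_quartet(["MKVALEDR" * 5] * 4)
    assert all("-" not in row for row in msa)
    assert len({len(r) for r in msa}) == 1


def test_align_quartet_round_trip(rng):
    seqs = ["".join(rng.choice(list(AA_ORDER), rng.integers(20, 40)))
            for _ in range(4)]
    msa = align_quartet(seqs)
    for row, seq in zip(msa, seqs):
        assert row.replace("-", "") == seq
    assert len({len(r) for r in msa}) == 1
    assert len(msa[0]) >= max(len(s) for s in seqs)


def test_align_quartet_beats_random_column_arrangements(rng):
    from dupcensus.homology import _load_matrix
    alphabet, mat = _load_matrix("BLOSUM62")
    idx = {c: i for i, c in enumerate(alphabet)}

    def sp_score(msa):
        total = 0.0
        for col in zip(*msa):
            residues = [c for c in col if c != "-"]
            for i in range(len(residues)):
                for j in range(i + 1, len(residues)):
                    total += mat[idx[residues[i]], idx[residues[j]]]
        return total

    seqs = ["".join(rng.choice(list("ACDE"), rng.integers(4, 9))) for _ in range(4)]
    ours = sp_score(align_quartet(seqs))
    width = max(len(s) for s in seqs) + 2
    for _ in range(50):
        msa = []
        for s in seqs:
            pos = sorted(rng.choice(width, size=len(s), replace=False))
            row = ["-"] * width
            for p, ch in zip(pos, s):
                row[p] = ch
            msa.append("".join(row))
        assert ours >= sp_score(msa)


# --- bootstrap --------------------------------------------------------------

def test_bootstrap_support_determinism_and_n1():
    msa = ["MKVLMKVL" * 6, "MKVLMKVL" * 6, "MKALMRVL" * 6, "MKALMRVL" * 6]
    fit = fit_quartet(msa)
    s1 = bootstrap_support(msa, n=20, seed=7, full_fit=fit)
    s2 = bootstrap_support(msa, n=20, seed=7, full_fit=fit)
    assert s1 == s2
    assert bootstrap_support(msa, n=1, seed=3, full_fit=fit) in (0.0, 100.0)
    with pytest.raises(ValueError):
        bootstrap_support(msa, n=0)


def test_bootstrap_high_support_for_long_internal_branch(rng):
    from dupcensus.synthetic_data import CodonEvolver
    from dupcensus.genome_io import translate_cds
    ev = CodonEvolver(2.0, 0.5)
    root = ev.sample_root(300, rng)
    anc1, anc2 = ev.evolve(root, 0.8, rng), ev.evolve(root, 0.8, rng)
    msa = [translate_cds(ev.evolve(anc, 0.3, rng))
           for anc in (anc1, anc1, anc2, anc2)]
    fit = fit_quartet(msa)
    assert fit.call == "TypeB"
    assert bootstrap_support(msa, n=100, seed=1, full_fit=fit) >= 95.0
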