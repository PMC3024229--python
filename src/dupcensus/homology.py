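"""Protein homology search, homolog families, and duplicate-pair calling.

The search mirrors a two-step reciprocal protein-similarity protocol:
every protein is aligned against every other protein of the same genome
(exact global affine-gap alignment, not a heuristic seeded search), hits are
filtered on E-value and percent identity, an edge is kept only when it passes
the thresholds in *both* directions, and homolog families are the connected
components of the resulting reciprocal graph. Two-copy families become
duplicate gene pairs; curated pairs below threshold can be forced in.

Scoring defaults follow gapped BLASTP: BLOSUM62, gap open 11, gap extend 1
(a gap of length k costs open + k*extend). E-values use the Karlin-Altschul
form E = K*m*n*exp(-lambda*score) with the published gapped BLOSUM62
constants; they are reported for thresholding, not re-estimated empirically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .genome_io import GeneRecord, GenomeBundle

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11, extend 1).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

DEFAULT_E_MAX = 1e-20
DEFAULT_ID_MIN = 30.0


@dataclass(frozen=True)
class KarlinAltschulParams:
    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka: KarlinAltschulParams = KarlinAltschulParams()


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    aligned_cols: int
    identities: int
    query_len: int
    subject_len: int
    aligned_query: str = ""
    aligned_subject: str = ""

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.aligned_cols


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    percent_identity: float
    evalue: float


@dataclass
class HomologFamily:
    members: frozenset[str]

    @property
    def copy_number(self) -> int:
        return len(self.members)


LOCATION_CLASSES = ("CI-CI", "CI-CII", "CII-CII", "C-P", "P-P")


@dataclass
class DuplicatePair:
    gene_a: GeneRecord
    gene_b: GeneRecord
    percent_identity: float
    location_class: str
    forced: bool = False

    @property
    def pair_id(self) -> str:
        return f"{self.gene_a.locus_tag}|{self.gene_b.locus_tag}"

    @property
    def divergence(self) -> float:
        return 100.0 - self.percent_identity


_MATRIX_CACHE: dict[str, tuple[str, np.ndarray]] = {}


def _load_matrix(name: str) -> tuple[str, np.ndarray]:
    """Return (alphabet, dense score array) for a named substitution matrix."""
    if name not in _MATRIX_CACHE:
        m = substitution_matrices.load(name)
        alphabet = str(m.alphabet)
        _MATRIX_CACHE[name] = (alphabet, np.asarray(m, dtype=np.float64))
    return _MATRIX_CACHE[name]


def _encode(seq: str, alphabet: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    enc = lut[codes]
    if (enc < 0).any():
        bad = sorted({seq[i] for i in np.where(enc < 0)[0]})
        raise ValueError(f"symbols {bad} absent from substitution matrix")
    return enc


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend):  # pragma: no cover - exercised via align_global
    """Fill Gotoh matrices for the pairwise score matrix S (m x n).

    M: last column is a substitution; X: gap in subject (consumes query row);
    Y: gap in query (consumes subject column). Gap of length k costs
    gap_open + k*gap_extend; adjacent opposite-direction gaps are allowed.
    """
    m, n = S.shape
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -gap_open - i * gap_extend
    for j in range(1, n + 1):
        Y[0, j] = -gap_open - j * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + S[i - 1, j - 1]

            open_x = M[i - 1, j]
            if Y[i - 1, j] > open_x:
                open_x = Y[i - 1, j]
            ext_x = X[i - 1, j] - gap_extend
            open_x = open_x - gap_open - gap_extend
            X[i, j] = open_x if open_x > ext_x else ext_x

            open_y = M[i, j - 1]
            if X[i, j - 1] > open_y:
                open_y = X[i, j - 1]
            ext_y = Y[i, j - 1] - gap_extend
            open_y = open_y - gap_open - gap_extend
            Y[i, j] = open_y if open_y > ext_y else ext_y
    return M, X, Y


@njit(cache=True)
def _gotoh_trace(S, M, X, Y, gap_open, gap_extend):  # pragma: no cover
    """Deterministic traceback; ties broken match > gap-in-subject > gap-in-query.

    Returns (ai, bi): 0-based source indices per alignment column, -1 = gap.
    """
    m, n = S.shape
    i, j = m, n
    state = 0
    best = M[i, j]
    if X[i, j] > best:
        state, best = 1, X[i, j]
    if Y[i, j] > best:
        state = 2
    ai = np.empty(m + n, dtype=np.int64)
    bi = np.empty(m + n, dtype=np.int64)
    k = 0
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            ai[k] = i - 1
            bi[k] = j - 1
            target = M[i, j] - S[i - 1, j - 1]
            i -= 1
            j -= 1
            if abs(M[i, j] - target) < eps:
                state = 0
            elif abs(X[i, j] - target) < eps:
                state = 1
            else:
                state = 2
        elif state == 1:
            ai[k] = i - 1
            bi[k] = -1
            val = X[i, j]
            if abs(M[i - 1, j] - gap_open - gap_extend - val) < eps:
                state = 0
            elif abs(Y[i - 1, j] - gap_open - gap_extend - val) < eps:
                state = 2
            else:
                state = 1
            i -= 1
        else:
            ai[k] = -1
            bi[k] = j - 1
            val = Y[i, j]
            if abs(M[i, j - 1] - gap_open - gap_extend - val) < eps:
                state = 0
            elif abs(X[i, j - 1] - gap_open - gap_extend - val) < eps:
                state = 1
            else:
                state = 2
            j -= 1
        k += 1
    return ai[:k][::-1].copy(), bi[:k][::-1].copy()


def align_global(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    query_id: str = "a",
    subject_id: str = "b",
    keep_alignment: bool = True,
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch/Gotoh) alignment with affine gaps.

    Percent identity uses all alignment columns, including gap columns, as
    the denominator; this single identity definition drives both pairing and
    the 100-minus-identity divergence downstream.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    alphabet, mat = _load_matrix(scoring.matrix_name)
    ea, eb = _encode(a, alphabet), _encode(b, alphabet)
    S = mat[ea][:, eb]
    M, X, Y = _gotoh_fill(S, float(scoring.gap_open), float(scoring.gap_extend))
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    ai, bi = _gotoh_trace(S, M, X, Y, float(scoring.gap_open), float(scoring.gap_extend))
    gap_a, gap_b = ai < 0, bi < 0
    same = (~gap_a) & (~gap_b) & (ea[np.maximum(ai, 0)] == eb[np.maximum(bi, 0)])
    ra = rb = ""
    if keep_alignment:
        ra = "".join("-" if g else a[k] for k, g in zip(ai, gap_a))
        rb = "".join("-" if g else b[k] for k, g in zip(bi, gap_b))
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        aligned_cols=len(ai),
        identities=int(same.sum()),
        query_len=len(a),
        subject_len=len(b),
        aligned_query=ra,
        aligned_subject=rb,
    )


def evalue(score: float, m: int, n: int, params: KarlinAltschulParams | None = None) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    params = params or KarlinAltschulParams()
    log_e = math.log(params.K) + math.log(m) + math.log(n) - params.lam * score
    if log_e > 700:
        return math.inf
    return math.exp(log_e)


def all_vs_all(
    bundle: GenomeBundle,
    e_max: float = DEFAULT_E_MAX,
    id_min: float = DEFAULT_ID_MIN,
    scoring: ScoringScheme | None = None,
) -> list[HomologyHit]:
    """All-vs-all within-genome similarity search; self-hits excluded.

    Global alignment is symmetric, so each unordered pair is aligned once and
    reported as two directed hits when it passes both thresholds.
    """
    scoring = scoring or ScoringScheme()
    hits: list[HomologyHit] = []
    genes = bundle.genes
    for ga, gb in itertools.combinations(genes, 2):
        res = align_global(ga.protein_seq, gb.protein_seq, scoring,
                           ga.locus_tag, gb.locus_tag, keep_alignment=False)
        ev = evalue(res.score, len(ga.protein_seq), len(gb.protein_seq), scoring.ka)
        if ev <= e_max and res.percent_identity >= id_min:
            hits.append(HomologyHit(ga.locus_tag, gb.locus_tag, res.score,
                                    res.percent_identity, ev))
            hits.append(HomologyHit(gb.locus_tag, ga.locus_tag, res.score,
                                    res.percent_identity, ev))
    return hits


COPY_CLASSES = ("2", "3", "4", ">=5")


def build_families(hits: list[HomologyHit]) -> tuple[list[HomologFamily], dict[str, int]]:
    """Reciprocal-edge families and the copy-number histogram over {2,3,4,>=5}.

    An undirected edge requires the hit to pass in both directions; families
    are connected components of the reciprocal graph.
    """
    directed = {(h.query_id, h.subject_id) for h in hits}
    g = nx.Graph()
    for q, s in directed:
        if (s, q) in directed:
            g.add_edge(q, s)
    families = sorted(
        (HomologFamily(frozenset(comp)) for comp in nx.connected_components(g)),
        key=lambda f: sorted(f.members),
    )
    histogram = {c: 0 for c in COPY_CLASSES}
    for fam in families:
        n = fam.copy_number
        histogram["2" if n == 2 else "3" if n == 3 else "4" if n == 4 else ">=5"] += 1
    return families, histogram


def location_class(gene_a: GeneRecord, gene_b: GeneRecord, bundle: GenomeBundle) -> str:
    """Classify a pair's genomic arrangement: CI-CI, CI-CII, CII-CII, C-P or P-P."""
    classes = (gene_a.replicon_class, gene_b.replicon_class)
    if classes == ("plasmid", "plasmid"):
        return "P-P"
    if "plasmid" in classes:
        return "C-P"
    ranks = bundle.chromosome_ranks()
    ra, rb = ranks[gene_a.replicon_id], ranks[gene_b.replicon_id]
    if ra == rb:
        return f"{ra}-{ra}"
    lo, hi = sorted((ra, rb), key=lambda r: (len(r), r))
    return f"{lo}-{hi}"


def call_duplicate_pairs(
    families: list[HomologFamily],
    bundle: GenomeBundle,
    forced_pairs: list[tuple[str, str]] | None = None,
    scoring: ScoringScheme | None = None,
) -> list[DuplicatePair]:
    """One DuplicatePair per two-copy family, plus curated sub-threshold pairs."""
    scoring = scoring or ScoringScheme()
    pairs: list[DuplicatePair] = []
    seen: set[frozenset[str]] = set()
    for fam in families:
        if fam.copy_number != 2:
            continue
        la, lb = sorted(fam.members)
        ga, gb = bundle.gene(la), bundle.gene(lb)
        res = align_global(ga.protein_seq, gb.protein_seq, scoring, la, lb)
        pairs.append(DuplicatePair(ga, gb, res.percent_identity,
                                   location_class(ga, gb, bundle)))
        seen.add(fam.members)
    for la, lb in forced_pairs or []:
        try:
            ga, gb = bundle.gene(la), bundle.gene(lb)
        except KeyError as exc:
            raise ValueError(f"forced pair references unknown locus: {exc}") from exc
        if frozenset((la, lb)) in seen:
            continue
        res = align_global(ga.protein_seq, gb.protein_seq, scoring, la, lb)
        pairs.append(DuplicatePair(ga, gb, res.percent_identity,
                                   location_class(ga, gb, bundle), forced=True))
    return pairs
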