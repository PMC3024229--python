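"""Codon-level functional-constraint analysis: Ka/Ks, omega, and cross-strain ANOVA.

Two estimators are provided:

* ``kaks_ng86`` - the classical Nei-Gojobori (1986) counting scheme: equal
  mutation weights, exhaustive averaging over shortest mutational pathways,
  Jukes-Cantor multiple-hit correction. Simple and assumption-light; it is
  the package's independent reference estimator.
* ``kaks_myn`` - the headline method: a modified Yang-Nielsen-style counting
  estimator that estimates the transition/transversion ratio kappa from the
  data, weights synonymous/nonsynonymous site counting by kappa and observed
  nucleotide frequencies, and corrects distances per site class with the
  Kimura two-parameter (HKY-style transition/transversion-aware) formula.

omega = Ka/Ks is interpreted against the conventional landmarks omega = 0.3,
1 and 3 for purifying, neutral and positive selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import CODON_TO_AA, STOP_CODONS

PURIFYING_MARK = 0.3
NEUTRAL_MARK = 1.0
POSITIVE_MARK = 3.0

_NT = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """Raised when a p-distance exceeds the correctable range."""


@dataclass
class CodonAlignment:
    """A gapless-by-codon pairwise nucleotide alignment (gap codons removed)."""

    seq_a: str
    seq_b: str
    n_dropped_codons: int = 0

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b) or len(self.seq_a) % 3 != 0:
            raise ValueError("codon alignment rows must be equal length, multiple of 3")
        for seq in (self.seq_a, self.seq_b):
            for i in range(0, len(seq), 3):
                if seq[i:i + 3] in STOP_CODONS:
                    raise ValueError(f"stop codon at position {i + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> list[tuple[str, str]]:
        return [(self.seq_a[i:i + 3], self.seq_b[i:i + 3])
                for i in range(0, len(self.seq_a), 3)]


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    omega: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    method: str
    kappa_hat: float | None = None
    saturated: bool = False

    @property
    def label(self) -> str:
        return classify_selection(self.omega)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: list[float]
    group_sds: list[float]
    pooled_sd: float


def backtranslate_pair(
    prot_aln: tuple[str, str], cds_a: str, cds_b: str
) -> CodonAlignment:
    """Map an aligned protein pair back onto its source codons.

    Each aligned residue is replaced by its source codon; columns where either
    row is a gap are dropped. The ungapped protein rows must translate exactly
    from the CDSs (terminal stop codons in the CDS are ignored).
    """
    from .genome_io import translate_cds

    row_a, row_b = prot_aln
    if len(row_a) != len(row_b):
        raise ValueError("aligned protein rows differ in length")
    for row, cds, name in ((row_a, cds_a, "a"), (row_b, cds_b, "b")):
        prot = row.replace("-", "")
        if translate_cds(cds) != prot:
            for i, (x, y) in enumerate(zip(translate_cds(cds), prot)):
                if x != y:
                    raise ValueError(
                        f"sequence {name}: CDS translation mismatch at residue {i + 1}"
                    )
            raise ValueError(f"sequence {name}: CDS/protein length mismatch")
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    dropped = 0
    for ca, cb in zip(row_a, row_b):
        codon_a = cds_a[3 * ia:3 * ia + 3] if ca != "-" else None
        codon_b = cds_b[3 * ib:3 * ib + 3] if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if codon_a is None or codon_b is None:
            dropped += 1
            continue
        out_a.append(codon_a)
        out_b.append(codon_b)
    return CodonAlignment("".join(out_a), "".join(out_b), n_dropped_codons=dropped)


def _aa(codon: str) -> str:
    return CODON_TO_AA[codon]


def _site_counts(codon: str, weight) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one codon.

    ``weight(pos, alt, is_transition)`` weights each possible point mutation;
    mutations to stop codons are excluded and each position contributes one
    site in total, so S + N = 3 per codon.
    """
    s = n = 0.0
    for pos in range(3):
        ws = wn = 0.0
        for alt in _NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            w = weight(pos, alt, (codon[pos], alt) in _TRANSITIONS)
            if _aa(mutant) == _aa(codon):
                ws += w
            else:
                wn += w
        tot = ws + wn
        if tot > 0:
            s += ws / tot
            n += wn / tot
        # A position with no viable non-stop mutation contributes no sites.
    return s, n


def _pathway_differences(ca: str, cb: str) -> tuple[float, float, float, float]:
    """Average (Sd_ts, Sd_tv, Nd_ts, Nd_tv) over shortest mutational pathways.

    Pathways passing through a stop codon are excluded and the remaining
    pathways re-weighted equally; if every pathway is blocked, all pathways
    are used (degenerate case).
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0, 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            syn = _aa(nxt) == _aa(cur)
            ts = (cur[pos], cb[pos]) in _TRANSITIONS
            steps.append((syn, ts))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:
        for order in itertools.permutations(diff_pos):
            cur = ca
            steps = []
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                syn = (nxt not in STOP_CODONS and cur not in STOP_CODONS
                       and _aa(nxt) == _aa(cur))
                ts = (cur[pos], cb[pos]) in _TRANSITIONS
                steps.append((syn, ts))
                cur = nxt
            paths.append(steps)
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    for steps in paths:
        for syn, ts in steps:
            if syn and ts:
                sd_ts += 1
            elif syn:
                sd_tv += 1
            elif ts:
                nd_ts += 1
            else:
                nd_tv += 1
    k = len(paths)
    return sd_ts / k, sd_tv / k, nd_ts / k, nd_tv / k


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"p-distance {p:.3f} >= 3/4, JC correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _kimura2p(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("transition/transversion proportions beyond K2P range")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def kaks_ng86(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction."""
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    s_a = n_a = s_b = n_b = 0.0
    unit = lambda pos, alt, ts: 1.0
    sd = nd = 0.0
    for ca, cb in aln.codon_pairs():
        sa, na = _site_counts(ca, unit)
        sb, nb = _site_counts(cb, unit)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        d = _pathway_differences(ca, cb)
        sd += d[0] + d[1]
        nd += d[2] + d[3]
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    ka = ks = None
    saturated = False
    try:
        ks = _jukes_cantor(sd / S) if S > 0 else None
    except SaturationError:
        saturated = True
    try:
        ka = _jukes_cantor(nd / N) if N > 0 else None
    except SaturationError:
        saturated = True
    omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(ka=ka, ks=ks, omega=omega, S=S, N=N, Sd=sd, Nd=nd,
                      method="NG86", saturated=saturated)


def _degeneracy(codon: str, pos: int) -> int:
    """0 = nondegenerate (all changes nonsynonymous), 4 = fourfold, else 2."""
    syn = nonsyn = 0
    for alt in _NT:
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1:]
        if mutant in STOP_CODONS:
            nonsyn += 1
            continue
        if _aa(mutant) == _aa(codon):
            syn += 1
        else:
            nonsyn += 1
    if syn == 3:
        return 4
    if syn == 0:
        return 0
    return 2


def _kappa_from_class(ts: float, tv: float, n: float) -> float | None:
    """K80 transition/transversion rate ratio from one site class."""
    if n < 10:
        return None
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return None
    a = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    b = -0.25 * math.log(w2)
    if b <= 0 or a <= 0:
        return None
    return a / b


def _estimate_kappa(aln: CodonAlignment) -> float:
    """Transition/transversion rate ratio, kappa.

    Within fourfold-degenerate sites every change is synonymous and within
    nondegenerate sites every change is nonsynonymous, so inside either class
    the observed transition/transversion pattern reflects the mutational
    kappa undistorted by selection. K80 estimates from the two classes are
    combined, weighted by site counts.
    """
    counts = {0: [0.0, 0.0, 0.0], 4: [0.0, 0.0, 0.0]}  # class -> [ts, tv, n]
    for ca, cb in aln.codon_pairs():
        for pos in range(3):
            da, db = _degeneracy(ca, pos), _degeneracy(cb, pos)
            if da != db or da == 2:
                continue
            c = counts[da]
            c[2] += 1
            if ca[pos] != cb[pos]:
                if (ca[pos], cb[pos]) in _TRANSITIONS:
                    c[0] += 1
                else:
                    c[1] += 1
    ests = []
    weights = []
    for cls in (0, 4):
        ts, tv, n = counts[cls]
        k = _kappa_from_class(ts, tv, n)
        if k is not None:
            ests.append(k)
            weights.append(n)
    if not ests:
        return 1.0
    kappa = float(np.average(ests, weights=weights))
    return float(min(max(kappa, 0.1), 20.0))


def _position_freqs(aln: CodonAlignment) -> np.ndarray:
    """Nucleotide frequencies per codon position, pooled over both rows (3x4)."""
    freqs = np.zeros((3, 4))
    lut = {c: i for i, c in enumerate(_NT)}
    for seq in (aln.seq_a, aln.seq_b):
        for i, ch in enumerate(seq):
            freqs[i % 3, lut[ch]] += 1.0
    return freqs / freqs.sum(axis=1, keepdims=True)


def kaks_myn(aln: CodonAlignment) -> KaKsResult:
    """Modified Yang-Nielsen-style Ka/Ks: kappa- and frequency-aware counting.

    kappa is estimated from fourfold-degenerate sites; synonymous and
    nonsynonymous site opportunities are weighted by kappa and the observed
    position-specific nucleotide frequencies; pathway-averaged differences are
    split into transitions and transversions and corrected per site class
    with the Kimura two-parameter formula. Collapses to NG86 when kappa = 1
    and frequencies are uniform.
    """
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    kappa = _estimate_kappa(aln)
    freqs = _position_freqs(aln)
    lut = {c: i for i, c in enumerate(_NT)}

    def weight(pos, alt, ts):
        return (kappa if ts else 1.0) * freqs[pos, lut[alt]]

    s_a = n_a = s_b = n_b = 0.0
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    for ca, cb in aln.codon_pairs():
        sa, na = _site_counts(ca, weight)
        sb, nb = _site_counts(cb, weight)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        d = _pathway_differences(ca, cb)
        sd_ts += d[0]; sd_tv += d[1]; nd_ts += d[2]; nd_tv += d[3]
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    ka = ks = None
    saturated = False
    try:
        ks = _kimura2p(sd_ts / S, sd_tv / S) if S > 0 else None
    except SaturationError:
        saturated = True
    try:
        ka = _kimura2p(nd_ts / N, nd_tv / N) if N > 0 else None
    except SaturationError:
        saturated = True
    omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(ka=ka, ks=ks, omega=omega, S=S, N=N,
                      Sd=sd_ts + sd_tv, Nd=nd_ts + nd_tv,
                      method="MYN", kappa_hat=kappa, saturated=saturated)


def classify_selection(omega: float | None) -> str:
    """Label omega against the 0.3 / 1 / 3 selection landmarks."""
    if omega is None:
        return "undefined"
    if omega <= PURIFYING_MARK:
        return "purifying"
    if omega >= POSITIVE_MARK:
        return "positive"
    return "neutral_zone"


def anova_oneway(groups: list[list[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with pooled standard deviation.

    Used to test whether omega distributions differ between strains. With zero
    within-group variance and equal means, F is defined as 0.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = len(arrs) - 1
    df_within = len(all_vals) - len(arrs)
    # guard against float noise when observations are (nearly) constant
    eps = 1e-12 * len(all_vals) * (abs(grand) + 1.0) ** 2
    if ss_within <= eps:
        F = 0.0 if ss_between <= eps else math.inf
        ss_within = 0.0
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within)) if math.isfinite(F) else 0.0
    pooled_sd = math.sqrt(ss_within / df_within)
    return AnovaResult(
        F=float(F), df_between=df_between, df_within=df_within, p=p,
        group_means=[float(a.mean()) for a in arrs],
        group_sds=[float(a.std(ddof=1)) for a in arrs],
        pooled_sd=pooled_sd,
    )
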