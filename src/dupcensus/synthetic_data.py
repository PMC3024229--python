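"""Synthetic multi-replicon genomes with duplications of known age class.

The generator emulates the study system end to end: a focal bacterial strain
with two chromosomes and a plasmid, two-copy gene families that duplicated
either *before* the speciation that separated the focal lineage from its
ortholog-bearing relatives (true Type-A) or *after* it (true Type-B), codon
sequences evolved under a GY94-style Markov process (rate proportional to
pi_codon * kappa^transition * omega^nonsynonymous, stop codons inaccessible),
three related strains with configurable per-copy gene loss, an ortholog
database of two outgroup species, and optional planted HGT intervals.

Age classes are generated structurally, by event order on the gene tree, not
by target topology, so downstream topology recovery is a genuine test. All
randomness flows from one master seed; the same seed yields byte-identical
bundles and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    COG_GENERAL_GROUPS,
    SENSE_CODONS,
    GeneRecord,
    GenomeBundle,
    Replicon,
    translate_cds,
    write_bundle,
    write_fasta,
)

_NT = "ACGT"
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_GROUP_LETTERS = {g: sorted(c for c, gg in COG_GENERAL_GROUPS.items() if gg == g)
                  for g in (1, 2, 3, 4)}


class CodonEvolver:
    """GY94-style codon substitution process over the 61 sense codons.

    The generator is normalized to one expected substitution per codon site,
    so ``t`` is in expected codon substitutions/site. Endpoint states are
    sampled exactly from P(t) = e^{Qt} via spectral decomposition (the model
    is reversible, so the symmetrized generator has a real spectrum).
    """

    def __init__(self, kappa: float, omega: float, codon_freqs: np.ndarray | None = None):
        n = len(SENSE_CODONS)
        pi = (np.full(n, 1.0 / n) if codon_freqs is None
              else np.asarray(codon_freqs, dtype=float))
        pi = pi / pi.sum()
        from .genome_io import CODON_TO_AA
        Q = np.zeros((n, n))
        for i, ci in enumerate(SENSE_CODONS):
            for pos in range(3):
                for alt in _NT:
                    if alt == ci[pos]:
                        continue
                    cj = ci[:pos] + alt + ci[pos + 1:]
                    j = _CODON_INDEX.get(cj)
                    if j is None:  # stop codon, inaccessible
                        continue
                    rate = pi[j]
                    if (ci[pos], alt) in _TRANSITION:
                        rate *= kappa
                    if CODON_TO_AA[ci] != CODON_TO_AA[cj]:
                        rate *= omega
                    Q[i, j] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(pi @ np.diag(Q))
        Q /= scale
        self.pi = pi
        self.kappa = kappa
        self.omega = omega
        sqrt_pi = np.sqrt(pi)
        B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]
        self._right = (evecs * sqrt_pi[:, None]).T

    def p_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def sample_root(self, n_codons: int, rng: np.random.Generator) -> str:
        idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=self.pi)
        return "".join(SENSE_CODONS[i] for i in idx)

    def evolve(self, seq: str, t: float, rng: np.random.Generator) -> str:
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return seq
        idx = np.array([_CODON_INDEX[seq[i:i + 3]] for i in range(0, len(seq), 3)])
        cum = np.cumsum(self.p_matrix(t)[idx], axis=1)
        u = rng.random(len(idx))
        new = (cum < u[:, None]).sum(axis=1)
        np.clip(new, 0, len(SENSE_CODONS) - 1, out=new)
        return "".join(SENSE_CODONS[i] for i in new)


def evolve_codon_seq(seq: str, t: float, kappa: float, omega: float,
                     seed: int | np.random.Generator = 0) -> str:
    """Evolve a stop-free CDS for time ``t`` under the GY94-style process."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return CodonEvolver(kappa, omega).evolve(seq, t, rng)


def gc_biased_codon_freqs(gc: float) -> np.ndarray:
    """Equilibrium codon frequencies for a genome with the given GC content."""
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS])
    return w / w.sum()


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Times are expected codon substitutions per codon site along one lineage.
    The defaults emulate the study regime: ~77% of duplications predate the
    speciation, strong purifying selection (mean omega 0.13), two chromosomes
    and a plasmid in genome-size-like proportions, and appreciable per-strain
    copy loss.
    """

    n_families: int = 50
    frac_duplicated: float = 0.5
    p_pre_speciation: float = 0.77
    n_codons: int = 300
    # branch lengths
    t_pre_dup: float = 0.6    # duplication -> speciation segment (ancient dups)
    t_post_dup: float = 0.3   # duplication -> present (recent dups)
    t_species: float = 0.8    # speciation -> present, per lineage
    t_strain: float = 0.05    # focal strain radiation depth
    # codon model
    kappa: float = 2.0
    omega_mean: float = 0.13
    omega_sd: float = 0.033
    gc_content: float | None = None  # None = uniform codon frequencies
    # genome layout: (replicon_id, class, placement probability)
    replicon_layout: tuple[tuple[str, str, float], ...] = (
        ("CI", "chromosome", 0.67),
        ("CII", "chromosome", 0.20),
        ("pA", "plasmid", 0.13),
    )
    strain_names: tuple[str, ...] = ("S1", "S2", "S3")
    copy_loss_prob: float = 0.3
    ortholog_species: tuple[str, ...] = ("spX", "spY")
    # general COG class weights (0 = unclassified)
    cog_group_probs: tuple[float, ...] = (0.183, 0.129, 0.163, 0.360, 0.165)
    n_hgt_intervals: int = 2
    hgt_interval_bp: int = 20_000
    copy_number_plan: tuple[int, ...] | None = None  # override: sizes of dup families
    master_seed: int = 0

    def __post_init__(self):
        for p in (self.frac_duplicated, self.p_pre_speciation, self.copy_loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for t in (self.t_pre_dup, self.t_post_dup, self.t_species, self.t_strain):
            if t < 0:
                raise ValueError("branch lengths must be >= 0")


@dataclass
class SimulatedCohort:
    focal: GenomeBundle
    strains: dict[str, GenomeBundle]
    ortholog_db: list[tuple[str, str, str]]  # (id, species, protein seq)
    truth: pd.DataFrame
    hgt_intervals: dict[str, list[tuple[int, int]]]
    config: SimConfig


def _draw_omega(cfg: SimConfig, rng: np.random.Generator) -> float:
    if cfg.omega_sd <= 0:
        return cfg.omega_mean
    sigma2 = math.log(1.0 + (cfg.omega_sd / cfg.omega_mean) ** 2)
    mu = math.log(cfg.omega_mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _draw_cog(cfg: SimConfig, rng: np.random.Generator) -> frozenset[str]:
    grp = int(rng.choice(5, p=np.asarray(cfg.cog_group_probs) / sum(cfg.cog_group_probs)))
    if grp == 0:
        return frozenset()
    letters = _GROUP_LETTERS[grp]
    return frozenset({letters[rng.integers(len(letters))]})


def _place_genes(
    strain: str,
    entries: list[tuple[str, str, frozenset[str]]],  # (locus, cds, cogs)
    cfg: SimConfig,
    rng: np.random.Generator,
) -> GenomeBundle:
    """Assign replicons and coordinates; returns a validated bundle."""
    probs = np.array([p for _, _, p in cfg.replicon_layout])
    probs = probs / probs.sum()
    cursors = {rid: 0 for rid, _, _ in cfg.replicon_layout}
    classes = {rid: cls for rid, cls, _ in cfg.replicon_layout}
    genes: list[GeneRecord] = []
    for locus, cds, cogs in entries:
        k = int(rng.choice(len(cfg.replicon_layout), p=probs))
        rid = cfg.replicon_layout[k][0]
        gap = int(rng.integers(100, 400))
        start = cursors[rid] + gap + 1
        end = start + len(cds) - 1
        cursors[rid] = end
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(
            locus_tag=locus, strain=strain, replicon_id=rid,
            replicon_class=classes[rid], start=start, end=end, strand=strand,
            cogs=cogs, protein_seq=translate_cds(cds), cds_seq=cds,
        ))
    replicons = {rid: Replicon(rid, classes[rid], cursors[rid] + 500)
                 for rid, _, _ in cfg.replicon_layout}
    return GenomeBundle(strain=strain, replicons=replicons, genes=genes)


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Simulate the focal genome, related strains, ortholog database and truth.

    Pre-speciation families duplicate on the root branch and each copy then
    speciates (true Type-A); post-speciation families duplicate inside the
    focal lineage (true Type-B). Strain bundles apply per-copy loss; ortholog
    species receive one sequence per surviving ancestral copy.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.master_seed)

    n_dup = int(round(cfg.n_families * cfg.frac_duplicated))
    sizes = (list(cfg.copy_number_plan) if cfg.copy_number_plan is not None
             else [2] * n_dup)
    n_single = cfg.n_families - len(sizes)
    if n_single < 0:
        raise ValueError("copy_number_plan longer than n_families")

    focal_entries: list[tuple[str, str, frozenset[str]]] = []
    strain_entries: dict[str, list[tuple[str, str, frozenset[str]]]] = {
        s: [] for s in cfg.strain_names
    }
    ortholog_db: list[tuple[str, str, str]] = []
    truth_rows: list[dict] = []
    counter = 0

    def next_locus() -> str:
        nonlocal counter
        counter += 1
        return f"RS1_{counter:04d}"

    half_species = cfg.t_species / 2.0

    for fam_idx, size in enumerate(sizes + [1] * n_single):
        duplicated = size >= 2
        omega = _draw_omega(cfg, rng)
        evolver = CodonEvolver(cfg.kappa, omega,
                               None if cfg.gc_content is None
                               else gc_biased_codon_freqs(cfg.gc_content))
        root = evolver.sample_root(cfg.n_codons, rng)
        cogs = _draw_cog(cfg, rng)
        fam_id = f"fam{fam_idx:04d}"

        focal_seqs: list[str] = []
        true_type = ""
        if duplicated:
            pre = bool(rng.random() < cfg.p_pre_speciation)
            true_type = "A" if pre else "B"
            if pre:
                # Duplication, then each copy independently speciates.
                for c in range(size):
                    anc = evolver.evolve(root, cfg.t_pre_dup, rng)
                    focal_seqs.append(evolver.evolve(anc, cfg.t_species, rng))
                    for sp in cfg.ortholog_species:
                        oseq = evolver.evolve(anc, cfg.t_species, rng)
                        ortholog_db.append(
                            (f"{sp}_{fam_id}_c{c + 1}", sp, translate_cds(oseq)))
            else:
                # Speciation first; the focal lineage duplicates later.
                t_before_dup = max(cfg.t_species - cfg.t_post_dup, 0.0)
                dup_anc = evolver.evolve(root, t_before_dup, rng)
                for _ in range(size):
                    focal_seqs.append(evolver.evolve(dup_anc, cfg.t_post_dup, rng))
                o_mid = evolver.evolve(root, half_species, rng)
                for sp in cfg.ortholog_species:
                    oseq = evolver.evolve(o_mid, half_species, rng)
                    ortholog_db.append((f"{sp}_{fam_id}", sp, translate_cds(oseq)))
        else:
            focal_seqs.append(evolver.evolve(root, cfg.t_species, rng))
            o_mid = evolver.evolve(root, half_species, rng)
            for sp in cfg.ortholog_species:
                oseq = evolver.evolve(o_mid, half_species, rng)
                ortholog_db.append((f"{sp}_{fam_id}", sp, translate_cds(oseq)))

        loci = [next_locus() for _ in focal_seqs]
        for locus, seq in zip(loci, focal_seqs):
            focal_entries.append((locus, seq, cogs))

        strain_loci: dict[str, list[str]] = {}
        for s in cfg.strain_names:
            kept: list[str] = []
            for locus, seq in zip(loci, focal_seqs):
                if duplicated and rng.random() < cfg.copy_loss_prob:
                    continue
                sseq = evolver.evolve(seq, cfg.t_strain, rng)
                slocus = f"{s}_{locus.split('_')[1]}"
                strain_entries[s].append((slocus, sseq, cogs))
                kept.append(slocus)
            strain_loci[s] = kept

        truth_rows.append({
            "family_id": fam_id,
            "duplicated": duplicated,
            "copy_number": size,
            "true_type": true_type,
            "omega": omega,
            "loci": ",".join(loci),
            **{f"loci_{s}": ",".join(strain_loci[s]) for s in cfg.strain_names},
        })

    focal = _place_genes("RS1", focal_entries, cfg, rng)
    strains = {s: _place_genes(s, strain_entries[s], cfg, rng)
               for s in cfg.strain_names}

    # Plant HGT intervals on the focal genome and flag genes inside them.
    hgt: dict[str, list[tuple[int, int]]] = {}
    rep_ids = [rid for rid, _, _ in cfg.replicon_layout]
    for _ in range(cfg.n_hgt_intervals):
        rid = rep_ids[int(rng.integers(len(rep_ids)))]
        length = focal.replicons[rid].length
        span = min(cfg.hgt_interval_bp, length)
        start = int(rng.integers(0, max(length - span, 1)))
        hgt.setdefault(rid, []).append((start, start + span))
    for rid in hgt:
        hgt[rid] = sorted(hgt[rid])

    truth = pd.DataFrame(truth_rows)
    hgt_loci = set()
    for g in focal.genes:
        for s, e in hgt.get(g.replicon_id, []):
            if g.start - 1 < e and g.end > s:
                hgt_loci.add(g.locus_tag)
    truth["hgt_loci"] = truth["loci"].map(
        lambda loci: ",".join(l for l in loci.split(",") if l in hgt_loci))

    focal.validate()
    for b in strains.values():
        b.validate()
    return SimulatedCohort(
        focal=focal, strains=strains, ortholog_db=ortholog_db,
        truth=truth, hgt_intervals=hgt, config=cfg,
    )


def read_ortholog_db(path: str | Path) -> list[tuple[str, str, str]]:
    """Load an ortholog database FASTA; species is the id's leading token."""
    from .genome_io import read_fasta

    return [(oid, oid.split("_", 1)[0], seq) for oid, seq in read_fasta(path)]


def write_cohort(directory: str | Path, cohort: SimulatedCohort) -> None:
    """Emit the cohort as standard bundle files plus truth table and HGT BED."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_bundle(directory / "focal", cohort.focal)
    for name, bundle in cohort.strains.items():
        write_bundle(directory / name, bundle)
    write_fasta(directory / "ortholog_db.faa",
                [(oid, seq) for oid, _, seq in cohort.ortholog_db])
    cohort.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    with open(directory / "hgt.bed", "w") as fh:
        for rid in sorted(cohort.hgt_intervals):
            for s, e in cohort.hgt_intervals[rid]:
                fh.write(f"{rid}\t{s}\t{e}\n")
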