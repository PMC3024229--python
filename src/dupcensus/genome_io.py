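"""Genome bundle I/O: FASTA, tabular gene annotation, and validated gene records.

A *bundle* is the on-disk unit this package consumes per strain/species:
a protein FASTA, a CDS nucleotide FASTA, a replicon table and a gene table.
Coordinates are 1-based inclusive on the forward strand (GFF convention);
``cds_seq`` is stored already strand-resolved (reverse-complemented for the
minus strand) so downstream codon arithmetic never touches strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# The 25 single-letter COG functional categories, grouped into the 4 general
# classes (information storage & processing; cellular processes; metabolism;
# poorly characterized). Unclassified genes map to general group 0.
COG_GENERAL_GROUPS: dict[str, int] = {
    # 1. Information storage and processing
    "J": 1, "A": 1, "K": 1, "L": 1, "B": 1,
    # 2. Cellular processes and signaling
    "D": 2, "Y": 2, "V": 2, "T": 2, "M": 2, "N": 2, "Z": 2, "W": 2, "U": 2, "O": 2,
    # 3. Metabolism
    "C": 3, "G": 3, "E": 3, "F": 3, "H": 3, "I": 3, "P": 3, "Q": 3,
    # 4. Poorly characterized
    "R": 4, "S": 4,
}
COG_ALPHABET: frozenset[str] = frozenset(COG_GENERAL_GROUPS)

GENERAL_GROUP_NAMES = {
    0: "not in COGs",
    1: "information storage and processing",
    2: "cellular processes",
    3: "metabolism",
    4: "poorly characterized",
}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

GENE_TABLE_COLUMNS = [
    "locus_tag", "strain", "replicon_id", "replicon_class",
    "start", "end", "strand", "cogs",
]


class GenomeIOError(ValueError):
    """Raised on malformed bundle inputs."""


def translate_cds(dna: str) -> str:
    """Translate a strand-resolved CDS under the bacterial genetic code.

    The terminal stop codon (if present) is stripped; an internal stop or an
    ambiguity that does not resolve to a unique amino acid is an error.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(dna)} not divisible by 3")
    aas = []
    n_codons = len(dna) // 3
    for i in range(n_codons):
        codon = dna[3 * i : 3 * i + 3]
        try:
            expansions = {a + b + c for a in _IUPAC[codon[0]]
                          for b in _IUPAC[codon[1]] for c in _IUPAC[codon[2]]}
        except KeyError as exc:
            raise GenomeIOError(f"invalid base in codon {codon!r}") from exc
        translations = {"*" if c in STOP_CODONS else CODON_TO_AA[c] for c in expansions}
        if len(translations) != 1:
            raise GenomeIOError(f"ambiguous codon {codon!r} at position {3 * i + 1}")
        aa = translations.pop()
        if aa == "*":
            if i != n_codons - 1:
                raise GenomeIOError(f"internal stop codon at codon {i + 1}")
            break
        aas.append(aa)
    return "".join(aas)


@dataclass
class GeneRecord:
    """A single protein-coding gene with its sequences and annotation."""

    locus_tag: str
    strain: str
    replicon_id: str
    replicon_class: str  # "chromosome" | "plasmid"
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" | "-"
    cogs: frozenset[str] = field(default_factory=frozenset)
    protein_seq: str = ""
    cds_seq: str = ""

    def validate(self) -> None:
        if self.start > self.end or self.start < 1:
            raise GenomeIOError(f"{self.locus_tag}: bad coordinates {self.start}..{self.end}")
        if self.replicon_class not in ("chromosome", "plasmid"):
            raise GenomeIOError(f"{self.locus_tag}: bad replicon class {self.replicon_class!r}")
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"{self.locus_tag}: bad strand {self.strand!r}")
        bad = set(self.cogs) - COG_ALPHABET
        if bad:
            raise GenomeIOError(f"{self.locus_tag}: unknown COG letters {sorted(bad)}")
        if translate_cds(self.cds_seq) != self.protein_seq:
            raise GenomeIOError(f"{self.locus_tag}: CDS does not translate to protein")

    @property
    def cog_general_groups(self) -> frozenset[int]:
        """General COG classes (1-4) this gene belongs to; {0} if unclassified."""
        if not self.cogs:
            return frozenset({0})
        return frozenset(COG_GENERAL_GROUPS[c] for c in self.cogs)


@dataclass
class Replicon:
    replicon_id: str
    replicon_class: str
    length: int


@dataclass
class GenomeBundle:
    """All genes of one strain plus its replicon layout."""

    strain: str
    replicons: dict[str, Replicon]
    genes: list[GeneRecord]

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            g.validate()
            if g.locus_tag in seen:
                raise GenomeIOError(f"duplicate locus tag {g.locus_tag}")
            seen.add(g.locus_tag)
            rep = self.replicons.get(g.replicon_id)
            if rep is None:
                raise GenomeIOError(f"{g.locus_tag}: unknown replicon {g.replicon_id}")
            if g.end > rep.length:
                raise GenomeIOError(
                    f"{g.locus_tag}: end {g.end} beyond replicon {g.replicon_id} "
                    f"length {rep.length}"
                )

    def gene(self, locus_tag: str) -> GeneRecord:
        try:
            return self._index[locus_tag]
        except AttributeError:
            self._index = {g.locus_tag: g for g in self.genes}
            return self._index[locus_tag]

    def chromosome_ranks(self) -> dict[str, str]:
        """Map chromosome replicon ids to 'CI'/'CII'/... by decreasing length."""
        chroms = sorted(
            (r for r in self.replicons.values() if r.replicon_class == "chromosome"),
            key=lambda r: (-r.length, r.replicon_id),
        )
        roman = ["CI", "CII", "CIII", "CIV", "CV"]
        return {r.replicon_id: roman[i] if i < len(roman) else f"C{i + 1}"
                for i, r in enumerate(chroms)}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, uppercased sequence)``.

    Duplicate ids, empty records and gap characters are rejected.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise GenomeIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        if not seq:
            raise GenomeIOError(f"empty sequence for {rec.id!r} in {path}")
        if "-" in seq or "." in seq:
            raise GenomeIOError(f"gap character in sequence {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_replicon_table(path: str | Path) -> dict[str, Replicon]:
    replicons: dict[str, Replicon] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["replicon_id", "replicon_class", "length"]:
            raise GenomeIOError(f"bad replicon table header in {path}: {header}")
        for line in fh:
            rid, rclass, length = line.rstrip("\n").split("\t")
            replicons[rid] = Replicon(rid, rclass, int(length))
    return replicons


def write_replicon_table(path: str | Path, replicons: dict[str, Replicon]) -> None:
    with open(path, "w") as fh:
        fh.write("replicon_id\treplicon_class\tlength\n")
        for r in replicons.values():
            fh.write(f"{r.replicon_id}\t{r.replicon_class}\t{r.length}\n")


def read_gene_table(
    path: str | Path,
    fasta_prot: str | Path,
    fasta_cds: str | Path,
    replicons: dict[str, Replicon] | str | Path,
) -> GenomeBundle:
    """Assemble a validated :class:`GenomeBundle` from a gene table and FASTAs.

    Every table row must have both a protein and a CDS FASTA entry; rows whose
    sequences are missing are reported by locus tag.
    """
    if not isinstance(replicons, dict):
        replicons = read_replicon_table(replicons)
    prot = dict(read_fasta(fasta_prot))
    cds = dict(read_fasta(fasta_cds))

    genes: list[GeneRecord] = []
    strain = ""
    missing: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TABLE_COLUMNS:
            raise GenomeIOError(f"bad gene table header in {path}: {header}")
        for line in fh:
            if not line.strip():
                continue
            locus, strain, rid, rclass, start, end, strand, cogs = line.rstrip("\n").split("\t")
            if locus not in prot or locus not in cds:
                missing.append(locus)
                continue
            genes.append(GeneRecord(
                locus_tag=locus,
                strain=strain,
                replicon_id=rid,
                replicon_class=rclass,
                start=int(start),
                end=int(end),
                strand=strand,
                cogs=frozenset() if cogs == "-" else frozenset(cogs),
                protein_seq=prot[locus],
                cds_seq=cds[locus],
            ))
    if missing:
        raise GenomeIOError(f"gene table rows lacking FASTA entries: {missing}")
    bundle = GenomeBundle(strain=strain, replicons=replicons, genes=genes)
    bundle.validate()
    return bundle


def write_gene_table(path: str | Path, bundle: GenomeBundle) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in bundle.genes:
            cogs = "".join(sorted(g.cogs)) or "-"
            fh.write(f"{g.locus_tag}\t{g.strain}\t{g.replicon_id}\t{g.replicon_class}"
                     f"\t{g.start}\t{g.end}\t{g.strand}\t{cogs}\n")


def write_bundle(directory: str | Path, bundle: GenomeBundle) -> None:
    """Write a bundle as genes.tsv / proteins.faa / cds.fna / replicons.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_gene_table(directory / "genes.tsv", bundle)
    write_replicon_table(directory / "replicons.tsv", bundle.replicons)
    write_fasta(directory / "proteins.faa", [(g.locus_tag, g.protein_seq) for g in bundle.genes])
    write_fasta(directory / "cds.fna", [(g.locus_tag, g.cds_seq) for g in bundle.genes])


def read_bundle(directory: str | Path) -> GenomeBundle:
    directory = Path(directory)
    return read_gene_table(
        directory / "genes.tsv",
        directory / "proteins.faa",
        directory / "cds.fna",
        directory / "replicons.tsv",
    )
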