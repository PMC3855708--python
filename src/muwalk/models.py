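"""Gene models and reference-sequence handling.

A :class:`GeneModel` is a minimal, strand-aware gene representation (span,
exons, CDS) sufficient for exon numbering of insertion sites and for
codon-level effect annotation of point lesions.  Coordinates are 1-based
and inclusive throughout, matching the convention of printed site tables.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import Seq

Span = tuple[int, int]


def gene_span(start: int, end: int) -> int:
    """Length of a gene reported from its printed start/end coordinates.

    The report convention is ``end - start``: printed gene lengths in maize
    locus descriptions are the coordinate difference, not the inclusive
    base count.
    """
    if end < start:
        raise ValueError(f"end < start: {start}..{end}")
    return end - start


@dataclass
class GeneModel:
    """A gene with exon and CDS structure on one reference sequence.

    ``exons`` and ``cds`` are lists of 1-based inclusive ``(start, end)``
    spans in genomic order (ascending), regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[Span] = field(default_factory=list)
    cds: list[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    # -- exon numbering -------------------------------------------------
    def exons_tx_order(self) -> list[Span]:
        """Exons in transcription order (exon 1 first)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def exon_number_at(self, start: int, end: int | None = None) -> int | None:
        """1-based transcription-order index of the first exon overlapping
        [start, end], or None if the range falls entirely between exons."""
        end = start if end is None else end
        for i, (es, ee) in enumerate(self.exons_tx_order(), start=1):
            if es <= end and start <= ee:
                return i
        return None

    def overlaps(self, start: int, end: int, chrom: str | None = None) -> bool:
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start <= end and start <= self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    # -- CDS geometry ---------------------------------------------------
    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_start_codon_pos(self) -> int:
        """Genomic position of the first base of the start codon."""
        if not self.cds:
            raise ValueError(f"{self.gene_id} has no CDS")
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]

    def cds_stop_codon_end(self) -> int:
        """Genomic position of the last base of the stop codon."""
        if not self.cds:
            raise ValueError(f"{self.gene_id} has no CDS")
        return self.cds[-1][1] if self.strand == "+" else self.cds[0][0]

    def cds_index_of(self, pos: int) -> int | None:
        """1-based position of a genomic coordinate within the spliced CDS,
        counted in transcription order; None if `pos` is not in the CDS."""
        offset = 0
        spans = self.cds if self.strand == "+" else list(reversed(self.cds))
        for s, e in spans:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s) + 1
                return offset + (e - pos) + 1
            offset += e - s + 1
        return None

    def genomic_pos_of_cds_index(self, cds_index: int) -> int:
        """Genomic coordinate of the 1-based spliced-CDS position."""
        if not 1 <= cds_index <= self.cds_length:
            raise IndexError(f"CDS index {cds_index} outside 1..{self.cds_length}")
        offset = cds_index - 1
        spans = self.cds if self.strand == "+" else list(reversed(self.cds))
        for s, e in spans:
            n = e - s + 1
            if offset < n:
                return s + offset if self.strand == "+" else e - offset
            offset -= n
        raise AssertionError("unreachable")

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in transcription order (reverse-complemented for
        minus-strand genes). `chrom_seq` is the full chromosome sequence."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


# -- reference sequence I/O ---------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences (gzip-tolerant)."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- GFF3 I/O ------------------------------------------------------------

def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models (gene/exon/CDS features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                cds=cds,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start))
    return models


def write_gff3(models: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.chrom, m.start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                "\t".join(
                    [g.chrom, "muwalk", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(
                    [g.chrom, "muwalk", "mRNA", str(g.start), str(g.end), ".", g.strand, ".",
                     f"ID={mrna_id};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.chrom, "muwalk", "exon", str(s), str(e), ".", g.strand, ".",
                         f"ID={mrna_id}.exon{i};Parent={mrna_id}"]
                    )
                    + "\n"
                )
            # CDS phase in genomic order: cumulative spliced length determines
            # the phase of each segment (transcription order).
            spans = g.cds if g.strand == "+" else list(reversed(g.cds))
            phases: dict[Span, int] = {}
            acc = 0
            for s, e in spans:
                phases[(s, e)] = (3 - acc % 3) % 3
                acc += e - s + 1
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    "\t".join(
                        [g.chrom, "muwalk", "CDS", str(s), str(e), ".", g.strand,
                         str(phases[(s, e)]), f"ID={mrna_id}.cds{i};Parent={mrna_id}"]
                    )
                    + "\n"
                )
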