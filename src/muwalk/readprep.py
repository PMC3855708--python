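"""Read preparation: barcode decoding, degenerate-TIR trimming, length and
unique-mapping filters.

Seq-Walking reads have the anatomy ``barcode + Mu TIR + genomic flank``.
The terminal inverted repeat (TIR) of the Mu element is amplified with a
degenerate primer, so the TIR segment is matched as an IUPAC pattern whose
expansion yields a small set of concrete sequences.  Everything up to and
including the TIR match is removed; the remaining genomic flank is what gets
aligned and, downstream, anchored to an insertion site.
"""

from __future__ import annotations

import gzip
import logging
import re
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Mapping

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 32-nt degenerate MuTIR primer 5'-AGAGAAGCCAACGCCA(A/T)CGCCTC(C/T)ATTTCGTC-3'.
MU_TIR = "AGAGAAGCCAACGCCAWCGCCTCYATTTCGTC"

_READ_ALPHABET = set("ACGTN")


@dataclass
class RawRead:
    """A raw sequencing read (barcode still attached)."""

    read_id: str
    sequence: str
    quality: str | None = None

    def validate(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.read_id}: empty sequence")
        bad = set(self.sequence) - _READ_ALPHABET
        if bad:
            raise ValueError(f"{self.read_id}: non-ACGTN characters {sorted(bad)}")


@dataclass
class TrimmedRead:
    """A read after barcode removal and TIR trimming: the genomic flank."""

    read_id: str
    flank_sequence: str
    pool_label: str | None = None
    tir_end_offset: int = 0


def _normalize_pattern(pattern: str) -> str:
    """Accept either IUPAC codes or bracket notation like ``[A/T]``."""
    rev_iupac = {frozenset(v): k for k, v in ambiguous_dna_values.items()}

    def repl(m: re.Match) -> str:
        bases = frozenset(m.group(1).replace("/", "").replace(",", "").upper())
        try:
            return rev_iupac[bases]
        except KeyError:
            raise ValueError(f"unrepresentable base set {sorted(bases)}") from None

    return re.sub(r"\[([ACGT/,]+)\]", repl, pattern.upper())


@dataclass
class TirPattern:
    """A degenerate TIR to match and trim, with a mismatch tolerance."""

    iupac_sequence: str = MU_TIR
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        self.iupac_sequence = _normalize_pattern(self.iupac_sequence)
        unknown = set(self.iupac_sequence) - set(ambiguous_dna_values)
        if unknown:
            raise ValueError(f"invalid IUPAC codes {sorted(unknown)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def __len__(self) -> int:
        return len(self.iupac_sequence)

    @property
    def allowed(self) -> list[frozenset[str]]:
        return [frozenset(ambiguous_dna_values[c]) for c in self.iupac_sequence]

    def expansions(self) -> list[str]:
        """All concrete sequences the degenerate pattern represents."""
        return ["".join(p) for p in product(*(ambiguous_dna_values[c] for c in self.iupac_sequence))]

    def regex(self) -> re.Pattern:
        return re.compile(
            "".join(c if len(ambiguous_dna_values[c]) == 1 else f"[{ambiguous_dna_values[c]}]"
                    for c in self.iupac_sequence)
        )

    def find(self, sequence: str) -> int | None:
        """Leftmost 0-based start of a match within ``max_mismatches``."""
        if self.max_mismatches == 0:
            m = self.regex().search(sequence)
            return m.start() if m else None
        k = len(self)
        allowed = self.allowed
        best: int | None = None
        for i in range(len(sequence) - k + 1):
            mm = 0
            for j in range(k):
                if sequence[i + j] not in allowed[j]:
                    mm += 1
                    if mm > self.max_mismatches:
                        break
            else:
                best = i
                break
        return best


def decode_barcodes(
    reads: Iterable[RawRead], barcode_map: Mapping[str, str]
) -> tuple[dict[str, list[RawRead]], list[RawRead]]:
    """Assign reads to pools by fixed-prefix barcode and strip the barcode.

    Returns ``(pools, undecoded)`` where ``pools`` maps each pool label to its
    decoded reads.  The decoding is a partition: every input read lands in
    exactly one pool or in the undecoded bin.
    """
    barcodes = sorted(barcode_map)
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if b.startswith(a) or a.startswith(b):
                raise ValueError(f"ambiguous barcode map: {a!r} is a prefix of {b!r}")
    pools: dict[str, list[RawRead]] = {label: [] for label in barcode_map.values()}
    undecoded: list[RawRead] = []
    for read in reads:
        for bc, label in barcode_map.items():
            if read.sequence.startswith(bc):
                pools[label].append(
                    RawRead(
                        read.read_id,
                        read.sequence[len(bc) :],
                        read.quality[len(bc) :] if read.quality else None,
                    )
                )
                break
        else:
            undecoded.append(read)
    return pools, undecoded


def trim_mu_tir(
    read: RawRead,
    pattern: TirPattern | None = None,
    pool_label: str | None = None,
    search_revcomp: bool = False,
) -> TrimmedRead | None:
    """Trim the leftmost TIR match from a read, returning the genomic flank.

    Returns None when no expansion of the pattern matches within the allowed
    number of mismatches (no-match is a value, not an error).  The TIR is
    searched on the forward read orientation; ``search_revcomp`` additionally
    tries the reverse complement when the forward search fails.
    """
    pattern = pattern or TirPattern()
    start = pattern.find(read.sequence)
    seq = read.sequence
    if start is None and search_revcomp:
        rc = str(Seq(read.sequence).reverse_complement())
        start = pattern.find(rc)
        seq = rc
    if start is None:
        return None
    end = start + len(pattern)
    return TrimmedRead(read.read_id, seq[end:], pool_label=pool_label, tir_end_offset=end)


def length_filter(reads: Iterable[TrimmedRead], min_length: int = 91) -> Iterator[TrimmedRead]:
    """Retain flanks of at least ``min_length`` bp (default keeps > 90 bp)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    for read in reads:
        if len(read.flank_sequence) >= min_length:
            yield read


def unique_mapping_filter(alignments: Iterable, min_mapq: int = 20) -> list:
    """Retain uniquely mapped alignments only.

    A read is kept when its primary alignment is mapped with mapping quality
    >= ``min_mapq`` and no alignment of the same read carries the secondary or
    supplementary flag.  Duplicate primaries for one read id keep the first
    and warn.  Accepts pysam ``AlignedSegment`` records.
    """
    records = list(alignments)
    multi = {r.query_name for r in records if r.is_secondary or r.is_supplementary}
    kept: list = []
    seen: set[str] = set()
    for r in records:
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            continue
        if r.query_name in multi or r.mapping_quality < min_mapq:
            continue
        if r.query_name in seen:
            warnings.warn(f"duplicate primary alignment for {r.query_name}; keeping first")
            continue
        seen.add(r.query_name)
        kept.append(r)
    return kept


# -- FASTQ I/O -----------------------------------------------------------

def read_fastq(path: str) -> Iterator[RawRead]:
    """Stream a FASTQ file (gzip-tolerant) as RawRead records."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield RawRead(rec.id, str(rec.seq).upper(), qual)


def write_fastq(reads: Iterable[RawRead | TrimmedRead], path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            seq = r.flank_sequence if isinstance(r, TrimmedRead) else r.sequence
            qual = getattr(r, "quality", None) or "I" * len(seq)
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
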