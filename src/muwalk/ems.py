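"""EMS-allele candidate triage and coding-consequence annotation.

EMS (ethyl methanesulfonate) alkylates guanine and induces almost
exclusively G:C -> A:T transitions, so a candidate lesion in an EMS-derived
allele is expected to be a G->A or C->T substitution (relative to the
reference strand; the two are the same event read from opposite strands).
Standing variation is removed by excluding any variant whose alternate
allele is observed in a founder panel, and surviving lesions are placed on
the gene model: a substitution in the CDS is re-translated codon-by-codon
and reported as a premature termination codon (PTC), non-synonymous, or
synonymous change with its 1-based amino-acid position; non-coding lesions
are reported with their distance to the start or stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .models import GeneModel

logger = logging.getLogger(__name__)

STOP = "*"

#: Lesion severity for choosing each allele's "best" (most likely causal) lesion.
SEVERITY = [
    "PTC",
    "frameshift",
    "non_synonymous",
    "exon_insertion",
    "synonymous",
    "UTR",
    "intron",
    "upstream",
    "downstream",
]

CODING = ("PTC", "non_synonymous", "synonymous")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class EffectAnnotation:
    """Consequence of a lesion relative to one gene model."""

    category: str
    aa_position: int | None = None
    aa_change: tuple[str, str] | None = None  # (ref_aa, alt_aa); alt '*' for PTC
    distance_bp: int | None = None  # to start codon (5') or stop codon (3')
    cds_position: int | None = None
    error: str | None = None

    @property
    def notation(self) -> str:
        """Table-style lesion notation, e.g. '655AA(Q/PTC)' or
        '28 bp upstream of start codon'."""
        if self.category in CODING and self.aa_position is not None:
            if self.aa_change is None:
                return f"{self.aa_position} AA"
            ref, alt = self.aa_change
            alt = "PTC" if alt == STOP else alt
            return f"{self.aa_position}AA({ref}/{alt})"
        if self.category == "upstream" or (
            self.category == "UTR" and self.distance_bp is not None and self.distance_bp > 0
        ):
            return f"{abs(self.distance_bp)} bp upstream of start codon"
        if self.category == "downstream":
            return f"{abs(self.distance_bp)} bp downstream of stop codon"
        return self.category


@dataclass
class SnpRecord:
    """A candidate point lesion (or small deletion) on the reference."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str  # single base, or a deletion descriptor like 'del:AC' / '-'
    allele_name: str = ""
    pool_support: int | None = None
    effect: EffectAnnotation | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def is_indel(self) -> bool:
        alt = self.alt_allele
        return (
            len(self.ref_allele) != 1
            or alt in ("-", "")
            or alt.lower().startswith("del")
            or len(alt) != 1
        )


def is_ems_transition(snp: SnpRecord) -> bool:
    """True iff the lesion is a canonical EMS transition: G->A or C->T.

    Exactly 2 of the 12 single-base substitution types qualify; indels are
    never EMS-typical.
    """
    if snp.is_indel:
        return False
    pair = (snp.ref_allele.upper(), snp.alt_allele.upper())
    return pair in (("G", "A"), ("C", "T"))


class PanelGenotypes:
    """Allele calls of a founder panel at candidate positions.

    Stores, per (chrom, pos, founder), the called allele and its supporting
    read count.  Missing data ('--') is simply absent: a founder with no
    call at a position can never exclude a variant.
    """

    def __init__(self, founders: Iterable[str] = ()) -> None:
        self.founders: set[str] = set(founders)
        self._calls: dict[tuple[str, int], dict[str, tuple[str, int]]] = {}

    def add_call(self, chrom: str, pos: int, founder: str, allele: str, support: int = 1) -> None:
        if allele in ("--", "", "."):
            return
        self.founders.add(founder)
        self._calls.setdefault((chrom, pos), {})[founder] = (allele.upper(), support)

    def founders_with_alt(self, chrom: str, pos: int, alt: str, min_support: int = 1) -> list[str]:
        calls = self._calls.get((chrom, pos), {})
        return [
            f for f, (allele, sup) in calls.items()
            if allele == alt.upper() and sup >= min_support
        ]

    def __len__(self) -> int:
        return len(self._calls)

    @classmethod
    def from_tsv(cls, path: str) -> "PanelGenotypes":
        """Long-format TSV: chrom, pos, founder, allele, support[, total]."""
        df = pd.read_csv(path, sep="\t", dtype={"allele": str})
        panel = cls()
        for row in df.to_dict("records"):
            panel.add_call(
                str(row["chrom"]), int(row["pos"]), str(row["founder"]),
                str(row["allele"]), int(row.get("support", 1)),
            )
        return panel

    def write_tsv(self, path: str) -> None:
        rows = [
            {"chrom": c, "pos": p, "founder": f, "allele": a, "support": s}
            for (c, p), calls in sorted(self._calls.items())
            for f, (a, s) in sorted(calls.items())
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "founder", "allele", "support"]).to_csv(
            path, sep="\t", index=False
        )


def exclude_panel_variants(
    snps: Sequence[SnpRecord], panel: PanelGenotypes, min_support: int = 1
) -> list[SnpRecord]:
    """Drop SNPs whose alternate allele is observed in any panel founder.

    A variant standing in the founder panel predates the mutagenesis and is
    excluded; missing founder data never excludes.  Adding founders can only
    shrink the retained set (monotone).
    """
    kept = []
    for snp in snps:
        if panel.founders_with_alt(snp.chrom, snp.pos, snp.alt_allele, min_support):
            logger.info("excluded %s:%d %s>%s: present in founder panel",
                        snp.chrom, snp.pos, snp.ref_allele, snp.alt_allele)
        else:
            kept.append(snp)
    return kept


def _complement(base: str) -> str:
    return base.upper().translate(_COMPLEMENT)


def annotate_effect(
    snp: SnpRecord, model: GeneModel, genome: Mapping[str, str]
) -> EffectAnnotation:
    """Annotate a lesion's consequence on one gene model.

    CDS positions are mapped strand-aware through the spliced CDS and the
    affected codon is re-translated under the standard genetic code.
    Positions outside the CDS report the category (UTR / intron / upstream /
    downstream) with the genomic distance to the start codon (5' side) or
    stop codon (3' side); distances are positive outward.  In-CDS indels are
    frameshifts.  A CDS whose spliced length is not a multiple of 3 yields
    an annotation with the ``error`` flag set.
    """
    seq = genome[snp.chrom]
    pos = snp.pos

    cds_pos = model.cds_index_of(pos)
    if cds_pos is not None and snp.is_indel:
        return EffectAnnotation(category="frameshift", cds_position=cds_pos)

    if cds_pos is not None:
        cds_seq = model.cds_sequence(seq)
        err = None
        if len(cds_seq) % 3 != 0:
            return EffectAnnotation(
                category="error", cds_position=cds_pos,
                error=f"CDS length {len(cds_seq)} not divisible by 3",
            )
        ref_genomic = seq[pos - 1]
        if snp.ref_allele.upper() not in ("", ".") and ref_genomic != snp.ref_allele.upper():
            err = f"reference mismatch: genome has {ref_genomic}, record says {snp.ref_allele}"
        codon_idx = (cds_pos - 1) // 3
        within = (cds_pos - 1) % 3
        codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
        alt_cds_base = snp.alt_allele.upper() if model.strand == "+" else _complement(snp.alt_allele)
        alt_codon = codon[:within] + alt_cds_base + codon[within + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == STOP and ref_aa != STOP:
            category = "PTC"
        elif ref_aa == alt_aa:
            category = "synonymous"
        else:
            category = "non_synonymous"
        return EffectAnnotation(
            category=category,
            aa_position=codon_idx + 1,
            aa_change=(ref_aa, alt_aa),
            cds_position=cds_pos,
            error=err,
        )

    # non-CDS: orient relative to transcription direction
    start_codon = model.cds_start_codon_pos()
    stop_end = model.cds_stop_codon_end()
    sign = 1 if model.strand == "+" else -1
    d_start = (start_codon - pos) * sign  # > 0: 5' of the start codon
    d_stop = (pos - stop_end) * sign      # > 0: 3' of the stop codon

    if model.contains(pos):
        if model.in_exon(pos):
            dist = d_start if d_start > 0 else -d_stop if d_stop > 0 else None
            return EffectAnnotation(category="UTR", distance_bp=abs(dist) if dist else None)
        return EffectAnnotation(category="intron")
    if d_start > 0 and (pos < model.start if model.strand == "+" else pos > model.end):
        return EffectAnnotation(category="upstream", distance_bp=d_start)
    return EffectAnnotation(category="downstream", distance_bp=max(d_stop, 0))


def best_lesion(effects: Sequence[EffectAnnotation]) -> EffectAnnotation | None:
    """Most severe lesion under PTC > non-synonymous > synonymous > non-coding."""
    ranked = [e for e in effects if e.category in SEVERITY]
    if not ranked:
        return None
    return min(ranked, key=lambda e: SEVERITY.index(e.category))


def allele_report(
    alleles: Mapping[str, Sequence[SnpRecord]],
    models: Sequence[GeneModel] | None = None,
    genome: Mapping[str, str] | None = None,
    panel: PanelGenotypes | None = None,
    min_support: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Per-allele lesion table and category summary.

    For each named allele: panel-shared variants are excluded, remaining
    lesions are annotated (against ``models``/``genome`` when given,
    otherwise pre-attached ``effect`` annotations are used), and the most
    severe lesion is reported with an EMS-typical flag.  The summary counts
    alleles whose best lesion is coding (PTC or non-synonymous) and PTC
    specifically.
    """
    rows = []
    for name, snps in alleles.items():
        snps = list(snps)
        n_input = len(snps)
        if panel is not None:
            snps = exclude_panel_variants(snps, panel, min_support)
        effects: list[tuple[SnpRecord, EffectAnnotation]] = []
        for snp in snps:
            eff = snp.effect
            if eff is None and models is not None and genome is not None:
                overlapping = [m for m in models if m.chrom == snp.chrom and m.start - 50_000 <= snp.pos <= m.end + 50_000]
                if overlapping:
                    nearest = min(
                        overlapping,
                        key=lambda m: 0 if m.contains(snp.pos) else min(
                            abs(snp.pos - m.start), abs(snp.pos - m.end)
                        ),
                    )
                    eff = annotate_effect(snp, nearest, genome)
            if eff is not None:
                effects.append((snp, eff))
        best = best_lesion([e for _, e in effects])
        best_snp = next((s for s, e in effects if e is best), None)
        rows.append(
            {
                "allele": name,
                "n_candidates": len(snps),
                "n_panel_excluded": n_input - len(snps),
                "category": best.category if best else "no candidate",
                "lesion": best.notation if best else "no candidate",
                "ems_typical": bool(best_snp and is_ems_transition(best_snp)),
                "causal_candidate": bool(best and best.category in ("PTC", "frameshift", "non_synonymous", "exon_insertion")),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["allele", "n_candidates", "n_panel_excluded", "category", "lesion",
                 "ems_typical", "causal_candidate"],
    )
    by_category = df["category"].value_counts().to_dict()
    summary = {
        "n_alleles": len(df),
        "by_category": by_category,
        "n_coding": int(df["category"].isin(["PTC", "non_synonymous"]).sum()),
        "n_ptc": int((df["category"] == "PTC").sum()),
        "n_no_candidate": int((df["category"] == "no candidate").sum()),
    }
    return df, summary
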