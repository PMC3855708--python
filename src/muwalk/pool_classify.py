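"""Pool comparison and candidate triage.

Sites observed in both the mutant and wild-type DNA pools are segregating in
the genetic background and cannot be causal, so they are removed; the
remainder are pool-specific.  Mutant-specific sites inside the genetic
mapping interval are ranked by read count — germinal (heritable) insertions
are present in every pooled individual and accumulate high counts, while
somatic insertions contribute on the order of one read — and cross-referenced
with differential-expression evidence to nominate the candidate gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mfs_sites import MFSSite, PoolCatalog
from .models import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class MappingInterval:
    """A genetic mapping interval (1-based, inclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end: {self.start}..{self.end}")

    @classmethod
    def from_bed(cls, path: str) -> "MappingInterval":
        with open(path) as fh:
            for line in fh:
                if line.strip() and not line.startswith(("#", "track", "browser")):
                    chrom, start, end = line.split()[:3]
                    return cls(chrom, int(start) + 1, int(end))
        raise ValueError(f"no interval in {path}")


@dataclass
class DegRecord:
    """One row of a differential-expression table (mutant vs. wild-type)."""

    gene_id: str
    log2_fold_change: float
    q_value: float
    q_threshold: float = 0.05
    strong_lfc: float = 4.0

    @property
    def is_deg(self) -> bool:
        return self.q_value <= self.q_threshold

    @property
    def is_strong(self) -> bool:
        return self.is_deg and abs(self.log2_fold_change) >= self.strong_lfc


def load_deg_table(path: str, q_threshold: float = 0.05) -> dict[str, DegRecord]:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_c = cols.get("gene_id", cols.get("gene", df.columns[0]))
    lfc_c = cols.get("log2fc", cols.get("log2_fold_change", df.columns[1]))
    q_c = cols.get("q_value", cols.get("qvalue", df.columns[2]))
    return {
        str(r[gene_c]): DegRecord(str(r[gene_c]), float(r[lfc_c]), float(r[q_c]), q_threshold)
        for _, r in df.iterrows()
    }


@dataclass
class CandidateEntry:
    site: MFSSite
    gene_id: str | None = None
    exon_number: int | None = None
    all_genes: list[tuple[str, int | None]] = field(default_factory=list)
    ambiguous: bool = False
    deg_status: bool | None = None  # None: non-genic or gene not in DEG table
    probable_somatic: bool = False
    rank: int | None = None


@dataclass
class CandidateReport:
    """Ranked triage output; the first entry is the candidate."""

    entries: list[CandidateEntry] = field(default_factory=list)
    low_confidence: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def candidate(self) -> CandidateEntry | None:
        return self.entries[0] if self.entries else None

    @property
    def candidate_gene(self) -> str | None:
        return self.candidate.gene_id if self.candidate else None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "rank": e.rank,
                    "chrom": e.site.chrom,
                    "start": e.site.start,
                    "end": e.site.end,
                    "read_count": e.site.read_count_mutant,
                    "target_gene": e.gene_id or "Non-genic insertion",
                    "exon": e.exon_number,
                    "deg": e.deg_status,
                    "probable_somatic": e.probable_somatic,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["rank", "chrom", "start", "end", "read_count", "target_gene",
                     "exon", "deg", "probable_somatic"],
        )


def classify_sites(mutant: PoolCatalog, wildtype: PoolCatalog) -> list[MFSSite]:
    """Classify the union of two pool catalogs by coordinate identity.

    A site with the same (chrom, start, end) in both pools is 'shared';
    otherwise it is 'mutant_specific' or 'wildtype_specific'.  Returned
    sites carry both pools' read counts.
    """
    wt_by_key = {s.key: s for s in wildtype.sites}
    out: list[MFSSite] = []
    seen: set = set()
    for s in mutant.sites:
        wt = wt_by_key.get(s.key)
        if wt is not None:
            out.append(
                replace(
                    s,
                    read_count_wildtype=wt.read_count_wildtype,
                    classification="shared",
                )
            )
        else:
            out.append(replace(s, classification="mutant_specific"))
        seen.add(s.key)
    for s in wildtype.sites:
        if s.key not in seen:
            out.append(replace(s, classification="wildtype_specific"))
    out.sort(key=lambda s: (s.chrom, s.start, s.end))
    return out


def intersect_interval(
    sites: Sequence[MFSSite], interval: MappingInterval, strict: bool = False
) -> list[MFSSite]:
    """Retain sites overlapping the mapping interval (any-overlap rule;
    ``strict`` requires full containment)."""
    if sites and all(s.chrom != interval.chrom for s in sites):
        warnings.warn(f"no site on interval chromosome {interval.chrom}")
        return []
    if strict:
        return [
            s for s in sites
            if s.chrom == interval.chrom and s.start >= interval.start and s.end <= interval.end
        ]
    return [
        s for s in sites
        if s.chrom == interval.chrom and s.start <= interval.end and s.end >= interval.start
    ]


def rank_by_count(sites: Sequence[MFSSite], min_count: int = 2) -> CandidateReport:
    """Rank mutant-specific sites by mutant-pool read count (descending).

    Sites with fewer than ``min_count`` reads are flagged probable-somatic
    and demoted below all high-count sites.  Ties break by coordinate
    ascending.
    """
    usable = [s for s in sites if s.classification in ("mutant_specific", "unclassified")]
    entries = [
        CandidateEntry(site=s, probable_somatic=s.read_count_mutant < min_count)
        for s in usable
    ]
    entries.sort(
        key=lambda e: (
            e.probable_somatic,
            -e.site.read_count_mutant,
            e.site.chrom,
            e.site.start,
            e.site.end,
        )
    )
    for i, e in enumerate(entries, 1):
        e.rank = i
    return CandidateReport(entries=entries)


def annotate_target_gene(
    site: MFSSite, models: Sequence[GeneModel]
) -> list[tuple[str, int | None]]:
    """Genes whose span overlaps the site, each with the exon number hit.

    Exons are numbered in transcription order (for a minus-strand gene the
    last genomic exon is exon 1).  An intronic hit reports exon None; an
    empty list means a non-genic insertion.
    """
    hits = []
    for g in models:
        if g.overlaps(site.start, site.end, site.chrom):
            hits.append((g.gene_id, g.exon_number_at(site.start, site.end)))
    return hits


def annotate_report(report: CandidateReport, models: Sequence[GeneModel]) -> CandidateReport:
    for e in report.entries:
        hits = annotate_target_gene(e.site, models)
        e.all_genes = hits
        if hits:
            e.gene_id, e.exon_number = hits[0]
            e.ambiguous = len(hits) > 1
            if e.ambiguous:
                logger.warning(
                    "site %s overlaps %d genes: %s", e.site.key, len(hits),
                    [g for g, _ in hits],
                )
    return report


def triage(
    report: CandidateReport, deg_table: Mapping[str, DegRecord] | Iterable[DegRecord]
) -> CandidateReport:
    """Final ordering: DEG-hitting sites first, then by read-count rank.

    The top entry is the candidate.  With an empty DEG table the ranking
    falls back to read counts alone (warning); a candidate whose gene is not
    differentially expressed is flagged low-confidence.
    """
    if not isinstance(deg_table, Mapping):
        deg_table = {d.gene_id: d for d in deg_table}
    if not deg_table:
        warnings.warn("empty DEG table: ranking falls back to read counts only")
    entries = list(report.entries)
    for e in entries:
        if e.gene_id is None or e.gene_id not in deg_table:
            e.deg_status = None
        else:
            e.deg_status = deg_table[e.gene_id].is_deg
    entries.sort(
        key=lambda e: (
            0 if e.deg_status else 1,
            e.probable_somatic,
            -e.site.read_count_mutant,
            e.site.chrom,
            e.site.start,
            e.site.end,
        )
    )
    for i, e in enumerate(entries, 1):
        e.rank = i
    low_conf = not entries or not entries[0].deg_status
    return CandidateReport(entries=entries, low_confidence=low_conf)
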