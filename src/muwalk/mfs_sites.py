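"""Mu-flanking-sequence (MFS) site calling from uniquely mapped flank reads.

Each trimmed flank alignment contributes one anchor observation: the
reference base immediately adjacent to the Mu insertion.  A forward-strand
flank ends just left of the insertion's target-site duplication (TSD) and
anchors its first base; a reverse-orientation flank starts just right of the
TSD and anchors its last base.  Because Mu1 duplicates 9 bp of target
sequence, the two anchors of one insertion are linked by

    right_anchor = left_anchor + tsd_span - 1

and anchor pairs satisfying this relation are merged into a single
dual-anchor MFS site spanning the TSD, with read counts summed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

TSD_SPAN = 9  # Mu1 target-site duplication length (bp)


@dataclass
class FlankObservation:
    """One aligned flank read reduced to its insertion-adjacent anchor."""

    chrom: str
    anchor_pos: int  # 1-based
    side: str  # 'left' (flank upstream of insertion) or 'right'
    pool_label: str | None = None

    def __post_init__(self) -> None:
        if self.anchor_pos < 1:
            raise ValueError(f"anchor_pos must be >= 1, got {self.anchor_pos}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")


@dataclass
class MFSSite:
    """A non-redundant MFS site: [start, end] covers the TSD when both
    anchors were observed (end - start = tsd_span - 1), otherwise
    start == end marks a single-anchor site."""

    chrom: str
    start: int
    end: int
    read_count_mutant: int = 0
    read_count_wildtype: int = 0
    classification: str = "unclassified"
    n_anchors: int = 2

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def single_anchor(self) -> bool:
        return self.n_anchors == 1

    def pool_count(self, pool_label: str) -> int:
        return self.read_count_mutant if pool_label == "mutant" else self.read_count_wildtype

    @property
    def total_count(self) -> int:
        return self.read_count_mutant + self.read_count_wildtype


@dataclass
class PoolCatalog:
    """All MFS sites observed in one DNA pool."""

    pool_label: str
    sites: list[MFSSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def keys(self) -> set[tuple[str, int, int]]:
        return {s.key for s in self.sites}

    def count_of(self, site: MFSSite) -> int:
        return site.pool_count(self.pool_label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "count": self.count_of(s),
                    "n_anchors": s.n_anchors,
                }
                for s in self.sites
            ],
            columns=["chrom", "start", "end", "count", "n_anchors"],
        )

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_bed(self, path: str) -> None:
        """BED6 with score = read count (BED is 0-based half-open)."""
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(
                    f"{s.chrom}\t{s.start - 1}\t{s.end}\tMFS\t{self.count_of(s)}\t+\n"
                )

    @classmethod
    def from_tsv(cls, path: str, pool_label: str) -> "PoolCatalog":
        df = pd.read_csv(path, sep="\t")
        sites = []
        for row in df.to_dict("records"):
            counts = {"read_count_mutant": 0, "read_count_wildtype": 0}
            counts[f"read_count_{pool_label}"] = int(row["count"])
            sites.append(
                MFSSite(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    n_anchors=int(row.get("n_anchors", 2)),
                    **counts,
                )
            )
        return cls(pool_label, sites)


def collect_observations(alignments: Iterable, pool_label: str | None = None) -> list[FlankObservation]:
    """Reduce uniquely mapped flank alignments to anchor observations.

    Forward-strand alignments anchor at their 1-based reference end + 1
    (side 'left'); reverse-strand alignments anchor at their 1-based
    reference start - 1 (side 'right').  Unmapped records are skipped and
    counted in the log.
    """
    obs: list[FlankObservation] = []
    skipped = 0
    for aln in alignments:
        if aln.is_unmapped:
            skipped += 1
            continue
        if aln.is_reverse:
            # pysam reference_start is 0-based == (1-based start) - 1
            obs.append(
                FlankObservation(aln.reference_name, aln.reference_start, "right", pool_label)
            )
        else:
            # pysam reference_end is 0-based-exclusive == 1-based inclusive end
            obs.append(
                FlankObservation(aln.reference_name, aln.reference_end + 1, "left", pool_label)
            )
    if skipped:
        logger.info("collect_observations: skipped %d unmapped records", skipped)
    return obs


def build_sites(
    observations: Iterable[FlankObservation],
    tsd_span: int = TSD_SPAN,
    pool_label: str | None = None,
    anchor_slop: int = 0,
) -> PoolCatalog:
    """Collapse anchor observations into a non-redundant site catalog.

    Observations at identical (chrom, side, anchor) sum; a left anchor L and
    a right anchor R merge into one dual-anchor site when
    R = L + tsd_span - 1 (within ``anchor_slop`` bp; nearest wins, then the
    lower coordinate).  Unpaired anchors become single-anchor sites with
    start == end.
    """
    if tsd_span < 1:
        raise ValueError("tsd_span must be >= 1")
    observations = list(observations)
    if pool_label is None:
        labels = {o.pool_label for o in observations if o.pool_label}
        pool_label = labels.pop() if len(labels) == 1 else "mutant"
    count_field = f"read_count_{pool_label}" if pool_label in ("mutant", "wildtype") else None

    counts: Counter = Counter()
    for o in observations:
        counts[(o.chrom, o.side, o.anchor_pos)] += 1

    def make(chrom: str, start: int, end: int, n: int, n_anchors: int) -> MFSSite:
        site = MFSSite(chrom, start, end, n_anchors=n_anchors)
        if count_field:
            setattr(site, count_field, n)
        else:  # unknown pool label: stash in mutant slot
            site.read_count_mutant = n
        return site

    sites: list[MFSSite] = []
    chroms = sorted({c for c, _, _ in counts})
    for chrom in chroms:
        lefts = {a: n for (c, s, a), n in counts.items() if c == chrom and s == "left"}
        rights = {a: n for (c, s, a), n in counts.items() if c == chrom and s == "right"}
        used_rights: set[int] = set()
        for left in sorted(lefts):
            target = left + tsd_span - 1
            candidates = [
                r for r in rights
                if r not in used_rights and abs(r - target) <= anchor_slop
            ]
            if candidates:
                right = min(candidates, key=lambda r: (abs(r - target), r))
                used_rights.add(right)
                sites.append(make(chrom, left, right, lefts[left] + rights[right], 2))
            else:
                sites.append(make(chrom, left, left, lefts[left], 1))
        # leftover right anchors; merge with an unpaired single at the same spot
        singles = {s.key: s for s in sites if s.n_anchors == 1 and s.chrom == chrom}
        for right in sorted(set(rights) - used_rights):
            key = (chrom, right, right)
            if key in singles:
                s = singles[key]
                if count_field:
                    setattr(s, count_field, getattr(s, count_field) + rights[right])
                else:
                    s.read_count_mutant += rights[right]
            else:
                site = make(chrom, right, right, rights[right], 1)
                sites.append(site)
                singles[key] = site
    sites.sort(key=lambda s: (s.chrom, s.start, s.end))
    return PoolCatalog(pool_label, sites)
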