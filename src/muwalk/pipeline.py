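"""End-to-end Seq-Walking orchestration.

Composes the module chain: unique-mapping filter -> anchor observations ->
TSD-paired site catalogs -> pool classification -> mapping-interval
intersection -> read-count ranking -> gene annotation -> DEG triage.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .mfs_sites import TSD_SPAN, PoolCatalog, build_sites, collect_observations
from .models import GeneModel
from .pool_classify import (
    CandidateReport,
    DegRecord,
    MappingInterval,
    annotate_report,
    classify_sites,
    intersect_interval,
    rank_by_count,
    triage,
)
from .readprep import unique_mapping_filter


def catalog_from_alignments(
    alignments: Iterable,
    pool_label: str,
    tsd_span: int = TSD_SPAN,
    min_mapq: int = 20,
    anchor_slop: int = 0,
) -> PoolCatalog:
    """Uniquely mapped alignments -> non-redundant MFS site catalog."""
    unique = unique_mapping_filter(alignments, min_mapq=min_mapq)
    obs = collect_observations(unique, pool_label)
    return build_sites(obs, tsd_span=tsd_span, pool_label=pool_label, anchor_slop=anchor_slop)


def locate_candidate(
    mutant_alignments: Iterable,
    wildtype_alignments: Iterable,
    interval: MappingInterval,
    models: Sequence[GeneModel],
    deg_table: Mapping[str, DegRecord],
    tsd_span: int = TSD_SPAN,
    min_mapq: int = 20,
    min_count: int = 2,
    strict_interval: bool = False,
) -> CandidateReport:
    """Run the full pipeline and return the triaged candidate report."""
    mutant = catalog_from_alignments(mutant_alignments, "mutant", tsd_span, min_mapq)
    wildtype = catalog_from_alignments(wildtype_alignments, "wildtype", tsd_span, min_mapq)
    classified = classify_sites(mutant, wildtype)
    in_interval = intersect_interval(classified, interval, strict=strict_interval)
    report = rank_by_count(in_interval, min_count=min_count)
    report = annotate_report(report, models)
    return triage(report, deg_table)
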