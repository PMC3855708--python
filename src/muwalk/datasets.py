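"""Packaged worked-example data: the printed gl13 site and allele tables.

These are the published summary tables for the maize *glossy13* locus
(GRMZM2G118243): the four mutant-specific MFS sites inside the 8 Mb mapping
interval with their read counts and DEG status, and the sequence lesions of
the eleven *gl13* mutant alleles.  They drive the worked examples and the
triage demonstrations; the raw reads behind them were never deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ems import STOP, EffectAnnotation, SnpRecord
from .mfs_sites import MFSSite
from .pool_classify import DegRecord, MappingInterval

GL13_GENE = "GRMZM2G118243"
#: Printed gl13 locus coordinates on chromosome 3.
GL13_SPAN = (10_272_500, 10_283_828)
#: The 8 Mb mapping interval on the long arm of chromosome 3 (chr3:5-13 Mb).
GL13_INTERVAL = MappingInterval("chr3", 5_000_000, 13_000_000)


def _load(name: str) -> pd.DataFrame:
    with resources.files("muwalk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_gl13_mfs_table() -> pd.DataFrame:
    """The four mutant-specific MFS sites in the gl13 mapping interval."""
    df = _load("gl13_mfs_interval.tsv")
    for col in ("start", "end", "read_count"):
        df[col] = df[col].astype(int)
    return df


def gl13_mfs_sites() -> list[MFSSite]:
    return [
        MFSSite(
            chrom=r["chrom"],
            start=int(r["start"]),
            end=int(r["end"]),
            read_count_mutant=int(r["read_count"]),
            classification="mutant_specific",
        )
        for r in load_gl13_mfs_table().to_dict("records")
    ]


def gl13_deg_table() -> dict[str, DegRecord]:
    """DEG evidence for the genes hit by the interval MFS sites, as printed
    (DEG defined by q <= 0.05 with log2FC > 4 in the site table)."""
    out: dict[str, DegRecord] = {}
    for r in load_gl13_mfs_table().to_dict("records"):
        gene = r["target_gene"]
        if gene == "Non-genic insertion":
            continue
        if r["deg"] == "Yes":
            out[gene] = DegRecord(gene, log2_fold_change=4.5, q_value=0.01)
        else:
            out.setdefault(gene, DegRecord(gene, log2_fold_change=0.0, q_value=1.0))
    return out


def gl13_site_genes() -> dict[tuple[str, int, int], str | None]:
    """Printed target-gene assignment per site key."""
    return {
        (r["chrom"], int(r["start"]), int(r["end"])): (
            None if r["target_gene"] == "Non-genic insertion" else r["target_gene"]
        )
        for r in load_gl13_mfs_table().to_dict("records")
    }


def load_gl13_alleles() -> pd.DataFrame:
    """The printed lesion table for the eleven gl13 mutant alleles."""
    df = _load("gl13_alleles.tsv")
    df["pos"] = df["pos"].astype(int)
    return df


def gl13_allele_records(mutagen: str | None = None) -> dict[str, list[SnpRecord]]:
    """Per-allele SNP records carrying their printed lesion annotations.

    ``mutagen='EMS'`` restricts to the eight EMS-induced alleles.
    """
    out: dict[str, list[SnpRecord]] = {}
    for r in load_gl13_alleles().to_dict("records"):
        if mutagen is not None and r["mutagen"] != mutagen:
            continue
        category = r["category"]
        aa_pos = None if r["aa_position"] == "-" else int(r["aa_position"])
        aa_change = None
        if r["aa_alt"] != "-":
            ref_aa = "" if r["aa_ref"] == "-" else r["aa_ref"]
            aa_change = (ref_aa, STOP if r["aa_alt"] == "*" else r["aa_alt"]) if ref_aa else None
        dist = None if r["distance_bp"] == "-" else int(r["distance_bp"])
        mutation = r["mutation"]
        if "->" in mutation:
            ref, alt = mutation.split("->")
        elif mutation.startswith("del:"):
            ref, alt = mutation[4:], "-"
        else:  # Mu insertion row
            ref, alt = "N", "<INS:Mu1>"
        effect = EffectAnnotation(
            category=category, aa_position=aa_pos, aa_change=aa_change, distance_bp=dist
        )
        out.setdefault(r["allele"], []).append(
            SnpRecord(
                chrom=r["chrom"],
                pos=int(r["pos"]),
                ref_allele=ref,
                alt_allele=alt,
                allele_name=r["allele"],
                effect=effect,
            )
        )
    return out
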