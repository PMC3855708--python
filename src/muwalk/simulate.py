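"""Synthetic Seq-Walking datasets with known truth.

The generator emulates the statistical structure the method assumes: a
random reference with multi-exon genes on both strands; germinal Mu
insertions shared or pool-specific, each with a 9-bp target-site duplication
and a high read count; somatic insertions contributing a single read; reads
with the ``barcode + degenerate TIR + flank`` anatomy (flank >= 91 bp); and
EMS-style variants (G/C -> A/T transitions placed to force a requested
coding consequence, plus transversion and founder-panel decoys).  Matching
truth alignments are emitted as SAM records so the test path is
aligner-free.  Everything is driven by one seed and is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
from Bio.Seq import Seq

from .ems import PanelGenotypes, SnpRecord, _complement
from .mfs_sites import MFSSite, PoolCatalog
from .models import GeneModel, write_fasta, write_gff3
from .pool_classify import DegRecord, MappingInterval
from .readprep import MU_TIR, RawRead, TirPattern

STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]

POOLS = ("mutant", "wildtype")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``n_sites_mutant`` / ``n_sites_wildtype`` are the total non-redundant
    insertion-site counts observed per pool (the published pool structure:
    471 mutant / 251 wild-type with 82 shared); ``somatic_rate`` is the
    expected number of pool-specific sites that are somatic (read count 1)
    rather than germinal.
    """

    seed: int = 0
    chrom: str = "chr1"
    genome_length_bp: int = 2_000_000
    n_genes: int = 40
    n_sites_mutant: int = 471
    n_sites_wildtype: int = 251
    n_shared: int = 82
    somatic_rate: float = 10.0
    read_count_mean: float = 200.0
    read_count_dispersion: float = 2.0
    tsd_span: int = 9
    min_flank: int = 91
    max_flank: int = 140
    barcodes: dict[str, str] = field(
        default_factory=lambda: {"AACCGAT": "mutant", "GGTTACA": "wildtype"}
    )
    causal: bool = True
    interval_halfwidth_bp: int = 150_000
    n_multimapped_reads: int = 10
    # EMS variant requests: (gene_index, category)
    ems_variants: tuple[tuple[int, str], ...] = (
        (1, "PTC"),
        (2, "non_synonymous"),
        (3, "synonymous"),
        (4, "upstream"),
    )
    n_transversion_decoys: int = 2
    n_panel_decoys: int = 2
    n_founders: int = 25

    def validate(self) -> None:
        if self.n_shared > min(self.n_sites_mutant, self.n_sites_wildtype):
            raise ValueError("n_shared exceeds a pool's site count")
        if min(self.n_sites_mutant, self.n_sites_wildtype, self.n_shared) < 0:
            raise ValueError("site counts must be >= 0")
        if self.tsd_span < 1:
            raise ValueError("tsd_span must be >= 1")
        if self.genome_length_bp < 10 * self.n_genes * 1_000:
            raise ValueError("genome too short to pack gene models (need >= 10 kb per gene)")


@dataclass
class PlantedInsertion:
    chrom: str
    tsd_start: int
    tsd_end: int
    kind: str  # 'germinal' | 'somatic'
    pools: tuple[str, ...]
    gene_id: str | None = None
    causal: bool = False


@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    expected_category: str
    allele_name: str
    decoy: str | None = None  # None | 'transversion' | 'panel'


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset."""

    insertions: list[PlantedInsertion] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)
    interval: MappingInterval | None = None
    causal_gene: str | None = None

    def to_json(self, path: str) -> None:
        payload = {
            "insertions": [dataclasses.asdict(i) for i in self.insertions],
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "interval": dataclasses.asdict(self.interval) if self.interval else None,
            "causal_gene": self.causal_gene,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ----------------------------------------------------------------------
# reference simulation
# ----------------------------------------------------------------------

def simulate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping multi-exon genes on both strands.

    Every gene's spliced CDS starts with ATG, ends with a stop codon, has no
    internal stop, and its length is a multiple of 3 by construction.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    L = config.genome_length_bp
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.integers(0, 4, L)]))

    slot = L // config.n_genes
    models: list[GeneModel] = []
    for g in range(config.n_genes):
        slot_start = g * slot + 1
        n_ex = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 400, n_ex)
        total = int(exon_lens.sum())
        exon_lens[-1] -= total % 3
        intron_lens = rng.integers(80, 200, max(n_ex - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        if span + 4_000 > slot:
            raise ValueError("infeasible packing: gene span exceeds its slot")
        gstart = slot_start + 2_000 + int(rng.integers(0, slot - span - 4_000))
        exons: list[tuple[int, int]] = []
        pos = gstart
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el) - 1))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(exon_lens.sum()) // 3
        middle = rng.choice(SENSE_CODONS, n_codons - 2)
        cds = "ATG" + "".join(middle) + str(rng.choice(sorted(STOP_CODONS)))
        genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
        off = 0
        for s, e in exons:
            n = e - s + 1
            seq[s - 1 : e] = list(genomic[off : off + n])
            off += n
        models.append(
            GeneModel(
                gene_id=f"SYNG{g + 1:04d}",
                chrom=config.chrom,
                strand=strand,
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
                cds=list(exons),
            )
        )
    return {config.chrom: "".join(seq)}, models


# ----------------------------------------------------------------------
# insertion planting
# ----------------------------------------------------------------------

def plant_insertions(
    config: SimConfig,
    models: Sequence[GeneModel] | None = None,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Plant germinal and somatic insertions with a 9-bp TSD each.

    Germinal insertion positions are sampled without replacement on a
    spacing grid; the shared subset is coordinate-identical across pools.
    When ``config.causal`` is set (and gene models are given), one mutant
    germinal insertion is placed inside an exon of a gene at the centre of
    the mapping interval; no decoy lands in that gene.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    L = config.genome_length_bp
    chrom = config.chrom
    tsd = config.tsd_span
    truth = TruthTable()

    causal_gene: GeneModel | None = None
    if config.causal and models:
        center = L // 2
        lo, hi = max(1, center - config.interval_halfwidth_bp), min(L, center + config.interval_halfwidth_bp)
        truth.interval = MappingInterval(chrom, lo, hi)
        inside = [m for m in models if m.start >= lo and m.end <= hi]
        if not inside:
            raise ValueError("no gene model inside the mapping interval")
        causal_gene = inside[int(rng.integers(0, len(inside)))]
        truth.causal_gene = causal_gene.gene_id

    grid = np.arange(1_000, L - 1_000 - tsd, 25)
    if causal_gene is not None:
        grid = grid[(grid < causal_gene.start - 200) | (grid > causal_gene.end + 200)]

    n_mut_specific = config.n_sites_mutant - config.n_shared - (1 if causal_gene is not None else 0)
    n_wt_specific = config.n_sites_wildtype - config.n_shared
    if n_mut_specific < 0:
        raise ValueError("n_sites_mutant too small for causal + shared sites")
    n_total = config.n_shared + n_mut_specific + n_wt_specific
    positions = rng.choice(grid, size=n_total, replace=False)

    def gene_at(start: int, end: int) -> str | None:
        if not models:
            return None
        for m in models:
            if m.overlaps(start, end, chrom):
                return m.gene_id
        return None

    groups = {
        ("mutant", "wildtype"): positions[: config.n_shared],
        ("mutant",): positions[config.n_shared : config.n_shared + n_mut_specific],
        ("wildtype",): positions[config.n_shared + n_mut_specific :],
    }
    for pools, pos_arr in groups.items():
        specific = len(pools) == 1
        n_som = min(rng.poisson(config.somatic_rate), len(pos_arr)) if specific else 0
        som_idx = set(rng.choice(len(pos_arr), size=n_som, replace=False)) if n_som else set()
        for i, p in enumerate(pos_arr):
            start = int(p)
            end = start + tsd - 1
            truth.insertions.append(
                PlantedInsertion(
                    chrom=chrom,
                    tsd_start=start,
                    tsd_end=end,
                    kind="somatic" if i in som_idx else "germinal",
                    pools=pools,
                    gene_id=gene_at(start, end),
                )
            )
    if causal_gene is not None:
        exons = causal_gene.exons_tx_order()
        es, ee = exons[min(1, len(exons) - 1)]
        start = int(rng.integers(es, ee - tsd + 1))
        truth.insertions.append(
            PlantedInsertion(
                chrom=chrom,
                tsd_start=start,
                tsd_end=start + tsd - 1,
                kind="germinal",
                pools=("mutant",),
                gene_id=causal_gene.gene_id,
                causal=True,
            )
        )
    return truth


def _draw_count(config: SimConfig, rng: np.random.Generator) -> int:
    """Germinal per-site read count: negative binomial conditioned on >= 1
    observation (a site is catalogued only because it was sequenced)."""
    r = config.read_count_dispersion
    p = r / (r + config.read_count_mean)
    while True:
        n = int(rng.negative_binomial(r, p))
        if n >= 1:
            return n


def draw_site_counts(
    config: SimConfig, truth: TruthTable, rng: np.random.Generator
) -> dict[tuple[int, str], int]:
    """Read count per (insertion index, pool)."""
    counts: dict[tuple[int, str], int] = {}
    for i, ins in enumerate(truth.insertions):
        for pool in ins.pools:
            counts[(i, pool)] = 1 if ins.kind == "somatic" else _draw_count(config, rng)
    return counts


def simulate_catalogs(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PoolCatalog, PoolCatalog, TruthTable]:
    """Two-pool MFS catalogs built directly from planted insertions
    (dual-anchor sites with drawn counts; no reads involved)."""
    rng = rng or np.random.default_rng(config.seed)
    truth = plant_insertions(config, models=None, rng=rng)
    counts = draw_site_counts(config, truth, rng)
    catalogs: dict[str, list[MFSSite]] = {p: [] for p in POOLS}
    for i, ins in enumerate(truth.insertions):
        for pool in ins.pools:
            site = MFSSite(ins.chrom, ins.tsd_start, ins.tsd_end, n_anchors=2)
            setattr(site, f"read_count_{pool}", counts[(i, pool)])
            catalogs[pool].append(site)
    for sites in catalogs.values():
        sites.sort(key=lambda s: (s.chrom, s.start))
    return (
        PoolCatalog("mutant", catalogs["mutant"]),
        PoolCatalog("wildtype", catalogs["wildtype"]),
        truth,
    )


# ----------------------------------------------------------------------
# read synthesis
# ----------------------------------------------------------------------

@dataclass
class SimReads:
    """Synthesized reads for one dataset: raw FASTQ-style reads (barcode and
    TIR attached) and matching truth alignments of the trimmed flanks."""

    header: pysam.AlignmentHeader
    reads: dict[str, list[RawRead]]
    alignments: dict[str, list[pysam.AlignedSegment]]
    counts: dict[tuple[int, str], int]


def synthesize_reads(
    config: SimConfig,
    genome: Mapping[str, str],
    truth: TruthTable,
    rng: np.random.Generator | None = None,
) -> SimReads:
    """Emit barcode+TIR+flank reads and their truth SAM records.

    Each germinal site's drawn count is split binomially between the left
    flank (forward-strand alignment ending at tsd_start - 1) and the right
    flank (reverse-strand alignment starting at tsd_end + 1).  All flanks
    are at least ``config.min_flank`` bp, so the length filter loses
    nothing by construction.  A configurable handful of multi-mapping read
    pairs (primary + secondary alignment) exercises the uniqueness filter.
    """
    rng = rng or np.random.default_rng(config.seed)
    seq = genome[config.chrom]
    L = len(seq)
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": config.chrom, "LN": L}]}
    )
    tir_expansions = TirPattern(MU_TIR).expansions()
    bc_of = {pool: bc for bc, pool in config.barcodes.items()}
    counts = draw_site_counts(config, truth, rng)
    reads: dict[str, list[RawRead]] = {p: [] for p in POOLS}
    alns: dict[str, list[pysam.AlignedSegment]] = {p: [] for p in POOLS}
    serial = {p: 0 for p in POOLS}

    def make_aln(name: str, pos1: int, flank: str, reverse: bool, flag_extra: int = 0) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = (16 if reverse else 0) | flag_extra
        a.reference_id = 0
        a.reference_start = pos1 - 1
        a.mapping_quality = 60
        a.cigarstring = f"{len(flank)}M"
        a.query_sequence = flank
        a.query_qualities = pysam.qualitystring_to_array("I" * len(flank))
        return a

    def emit(pool: str, ins: PlantedInsertion, side: str) -> None:
        serial[pool] += 1
        name = f"{pool}_{serial[pool]:07d}"
        flen = int(rng.integers(config.min_flank, config.max_flank + 1))
        tir = tir_expansions[int(rng.integers(0, len(tir_expansions)))]
        if side == "left":
            end1 = ins.tsd_start - 1
            start1 = max(1, end1 - flen + 1)
            segment = seq[start1 - 1 : end1]
            fastq_seq = bc_of[pool] + tir + segment
            alns[pool].append(make_aln(name, start1, segment, reverse=False))
        else:
            start1 = ins.tsd_end + 1
            segment = seq[start1 - 1 : min(L, start1 - 1 + flen)]
            fastq_seq = bc_of[pool] + tir + str(Seq(segment).reverse_complement())
            alns[pool].append(make_aln(name, start1, segment, reverse=True))
        reads[pool].append(RawRead(name, fastq_seq, "I" * len(fastq_seq)))

    for i, ins in enumerate(truth.insertions):
        for pool in ins.pools:
            c = counts[(i, pool)]
            left_n = int(rng.binomial(c, 0.5))
            for _ in range(left_n):
                emit(pool, ins, "left")
            for _ in range(c - left_n):
                emit(pool, ins, "right")

    # multi-mapping decoys: one primary + one secondary alignment each
    germinal = [ins for ins in truth.insertions if ins.kind == "germinal"]
    for k in range(config.n_multimapped_reads):
        pool = POOLS[k % 2]
        ins = germinal[int(rng.integers(0, len(germinal)))]
        if pool not in ins.pools:
            ins = next(i for i in germinal if pool in i.pools)
        serial[pool] += 1
        name = f"{pool}_mm_{serial[pool]:07d}"
        flen = int(rng.integers(config.min_flank, config.max_flank + 1))
        end1 = ins.tsd_start - 1
        start1 = max(1, end1 - flen + 1)
        segment = seq[start1 - 1 : end1]
        tir = tir_expansions[int(rng.integers(0, len(tir_expansions)))]
        reads[pool].append(RawRead(name, bc_of[pool] + tir + segment, "I" * (len(segment) + len(tir) + len(bc_of[pool]))))
        alns[pool].append(make_aln(name, start1, segment, reverse=False))
        alt_pos = int(rng.integers(1, L - flen))
        alns[pool].append(make_aln(name, alt_pos, segment, reverse=False, flag_extra=256))
    return SimReads(header=header, reads=reads, alignments=alns, counts=counts)


# ----------------------------------------------------------------------
# EMS variant planting
# ----------------------------------------------------------------------

def _classify_codon_change(codon: str, j: int, alt_base: str) -> str:
    new = codon[:j] + alt_base + codon[j + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(new).translate())
    if alt_aa == "*" and ref_aa != "*":
        return "PTC"
    if ref_aa == alt_aa:
        return "synonymous"
    return "non_synonymous"


def plant_ems_variants(
    config: SimConfig,
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
    max_tries: int = 500,
) -> tuple[list[SnpRecord], PanelGenotypes, list[PlantedVariant]]:
    """Realize requested lesion categories as EMS-style transitions.

    Each request (gene index, category) is planted as a G->A or C->T change
    (in CDS orientation; strand-aware on the genome) at a codon position that
    forces the category, with bounded retries.  Transversion decoys and
    founder-panel-shared decoys are added per the config.
    """
    rng = rng or np.random.default_rng(config.seed)
    snps: list[SnpRecord] = []
    planted: list[PlantedVariant] = []
    panel = PanelGenotypes(f"F{i:02d}" for i in range(1, config.n_founders + 1))
    founders = sorted(panel.founders)
    serial = 0

    def realize(model: GeneModel, cds_pos: int, alt_cds: str) -> tuple[int, str, str]:
        gpos = model.genomic_pos_of_cds_index(cds_pos)
        gref = genome[model.chrom][gpos - 1]
        galt = alt_cds if model.strand == "+" else _complement(alt_cds)
        return gpos, gref, galt

    def add(model: GeneModel, pos: int, ref: str, alt: str, category: str, decoy: str | None) -> SnpRecord:
        nonlocal serial
        serial += 1
        name = f"allele_{serial:02d}_{category}"
        snp = SnpRecord(model.chrom, pos, ref, alt, allele_name=name)
        snps.append(snp)
        planted.append(
            PlantedVariant(model.chrom, pos, ref, alt, model.gene_id, category, name, decoy)
        )
        return snp

    def plant_coding(model: GeneModel, category: str, transition: bool = True, decoy: str | None = None) -> None:
        cds = model.cds_sequence(genome[model.chrom])
        n_codons = len(cds) // 3
        for _ in range(max_tries):
            ci = int(rng.integers(1, n_codons - 1))  # skip start and stop codons
            codon = cds[ci * 3 : ci * 3 + 3]
            j = int(rng.integers(0, 3))
            base = codon[j]
            if transition:
                if base not in "GC":
                    continue
                alt = "A" if base == "G" else "T"
            else:  # transversion decoy
                if base != "C":
                    continue
                alt = "A"
            got = _classify_codon_change(codon, j, alt)
            if got != category:
                continue
            pos, gref, galt = realize(model, ci * 3 + j + 1, alt)
            add(model, pos, gref, galt, category, decoy)
            return
        raise RuntimeError(f"could not realize a {category} lesion in {model.gene_id}")

    for gene_index, category in config.ems_variants:
        model = models[gene_index % len(models)]
        if category in ("PTC", "non_synonymous", "synonymous"):
            plant_coding(model, category)
        elif category == "upstream":
            seq = genome[model.chrom]
            for _ in range(max_tries):
                offset = int(rng.integers(10, 500))
                pos = (model.cds_start_codon_pos() - offset) if model.strand == "+" else (
                    model.cds_start_codon_pos() + offset
                )
                if not 1 <= pos <= len(seq) or model.contains(pos):
                    continue
                base = seq[pos - 1]
                if base not in "GC":
                    continue
                add(model, pos, base, "A" if base == "G" else "T", "upstream", None)
                break
            else:
                raise RuntimeError(f"could not place an upstream lesion near {model.gene_id}")
        else:
            raise ValueError(f"unsupported requested category {category!r}")

    for _ in range(config.n_transversion_decoys):
        model = models[int(rng.integers(0, len(models)))]
        plant_coding(model, "non_synonymous", transition=False, decoy="transversion")
    for _ in range(config.n_panel_decoys):
        model = models[int(rng.integers(0, len(models)))]
        plant_coding(model, "non_synonymous", transition=True, decoy="panel")
        v = planted[-1]
        carrier = founders[int(rng.integers(0, len(founders)))]
        panel.add_call(v.chrom, v.pos, carrier, v.alt, support=int(rng.integers(3, 12)))

    # background founder calls: a few founders confirmed reference everywhere
    for v in planted:
        for f in founders[:3]:
            if not panel.founders_with_alt(v.chrom, v.pos, v.alt):
                panel.add_call(v.chrom, v.pos, f, v.ref, support=int(rng.integers(5, 20)))
    return snps, panel, planted


# ----------------------------------------------------------------------
# full dataset emission
# ----------------------------------------------------------------------

def deg_table_for(
    models: Sequence[GeneModel], truth: TruthTable, rng: np.random.Generator
) -> dict[str, DegRecord]:
    """Differential-expression evidence: the causal gene is a strong DEG,
    every other gene is null with noise."""
    out: dict[str, DegRecord] = {}
    for m in models:
        if truth.causal_gene == m.gene_id:
            out[m.gene_id] = DegRecord(m.gene_id, log2_fold_change=5.2, q_value=0.001)
        else:
            out[m.gene_id] = DegRecord(
                m.gene_id,
                log2_fold_change=float(rng.normal(0, 0.5)),
                q_value=float(rng.uniform(0.2, 0.95)),
            )
    return out


def write_dataset(config: SimConfig, outdir: str) -> TruthTable:
    """Generate and write a complete self-contained dataset.

    Writes genome.fasta, genes.gff3, per-pool FASTQ and SAM, interval.bed,
    deg.tsv, snps.tsv, panel.tsv and truth.json.  Byte-identical for a fixed
    config (determinism is part of the contract).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, models = simulate_reference(config, rng)
    truth = plant_insertions(config, models, rng)
    sim = synthesize_reads(config, genome, truth, rng)
    snps, panel, variants = plant_ems_variants(config, genome, models, rng)
    truth.variants = variants

    write_fasta(genome, out / "genome.fasta")
    write_gff3(models, out / "genes.gff3")
    for pool in POOLS:
        with open(out / f"{pool}.fastq", "w") as fh:
            for r in sim.reads[pool]:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
        with pysam.AlignmentFile(str(out / f"{pool}.sam"), "w", header=sim.header) as sam:
            for a in sim.alignments[pool]:
                sam.write(a)
    if truth.interval:
        with open(out / "interval.bed", "w") as fh:
            iv = truth.interval
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tmapping_interval\n")
    deg = deg_table_for(models, truth, rng)
    with open(out / "deg.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tq_value\n")
        for d in deg.values():
            fh.write(f"{d.gene_id}\t{d.log2_fold_change:.4f}\t{d.q_value:.4f}\n")
    with open(out / "snps.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tallele\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{s.allele_name}\n")
    panel.write_tsv(out / "panel.tsv")
    truth.to_json(out / "truth.json")
    return truth
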