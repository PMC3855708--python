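import numpy as np
import pysam
import pytest

from muwalk.models import GeneModel
from muwalk.simulate import SimConfig, plant_insertions, simulate_reference, synthesize_reads


def make_header(chrom: str = "chr3", length: int = 50_000_000) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
    )


def make_aln(
    header: pysam.AlignmentHeader,
    name: str,
    start1: int,
    length: int = 100,
    reverse: bool = False,
    mapq: int = 60,
    flag_extra: int = 0,
    unmapped: bool = False,
) -> pysam.AlignedSegment:
    """A minimal aligned segment with a 1-based start and all-M cigar."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = (16 if reverse else 0) | flag_extra | (4 if unmapped else 0)
    if not unmapped:
        a.reference_id = 0
        a.reference_start = start1 - 1
        a.cigarstring = f"{length}M"
    a.mapping_quality = mapq
    a.query_sequence = "A" * length
    return a


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: one causal insertion in a DEG gene inside the
    mapping interval among >= 50 decoy insertions, somatic noise on."""
    return SimConfig(
        seed=7,
        genome_length_bp=400_000,
        n_genes=12,
        n_sites_mutant=60,
        n_sites_wildtype=25,
        n_shared=8,
        somatic_rate=5,
        interval_halfwidth_bp=60_000,
    )


@pytest.fixture(scope="session")
def sim_dataset(small_config):
    """(genome, models, truth, sim_reads) for the scaled study, shared
    across tests; treat as read-only."""
    rng = np.random.default_rng(small_config.seed)
    genome, models = simulate_reference(small_config, rng)
    truth = plant_insertions(small_config, models, rng)
    sim = synthesize_reads(small_config, genome, truth, rng)
    return genome, models, truth, sim


def toy_gene(
    strand: str = "+",
    cds: str = "ATGCAGCAGTGA",
    flank: int = 100,
    rng_seed: int = 5,
    utr: int = 0,
) -> tuple[dict[str, str], GeneModel]:
    """A single-exon toy gene embedded in random sequence.

    The CDS occupies positions [flank+1, flank+len(cds)]; for a minus-strand
    gene the genomic segment is the reverse complement so the spliced CDS is
    identical on both strands.  ``utr`` extends the exon by that many bases
    on each side of the CDS.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    left = "".join(bases[rng.integers(0, 4, flank)])
    right = "".join(bases[rng.integers(0, 4, flank)])
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    seq = left + genomic + right
    cds_span = (flank + 1, flank + len(cds))
    exon_span = (cds_span[0] - utr, cds_span[1] + utr)
    model = GeneModel(
        gene_id="TOY1",
        chrom="chrT",
        strand=strand,
        start=exon_span[0],
        end=exon_span[1],
        exons=[exon_span],
        cds=[cds_span],
    )
    return {"chrT": seq}, model
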