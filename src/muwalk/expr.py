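"""Expression arithmetic: qPCR relative quantification, RPKM,
upper-quartile normalization factors, and report fractions."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass
class CtPair:
    """A qPCR cycle-threshold pair: target gene vs. endogenous reference."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"Ct values must be finite and >= 0, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def rq(ct_target: float | CtPair, ct_reference: float | None = None) -> float:
    """Relative quantification by the 2^-dCt method, dCt = Ct(target) - Ct(ref)."""
    if isinstance(ct_target, CtPair):
        pair = ct_target
    else:
        if ct_reference is None:
            raise TypeError("rq() needs a CtPair or two Ct values")
        pair = CtPair(ct_target, ct_reference)
    return 2.0 ** (-pair.delta_ct)


def rpkm(read_count: int, gene_length_bp: int, library_mapped_reads: int) -> float:
    """Reads per kilobase of gene model per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if library_mapped_reads <= 0:
        raise ValueError("library_mapped_reads must be > 0")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return read_count / (gene_length_bp / 1_000) / (library_mapped_reads / 1_000_000)


@dataclass
class ExpressionMeasure:
    """Per-gene expression with its RPKM value."""

    gene_id: str
    read_count: int
    gene_length_bp: int
    library_mapped_reads: int

    @property
    def rpkm(self) -> float:
        return rpkm(self.read_count, self.gene_length_bp, self.library_mapped_reads)


def upper_quartile_factor(counts) -> float:
    """Per-sample normalization factor: the 0.75 quantile of the per-gene
    read-count vector, computed with linear interpolation between order
    statistics (numpy's default convention)."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or not np.any(arr > 0):
        raise ValueError("upper_quartile_factor needs at least one nonzero count")
    return float(np.quantile(arr, 0.75))


def report_fraction(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * n / d, rounded half-up to ``decimals`` (as printed in reports)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    pct = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))
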