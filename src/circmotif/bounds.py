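"""Exon-span and exon-composition bounds for a large circRNA from a
circAST-style exon-inclusion matrix.

The back-splice junction fixes the circle's outer span (donor - acceptor + 1
exons).  RNase-R-enriched sequencing tells which in-span exons were ever
detected inside circRNAs from that region: exons detected in no sample
cannot be part of the circle (upper bound = span - never_included), exons
detected in every sample are taken as its robust core (lower bound =
always_detected).  When exon lengths are available the same sets give
nucleotide size bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import CircJunction, ExonModel, InclusionMatrix, ModelError


@dataclass(frozen=True)
class BoundsResult:
    span_exons: int
    never_included: int
    always_detected: int
    max_exons: int
    min_exons: int
    min_size_nt: Optional[int] = None
    max_size_nt: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.min_exons <= self.max_exons <= self.span_exons:
            raise ModelError(
                f"inconsistent bounds: min {self.min_exons}, max "
                f"{self.max_exons}, span {self.span_exons}"
            )


def exon_span(cj: CircJunction) -> int:
    """Number of exons the circle can span, donor and acceptor inclusive."""
    if cj.acceptor_exon > cj.donor_exon:
        raise ModelError(f"{cj.junction_id}: acceptor downstream of donor")
    return cj.donor_exon - cj.acceptor_exon + 1


def bounds_from_inclusion(
    cj: CircJunction,
    matrix: InclusionMatrix,
    model: Optional[ExonModel] = None,
) -> BoundsResult:
    """Exon-content (and optionally nt-size) bounds for the focal circle."""
    span = exon_span(cj)
    span_exons = range(cj.acceptor_exon, cj.donor_exon + 1)
    missing = [e for e in span_exons if e not in matrix.exon_numbers]
    if missing:
        raise ModelError(
            f"{cj.junction_id}: inclusion matrix missing in-span exons {missing}"
        )
    never = [e for e in span_exons if not any(matrix.row(e))]
    always = [e for e in span_exons if all(matrix.row(e))]
    min_size = max_size = None
    if model is not None:
        min_size = sum(model.exon_length(e) for e in always)
        max_size = sum(
            model.exon_length(e) for e in span_exons if e not in set(never)
        )
    return BoundsResult(
        span_exons=span,
        never_included=len(never),
        always_detected=len(always),
        max_exons=span - len(never),
        min_exons=len(always),
        min_size_nt=min_size,
        max_size_nt=max_size,
    )
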