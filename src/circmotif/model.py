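"""Domain types shared by all analysis stages.

Coordinate conventions
----------------------
All positions are 1-based and inclusive (GTF/VCF style); the BED reader/writer
converts at the boundary.  Exon lists are kept in *transcript* (5'->3') order,
so on the minus strand genomic coordinates descend.  Junction and motif
sequences are always expressed in transcript orientation; genomic positions
are recovered through :class:`ExonModel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

NUCLEOTIDES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degenerate nucleotide codes -> the set of concrete bases matched.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ModelError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass(frozen=True)
class GenomeSeq:
    """A single contig: a name and its nucleotide sequence (A/C/G/T/N)."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ModelError(f"contig {self.contig_name!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ModelError(
                f"contig {self.contig_name!r}: non-ACGTN characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise ModelError(
                f"position {pos} outside contig {self.contig_name!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[pos - 1]

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ModelError(
                f"interval [{start}, {end}] outside contig {self.contig_name!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


class Genome(Mapping[str, GenomeSeq]):
    """Immutable mapping of contig name -> :class:`GenomeSeq`."""

    def __init__(self, contigs: Sequence[GenomeSeq]):
        self._contigs = {c.contig_name: c for c in contigs}

    def __getitem__(self, name: str) -> GenomeSeq:
        try:
            return self._contigs[name]
        except KeyError:
            raise ModelError(f"unknown contig {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def base(self, contig: str, pos: int) -> str:
        return self[contig].base(pos)

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self[contig].fetch(start, end)


@dataclass(frozen=True)
class ExonModel:
    """Ordered, numbered exons of one transcript.

    ``exons`` holds (start, end) genomic intervals in transcript order, so
    exon_number i corresponds to ``exons[i - 1]``.  ``cds`` is an optional
    (start, end) in *transcript* coordinates, 1-based inclusive, whose length
    must be divisible by 3.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(
                f"{self.transcript_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: empty exon list")
        for s, e in self.exons:
            if s > e or s < 1:
                raise ModelError(
                    f"{self.transcript_id}: bad exon interval ({s}, {e})"
                )
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ModelError(
                    f"{self.transcript_id}: overlapping exons "
                    f"({s1}, {e1}) and ({s2}, {e2})"
                )
        expect = ordered if self.strand == "+" else ordered[::-1]
        if tuple(expect) != self.exons:
            raise ModelError(
                f"{self.transcript_id}: exons not in transcript (5'->3') order "
                f"for strand {self.strand}"
            )
        if self.cds is not None:
            cs, ce = self.cds
            if not (1 <= cs <= ce <= self.transcript_length):
                raise ModelError(f"{self.transcript_id}: CDS outside transcript")
            if (ce - cs + 1) % 3 != 0:
                raise ModelError(
                    f"{self.transcript_id}: CDS length not divisible by 3"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_interval(self, exon_number: int) -> tuple[int, int]:
        if not 1 <= exon_number <= self.n_exons:
            raise ModelError(
                f"{self.transcript_id}: exon {exon_number} out of range "
                f"1..{self.n_exons}"
            )
        return self.exons[exon_number - 1]

    def exon_length(self, exon_number: int) -> int:
        s, e = self.exon_interval(exon_number)
        return e - s + 1

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exon_sequence(self, genome: Genome, exon_number: int) -> str:
        """Exon sequence in transcript orientation."""
        s, e = self.exon_interval(exon_number)
        seq = genome.fetch(self.contig, s, e)
        return seq if self.strand == "+" else reverse_complement(seq)

    def exon_genomic_positions(self, exon_number: int) -> tuple[int, ...]:
        """Genomic positions of the exon's bases, in transcript order."""
        s, e = self.exon_interval(exon_number)
        pos = tuple(range(s, e + 1))
        return pos if self.strand == "+" else pos[::-1]

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a 1-based transcript position to its genomic position."""
        if tpos < 1:
            raise ModelError(f"transcript position {tpos} < 1")
        off = tpos
        for s, e in self.exons:
            n = e - s + 1
            if off <= n:
                return s + off - 1 if self.strand == "+" else e - off + 1
            off -= n
        raise ModelError(
            f"{self.transcript_id}: transcript position {tpos} beyond "
            f"length {self.transcript_length}"
        )

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position to a transcript position (exonic only)."""
        acc = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                within = gpos - s if self.strand == "+" else e - gpos
                return acc + within + 1
            acc += e - s + 1
        raise ModelError(
            f"{self.transcript_id}: genomic position {gpos} is not exonic"
        )

    def exon_of_transcript_pos(self, tpos: int) -> int:
        """Exon number containing a transcript position."""
        off = tpos
        for i, (s, e) in enumerate(self.exons, start=1):
            n = e - s + 1
            if off <= n:
                return i
            off -= n
        raise ModelError(
            f"{self.transcript_id}: transcript position {tpos} beyond end"
        )


def transcript_sequence(genome: Genome, model: ExonModel) -> str:
    """Mature (spliced) transcript sequence in transcript orientation.

    Exon sequences are concatenated in transcript order; minus-strand
    exons are reverse-complemented individually, which is equivalent to
    reverse-complementing the genomic concatenation.
    """
    contig = genome[model.contig]
    for s, e in model.exons:
        if e > len(contig):
            raise ModelError(
                f"{model.transcript_id}: exon ({s}, {e}) outside contig "
                f"{model.contig!r} (length {len(contig)})"
            )
    return "".join(
        model.exon_sequence(genome, i) for i in range(1, model.n_exons + 1)
    )


@dataclass(frozen=True)
class CircJunction:
    """One back-splice event: the donor end of the 3'-most exon of the circle
    joins the acceptor end of the 5'-most exon."""

    transcript_id: str
    acceptor_exon: int
    donor_exon: int
    dependency_class: str  # rbm20_dependent | rbm20_independent
    host_class: str  # TTN | other

    DEPENDENCY_CLASSES = ("rbm20_dependent", "rbm20_independent")
    HOST_CLASSES = ("TTN", "other")

    def __post_init__(self) -> None:
        if self.acceptor_exon > self.donor_exon:
            raise ModelError(
                f"{self.junction_id}: acceptor exon {self.acceptor_exon} "
                f"downstream of donor exon {self.donor_exon}"
            )
        if self.acceptor_exon < 1:
            raise ModelError(f"{self.junction_id}: exon numbers must be >= 1")
        if self.dependency_class not in self.DEPENDENCY_CLASSES:
            raise ModelError(
                f"{self.junction_id}: unknown dependency class "
                f"{self.dependency_class!r}"
            )
        if self.host_class not in self.HOST_CLASSES:
            raise ModelError(
                f"{self.junction_id}: unknown host class {self.host_class!r}"
            )

    @property
    def junction_id(self) -> str:
        return f"{self.transcript_id}:{self.acceptor_exon}-{self.donor_exon}"

    def validate_against(self, model: ExonModel) -> None:
        if self.donor_exon > model.n_exons:
            raise ModelError(
                f"{self.junction_id}: donor exon beyond transcript "
                f"({model.n_exons} exons)"
            )


@dataclass(frozen=True)
class JunctionSequence:
    """Fixed window around a junction, in transcript orientation.

    ``junction_offset`` bases precede the junction point.  ``genomic_positions``
    (parallel to ``seq``) records where each base lives on the genome so motif
    occurrences can be mapped back to genomic sites.
    """

    seq: str
    junction_offset: int
    origin: str  # "BSJ" | "LJ"
    source_id: str
    contig: str = ""
    genomic_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.junction_offset < len(self.seq):
            raise ModelError(
                f"{self.source_id}: junction offset {self.junction_offset} "
                f"not inside sequence of length {len(self.seq)}"
            )
        if self.origin not in ("BSJ", "LJ"):
            raise ModelError(f"{self.source_id}: unknown origin {self.origin!r}")
        if self.genomic_positions and len(self.genomic_positions) != len(self.seq):
            raise ModelError(
                f"{self.source_id}: genomic positions do not align with sequence"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with gnomAD-style allele bookkeeping."""

    contig: str
    pos: int
    ref: str
    alt: str
    allele_count: int
    allele_number: int
    median_depth: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ModelError(f"{self.contig}:{self.pos}: ref equals alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ModelError(f"{self.contig}:{self.pos}: not a SNV")
        if self.allele_count > self.allele_number:
            raise ModelError(f"{self.contig}:{self.pos}: AC > AN")
        if self.allele_number <= 0:
            raise ModelError(f"{self.contig}:{self.pos}: AN must be positive")
        if self.median_depth < 0:
            raise ModelError(f"{self.contig}:{self.pos}: negative depth")

    @property
    def allele_frequency(self) -> float:
        return self.allele_count / self.allele_number


class MutationRateTable:
    """Per-site, per-allele neutral mutation probabilities keyed by
    trinucleotide context, substitution and CpG methylation bin.

    Keys are strand-collapsed: a context and its reverse complement share one
    rate.  The canonical key has ref in {A, C}; CpG context means canonical
    ref == C with right neighbour G.  Methylation bins: 0 none, 1 partial,
    2 high; non-zero bins are defined for CpG contexts only.
    """

    METHYL_BINS = (0, 1, 2)

    def __init__(self, rates: Mapping[tuple[str, str, str, str, int], float]):
        self._rates: dict[tuple[str, str, str, str, int], float] = {}
        for (left, ref, alt, right, mbin), rate in rates.items():
            key = self.canonical_key(left, ref, alt, right)
            if rate <= 0:
                raise ModelError(f"rate for {key} bin {mbin} must be > 0")
            if mbin not in self.METHYL_BINS:
                raise ModelError(f"unknown methylation bin {mbin}")
            if mbin != 0 and not self.is_cpg_key(key):
                raise ModelError(
                    f"methylation bin {mbin} on non-CpG context {key}"
                )
            prev = self._rates.get(key + (mbin,))
            if prev is not None and prev != rate:
                raise ModelError(
                    f"conflicting strand-collapsed rates for {key} bin {mbin}"
                )
            self._rates[key + (mbin,)] = rate

    @staticmethod
    def canonical_key(left: str, ref: str, alt: str, right: str) -> tuple[str, str, str, str]:
        if ref in "GT":
            comp = dict(zip("ACGT", "TGCA"))
            return (comp[right], comp[ref], comp[alt], comp[left])
        return (left, ref, alt, right)

    @staticmethod
    def is_cpg_key(key: tuple[str, str, str, str]) -> bool:
        return key[1] == "C" and key[3] == "G"

    def rate(self, left: str, ref: str, alt: str, right: str, methyl_bin: int = 0) -> float:
        key = self.canonical_key(left, ref, alt, right)
        if methyl_bin != 0 and not self.is_cpg_key(key):
            raise ModelError(
                f"methylation bin {methyl_bin} requested for non-CpG context "
                f"{left}[{ref}>{alt}]{right}"
            )
        try:
            return self._rates[key + (methyl_bin,)]
        except KeyError:
            raise ModelError(
                f"no rate for context {left}[{ref}>{alt}]{right} "
                f"bin {methyl_bin}"
            ) from None

    def items(self):
        return self._rates.items()


@dataclass(frozen=True)
class MotifRecord:
    """One RBP binding motif, as an IUPAC consensus string."""

    motif_id: str
    rbp_name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ModelError(f"motif {self.motif_id}: pattern shorter than 3")
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ModelError(
                f"motif {self.motif_id}: non-IUPAC characters {sorted(bad)}"
            )


class MotifTable:
    """Ordered collection of :class:`MotifRecord` (ATtRACT-style)."""

    def __init__(self, records: Sequence[MotifRecord]):
        self.records = tuple(records)
        ids = [r.motif_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate motif ids in motif table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MotifRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class InclusionMatrix:
    """Exon x sample detection booleans from assembled, RNase-R-enriched
    circRNA sequencing (circAST-style output)."""

    exon_numbers: tuple[int, ...]
    samples: tuple[str, ...]
    detected: tuple[tuple[bool, ...], ...]  # rows follow exon_numbers

    def __post_init__(self) -> None:
        if not self.samples:
            raise ModelError("inclusion matrix needs at least one sample")
        if len(self.detected) != len(self.exon_numbers):
            raise ModelError("inclusion matrix rows do not match exon numbers")
        for row in self.detected:
            if len(row) != len(self.samples):
                raise ModelError("inclusion matrix row width != sample count")
        if len(set(self.exon_numbers)) != len(self.exon_numbers):
            raise ModelError("duplicate exon numbers in inclusion matrix")

    def row(self, exon_number: int) -> tuple[bool, ...]:
        try:
            i = self.exon_numbers.index(exon_number)
        except ValueError:
            raise ModelError(
                f"exon {exon_number} absent from inclusion matrix"
            ) from None
        return self.detected[i]


def _standard_code() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_name["Standard"]
    code = dict(table.forward_table)
    code.update({stop: "*" for stop in table.stop_codons})
    return code


STANDARD_CODE = _standard_code()


def translate_codon(codon: str) -> str:
    """Standard-code translation of one codon; '*' for stop."""
    try:
        return STANDARD_CODE[codon]
    except KeyError:
        raise ModelError(f"cannot translate codon {codon!r}") from None
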