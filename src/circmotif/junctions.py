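"""Back-splice and linear junction sequences, IUPAC motif occurrences, and
occurrence classification.

A back-splice junction (BSJ) joins the donor (3') end of the circle's
downstream exon to the acceptor (5') end of its upstream exon, so the window
``suffix(donor exon) ++ prefix(acceptor exon)`` exists only in the circular
molecule.  A linear junction (LJ) is an ordinary adjacent exon boundary in
the mature mRNA.  Exons shorter than the window are clamped to their length:
the window never walks into a neighbouring exon, keeping junction sequences
independent of the circle's uncertain internal splicing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from .model import (
    IUPAC_CODES,
    CircJunction,
    ExonModel,
    Genome,
    JunctionSequence,
    ModelError,
)


@dataclass(frozen=True)
class JunctionWindow:
    """Number of bases taken from each side of a junction (default 25)."""

    w: int = 25

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ModelError("junction window must be >= 1")


@dataclass(frozen=True)
class Occurrence:
    """One motif match inside a junction window or transcript."""

    start: int  # 0-based within the scanned sequence
    length: int
    spans_junction: bool

    @property
    def end(self) -> int:
        return self.start + self.length


def build_bsj_sequence(
    genome: Genome,
    model: ExonModel,
    cj: CircJunction,
    window: JunctionWindow = JunctionWindow(),
) -> JunctionSequence:
    """Window around a back-splice junction, in transcript orientation.

    Left half: last min(w, len) bases of the donor exon; right half: first
    min(w, len) bases of the acceptor exon.  ``junction_offset`` equals the
    donor-side length.  A single-exon circle yields suffix ++ prefix of the
    same exon.
    """
    cj.validate_against(model)
    w = window.w
    donor_seq = model.exon_sequence(genome, cj.donor_exon)
    acc_seq = model.exon_sequence(genome, cj.acceptor_exon)
    donor_pos = model.exon_genomic_positions(cj.donor_exon)
    acc_pos = model.exon_genomic_positions(cj.acceptor_exon)
    ld = min(w, len(donor_seq))
    la = min(w, len(acc_seq))
    return JunctionSequence(
        seq=donor_seq[-ld:] + acc_seq[:la],
        junction_offset=ld,
        origin="BSJ",
        source_id=cj.junction_id,
        contig=model.contig,
        genomic_positions=donor_pos[-ld:] + acc_pos[:la],
    )


def build_lj_sequences(
    genome: Genome,
    model: ExonModel,
    window: JunctionWindow = JunctionWindow(),
) -> list[JunctionSequence]:
    """One window per adjacent exon pair (i, i+1) of the linear transcript."""
    if model.n_exons < 2:
        raise ModelError(
            f"{model.transcript_id}: need >= 2 exons for linear junctions"
        )
    w = window.w
    out = []
    for i in range(1, model.n_exons):
        up = model.exon_sequence(genome, i)
        down = model.exon_sequence(genome, i + 1)
        up_pos = model.exon_genomic_positions(i)
        down_pos = model.exon_genomic_positions(i + 1)
        lu = min(w, len(up))
        ld = min(w, len(down))
        out.append(
            JunctionSequence(
                seq=up[-lu:] + down[:ld],
                junction_offset=lu,
                origin="LJ",
                source_id=f"{model.transcript_id}:LJ:{i}-{i + 1}",
                contig=model.contig,
                genomic_positions=up_pos[-lu:] + down_pos[:ld],
            )
        )
    return out


# ---------------------------------------------------------------------------
# IUPAC scanning

@lru_cache(maxsize=4096)
def compile_iupac(pattern: str) -> re.Pattern:
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ModelError(f"invalid IUPAC characters {sorted(bad)} in {pattern!r}")
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + "".join(sorted(IUPAC_CODES[c])) + "]"
        for c in pattern
    )
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({body}))")


def scan_string(seq: str, pattern: str) -> list[int]:
    """All 0-based start positions where ``pattern`` matches under IUPAC
    semantics (overlaps included).  'N' in the subject matches nothing."""
    if len(pattern) > len(seq):
        return []
    return [m.start() for m in compile_iupac(pattern).finditer(seq)]


def find_occurrences(js: JunctionSequence, pattern: str) -> list[Occurrence]:
    """IUPAC occurrences of ``pattern`` in a junction window; an occurrence
    spans the junction iff it covers bases on both sides of the offset."""
    k = len(pattern)
    return [
        Occurrence(
            start=s,
            length=k,
            spans_junction=(s < js.junction_offset and s + k > js.junction_offset),
        )
        for s in scan_string(js.seq, pattern)
    ]


# ---------------------------------------------------------------------------
# genomic classification of motif occurrences

@dataclass(frozen=True)
class ClassifiedOccurrence:
    """A motif occurrence with its formation class and genomic footprint.

    ``occurrence_class`` is one of bsj_created / lj_created / within_exon.
    ``inclusion`` labels whether the occurrence's exon(s) lie inside any
    circRNA span (included_in_circRNA / excluded); an LJ occurrence touching
    an included exon counts as included.
    """

    occurrence_class: str
    source_id: str
    pattern: str
    start: int
    contig: str
    genomic_sites: tuple[int, ...]
    inclusion: str


def included_exons(model: ExonModel, circ_set: Sequence[CircJunction]) -> set[int]:
    """Exon numbers lying within [acceptor, donor] of any circRNA of this
    transcript."""
    included: set[int] = set()
    for cj in circ_set:
        if cj.transcript_id != model.transcript_id:
            continue
        included.update(range(cj.acceptor_exon, cj.donor_exon + 1))
    return included


def _occurrence_sites(js: JunctionSequence, occ: Occurrence) -> tuple[int, ...]:
    if not js.genomic_positions:
        raise ModelError(
            f"{js.source_id}: occurrence cannot be mapped to the genome "
            "(no genomic positions on the window)"
        )
    return js.genomic_positions[occ.start : occ.end]


def classify_occurrence(
    model: ExonModel,
    circ_set: Sequence[CircJunction],
    js: JunctionSequence,
    occ: Occurrence,
    pattern: str,
) -> ClassifiedOccurrence:
    """Label one occurrence by how the sequence containing it was formed."""
    sites = _occurrence_sites(js, occ)
    incl = included_exons(model, circ_set)
    touched = {
        model.exon_of_transcript_pos(model.genomic_to_transcript(g)) for g in sites
    }
    if occ.spans_junction:
        cls = "bsj_created" if js.origin == "BSJ" else "lj_created"
    else:
        cls = "within_exon"
    inclusion = (
        "included_in_circRNA" if touched & incl else "excluded"
    )
    return ClassifiedOccurrence(
        occurrence_class=cls,
        source_id=js.source_id,
        pattern=pattern,
        start=occ.start,
        contig=js.contig,
        genomic_sites=sites,
        inclusion=inclusion,
    )


def collect_motif_occurrences(
    genome: Genome,
    model: ExonModel,
    circ_set: Sequence[CircJunction],
    pattern: str,
    window: JunctionWindow = JunctionWindow(),
) -> list[ClassifiedOccurrence]:
    """All classified occurrences of ``pattern`` on one transcript.

    BSJ-created: junction-spanning occurrences in the BSJ window of each
    circle.  LJ-created: junction-spanning occurrences at adjacent exon
    boundaries.  Within-exon: occurrences of the motif lying entirely inside
    a single exon, found by scanning each exon's sequence.  Non-spanning hits
    inside junction windows are *not* reported separately: the per-exon scan
    already covers them exactly once.
    """
    out: list[ClassifiedOccurrence] = []
    for cj in circ_set:
        if cj.transcript_id != model.transcript_id:
            continue
        js = build_bsj_sequence(genome, model, cj, window)
        for occ in find_occurrences(js, pattern):
            if occ.spans_junction:
                out.append(classify_occurrence(model, circ_set, js, occ, pattern))
    if model.n_exons >= 2:
        for js in build_lj_sequences(genome, model, window):
            for occ in find_occurrences(js, pattern):
                if occ.spans_junction:
                    out.append(
                        classify_occurrence(model, circ_set, js, occ, pattern)
                    )
    incl = included_exons(model, circ_set)
    for exon_number in range(1, model.n_exons + 1):
        seq = model.exon_sequence(genome, exon_number)
        pos = model.exon_genomic_positions(exon_number)
        for s in scan_string(seq, pattern):
            out.append(
                ClassifiedOccurrence(
                    occurrence_class="within_exon",
                    source_id=f"{model.transcript_id}:exon:{exon_number}",
                    pattern=pattern,
                    start=s,
                    contig=model.contig,
                    genomic_sites=pos[s : s + len(pattern)],
                    inclusion=(
                        "included_in_circRNA" if exon_number in incl else "excluded"
                    ),
                )
            )
    return out


def occurrence_report(occurrences: Iterable[ClassifiedOccurrence]):
    """Plot/diff-friendly table of classified occurrences."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "source_id": o.source_id,
                "pattern": o.pattern,
                "start": o.start,
                "occurrence_class": o.occurrence_class,
                "inclusion": o.inclusion,
                "contig": o.contig,
                "genomic_sites": ",".join(map(str, o.genomic_sites)),
            }
            for o in occurrences
        ]
    )
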