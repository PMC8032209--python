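"""Junction-spanning consensus discovery and RBP motif enrichment.

Consensus discovery is an exhaustive exact k-mer vote: for every k in the
searched range, every k-mer that straddles the junction in a class member is
a candidate; the winner maximises the fraction of class sequences carrying a
junction-spanning exact occurrence (prevalence), with ties broken toward the
longer k-mer and then lexicographically.  The discovered object is a single
ungapped word, so exhaustive search is exact.

Enrichment between two sequence sets is a per-motif 2x2 presence table with
a two-sided Fisher exact test, a Haldane-Anscombe-corrected sample odds
ratio, and Benjamini-Hochberg adjustment across the motifs of the comparison.
For sets of very unequal length (full circRNA vs linear mRNA) presence is
counted on non-overlapping 500-nt tiles to remove length confounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .model import (
    CircJunction,
    ExonModel,
    Genome,
    JunctionSequence,
    ModelError,
    MotifTable,
)
from .junctions import JunctionWindow, build_bsj_sequence, included_exons, scan_string


@dataclass(frozen=True)
class ConsensusResult:
    """Winning junction-spanning k-mer of a circRNA class."""

    consensus: str
    k: int
    prevalence: float
    carrier_ids: tuple[str, ...] = ()
    diagnostic: str = ""

    @property
    def empty(self) -> bool:
        return not self.consensus


def _spanning_kmers(js: JunctionSequence, k: int) -> set[str]:
    """Exact k-mers of ``js.seq`` whose occurrence straddles the junction."""
    off = js.junction_offset
    lo = max(0, off - k + 1)
    hi = min(len(js.seq) - k, off - 1)
    return {js.seq[s : s + k] for s in range(lo, hi + 1)}


def discover_consensus(
    class_seqs: Sequence[JunctionSequence],
    k_min: int = 5,
    k_max: int = 12,
    min_prevalence: float = 0.5,
) -> ConsensusResult:
    """Exhaustive junction-spanning consensus of a sequence class.

    Returns an empty result (with a diagnostic) when no k-mer reaches
    ``min_prevalence``.  Prevalence is reported over the whole class.
    """
    if not class_seqs:
        raise ModelError("discover_consensus: empty sequence class")
    if k_min < 1 or k_min > k_max:
        raise ModelError(f"bad k range [{k_min}, {k_max}]")
    n = len(class_seqs)
    best: tuple[float, int, str] | None = None
    best_carriers: tuple[str, ...] = ()
    for k in range(k_min, k_max + 1):
        votes: Counter[str] = Counter()
        carriers: dict[str, list[str]] = {}
        for js in class_seqs:
            for kmer in _spanning_kmers(js, k):
                votes[kmer] += 1
                carriers.setdefault(kmer, []).append(js.source_id)
        for kmer, count in votes.items():
            prev = count / n
            if prev < min_prevalence:
                continue
            # maximise prevalence, then k, then lexicographic order
            key = (prev, k, kmer)
            if best is None or (
                (key[0], key[1]) > (best[0], best[1])
                or ((key[0], key[1]) == (best[0], best[1]) and kmer < best[2])
            ):
                best = key
                best_carriers = tuple(sorted(carriers[kmer]))
    if best is None:
        return ConsensusResult(
            "", 0, 0.0,
            diagnostic=(
                f"no junction-spanning k-mer (k in [{k_min}, {k_max}]) reaches "
                f"prevalence {min_prevalence} over {n} sequences"
            ),
        )
    prev, k, kmer = best
    return ConsensusResult(kmer, k, prev, carrier_ids=best_carriers)


# ---------------------------------------------------------------------------
# motif-table scanning and enrichment

def scan_motif_table(
    seqs: Mapping[str, str] | Sequence[JunctionSequence], motifs: MotifTable
) -> pd.DataFrame:
    """Presence matrix (sequence x motif): True iff >= 1 IUPAC occurrence
    anywhere in the sequence."""
    if not isinstance(seqs, Mapping):
        seqs = {js.source_id: js.seq for js in seqs}
    data = {
        m.motif_id: [bool(scan_string(s, m.pattern)) for s in seqs.values()]
        for m in motifs
    }
    return pd.DataFrame(data, index=list(seqs.keys()), dtype=bool)


@dataclass(frozen=True)
class EnrichmentRow:
    motif_id: str
    rbp_name: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    odds_ratio: float
    p_value: float
    q_value: float = field(default=float("nan"), compare=False)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample OR for table (a, b; c, d) with Haldane-Anscombe 0.5 added to
    every cell when any cell is zero."""
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def enrichment_compare(
    set_a: Mapping[str, str] | Sequence[JunctionSequence],
    set_b: Mapping[str, str] | Sequence[JunctionSequence],
    motifs: MotifTable,
) -> list[EnrichmentRow]:
    """Per-motif presence enrichment between two sequence sets.

    For each motif the 2x2 table is (present_a, absent_a; present_b,
    absent_b); the p-value is the two-sided Fisher exact test and q-values
    are BH-adjusted across the motifs of this comparison only.
    """
    pres_a = scan_motif_table(set_a, motifs)
    pres_b = scan_motif_table(set_b, motifs)
    if pres_a.shape[0] == 0 or pres_b.shape[0] == 0:
        raise ModelError("enrichment_compare: a set has zero sequences")
    return _rows_from_presence(pres_a, pres_b, motifs)


def _rows_from_presence(
    pres_a: pd.DataFrame, pres_b: pd.DataFrame, motifs: MotifTable
) -> list[EnrichmentRow]:
    rows = []
    na, nb = pres_a.shape[0], pres_b.shape[0]
    for m in motifs:
        ca = int(pres_a[m.motif_id].sum())
        cb = int(pres_b[m.motif_id].sum())
        table = [[ca, na - ca], [cb, nb - cb]]
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            EnrichmentRow(
                m.motif_id, m.rbp_name, ca, na, cb, nb,
                _sample_odds_ratio(ca, na - ca, cb, nb - cb), float(p),
            )
        )
    if rows:
        _, q, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        rows = [
            EnrichmentRow(
                r.motif_id, r.rbp_name, r.count_a, r.total_a, r.count_b,
                r.total_b, r.odds_ratio, r.p_value, float(qi),
            )
            for r, qi in zip(rows, q)
        ]
    return rows


def tile_sequences(seqs: Mapping[str, str], tile: int = 500) -> dict[str, str]:
    """Cut sequences into non-overlapping tiles (last partial tile kept)."""
    out = {}
    for sid, s in seqs.items():
        for i, start in enumerate(range(0, len(s), tile)):
            out[f"{sid}:tile{i}"] = s[start : start + tile]
    return out


def enrichment_compare_tiled(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    motifs: MotifTable,
    tile: int = 500,
) -> list[EnrichmentRow]:
    """Presence enrichment on non-overlapping tiles, for sets whose sequences
    differ grossly in length (e.g. full circRNAs vs the linear mRNA)."""
    return enrichment_compare(
        tile_sequences(set_a, tile), tile_sequences(set_b, tile), motifs
    )


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "rbp_name": r.rbp_name,
                "count_a": r.count_a,
                "total_a": r.total_a,
                "count_b": r.count_b,
                "total_b": r.total_b,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# standard comparison bundle

def circle_sequence(genome: Genome, model: ExonModel, cj: CircJunction) -> str:
    """Mature circle sequence: concatenated exons acceptor..donor.  Internal
    linear splicing inside the circle is unknown, so all spanned exons are
    kept."""
    return "".join(
        model.exon_sequence(genome, i)
        for i in range(cj.acceptor_exon, cj.donor_exon + 1)
    )


def circularize(seq: str, wrap: int) -> str:
    """Append the first ``wrap`` bases so scans respect circular topology."""
    return seq + seq[: max(0, min(wrap, len(seq) - 1))]


def run_standard_comparisons(
    genome: Genome,
    models: Mapping[str, ExonModel],
    circ_set: Sequence[CircJunction],
    motifs: MotifTable,
    ttn_transcript: str,
    window: JunctionWindow = JunctionWindow(),
    tile: int = 500,
) -> dict[str, list[EnrichmentRow]]:
    """The five standard enrichment comparisons.

    1. bsj_dependent_vs_independent — BSJ windows, RBM20-dependent vs
       -independent circRNAs.
    2. bsj_ttn_vs_nonttn — BSJ windows, TTN-derived vs other circRNAs.
    3. circ_ttn_vs_nonttn — full circle sequences (circular topology),
       TTN-derived vs other circRNAs.
    4. circ_ttn_vs_linear_mrna — full TTN circle sequences vs the linear TTN
       mRNA, tiled to remove length confounding.
    5. exons_included_vs_excluded — TTN exon sequences inside vs outside
       every circRNA span.
    """
    from .model import transcript_sequence

    present = {cj.dependency_class for cj in circ_set}
    missing = set(CircJunction.DEPENDENCY_CLASSES) - present
    if missing:
        raise ModelError(f"missing dependency classes: {sorted(missing)}")
    if ttn_transcript not in models:
        raise ModelError(f"unknown focal transcript {ttn_transcript!r}")

    max_len = max(len(m.pattern) for m in motifs) if len(motifs) else 1

    def bsj_windows(junctions):
        return {
            cj.junction_id: build_bsj_sequence(
                genome, models[cj.transcript_id], cj, window
            ).seq
            for cj in junctions
        }

    def circle_seqs(junctions):
        return {
            cj.junction_id: circularize(
                circle_sequence(genome, models[cj.transcript_id], cj), max_len - 1
            )
            for cj in junctions
        }

    dep = [c for c in circ_set if c.dependency_class == "rbm20_dependent"]
    indep = [c for c in circ_set if c.dependency_class == "rbm20_independent"]
    ttn = [c for c in circ_set if c.host_class == "TTN"]
    other = [c for c in circ_set if c.host_class == "other"]
    ttn_model = models[ttn_transcript]
    incl = included_exons(ttn_model, circ_set)
    exon_seqs_in = {
        f"{ttn_transcript}:exon:{i}": ttn_model.exon_sequence(genome, i)
        for i in range(1, ttn_model.n_exons + 1)
        if i in incl
    }
    exon_seqs_out = {
        f"{ttn_transcript}:exon:{i}": ttn_model.exon_sequence(genome, i)
        for i in range(1, ttn_model.n_exons + 1)
        if i not in incl
    }
    return {
        "bsj_dependent_vs_independent": enrichment_compare(
            bsj_windows(dep), bsj_windows(indep), motifs
        ),
        "bsj_ttn_vs_nonttn": enrichment_compare(
            bsj_windows(ttn), bsj_windows(other), motifs
        ),
        "circ_ttn_vs_nonttn": enrichment_compare(
            circle_seqs(ttn), circle_seqs(other), motifs
        ),
        "circ_ttn_vs_linear_mrna": enrichment_compare_tiled(
            {cj.junction_id: circle_sequence(genome, ttn_model, cj) for cj in ttn},
            {ttn_transcript: transcript_sequence(genome, ttn_model)},
            motifs,
            tile=tile,
        ),
        "exons_included_vs_excluded": enrichment_compare(
            exon_seqs_in, exon_seqs_out, motifs
        ),
    }
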