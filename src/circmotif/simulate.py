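"""Synthetic data generator for the whole pipeline.

The generator builds a TTN-like gene (363 exons, circRNA-producing "I-band"
sub-region spanning exons 79-145) plus background genes, plants an 8-nt
motif (default AAAGAACC, split 4 donor-side + 4 acceptor-side) so that it is
*created by back-splicing* in a configured number of circRNA carriers, and
emits every input the analysis consumes: genome FASTA, exon annotation,
junction table, rare-variant VCF, mutation-rate table, methylation and depth
tracks, RBP motif table, exon-inclusion matrix, and a ground-truth manifest.

Ground truth is enforced, not merely sampled: after planting, every
non-carrier back-splice window is checked for junction-spanning fragments of
the planted motif (length >= 5) arising by chance or from shared edited
exons, and offending junctions are re-drawn.  Carrier and non-carrier sets
are therefore exact for any seed, which is what makes plant-and-recover
round trips deterministic.

Rare variants are drawn per site and alt allele as Poisson counts with mean
rate x depth-ascertainment x class-specific selection thinning s (s = 1:
neutral; s < 1: purifying selection).  Depth ascertainment uses
min(1, ln d / ln d0) below the full-coverage threshold d0 = 30, which the
constraint stage re-fits from the data rather than being told.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as cio
from .constraint import enumerate_coding_consequences
from .junctions import JunctionWindow, build_bsj_sequence, find_occurrences
from .model import (
    CircJunction,
    ExonModel,
    Genome,
    GenomeSeq,
    InclusionMatrix,
    JunctionSequence,
    ModelError,
    MotifRecord,
    MotifTable,
    MutationRateTable,
    VariantRecord,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Defaults encode the study conditions the analysis is built around."""

    seed: int = 42
    n_exons: int = 363
    circ_region: tuple[int, int] = (79, 145)
    exon_len_range: tuple[int, int] = (50, 300)
    intron_len_range: tuple[int, int] = (100, 300)
    flank: int = 100
    n_dependent_circ: int = 63
    n_dependent_carriers: int = 44
    dependent_prevalence_target: float = 0.70
    n_other_circ: int = 200
    n_other_carriers: int = 3
    motif: str = "AAAGAACC"
    motif_split: tuple[int, int] = (4, 4)
    rare_af_threshold: float = 0.001
    selection_thinning: dict = field(
        default_factory=lambda: {
            "motif_bsj": 0.5,
            "motif_within_exon": 0.5,
            "motif_lj": 1.0,
            "synonymous": 1.0,
            "missense": 1.0,
            "truncating": 0.2,
        }
    )
    depth_log_mean: float = math.log(40.0)
    depth_log_sigma: float = 0.5
    depth_d0: float = 30.0
    n_samples_inclusion: int = 3
    never_included_exons: int = 9
    always_detected_exons: int = 35
    allele_number: int = 251496
    n_background_genes: int = 25
    background_exon_range: tuple[int, int] = (8, 30)
    n_lj_motif_included: int = 18
    n_lj_motif_excluded: int = 18
    n_within_motif_included: int = 24
    n_within_motif_excluded: int = 12
    ttn_transcript: str = "TTN_SYN"

    def __post_init__(self) -> None:
        if self.n_dependent_carriers > self.n_dependent_circ:
            raise ModelError("more carriers than dependent circRNAs")
        if sum(self.motif_split) != len(self.motif):
            raise ModelError("motif split does not sum to motif length")
        pct = round(100 * self.n_dependent_carriers / self.n_dependent_circ)
        if pct != round(100 * self.dependent_prevalence_target):
            raise ModelError(
                f"carrier fraction rounds to {pct}%, target is "
                f"{round(100 * self.dependent_prevalence_target)}%"
            )


def default_rate_table(
    transversion: float = 0.008,
    transition_fold: float = 3.0,
    cpg_partial_fold: float = 5.0,
    cpg_high_fold: float = 10.0,
) -> MutationRateTable:
    """Desk-scale neutral rate table: transitions 3x transversions; CpG C>T
    transitions elevated with methylation (5x / 10x the transversion rate at
    partial / high methylation).  Rates are per-site per-allele probabilities
    on a synthetic scale; real analyses must supply their own table."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    rates: dict[tuple[str, str, str, str, int], float] = {}
    for left in "ACGT":
        for ref in "AC":  # canonical refs; reverse complements collapse here
            for alt in "ACGT":
                if alt == ref:
                    continue
                for right in "ACGT":
                    base = (
                        transversion * transition_fold
                        if (ref, alt) in transitions
                        else transversion
                    )
                    rates[(left, ref, alt, right, 0)] = base
                    if ref == "C" and right == "G":
                        if (ref, alt) in transitions:
                            rates[(left, ref, alt, right, 1)] = (
                                transversion * cpg_partial_fold
                            )
                            rates[(left, ref, alt, right, 2)] = (
                                transversion * cpg_high_fold
                            )
                        else:
                            rates[(left, ref, alt, right, 1)] = base
                            rates[(left, ref, alt, right, 2)] = base
    return MutationRateTable(rates)


def default_motif_table(motif: str = "AAAGAACC") -> MotifTable:
    """ATtRACT-style table: the SRSF10 consensus plus decoy RBP motifs."""
    return MotifTable(
        [
            MotifRecord("M001", "SRSF10", motif),
            MotifRecord("M002", "SRSF1", "GGAGGA"),
            MotifRecord("M003", "PTBP1", "TCTTTCT"),
            MotifRecord("M004", "HNRNPA1", "TAGGGT"),
            MotifRecord("M005", "ELAVL1", "TTTRTTT"),
            MotifRecord("M006", "QKI", "ACTAAC"),
            MotifRecord("M007", "RBM20", "TCTT"),
            MotifRecord("M008", "SRSF2", "SSNG"),
        ]
    )


@dataclass
class SyntheticDataset:
    """Everything one seeded run of the generator produced."""

    cfg: SyntheticConfig
    genome: Genome
    models: dict[str, ExonModel]
    junctions: list[CircJunction]
    rates: MutationRateTable
    motif_table: MotifTable
    methylation: dict[tuple[str, int], float]
    depths: dict[tuple[str, int], float]
    variants: list[VariantRecord]
    inclusion: InclusionMatrix
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_genome_fasta(self.genome, out / "genome.fa")
        cio.write_gtf(self.models, out / "annotation.gtf")
        cio.write_exon_tsv(self.models, out / "exons.tsv")
        cio.write_junctions(self.junctions, out / "junctions.tsv")
        cio.write_vcf(self.variants, self.genome, out / "variants.vcf")
        cio.write_rate_table(self.rates, out / "rates.tsv")
        cio.write_motif_table(self.motif_table, out / "motifs.tsv")
        cio.write_position_table(self.methylation, "methyl_bin", out / "methylation.tsv")
        cio.write_position_table(self.depths, "median_depth", out / "depths.tsv")
        cio.write_inclusion_matrix(self.inclusion, out / "inclusion.tsv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


# ---------------------------------------------------------------------------
# genome and annotation

def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _build_transcript(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    transcript_id: str,
    contig: str,
    n_exons: int,
) -> tuple[list[str], ExonModel]:
    lo, hi = cfg.exon_len_range
    ilo, ihi = cfg.intron_len_range
    exon_lens = rng.integers(lo, hi + 1, size=n_exons)
    intron_lens = rng.integers(ilo, ihi + 1, size=max(n_exons - 1, 0))
    seq: list[str] = _random_bases(rng, cfg.flank)
    exons = []
    for i, elen in enumerate(exon_lens):
        start = len(seq) + 1
        seq.extend(_random_bases(rng, int(elen)))
        exons.append((start, len(seq)))
        if i < n_exons - 1:
            seq.extend(_random_bases(rng, int(intron_lens[i])))
    seq.extend(_random_bases(rng, cfg.flank))
    tx_len = int(exon_lens.sum())
    cds = (1, tx_len - tx_len % 3)
    model = ExonModel(transcript_id, contig, "+", tuple(exons), cds=cds)
    return seq, model


def generate_genome_and_annotation(
    cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, list[str]], dict[str, ExonModel]]:
    """Mutable genome (contig -> list of bases) plus exon models: one
    TTN-like multi-exon gene and the background genes hosting the non-TTN
    circRNA class."""
    rng = rng or np.random.default_rng(cfg.seed)
    contigs: dict[str, list[str]] = {}
    models: dict[str, ExonModel] = {}
    seq, model = _build_transcript(
        rng, cfg, cfg.ttn_transcript, "chrT", cfg.n_exons
    )
    contigs["chrT"] = seq
    models[cfg.ttn_transcript] = model
    for g in range(1, cfg.n_background_genes + 1):
        tid, contig = f"BG{g:02d}", f"chrB{g:02d}"
        n_ex = int(rng.integers(*cfg.background_exon_range))
        seq, model = _build_transcript(rng, cfg, tid, contig, n_ex)
        contigs[contig] = seq
        models[tid] = model
    return contigs, models


# ---------------------------------------------------------------------------
# circRNA junctions with planted carriers

def _plant(contigs, model: ExonModel, exon: int, offset: int, bases: str) -> None:
    """Overwrite ``bases`` inside an exon at 0-based transcript-orientation
    offset (plus-strand models only, which is all the generator builds)."""
    s, _ = model.exon_interval(exon)
    g0 = s + offset
    contigs[model.contig][g0 - 1 : g0 - 1 + len(bases)] = list(bases)


def _plant_junction_motif(contigs, model, donor_exon, acceptor_exon, cfg) -> None:
    nd, na = cfg.motif_split
    _plant(contigs, model, donor_exon, model.exon_length(donor_exon) - nd,
           cfg.motif[:nd])
    _plant(contigs, model, acceptor_exon, 0, cfg.motif[nd : nd + na])


def _motif_fragments(motif: str, min_len: int = 5) -> list[str]:
    return [
        motif[i : i + k]
        for k in range(min_len, len(motif) + 1)
        for i in range(len(motif) - k + 1)
    ]


def _window_is_clean(
    contigs, model: ExonModel, cj: CircJunction, cfg: SyntheticConfig
) -> bool:
    """True iff the junction's BSJ window has no junction-spanning occurrence
    of any fragment (>= 5 nt) of the planted motif.

    Reads the mutable genome directly (generator models are plus-strand), so
    it can run inside the planting loop without freezing the genome.
    """
    w = len(cfg.motif)
    ds, de = model.exon_interval(cj.donor_exon)
    as_, ae = model.exon_interval(cj.acceptor_exon)
    donor = "".join(contigs[model.contig][max(ds - 1, de - w) : de])
    acceptor = "".join(contigs[model.contig][as_ - 1 : min(ae, as_ - 1 + w)])
    js = JunctionSequence(
        seq=donor + acceptor, junction_offset=len(donor),
        origin="BSJ", source_id=cj.junction_id,
    )
    return not any(
        occ.spans_junction
        for frag in _motif_fragments(cfg.motif)
        for occ in find_occurrences(js, frag)
    )


def _sample_pairs(rng, n: int, lo: int, hi: int, taken: set) -> list[tuple[int, int]]:
    """Sample n distinct (acceptor < donor) exon pairs in [lo, hi]."""
    pairs = []
    tries = 0
    while len(pairs) < n:
        a = int(rng.integers(lo, hi))
        d = int(rng.integers(a + 1, hi + 1))
        if (a, d) not in taken:
            taken.add((a, d))
            pairs.append((a, d))
        tries += 1
        if tries > 100 * n + 1000:
            raise ModelError("could not sample enough distinct junction pairs")
    return pairs


def generate_circ_junctions(
    cfg: SyntheticConfig,
    contigs: dict[str, list[str]],
    models: dict[str, ExonModel],
    rng: np.random.Generator,
) -> tuple[list[CircJunction], dict]:
    """Sample both circRNA classes, plant carrier motif halves into the
    genome, and guarantee the carrier/non-carrier split by re-drawing any
    non-carrier whose window forms motif fragments by chance."""
    lo, hi = cfg.circ_region
    ttn = models[cfg.ttn_transcript]
    # focal junction first: the large circle spanning the whole region
    pairs = [(lo, hi)] + _sample_pairs(rng, cfg.n_dependent_circ - 1, lo, hi, {(lo, hi)})
    dependent = [
        CircJunction(cfg.ttn_transcript, a, d, "rbm20_dependent", "TTN")
        for a, d in pairs
    ]
    carriers = dependent[: cfg.n_dependent_carriers]

    other: list[CircJunction] = []
    bg_ids = sorted(t for t in models if t != cfg.ttn_transcript)
    taken_bg: set[tuple[str, int, int]] = set()
    while len(other) < cfg.n_other_circ:
        tid = bg_ids[int(rng.integers(0, len(bg_ids)))]
        n_ex = models[tid].n_exons
        a = int(rng.integers(1, n_ex))
        d = int(rng.integers(a + 1, n_ex + 1))
        if (tid, a, d) in taken_bg:
            continue
        taken_bg.add((tid, a, d))
        other.append(CircJunction(tid, a, d, "rbm20_independent", "other"))
    other_carriers = other[: cfg.n_other_carriers]

    for cj in carriers:
        _plant_junction_motif(contigs, ttn, cj.donor_exon, cj.acceptor_exon, cfg)
    for cj in other_carriers:
        _plant_junction_motif(
            contigs, models[cj.transcript_id], cj.donor_exon, cj.acceptor_exon, cfg
        )

    manifest = {
        "carriers_dependent": [cj.junction_id for cj in carriers],
        "carriers_other": [cj.junction_id for cj in other_carriers],
        "n_dependent_circ": cfg.n_dependent_circ,
        "n_other_circ": cfg.n_other_circ,
        "motif": cfg.motif,
        "motif_split": list(cfg.motif_split),
    }
    return dependent + other, manifest


def _enforce_ground_truth(
    cfg: SyntheticConfig,
    contigs,
    models,
    junctions: list[CircJunction],
    manifest: dict,
    rng: np.random.Generator,
) -> list[CircJunction]:
    """Re-draw non-carrier junctions whose windows are not motif-free."""
    carrier_ids = set(manifest["carriers_dependent"]) | set(manifest["carriers_other"])
    lo, hi = cfg.circ_region
    taken = {
        (cj.transcript_id, cj.acceptor_exon, cj.donor_exon) for cj in junctions
    }
    out = []
    for cj in junctions:
        if cj.junction_id in carrier_ids:
            out.append(cj)
            continue
        current = cj
        for _ in range(200):
            if _window_is_clean(contigs, models[current.transcript_id], current, cfg):
                break
            taken.discard(
                (current.transcript_id, current.acceptor_exon, current.donor_exon)
            )
            if cj.host_class == "TTN":
                a = int(rng.integers(lo, hi))
                d = int(rng.integers(a + 1, hi + 1))
                cand = (cfg.ttn_transcript, a, d)
            else:
                n_ex = models[cj.transcript_id].n_exons
                a = int(rng.integers(1, n_ex))
                d = int(rng.integers(a + 1, n_ex + 1))
                cand = (cj.transcript_id, a, d)
            if cand in taken:
                taken.add(
                    (current.transcript_id, current.acceptor_exon, current.donor_exon)
                )
                continue
            taken.add(cand)
            current = CircJunction(
                cand[0], cand[1], cand[2], cj.dependency_class, cj.host_class
            )
        else:
            raise ModelError(
                f"could not find a motif-free replacement for {cj.junction_id}"
            )
        out.append(current)
    # carriers must really carry the motif across their junction
    genome = Genome([GenomeSeq(c, "".join(s)) for c, s in contigs.items()])
    for cj in out:
        if cj.junction_id in carrier_ids:
            js = build_bsj_sequence(
                genome, models[cj.transcript_id], cj, JunctionWindow(len(cfg.motif))
            )
            if not any(o.spans_junction for o in find_occurrences(js, cfg.motif)):
                raise ModelError(f"carrier {cj.junction_id} lost its planted motif")
    return out


# ---------------------------------------------------------------------------
# linear-junction and within-exon motif plants

def plant_linear_and_exonic_motifs(
    cfg: SyntheticConfig,
    contigs,
    models,
    junctions: list[CircJunction],
    carrier_ids: set[str],
    rng: np.random.Generator,
) -> dict:
    """Plant the motif at TTN linear junctions (inside and outside the
    circRNA-covered region) and inside exon bodies, so the LJ and within-exon
    constraint classes are populated.

    LJ pairs sharing an edited exon end with a back-splice carrier are
    excluded: the LJ and BSJ site classes carry different selection signals,
    so their genomic footprints must stay disjoint for either to be
    recoverable.  The included-region quota shrinks if few conflict-free
    pairs remain.
    """
    ttn = models[cfg.ttn_transcript]
    covered: set[int] = set()
    carrier_donors: set[int] = set()
    carrier_acceptors: set[int] = set()
    for cj in junctions:
        if cj.transcript_id == cfg.ttn_transcript:
            covered.update(range(cj.acceptor_exon, cj.donor_exon + 1))
        if cj.junction_id in carrier_ids:
            carrier_donors.add(cj.donor_exon)
            carrier_acceptors.add(cj.acceptor_exon)
    pairs_in = [
        (i, i + 1)
        for i in range(1, ttn.n_exons)
        if i in covered and i + 1 in covered
        and i not in carrier_donors and i + 1 not in carrier_acceptors
    ]
    pairs_out = [
        (i, i + 1)
        for i in range(1, ttn.n_exons)
        if i not in covered and i + 1 not in covered
    ]
    n_in = min(cfg.n_lj_motif_included, len(pairs_in))
    sel_in = [pairs_in[j] for j in rng.choice(len(pairs_in), n_in, replace=False)]
    sel_out = [pairs_out[j] for j in rng.choice(len(pairs_out), cfg.n_lj_motif_excluded, replace=False)]
    for i, j in sel_in + sel_out:
        _plant_junction_motif(contigs, ttn, donor_exon=i, acceptor_exon=j, cfg=cfg)

    k = len(cfg.motif)
    exons_in = sorted(covered)
    exons_out = [e for e in range(1, ttn.n_exons + 1) if e not in covered]
    within = []
    for pool, n in (
        (exons_in, cfg.n_within_motif_included),
        (exons_out, cfg.n_within_motif_excluded),
    ):
        eligible = [e for e in pool if ttn.exon_length(e) >= k + 20]
        for e in (eligible[j] for j in rng.choice(len(eligible), n, replace=False)):
            off = int(rng.integers(10, ttn.exon_length(e) - k - 10 + 1))
            _plant(contigs, ttn, e, off, cfg.motif)
            within.append((int(e), off))
    return {
        "lj_plants_included": [list(p) for p in sel_in],
        "lj_plants_excluded": [list(p) for p in sel_out],
        "within_exon_plants": [list(p) for p in within],
    }


# ---------------------------------------------------------------------------
# methylation, depths, variants

def generate_methylation(
    genome: Genome, model: ExonModel, rng: np.random.Generator
) -> dict[tuple[str, int], float]:
    """Assign bins (0 none / 1 partial / 2 high) to exonic CpG cytosines."""
    out: dict[tuple[str, int], float] = {}
    contig = genome[model.contig]
    for s, e in model.exons:
        for pos in range(s, e + 1):
            if contig.base(pos) == "C" and pos < len(contig) and contig.base(pos + 1) == "G":
                out[(model.contig, pos)] = int(
                    rng.choice([0, 1, 2], p=[0.5, 0.2, 0.3])
                )
    return out


def generate_depths(
    cfg: SyntheticConfig, model: ExonModel, rng: np.random.Generator
) -> dict[tuple[str, int], float]:
    """Truncated log-normal median site depths over all exonic positions."""
    positions = [
        (model.contig, pos) for s, e in model.exons for pos in range(s, e + 1)
    ]
    d = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sigma, size=len(positions))
    d = np.maximum(d, 1.0)
    return {key: float(round(val, 2)) for key, val in zip(positions, d)}


def true_depth_factor(depth: float, d0: float = 30.0) -> float:
    """Ascertainment used when *generating* variants; the analysis re-fits
    its own depth model and never sees these coefficients."""
    if depth >= d0:
        return 1.0
    return min(1.0, math.log(max(depth, 1.0)) / math.log(d0))


def generate_variants(
    cfg: SyntheticConfig,
    genome: Genome,
    rates: MutationRateTable,
    site_classes: list,  # list[SiteClass], first match wins for thinning
    depths: dict[tuple[str, int], float],
    methylation: dict[tuple[str, int], float],
    rng: np.random.Generator,
    scale: float = 1.0,
) -> list[VariantRecord]:
    """Poisson-sample rare variants per site and alt allele.

    Thinning s comes from ``cfg.selection_thinning`` keyed by the label of
    the *first* site class containing the site-alt (classes are passed in
    priority order).  Allele counts are the Poisson draws themselves, so
    everything survives the rare filter (AN is gnomAD-sized).
    """
    from .constraint import _context, _methyl_bin

    assignments: dict[tuple[str, int, str], str] = {}
    for cls in site_classes:
        for (contig, pos), alts in cls.sites.items():
            for alt in alts:
                assignments.setdefault((contig, pos, alt), cls.label)

    keys = sorted(assignments)
    mus = np.empty(len(keys))
    deps = np.empty(len(keys))
    ref_bases = []
    for idx, (contig, pos, alt) in enumerate(keys):
        left, ref, right = _context(genome, contig, pos)
        mbin = _methyl_bin(methylation, contig, pos, left, ref, right)
        d = depths.get((contig, pos), cfg.depth_d0)
        s = cfg.selection_thinning.get(assignments[(contig, pos, alt)], 1.0)
        mus[idx] = (
            rates.rate(left, ref, alt, right, mbin)
            * scale
            * true_depth_factor(d, cfg.depth_d0)
            * s
        )
        deps[idx] = d
        ref_bases.append(ref)
    counts = rng.poisson(mus)
    out = []
    for (contig, pos, alt), ref, k, d in zip(keys, ref_bases, counts, deps):
        if k >= 1:
            out.append(
                VariantRecord(contig, pos, ref, alt, int(k), cfg.allele_number, float(d))
            )
    return out


# ---------------------------------------------------------------------------
# inclusion matrix

def generate_inclusion_matrix(
    cfg: SyntheticConfig, focal: CircJunction, rng: np.random.Generator
) -> InclusionMatrix:
    """Exon x sample detections over the focal span: a configured number of
    exons seen in no sample, a configured number seen in all samples, the
    rest in a random non-empty strict subset of samples.  The junction's own
    acceptor and donor exons are always detected."""
    span = list(range(focal.acceptor_exon, focal.donor_exon + 1))
    n = len(span)
    ns = cfg.n_samples_inclusion
    if cfg.never_included_exons + cfg.always_detected_exons > n:
        raise ModelError("never + always exceeds the focal span")
    interior = [e for e in span if e not in (focal.acceptor_exon, focal.donor_exon)]
    never = set(
        interior[j]
        for j in rng.choice(len(interior), cfg.never_included_exons, replace=False)
    )
    rest = [e for e in interior if e not in never]
    always = {focal.acceptor_exon, focal.donor_exon}
    always.update(
        rest[j]
        for j in rng.choice(len(rest), cfg.always_detected_exons - 2, replace=False)
    )
    strict_subsets = [
        tuple(bool(m & (1 << s)) for s in range(ns))
        for m in range(1, 2**ns - 1)
    ]
    rows = []
    for e in span:
        if e in never:
            rows.append(tuple([False] * ns))
        elif e in always:
            rows.append(tuple([True] * ns))
        else:
            rows.append(strict_subsets[int(rng.integers(0, len(strict_subsets)))])
    return InclusionMatrix(
        exon_numbers=tuple(span),
        samples=tuple(f"heart{i + 1}" for i in range(ns)),
        detected=tuple(rows),
    )


# ---------------------------------------------------------------------------
# one-shot generation

def generate(cfg: SyntheticConfig = SyntheticConfig(), include_variants: bool = True) -> SyntheticDataset:
    """Run the whole generator under one seed."""
    from .constraint import build_motif_site_classes, SiteClass
    from .junctions import collect_motif_occurrences

    rng = np.random.default_rng(cfg.seed)
    contigs, models = generate_genome_and_annotation(cfg, rng)
    junctions, manifest = generate_circ_junctions(cfg, contigs, models, rng)
    carrier_ids = set(manifest["carriers_dependent"]) | set(manifest["carriers_other"])
    plant_manifest = plant_linear_and_exonic_motifs(
        cfg, contigs, models, junctions, carrier_ids, rng
    )
    junctions = _enforce_ground_truth(cfg, contigs, models, junctions, manifest, rng)
    genome = Genome([GenomeSeq(c, "".join(s)) for c, s in contigs.items()])
    manifest.update(plant_manifest)
    manifest["seed"] = cfg.seed
    manifest["selection_thinning"] = dict(cfg.selection_thinning)
    manifest["focal_junction"] = junctions[0].junction_id

    ttn = models[cfg.ttn_transcript]
    methylation = generate_methylation(genome, ttn, rng)
    depths = generate_depths(cfg, ttn, rng)
    rates = default_rate_table()
    inclusion = generate_inclusion_matrix(cfg, junctions[0], rng)

    variants: list[VariantRecord] = []
    if include_variants:
        occurrences = collect_motif_occurrences(
            genome, ttn, junctions, cfg.motif, JunctionWindow(25)
        )
        motif_classes = build_motif_site_classes(genome, occurrences)
        by_label = {c.label: c for c in motif_classes}
        lj_all = by_label["motif_lj_all"]
        consequence = enumerate_coding_consequences(genome, ttn)
        gen_classes = [
            by_label["motif_bsj"],
            by_label["motif_within_exon"],
            SiteClass("motif_lj", lj_all.sites),
            consequence["truncating"],
            consequence["synonymous"],
            consequence["missense"],
        ]
        variants = generate_variants(
            cfg, genome, rates, gen_classes, depths, methylation, rng
        )

    return SyntheticDataset(
        cfg=cfg,
        genome=genome,
        models=models,
        junctions=junctions,
        rates=rates,
        motif_table=default_motif_table(cfg.motif),
        methylation=methylation,
        depths=depths,
        variants=variants,
        inclusion=inclusion,
        manifest=manifest,
    )
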