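"""File readers and writers for all pipeline inputs and outputs.

Standard formats go through standard libraries: FASTA via Biopython, GTF via
gffutils, VCF via pysam.  Everything tabular is plain TSV through pandas.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CircJunction,
    ExonModel,
    Genome,
    GenomeSeq,
    InclusionMatrix,
    ModelError,
    MotifRecord,
    MotifTable,
    MutationRateTable,
    VariantRecord,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genome FASTA

def read_genome_fasta(path: str | Path) -> Genome:
    contigs = [
        GenomeSeq(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not contigs:
        raise ModelError(f"no sequences in FASTA {path}")
    return Genome(contigs)


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=name, description="")
        for name, c in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# exon annotation

def read_exon_annotation(path: str | Path, dialect: str = "gtf") -> dict[str, ExonModel]:
    """Read exon structures (one transcript per gene) from GTF or BED12.

    Exon numbers are assigned in transcript 5'->3' order: ascending genomic
    coordinates on '+', descending on '-'.
    """
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ModelError(f"unknown annotation dialect {dialect!r}")


def _read_gtf(path: str | Path) -> dict[str, ExonModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ModelError(f"{path}: feature without transcript_id")
        if feat.strand not in ("+", "-"):
            raise ModelError(f"{path}: transcript {tid}: unknown strand {feat.strand!r}")
        prev = meta.setdefault(tid, (feat.seqid, feat.strand))
        if prev != (feat.seqid, feat.strand):
            raise ModelError(f"{path}: transcript {tid} spans contigs/strands")
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))
    models: dict[str, ExonModel] = {}
    for tid, ivals in exons.items():
        contig, strand = meta[tid]
        ordered = sorted(ivals)
        if strand == "-":
            ordered = ordered[::-1]
        model = ExonModel(tid, contig, strand, tuple(ordered))
        if tid in cds:
            tpos = []
            for s, e in cds[tid]:
                tpos.append(model.genomic_to_transcript(s))
                tpos.append(model.genomic_to_transcript(e))
            model = ExonModel(
                tid, contig, strand, tuple(ordered), cds=(min(tpos), max(tpos))
            )
        models[tid] = model
    if not models:
        raise ModelError(f"no exon features in {path}")
    return models


def _read_bed12(path: str | Path) -> dict[str, ExonModel]:
    cols = [
        "chrom", "chromStart", "chromEnd", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
        "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    models: dict[str, ExonModel] = {}
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ModelError(f"{path}: transcript {row.name}: unknown strand")
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(starts) != int(row.blockCount):
            raise ModelError(f"{path}: transcript {row.name}: malformed blocks")
        ivals = [
            (int(row.chromStart) + st + 1, int(row.chromStart) + st + sz)
            for st, sz in zip(starts, sizes)
        ]
        if row.strand == "-":
            ivals = ivals[::-1]
        models[str(row.name)] = ExonModel(
            str(row.name), str(row.chrom), row.strand, tuple(ivals)
        )
    if not models:
        raise ModelError(f"no records in {path}")
    return models


def write_gtf(models: Mapping[str, ExonModel], path: str | Path, source: str = "circmotif") -> None:
    lines = []
    for model in models.values():
        genomic = sorted(model.exons)
        numbers = (
            range(1, model.n_exons + 1)
            if model.strand == "+"
            else range(model.n_exons, 0, -1)
        )
        for (s, e), num in zip(genomic, numbers):
            attrs = (
                f'gene_id "{model.transcript_id}"; '
                f'transcript_id "{model.transcript_id}"; '
                f'exon_number "{num}";'
            )
            lines.append(
                f"{model.contig}\t{source}\texon\t{s}\t{e}\t.\t{model.strand}\t.\t{attrs}"
            )
        if model.cds is not None:
            for s, e in _cds_genomic_intervals(model):
                attrs = (
                    f'gene_id "{model.transcript_id}"; '
                    f'transcript_id "{model.transcript_id}";'
                )
                lines.append(
                    f"{model.contig}\t{source}\tCDS\t{s}\t{e}\t.\t{model.strand}\t0\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _cds_genomic_intervals(model: ExonModel) -> list[tuple[int, int]]:
    cs, ce = model.cds
    ivals = []
    acc = 0
    for s, e in model.exons:
        n = e - s + 1
        lo, hi = max(cs, acc + 1), min(ce, acc + n)
        if lo <= hi:
            if model.strand == "+":
                ivals.append((s + (lo - acc - 1), s + (hi - acc - 1)))
            else:
                ivals.append((e - (hi - acc - 1), e - (lo - acc - 1)))
        acc += n
    return sorted(ivals)


# native exon TSV (round-trippable, keeps CDS)

def write_exon_tsv(models: Mapping[str, ExonModel], path: str | Path) -> None:
    rows = []
    for model in models.values():
        for num, (s, e) in enumerate(model.exons, start=1):
            rows.append(
                {
                    "transcript_id": model.transcript_id,
                    "contig": model.contig,
                    "strand": model.strand,
                    "exon_number": num,
                    "start": s,
                    "end": e,
                    "cds_start": model.cds[0] if model.cds else -1,
                    "cds_end": model.cds[1] if model.cds else -1,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_exon_tsv(path: str | Path) -> dict[str, ExonModel]:
    df = pd.read_csv(path, sep="\t")
    models = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("exon_number")
        cds = None
        if int(grp.iloc[0]["cds_start"]) >= 0:
            cds = (int(grp.iloc[0]["cds_start"]), int(grp.iloc[0]["cds_end"]))
        models[str(tid)] = ExonModel(
            str(tid),
            str(grp.iloc[0]["contig"]),
            str(grp.iloc[0]["strand"]),
            tuple((int(r.start), int(r.end)) for r in grp.itertuples()),
            cds=cds,
        )
    return models


# ---------------------------------------------------------------------------
# variants

class VariantList(list):
    """List of :class:`VariantRecord` that remembers skipped non-SNV rows."""

    def __init__(self, records: Iterable[VariantRecord] = (), n_skipped: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped


def read_variants(path: str | Path, dialect: str = "vcf") -> VariantList:
    """Read SNVs with AC/AN/median-depth annotations; non-SNVs are skipped
    (count kept on the result), multi-allelic rows are rejected."""
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    raise ModelError(f"unknown variant dialect {dialect!r}")


def _read_vcf(path: str | Path) -> VariantList:
    out = VariantList()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ModelError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "split upstream"
                )
            alt = rec.alts[0]
            if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                out.n_skipped += 1
                continue
            info = rec.info
            for key in ("AC", "AN", "DPM"):
                if key not in info:
                    raise ModelError(
                        f"{path}: record {rec.chrom}:{rec.pos} missing INFO/{key}"
                    )
            ac = info["AC"]
            ac = ac[0] if isinstance(ac, tuple) else ac
            out.append(
                VariantRecord(
                    rec.chrom, rec.pos, rec.ref, alt,
                    int(ac), int(info["AN"]), float(info["DPM"]),
                )
            )
    if out.n_skipped:
        log.info("read_variants: skipped %d non-SNV records", out.n_skipped)
    return out


def _read_variant_tsv(path: str | Path) -> VariantList:
    df = pd.read_csv(path, sep="\t")
    needed = {"contig", "pos", "ref", "alt", "AC", "AN", "DP_median"}
    missing = needed - set(df.columns)
    if missing:
        raise ModelError(f"{path}: missing columns {sorted(missing)}")
    out = VariantList()
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            out.n_skipped += 1
            continue
        out.append(
            VariantRecord(
                str(row.contig), int(row.pos), ref, alt,
                int(row.AC), int(row.AN), float(row.DP_median),
            )
        )
    if out.n_skipped:
        log.info("read_variants: skipped %d non-SNV records", out.n_skipped)
    return out


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##INFO=<ID=DPM,Number=1,Type=Float,Description="Median site depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: Sequence[VariantRecord], genome: Genome, path: str | Path) -> None:
    contigs = "".join(
        f"##contig=<ID={name},length={len(seq)}>\n" for name, seq in genome.items()
    )
    lines = [VCF_HEADER.format(contigs=contigs)]
    for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.alt)):
        lines.append(
            f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            f"AC={v.allele_count};AN={v.allele_number};DPM={v.median_depth:g}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# small tables

def read_rate_table(path: str | Path) -> MutationRateTable:
    df = pd.read_csv(path, sep="\t")
    rates = {
        (str(r.left), str(r.ref), str(r.alt), str(r.right), int(r.methyl_bin)):
            float(r.rate)
        for r in df.itertuples(index=False)
    }
    return MutationRateTable(rates)


def write_rate_table(table: MutationRateTable, path: str | Path) -> None:
    rows = [
        {"left": k[0], "ref": k[1], "alt": k[2], "right": k[3],
         "methyl_bin": k[4], "rate": rate}
        for k, rate in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_motif_table(path: str | Path) -> MotifTable:
    df = pd.read_csv(path, sep="\t")
    return MotifTable(
        [
            MotifRecord(str(r.motif_id), str(r.rbp_name), str(r.pattern).upper())
            for r in df.itertuples(index=False)
        ]
    )


def write_motif_table(table: MotifTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"motif_id": r.motif_id, "rbp_name": r.rbp_name, "pattern": r.pattern}
            for r in table
        ]
    ).to_csv(path, sep="\t", index=False)


def read_junctions(path: str | Path) -> list[CircJunction]:
    df = pd.read_csv(path, sep="\t")
    return [
        CircJunction(
            str(r.transcript_id), int(r.acceptor_exon), int(r.donor_exon),
            str(r.dependency_class), str(r.host_class),
        )
        for r in df.itertuples(index=False)
    ]


def write_junctions(junctions: Sequence[CircJunction], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": cj.transcript_id,
                "acceptor_exon": cj.acceptor_exon,
                "donor_exon": cj.donor_exon,
                "dependency_class": cj.dependency_class,
                "host_class": cj.host_class,
            }
            for cj in junctions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_inclusion_matrix(path: str | Path) -> InclusionMatrix:
    df = pd.read_csv(path, sep="\t")
    if "exon_number" not in df.columns or df.shape[1] < 2:
        raise ModelError(f"{path}: need exon_number plus >=1 sample column")
    samples = tuple(c for c in df.columns if c != "exon_number")
    return InclusionMatrix(
        exon_numbers=tuple(int(x) for x in df["exon_number"]),
        samples=samples,
        detected=tuple(
            tuple(bool(row[s]) for s in samples)
            for row in df.to_dict("records")
        ),
    )


def write_inclusion_matrix(matrix: InclusionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        list(matrix.detected), columns=list(matrix.samples), dtype=int
    )
    df.insert(0, "exon_number", matrix.exon_numbers)
    df.to_csv(path, sep="\t", index=False)


def read_position_table(path: str | Path, value_col: str) -> dict[tuple[str, int], float]:
    """Read a (contig, pos, value) TSV into a lookup dict (methylation bins,
    per-site median depths)."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.contig), int(r.pos)): float(getattr(r, value_col))
        for r in df.itertuples(index=False)
    }


def write_position_table(
    values: Mapping[tuple[str, int], float], value_col: str, path: str | Path
) -> None:
    rows = [
        {"contig": c, "pos": p, value_col: v}
        for (c, p), v in sorted(values.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
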