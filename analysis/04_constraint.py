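#!/usr/bin/env python
"""Genetic constraint of motif-forming genomic sites.

Classifies every genomic occurrence of the junction-created motif on the
TTN-like gene by how it is formed (back-splicing, linear splicing in exons
included or excluded from circRNAs, or within an exon body), adds the
synonymous / missense / truncating validation classes, and computes each
class's observed/expected rare-variant ratio with a 90% exact Poisson
interval under the trinucleotide + methylation + depth-corrected neutral
model, calibrated so synonymous o/e = 1.  Writes results/constraint.tsv and
results/depth_model.json.
"""

import json
from pathlib import Path

from circmotif import io as cio
from circmotif.constraint import (
    build_motif_site_classes,
    constraint_report,
    enumerate_coding_consequences,
)
from circmotif.junctions import JunctionWindow, collect_motif_occurrences

DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    if not DATA.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    consensus_file = RESULTS / "consensus.json"
    if not consensus_file.exists():
        raise SystemExit("run analysis/02_discover_motif.py first")
    motif = json.loads(consensus_file.read_text())["consensus"]

    genome = cio.read_genome_fasta(DATA / "genome.fa")
    models = cio.read_exon_annotation(DATA / "annotation.gtf", "gtf")
    ttn = models["TTN_SYN"]
    junctions = cio.read_junctions(DATA / "junctions.tsv")
    variants = cio.read_variants(DATA / "variants.vcf", "vcf")
    rates = cio.read_rate_table(DATA / "rates.tsv")
    methyl = cio.read_position_table(DATA / "methylation.tsv", "methyl_bin")
    depths = cio.read_position_table(DATA / "depths.tsv", "median_depth")

    occurrences = collect_motif_occurrences(
        genome, ttn, junctions, motif, JunctionWindow(25)
    )
    classes = build_motif_site_classes(genome, occurrences)
    classes += list(enumerate_coding_consequences(genome, ttn).values())

    results, table, depth_model, lam = constraint_report(
        classes, variants, genome, rates, methyl, depths
    )
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "constraint.tsv", sep="\t", index=False)
    (RESULTS / "depth_model.json").write_text(json.dumps({
        "d0": depth_model.d0, "a": depth_model.a, "b": depth_model.b,
        "lambda_cal": lam,
    }, indent=2))
    print(f"calibration: lambda={lam:.3f}, depth model "
          f"a={depth_model.a:.3f} b={depth_model.b:.3f} (d0={depth_model.d0:g})")
    for r in results:
        flag = "  <- constrained" if r.constrained else ""
        print(f"  {r.label:18s} o/e = {r.observed:4d}/{r.expected:7.1f} "
              f"= {r.oe:5.2f}  [{r.ci90_low:.2f}, {r.ci90_high:.2f}]{flag}")


if __name__ == "__main__":
    main()
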