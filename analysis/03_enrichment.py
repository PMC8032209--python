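#!/usr/bin/env python
"""RBP motif enrichment across circRNA sequence classes.

Scans an ATtRACT-style motif table over five paired sequence sets (BSJ
windows by RBM20 dependency, BSJ windows and full circle sequences by host
gene, full TTN circles vs the linear mRNA in 500-nt tiles, and TTN exons
inside vs outside every circle span), testing per-motif presence with
two-sided Fisher exact tests and BH correction within each comparison.
Writes one results/enrichment_<comparison>.tsv per panel.
"""

from pathlib import Path

from circmotif import io as cio
from circmotif.motifs import enrichment_table, run_standard_comparisons

DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    if not DATA.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    genome = cio.read_genome_fasta(DATA / "genome.fa")
    models = cio.read_exon_annotation(DATA / "annotation.gtf", "gtf")
    junctions = cio.read_junctions(DATA / "junctions.tsv")
    motifs = cio.read_motif_table(DATA / "motifs.tsv")

    reports = run_standard_comparisons(
        genome, models, junctions, motifs, ttn_transcript="TTN_SYN"
    )
    RESULTS.mkdir(exist_ok=True)
    for name, rows in reports.items():
        table = enrichment_table(rows).sort_values("q_value")
        table.to_csv(RESULTS / f"enrichment_{name}.tsv", sep="\t", index=False)
        top = table.iloc[0]
        print(f"{name}: top motif {top.rbp_name} ({top.motif_id}) "
              f"OR={top.odds_ratio:.2f} q={top.q_value:.2e} "
              f"[{top.count_a}/{top.total_a} vs {top.count_b}/{top.total_b}]")


if __name__ == "__main__":
    main()
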