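# circmotif

Circular RNAs (circRNAs) arise by back-splicing: the donor (5' splice) site
of a downstream exon joins the acceptor (3' splice) site of an upstream
exon, closing the transcript into a covalent circle. The junction this
creates carries a sequence that exists in no linear transcript — the suffix
of the downstream exon runs directly into the prefix of the upstream one.
For the large circRNAs of the titin (*TTN*) transcript whose biogenesis
depends on the splice factor RBM20, that junction-created word is an
RNA-binding-protein motif (an SRSF10 site), and the genomic bases that form
it show depletion of rare human variation.

`circmotif` is an analysis pipeline (library + scripts + CLI) for that
class of question. It covers four computations:

1. **Junction sequence construction** — windows of `w` nt per side around
   every back-splice junction (BSJ) and every linear exon–exon junction
   (LJ), clamped to exon boundaries, in transcript orientation, with each
   base mapped back to its genomic position.
2. **Junction-spanning consensus discovery** — exhaustive exact k-mer
   voting over `k ∈ [k_min, k_max]`: the winner maximises *prevalence*, the
   fraction of class sequences with an exact occurrence straddling the
   junction (ties → longer k-mer → lexicographic).
3. **RBP motif enrichment** — IUPAC presence/absence of an ATtRACT-style
   motif table in paired sequence sets, per-motif two-sided Fisher exact
   tests with Haldane–Anscombe odds ratios and Benjamini–Hochberg
   correction; grossly length-mismatched sets (full circles vs the linear
   mRNA) are compared on non-overlapping 500-nt tiles.
4. **Regional genetic constraint** — observed rare variants (AF < 0.1%)
   versus the expectation of a neutral model,

   `expected = λ · Σ_sites Σ_alts rate(trinucleotide context, ref→alt,
   CpG-methylation bin) · depth_factor(median depth)`,

   with the o/e ratio reported with a 90% exact Poisson (chi-square form)
   interval, `λ` calibrated so synonymous o/e = 1, and the low-coverage
   factor `min(1, a + b·ln d)` below `d₀ = 30` refit from calibration data.

Because the original heart RNA-seq and gnomAD inputs are not desk-scale,
the package ships a first-class synthetic generator (`circmotif.simulate`)
that reproduces the study's structure: a 363-exon TTN-like gene whose
exon-79–145 region emits 63 RBM20-dependent circRNAs, 44 of which form the
8-nt motif `AAAGAACC` across their junction (69.8% ≈ 70%), 200 background
circRNAs with 3 carriers, Poisson-sampled rare variants under class-specific
selection, and a 3-sample exon-inclusion matrix for the focal
exon-145→79 circle.

## Worked example

```bash
python analysis/01_simulate.py        # writes scratch/data/
python analysis/02_discover_motif.py  # writes results/consensus.json
python analysis/05_isoform_bounds.py  # writes results/bounds.json
```

prints

```
consensus: AAAGAACC (k=8), prevalence 69.8% of 63 RBM20-dependent circRNAs
junction-formed motif: 44 TTN-derived vs 3 non-TTN circRNAs
...
focal junction TTN_SYN:79-145: spans 67 exons
  9 exons detected in no sample, 35 in all 3 samples
  composition bound: 35 to 58 exons (6905 to 10738 nt)
```

i.e. the discovery stage recovers the planted 8-mer from junction windows
alone, it marks 44 of 63 TTN circRNAs (70%) and only 3 of 200 background
circRNAs, and the focal 67-exon circle can contain between 35 exons (seen
in every sample) and 58 exons (67 minus the 9 never observed).
`analysis/03_enrichment.py` and `analysis/04_constraint.py` run the
enrichment panels and the constraint table (synonymous o/e pinned to 1 by
calibration; back-splice motif sites depleted). The same stages are
available as `circmotif simulate|build-junctions|discover|scan|enrich|
constraint|bounds|all` subcommands.

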