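# Methods

## Coordinate and sequence conventions

All coordinates are 1-based inclusive (GTF/VCF convention); the BED12
reader converts at the boundary. Exons are numbered 1..N in transcript
(5'→3') order, so exon 1 is the genomically last exon on the minus strand.
Every junction or motif sequence is an RNA-level object and is therefore
expressed in transcript orientation; each window carries the genomic
position of every base so occurrences can be mapped back to DNA sites.

A back-splice junction is written (acceptor exon, donor exon) with
acceptor ≤ donor: the donor end of the circle's 3'-most exon joins the
acceptor end of its 5'-most exon. The span of a circle is
`donor − acceptor + 1` exons.

## Junction windows

Windows take `w` bases from each side of the junction (default `w = 25`,
configurable). The default comfortably exceeds the 8-nt motif; any `w ≥
motif length − 1` captures every junction-spanning occurrence. Exons
shorter than `w` clamp the half-window to the exon — the window never
continues into the next exon, because which exons a circle retains
internally is exactly what is uncertain, and clamping keeps the junction
sequence independent of that.

## Consensus discovery

The discovered object is a single ungapped word, so discovery is exhaustive
and exact rather than an EM-style motif search: for every k in the searched
range, every exact k-mer whose occurrence straddles the junction of a class
member votes once per sequence; the consensus maximises prevalence over the
whole class, with ties resolved toward larger k and then lexicographically.
Default minimum prevalence is 0.5 — the biological signal sits at ~70%, so
0.5 recovers it with margin while rejecting sporadic words. The result is
order-invariant and testable against brute-force enumeration.

## Enrichment statistics

Presence (≥ 1 IUPAC occurrence) per sequence feeds a per-motif 2×2 table;
p-values are two-sided Fisher exact tests, odds ratios are sample ORs with
0.5 added to all cells when any cell is zero (Haldane–Anscombe), and BH
correction is applied across the motifs of one comparison only, mirroring
per-panel reporting. Full circle sequences are scanned with a wrap of
(motif length − 1) bases so occurrences crossing the circle origin count.
For the circle-vs-linear-mRNA comparison, presence per sequence would be
confounded by length (the mRNA is one ~64-kb sequence), so both sides are
cut into non-overlapping 500-nt tiles and the table counts tiles; the tile
size is configurable and declared in the output.

## Constraint model

Observed counts are distinct rare variants: SNVs with allele count ≥ 1 and
allele frequency strictly below 0.1%. Expected counts are

```
expected = λ · Σ_sites Σ_alts rate(left, ref→alt, right, methyl_bin) · f(d)
```

* **Rates** are per-site per-allele probabilities keyed by trinucleotide
  context and substitution, strand-collapsed (a context and its reverse
  complement share a rate; canonical keys have ref ∈ {A, C}). CpG contexts
  carry methylation bins 0/1/2 (none/partial/high) with their own rates;
  non-CpG sites always use bin 0. The shipped default table (transitions
  3× transversions; high-methylation CpG transitions 10× the transversion
  rate) is a desk-scale fixture — real analyses must supply their own.
* **Depth correction** `f(d) = min(1, a + b·ln d)` below `d₀ = 30`,
  identity above. `a` and `b` are refit on the calibration class by
  binning low-coverage sites by depth and regressing each bin's
  observed/expected (normalised by the full-coverage ratio) on ln d; with
  too few low-coverage observations the fit falls back to no correction,
  which is conservative.
* **Calibration** `λ = observed/expected` on a class assumed to be under
  minimal selection (synonymous sites), making that class's o/e exactly 1
  by construction; missense serves as a semi-independent sanity check and
  truncating variants as a positive control for depletion.
* **Interval**: the o/e ratio is reported with the exact Poisson
  (Garwood, chi-square form) interval on the observed count, expected
  treated as fixed: `lo = χ²(α/2, 2·obs)/(2·exp)` (0 when obs = 0),
  `hi = χ²(1−α/2, 2·obs+2)/(2·exp)`, default level 90%. This interval is
  conservative: its exact coverage, computable by enumeration, is ≥ the
  nominal level for every mean (e.g. 92.7% at mean 20), which is the
  standard price of exactness for discrete counts. Classes with
  `hi < 1` are flagged constrained.

Consequence labels come from standard-code codon translation of ref and
alt (same residue → synonymous; stop gained → truncating; everything else,
including stop-loss, → missense). The CDS is required to be a multiple of
3 and one transcript per gene is assumed — the TTN-like meta-transcript is
the union model, matching the single exon numbering the analysis uses.

Motif site classes overlap the consequence classes (motif bases are coding
bases). The report treats each class marginally, as the figure-style
presentation does; the calibration class therefore contains a small
fraction (<1%) of motif sites, a negligible bias documented here rather
than corrected.

## Composition bounds

For a focal circle the inclusion matrix (exon × sample booleans from
RNase-R-enriched, assembled circRNA sequencing) gives: exons detected in no
sample cannot be in the circle (upper bound = span − never_included), exons
detected in every sample are its robust core (lower bound =
always_detected); with exon lengths these become nt-size bounds.
"Included" deliberately does not distinguish variability caused by
back-splicing choice from internal linear splicing — the bounds are valid
under either. Adding a sample can only shrink the always-detected core and
can only rescue never-included exons, so the lower bound is non-increasing
and the upper bound non-decreasing in sample count.

## Synthetic data: what it emulates and what it does not

The generator is the package's study-condition definition, not a tuning
surface. Defaults: a 363-exon plus-strand TTN-like gene (exon lengths
50–300 nt, introns 100–300 nt), circRNA-producing region exons 79–145; 63
RBM20-dependent circRNAs sampled in that region (the focal 79–145 circle
first) with 44 carriers of the 8-nt motif `AAAGAACC` split 4 donor-side /
4 acceptor-side across their junction (44/63 = 69.8%, rounding to the
target 70%); 200 background circRNAs on 25 background genes with 3
carriers; allele number 251,496 (2 × 125,748 individuals, cosmetic
realism); depths log-normal(ln 40, 0.5) truncated at 1; 3 inclusion-matrix
samples with exactly 9 never-included and 35 always-detected exons in the
focal span. The class sizes 63 and 200 are the smallest round numbers that
realise the printed prevalence and both carrier counts simultaneously.
The motif's donor/acceptor split is a fixture choice (symmetric 4+4),
configurable because the real split is not machine-readable.

Carrier halves overwrite genome bases (no insertions), so the annotation
never moves. Ground truth is *enforced*: after planting, every non-carrier
junction window is checked for junction-spanning fragments (≥ 5 nt) of the
planted motif — arising by chance or because a non-carrier shares an
edited exon end with a carrier — and offending junctions are re-drawn.
Likewise, linear-junction plants avoid exon ends already edited by
carriers so the LJ and BSJ constraint classes stay disjoint and their
different selection signals remain recoverable. These checks make the
carrier counts and the discovered consensus exact under any seed; what
passing them demonstrates is that the pipeline recovers a planted signal
without false positives, not that real junction windows are this clean
(real data carries sequencing error, ambiguous junction calls and
paralogy, none of which are modelled).

Rare variants are drawn per site and alt allele as Poisson counts with
mean `rate · f_true(d) · s`, where `f_true(d) = min(1, ln d / ln 30)` is a
depth-ascertainment curve the analysis never sees (it refits its own), and
`s` is the class's selection-thinning factor (defaults: 1.0 for linear
motif sites and synonymous/missense, 0.5 for back-splice and within-exon
motif sites, 0.2 for truncating — encoding the qualitative finding that
only junction-formed and exonic motif copies are under selection).
Observed counts are distinct variants while the model's expectation sums
Poisson means, a mismatch of order rate/2 (< 2% at default rates) absorbed
by calibration. Methylation bins are assigned 50/20/30% to exonic CpGs.

## Problem sizes and numerical choices

The default dataset (one ~160-kb TTN-like contig plus ~25 background
genes, ~190k coding site-alleles, ~2.5k variants) generates in a few
seconds and the whole pipeline runs in well under a minute, which is the
scale the test suite and the acceptance script use. Simulation-backed
property tests use dedicated toy site sets sized so their tolerances are
several standard errors wide (e.g. expected ≈ 3000 per half for held-out
neutrality, 50 seeded runs for thinning recovery). Fisher p-values are
checked against exact rational enumeration to 1e-12; interval endpoints
against numeric tail inversion to 1e-9. Ties in consensus discovery are
broken deterministically (prevalence, then k, then lexicographic), and all
randomness flows from a single integer seed through one numpy Generator,
so fixed seeds give byte-identical outputs.

## Known limitations

One transcript per gene; SNVs only (no indels or structural variants);
no read-level simulation (junction calls are taken as given); no RNA
secondary-structure weighting of motif accessibility; the neutral rate
table is synthetic in scale; constraint classes are reported marginally
despite partial overlap; and the LJ included/excluded split assigns
boundary-straddling occurrences that touch any included exon to the
included class.
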