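"""Regional genetic constraint: observed vs expected rare variants under a
neutral trinucleotide mutation model with CpG-methylation strata and a
sequencing-depth correction.

The expected count for a site class is

    expected = lambda_cal * sum_sites sum_alts rate(context, ref>alt, bin)
                                      * depth_factor(median depth at site)

where ``rate`` comes from a strand-collapsed trinucleotide table, the
methylation bin applies at CpG sites, and the depth factor down-weights
low-coverage sites (min(1, a + b*ln d) below a full-coverage threshold d0,
identity above).  ``lambda_cal`` is fixed so that a calibration class assumed
to be under minimal selection (synonymous sites) has observed/expected = 1.

The summary statistic is the o/e ratio with an exact Poisson 90% interval in
its chi-square form, treating the expected count as fixed:

    lo = chi2.ppf(0.05, 2*obs) / (2*expected)          (0 when obs = 0)
    hi = chi2.ppf(0.95, 2*(obs + 1)) / (2*expected)

o/e < 1 with hi < 1 marks a constrained class (depleted of rare variation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .junctions import ClassifiedOccurrence
from .model import (
    ExonModel,
    Genome,
    ModelError,
    MutationRateTable,
    VariantRecord,
    translate_codon,
    transcript_sequence,
)

ALL_BASES = ("A", "C", "G", "T")

MOTIF_CLASS_LABELS = (
    "motif_lj_all",
    "motif_lj_included",
    "motif_lj_excluded",
    "motif_bsj",
    "motif_within_exon",
)
CONSEQUENCE_LABELS = ("synonymous", "missense", "truncating")


@dataclass(frozen=True)
class SiteClass:
    """A named set of genomic sites with the alt alleles counted there."""

    label: str
    sites: Mapping[tuple[str, int], frozenset[str]]

    @property
    def n_site_alleles(self) -> int:
        return sum(len(alts) for alts in self.sites.values())

    def contains(self, variant: VariantRecord) -> bool:
        alts = self.sites.get((variant.contig, variant.pos))
        return alts is not None and variant.alt in alts


@dataclass(frozen=True)
class ConstraintResult:
    label: str
    observed: int
    expected: float
    oe: float
    ci90_low: float
    ci90_high: float

    @property
    def constrained(self) -> bool:
        return self.ci90_high < 1.0


@dataclass(frozen=True)
class DepthModel:
    """Ascertainment factor min(1, a + b*ln d) below ``d0``, 1 at d >= d0."""

    d0: float = 30.0
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ModelError("depth model must be monotone non-decreasing (b >= 0)")

    def factor(self, depth: float) -> float:
        if depth >= self.d0:
            return 1.0
        return min(1.0, max(0.0, self.a + self.b * math.log(max(depth, 1.0))))


# ---------------------------------------------------------------------------
# observed side

def filter_rare(
    variants: Sequence[VariantRecord], threshold: float = 1e-3
) -> list[VariantRecord]:
    """Keep observed rare variants: AC >= 1 and AF strictly below threshold."""
    return [
        v
        for v in variants
        if v.allele_count >= 1 and v.allele_frequency < threshold
    ]


def count_observed(site_class: SiteClass, rare_variants: Sequence[VariantRecord]) -> int:
    return sum(1 for v in rare_variants if site_class.contains(v))


# ---------------------------------------------------------------------------
# expected side

def _context(genome: Genome, contig: str, pos: int) -> tuple[str, str, str]:
    contig_seq = genome[contig]
    if pos < 2 or pos > len(contig_seq) - 1:
        raise ModelError(
            f"{contig}:{pos}: no trinucleotide context at contig edge"
        )
    left, ref, right = (
        contig_seq.base(pos - 1),
        contig_seq.base(pos),
        contig_seq.base(pos + 1),
    )
    if "N" in (left, ref, right):
        raise ModelError(f"{contig}:{pos}: ambiguous (N) trinucleotide context")
    return left, ref, right


def _methyl_bin(
    methyl: Optional[Mapping[tuple[str, int], float]],
    contig: str,
    pos: int,
    left: str,
    ref: str,
    right: str,
) -> int:
    """Methylation bin for a site; CpG status is strand-collapsed, so the G
    of a CpG reads the bin recorded at its paired C."""
    if methyl is None:
        return 0
    if ref == "C" and right == "G":
        return int(methyl.get((contig, pos), 0))
    if ref == "G" and left == "C":
        return int(methyl.get((contig, pos - 1), 0))
    return 0


def expected_variants(
    site_class: SiteClass,
    genome: Genome,
    rates: MutationRateTable,
    methyl: Optional[Mapping[tuple[str, int], float]] = None,
    depth_model: Optional[DepthModel] = None,
    depths: Optional[Mapping[tuple[str, int], float]] = None,
    lambda_cal: float = 1.0,
) -> float:
    """Expected rare-variant count for a site class under the neutral model."""
    if lambda_cal <= 0:
        raise ModelError("lambda_cal must be > 0")
    dm = depth_model or DepthModel()
    total = 0.0
    for (contig, pos), alts in site_class.sites.items():
        left, ref, right = _context(genome, contig, pos)
        mbin = _methyl_bin(methyl, contig, pos, left, ref, right)
        depth = depths.get((contig, pos), dm.d0) if depths else dm.d0
        f = dm.factor(depth)
        for alt in alts:
            total += rates.rate(left, ref, alt, right, mbin) * f
    return lambda_cal * total


def calibrate_lambda(
    calibration_class: SiteClass,
    observed_count: int,
    genome: Genome,
    rates: MutationRateTable,
    methyl: Optional[Mapping[tuple[str, int], float]] = None,
    depth_model: Optional[DepthModel] = None,
    depths: Optional[Mapping[tuple[str, int], float]] = None,
) -> float:
    """Scale factor making the calibration class's o/e exactly 1."""
    if observed_count <= 0:
        raise ModelError(
            "cannot calibrate: zero observed variants on calibration class"
        )
    uncal = expected_variants(
        calibration_class, genome, rates, methyl, depth_model, depths, 1.0
    )
    if uncal <= 0:
        raise ModelError("cannot calibrate: uncalibrated expected is zero")
    return observed_count / uncal


def fit_depth_model(
    calibration_class: SiteClass,
    rare_variants: Sequence[VariantRecord],
    genome: Genome,
    rates: MutationRateTable,
    methyl: Optional[Mapping[tuple[str, int], float]],
    depths: Mapping[tuple[str, int], float],
    d0: float = 30.0,
    n_bins: int = 8,
) -> DepthModel:
    """Fit the low-coverage correction on a calibration class.

    Sites below ``d0`` are binned by depth; each bin's observed/expected
    ratio (normalised by the full-coverage ratio, so the fit is independent
    of the overall calibration scale) is regressed on ln d by least squares.
    Falls back to no correction when there are too few low-coverage data.
    """
    per_site_mu: dict[tuple[str, int], float] = {}
    for (contig, pos), alts in calibration_class.sites.items():
        left, ref, right = _context(genome, contig, pos)
        mbin = _methyl_bin(methyl, contig, pos, left, ref, right)
        per_site_mu[(contig, pos)] = sum(
            rates.rate(left, ref, alt, right, mbin) for alt in alts
        )
    obs_per_site: dict[tuple[str, int], int] = {}
    for v in rare_variants:
        if calibration_class.contains(v):
            obs_per_site[(v.contig, v.pos)] = obs_per_site.get((v.contig, v.pos), 0) + 1

    full_mu = full_obs = 0.0
    low = []  # (ln d, mu, obs)
    for key, mu in per_site_mu.items():
        d = depths.get(key, d0)
        o = obs_per_site.get(key, 0)
        if d >= d0:
            full_mu += mu
            full_obs += o
        else:
            low.append((math.log(max(d, 1.0)), mu, o))
    if full_mu <= 0 or full_obs <= 0 or len(low) < 20:
        return DepthModel(d0=d0)
    base_ratio = full_obs / full_mu
    low_arr = np.array(low)
    edges = np.quantile(low_arr[:, 0], np.linspace(0, 1, n_bins + 1))
    xs, ys = [], []
    for i in range(n_bins):
        mask = (low_arr[:, 0] >= edges[i]) & (
            low_arr[:, 0] <= edges[i + 1] if i == n_bins - 1 else low_arr[:, 0] < edges[i + 1]
        )
        mu_bin = low_arr[mask, 1].sum()
        obs_bin = low_arr[mask, 2].sum()
        if mu_bin > 0:
            xs.append(low_arr[mask, 0].mean())
            ys.append((obs_bin / mu_bin) / base_ratio)
    if len(xs) < 2:
        return DepthModel(d0=d0)
    b, a = np.polyfit(xs, ys, 1)
    if b < 0:  # noise produced a non-monotone fit; no correction is safer
        return DepthModel(d0=d0)
    return DepthModel(d0=d0, a=float(a), b=float(b))


# ---------------------------------------------------------------------------
# o/e ratio with exact Poisson interval

def oe_with_ci(observed: int, expected: float, level: float = 0.90) -> ConstraintResult:
    """Observed/expected ratio with an exact Poisson (chi-square form)
    confidence interval, expected treated as fixed."""
    if expected <= 0:
        raise ModelError("expected must be > 0")
    if observed < 0:
        raise ModelError("observed must be >= 0")
    alpha = (1.0 - level) / 2.0
    lo = 0.0 if observed == 0 else chi2.ppf(alpha, 2 * observed) / (2 * expected)
    hi = chi2.ppf(1.0 - alpha, 2 * (observed + 1)) / (2 * expected)
    return ConstraintResult(
        label="", observed=observed, expected=expected,
        oe=observed / expected, ci90_low=float(lo), ci90_high=float(hi),
    )


# ---------------------------------------------------------------------------
# coding consequences

def classify_consequence(model: ExonModel, genome: Genome, variant: VariantRecord) -> str:
    """synonymous / missense / truncating by standard-code codon translation
    (stop-loss folded into missense)."""
    if model.cds is None:
        raise ModelError(f"{model.transcript_id}: no CDS on model")
    tpos = model.genomic_to_transcript(variant.pos)
    cs, ce = model.cds
    if not cs <= tpos <= ce:
        raise ModelError(
            f"{variant.contig}:{variant.pos}: outside CDS of {model.transcript_id}"
        )
    tx = transcript_sequence(genome, model)
    ref_base = tx[tpos - 1]
    # variant ref/alt are genomic-strand; flip onto the transcript strand
    if model.strand == "-":
        comp = dict(zip("ACGT", "TGCA"))
        var_ref, var_alt = comp[variant.ref], comp[variant.alt]
    else:
        var_ref, var_alt = variant.ref, variant.alt
    if ref_base != var_ref:
        raise ModelError(
            f"{variant.contig}:{variant.pos}: ref {variant.ref} does not match "
            f"transcript base {ref_base}"
        )
    cds_off = tpos - cs  # 0-based within CDS
    codon_start = cs - 1 + 3 * (cds_off // 3)
    codon = tx[codon_start : codon_start + 3]
    within = cds_off % 3
    alt_codon = codon[:within] + var_alt + codon[within + 1 :]
    ref_aa, alt_aa = translate_codon(codon), translate_codon(alt_codon)
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "truncating"
    return "missense"


def enumerate_coding_consequences(
    genome: Genome, model: ExonModel
) -> dict[str, SiteClass]:
    """Site classes of every possible coding SNV of one transcript, keyed by
    consequence label."""
    if model.cds is None:
        raise ModelError(f"{model.transcript_id}: no CDS on model")
    tx = transcript_sequence(genome, model)
    cs, ce = model.cds
    comp = dict(zip("ACGT", "TGCA"))
    # genomic position of every transcript base, precomputed once
    gpos_of = [
        g
        for i in range(1, model.n_exons + 1)
        for g in model.exon_genomic_positions(i)
    ]
    sites: dict[str, dict[tuple[str, int], set[str]]] = {
        lab: {} for lab in CONSEQUENCE_LABELS
    }
    for tpos in range(cs, ce + 1):
        gpos = gpos_of[tpos - 1]
        t_ref = tx[tpos - 1]
        cds_off = tpos - cs
        codon_start = cs - 1 + 3 * (cds_off // 3)
        codon = tx[codon_start : codon_start + 3]
        within = cds_off % 3
        ref_aa = translate_codon(codon)
        for t_alt in ALL_BASES:
            if t_alt == t_ref:
                continue
            alt_codon = codon[:within] + t_alt + codon[within + 1 :]
            alt_aa = translate_codon(alt_codon)
            if alt_aa == ref_aa:
                lab = "synonymous"
            elif alt_aa == "*":
                lab = "truncating"
            else:
                lab = "missense"
            g_alt = t_alt if model.strand == "+" else comp[t_alt]
            sites[lab].setdefault((model.contig, gpos), set()).add(g_alt)
    return {
        lab: SiteClass(lab, {k: frozenset(v) for k, v in site_map.items()})
        for lab, site_map in sites.items()
    }


# ---------------------------------------------------------------------------
# motif site classes and the full report

def build_motif_site_classes(
    genome: Genome,
    occurrences: Sequence[ClassifiedOccurrence],
) -> list[SiteClass]:
    """Group the genomic sites of classified motif occurrences into the five
    motif constraint classes.  A BSJ-created occurrence contributes only the
    exon-resident sites of its two halves (which is the whole footprint: the
    windows never leave their exons).  All non-ref alts are counted."""
    buckets: dict[str, dict[tuple[str, int], set[str]]] = {
        lab: {} for lab in MOTIF_CLASS_LABELS
    }

    def add(label: str, occ: ClassifiedOccurrence) -> None:
        for pos in occ.genomic_sites:
            ref = genome.base(occ.contig, pos)
            alts = {b for b in ALL_BASES if b != ref}
            buckets[label].setdefault((occ.contig, pos), set()).update(alts)

    for occ in occurrences:
        if occ.occurrence_class == "bsj_created":
            add("motif_bsj", occ)
        elif occ.occurrence_class == "lj_created":
            add("motif_lj_all", occ)
            if occ.inclusion == "included_in_circRNA":
                add("motif_lj_included", occ)
            else:
                add("motif_lj_excluded", occ)
        elif occ.occurrence_class == "within_exon":
            add("motif_within_exon", occ)
        else:
            raise ModelError(f"unknown occurrence class {occ.occurrence_class!r}")
    return [
        SiteClass(lab, {k: frozenset(v) for k, v in buckets[lab].items()})
        for lab in MOTIF_CLASS_LABELS
    ]


def constraint_report(
    classes: Sequence[SiteClass],
    variants: Sequence[VariantRecord],
    genome: Genome,
    rates: MutationRateTable,
    methyl: Optional[Mapping[tuple[str, int], float]] = None,
    depths: Optional[Mapping[tuple[str, int], float]] = None,
    calibration_label: str = "synonymous",
    rare_threshold: float = 1e-3,
    level: float = 0.90,
    d0: float = 30.0,
) -> tuple[list[ConstraintResult], pd.DataFrame, DepthModel, float]:
    """End-to-end constraint pipeline over a list of site classes.

    Filters rare variants, fits the depth correction and the calibration
    scale on ``calibration_label``, then reports one o/e row (with the exact
    Poisson interval) per class.
    """
    by_label = {c.label: c for c in classes}
    if calibration_label not in by_label:
        raise ModelError(f"calibration class {calibration_label!r} missing")
    rare = filter_rare(variants, rare_threshold)
    calib = by_label[calibration_label]
    if depths is not None:
        depth_model = fit_depth_model(
            calib, rare, genome, rates, methyl, depths, d0=d0
        )
    else:
        depth_model = DepthModel(d0=d0)
    lam = calibrate_lambda(
        calib, count_observed(calib, rare), genome, rates, methyl,
        depth_model, depths,
    )
    results = []
    for cls in classes:
        obs = count_observed(cls, rare)
        exp = expected_variants(
            cls, genome, rates, methyl, depth_model, depths, lam
        )
        r = oe_with_ci(obs, exp, level)
        results.append(
            ConstraintResult(cls.label, r.observed, r.expected, r.oe,
                             r.ci90_low, r.ci90_high)
        )
    table = pd.DataFrame(
        [
            {
                "label": r.label,
                "observed": r.observed,
                "expected": r.expected,
                "oe": r.oe,
                "ci90_low": r.ci90_low,
                "ci90_high": r.ci90_high,
                "constrained_flag": r.constrained,
            }
            for r in results
        ]
    )
    return results, table, depth_model, lam
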