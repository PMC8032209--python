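"""Observed/expected constraint model: rates, depth, calibration, intervals,
consequences."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import chi2, poisson

from oracles import CODON_TABLE, consequence_oracle

from circmotif.constraint import (
    DepthModel,
    SiteClass,
    build_motif_site_classes,
    calibrate_lambda,
    classify_consequence,
    constraint_report,
    enumerate_coding_consequences,
    expected_variants,
    filter_rare,
    oe_with_ci,
)
from circmotif.model import (
    ExonModel,
    Genome,
    GenomeSeq,
    ModelError,
    MutationRateTable,
    VariantRecord,
)


def _flat_rates(rate=0.01):
    return MutationRateTable(
        {
            (l, ref, alt, r, 0): rate
            for l in "ACGT"
            for ref in "AC"
            for alt in "ACGT"
            if alt != ref
            for r in "ACGT"
        }
    )


def _toy_site_class(label, contig, start, n, genome):
    sites = {}
    for pos in range(start, start + n):
        ref = genome.base(contig, pos)
        sites[(contig, pos)] = frozenset(b for b in "ACGT" if b != ref)
    return SiteClass(label, sites)


class TestRareFilter:
    def test_singleton_in_gnomad_sized_cohort_is_kept(self):
        v = VariantRecord("c", 5, "A", "G", 1, 251496, 30)
        assert filter_rare([v]) == [v]

    def test_af_above_threshold_removed(self):
        v = VariantRecord("c", 5, "A", "G", 300, 251496, 30)  # AF ~1.19e-3
        assert filter_rare([v]) == []

    def test_unobserved_allele_removed(self):
        v = VariantRecord("c", 5, "A", "G", 0, 251496, 30)
        assert filter_rare([v]) == []

    def test_threshold_is_strict(self):
        v = VariantRecord("c", 5, "A", "G", 1, 1000, 30)  # AF exactly 1e-3
        assert filter_rare([v]) == []


class TestExpectedVariants:
    def test_single_site_single_alt_equals_rate(self):
        g = Genome([GenomeSeq("c", "TACT")])
        cls = SiteClass("x", {("c", 2): frozenset("G")})
        got = expected_variants(cls, g, _flat_rates(0.013))
        assert got == pytest.approx(0.013, abs=1e-15)

    def test_matches_per_site_summation_oracle(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 120)])
        g = Genome([GenomeSeq("c", seq)])
        rates = _flat_rates(0.01)
        cls = _toy_site_class("x", "c", 10, 100, g)
        depths = {("c", p): float(d) for p, d in
                  zip(range(10, 110), rng.uniform(5, 60, 100))}
        dm = DepthModel(d0=30, a=0.1, b=0.25)
        got = expected_variants(cls, g, rates, None, dm, depths, lambda_cal=1.7)
        # spreadsheet-style oracle: explicit row-by-row accumulation
        oracle = 0.0
        for pos in range(10, 110):
            d = depths[("c", pos)]
            f = 1.0 if d >= 30 else min(1.0, max(0.0, 0.1 + 0.25 * math.log(d)))
            oracle += 3 * 0.01 * f * 1.7
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_halving_depth_factor_halves_expected(self):
        g = Genome([GenomeSeq("c", "TACTACTACT")])
        cls = _toy_site_class("x", "c", 2, 6, g)
        full = expected_variants(cls, g, _flat_rates())
        # a depth model whose factor is exactly 0.5 everywhere below d0
        dm = DepthModel(d0=1e9, a=0.5, b=0.0)
        depths = {k: 10.0 for k in cls.sites}
        half = expected_variants(cls, g, _flat_rates(), None, dm, depths)
        assert half == pytest.approx(full / 2)

    def test_linearity_over_disjoint_classes(self):
        g = Genome([GenomeSeq("c", "TACTACTACTACTACT")])
        a = _toy_site_class("a", "c", 2, 5, g)
        b = _toy_site_class("b", "c", 9, 5, g)
        union = SiteClass("u", {**a.sites, **b.sites})
        r = _flat_rates()
        assert expected_variants(union, g, r) == pytest.approx(
            expected_variants(a, g, r) + expected_variants(b, g, r)
        )

    def test_depth_monotonicity(self):
        dm = DepthModel(d0=30, a=0.0, b=1 / math.log(30))
        factors = [dm.factor(d) for d in (1, 2, 5, 10, 20, 29, 30, 50)]
        assert factors == sorted(factors)
        assert factors[-2] == factors[-1] == 1.0

    def test_n_context_is_an_error(self):
        g = Genome([GenomeSeq("c", "TANT")])
        cls = SiteClass("x", {("c", 3): frozenset("G")})
        with pytest.raises(ModelError, match="c:3"):
            expected_variants(cls, g, _flat_rates())


class TestCalibration:
    def test_observed_equals_expected_gives_lambda_one(self):
        g = Genome([GenomeSeq("c", "TACT")])
        cls = SiteClass("x", {("c", 2): frozenset("G")})
        lam = calibrate_lambda(cls, 1, g, _flat_rates(1.0))
        assert lam == pytest.approx(1.0)

    def test_observed_twice_expected_gives_lambda_two(self):
        g = Genome([GenomeSeq("c", "TACT")])
        cls = SiteClass("x", {("c", 2): frozenset("G")})
        lam = calibrate_lambda(cls, 2, g, _flat_rates(1.0))
        assert lam == pytest.approx(2.0)

    def test_zero_observed_cannot_calibrate(self):
        g = Genome([GenomeSeq("c", "TACT")])
        cls = SiteClass("x", {("c", 2): frozenset("G")})
        with pytest.raises(ModelError):
            calibrate_lambda(cls, 0, g, _flat_rates())

    def test_calibration_class_oe_is_exactly_one(self):
        # when calibration and validation coincide, o/e is 1 by construction
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 220)])
        g = Genome([GenomeSeq("c", seq)])
        cls = _toy_site_class("synonymous", "c", 10, 200, g)
        variants = [
            VariantRecord("c", p, g.base("c", p),
                          next(b for b in "ACGT" if b != g.base("c", p)),
                          1, 251496, 40.0)
            for p in range(10, 10 + 37)
        ]
        results, table, _, _ = constraint_report(
            [cls], variants, g, _flat_rates()
        )
        assert results[0].oe == pytest.approx(1.0, abs=1e-12)

    def test_neutral_heldout_recovery_across_seeds(self):
        # calibrate on one half of a neutral site set, validate on the other:
        # the held-out o/e stays within 10% for 20 consecutive seeds (site
        # set sized so expected ~3000 per half)
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 200_004)])
        g = Genome([GenomeSeq("c", seq)])
        calib = _toy_site_class("calib", "c", 2, 100_000, g)
        holdout = _toy_site_class("holdout", "c", 100_002, 100_000, g)
        rates = _flat_rates(0.01)
        exp_c = expected_variants(calib, g, rates)
        exp_h = expected_variants(holdout, g, rates)
        for seed in range(20):
            r = np.random.default_rng(seed)
            obs_c = r.poisson(exp_c)
            obs_h = r.poisson(exp_h)
            lam = obs_c / exp_c
            oe = obs_h / (lam * exp_h)
            assert 0.9 <= oe <= 1.1, (seed, oe)


class TestOeWithCi:
    def test_zero_observed_closed_form(self):
        r = oe_with_ci(0, 3.0)
        assert r.oe == 0.0 and r.ci90_low == 0.0
        assert r.ci90_high == pytest.approx(chi2.ppf(0.95, 2) / 6.0)

    def test_interval_brackets_ratio_one_when_obs_equals_exp(self):
        r = oe_with_ci(10, 10.0)
        assert r.ci90_low < 1.0 < r.ci90_high

    def test_exact_coverage_matches_enumeration(self):
        # the Garwood interval is conservative: its exact coverage at a
        # given mean, computed by enumeration, is >= the nominal level, and
        # a seeded Monte-Carlo run agrees with the enumeration
        mu = 20.0
        xs = np.arange(0, 200)
        lo = np.where(xs > 0, chi2.ppf(0.05, 2 * xs) / (2 * mu), 0.0)
        hi = chi2.ppf(0.95, 2 * (xs + 1)) / (2 * mu)
        contains = (lo <= 1.0) & (1.0 <= hi)
        exact = float((poisson.pmf(xs, mu) * contains).sum())
        assert exact >= 0.90
        rng = np.random.default_rng(0)
        draws = rng.poisson(mu, size=2000)
        mc = np.mean([bool(contains[x]) for x in draws])
        assert mc == pytest.approx(exact, abs=3 * math.sqrt(exact * (1 - exact) / 2000))

    def test_expected_nonpositive_rejected(self):
        with pytest.raises(ModelError):
            oe_with_ci(3, 0.0)


class TestConsequences:
    def _model_for(self, codon):
        seq = "AC" + codon + "GT"
        return Genome([GenomeSeq("c", seq)]), ExonModel(
            "t", "c", "+", ((3, 5),), cds=(1, 3)
        )

    def test_leucine_synonymous(self):
        g, m = self._model_for("CTT")
        v = VariantRecord("c", 5, "T", "C", 1, 100, 30)  # CTT -> CTC
        assert classify_consequence(m, g, v) == "synonymous"

    def test_stop_gain_is_truncating(self):
        g, m = self._model_for("TGG")
        v = VariantRecord("c", 5, "G", "A", 1, 100, 30)  # TGG -> TGA
        assert classify_consequence(m, g, v) == "truncating"

    def test_all_576_codon_snv_cases_match_oracle(self):
        for codon in CODON_TABLE:
            g, m = self._model_for(codon)
            for pos_in_codon, alt in product(range(3), "ACGT"):
                if codon[pos_in_codon] == alt:
                    continue
                v = VariantRecord(
                    "c", 3 + pos_in_codon, codon[pos_in_codon], alt, 1, 100, 30
                )
                assert classify_consequence(m, g, v) == consequence_oracle(
                    codon, pos_in_codon, alt
                )

    def test_variant_outside_cds_rejected(self):
        g, m = self._model_for("CTT")
        v = VariantRecord("c", 1, "A", "G", 1, 100, 30)
        with pytest.raises(ModelError):
            classify_consequence(m, g, v)

    def test_minus_strand_consequences(self):
        # transcript CTT (Leu) encoded on the minus strand: genomic AAG
        g = Genome([GenomeSeq("c", "ACAAGGT")])
        m = ExonModel("t", "c", "-", ((3, 5),), cds=(1, 3))
        # genomic A>G at pos 5 is transcript T>C at codon position 1 -> CTC
        v = VariantRecord("c", 3, "A", "G", 1, 100, 30)
        assert classify_consequence(m, g, v) == "synonymous"

    def test_enumeration_agrees_with_classifier(self):
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        seq = "AC" + "".join(bases[rng.integers(0, 4, 30)]) + "GT"
        g = Genome([GenomeSeq("c", seq)])
        m = ExonModel("t", "c", "+", ((3, 32),), cds=(1, 30))
        classes = enumerate_coding_consequences(g, m)
        for lab, cls in classes.items():
            for (contig, pos), alts in cls.sites.items():
                for alt in alts:
                    v = VariantRecord(contig, pos, g.base(contig, pos), alt, 1, 100, 30)
                    assert classify_consequence(m, g, v) == lab


class TestMotifSiteClasses:
    def test_bsj_occurrence_contributes_both_exon_halves(self, toy_genome, toy_model_plus):
        from circmotif.junctions import JunctionWindow, collect_motif_occurrences
        from circmotif.model import CircJunction

        cj = CircJunction("toyP", 1, 3, "rbm20_dependent", "TTN")
        occs = collect_motif_occurrences(
            toy_genome, toy_model_plus, [cj], "AGATGGGG", JunctionWindow(4)
        )
        classes = {c.label: c for c in build_motif_site_classes(toy_genome, occs)}
        bsj_sites = set(classes["motif_bsj"].sites)
        assert bsj_sites == {("chr1", p) for p in (57, 58, 59, 60, 11, 12, 13, 14)}
        # every non-ref alt is allowed at each site
        assert all(len(a) == 3 for a in classes["motif_bsj"].sites.values())

    def test_lj_subclasses_partition_lj_all(self, default_dataset):
        from circmotif.junctions import JunctionWindow, collect_motif_occurrences

        ds = default_dataset
        occs = collect_motif_occurrences(
            ds.genome, ds.models["TTN_SYN"], ds.junctions, ds.manifest["motif"],
            JunctionWindow(25),
        )
        classes = {c.label: c for c in build_motif_site_classes(ds.genome, occs)}
        all_sites = set(classes["motif_lj_all"].sites)
        inc = set(classes["motif_lj_included"].sites)
        exc = set(classes["motif_lj_excluded"].sites)
        assert inc | exc == all_sites
        assert not inc & exc
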