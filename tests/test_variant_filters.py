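"""Filter-cascade unit and property tests.

The inheritance-mode filter is checked against an exhaustively enumerated
truth table coded independently of the implementation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelyield import variant_filters as vf
from panelyield.cohort_io import load_lcr


def call(zyg="het", dp=40, gq=90, ad_ref=20, ad_alt=20, sample="s"):
    return vf.GenotypeCall(sample, zyg, dp, gq, ad_ref, ad_alt)


class TestSitePrefilter:
    def test_pass_no_lcr(self):
        assert vf.site_prefilter("PASS", "chr1", 100, None)

    def test_vqsr_tranche_fails(self):
        assert not vf.site_prefilter("VQSRTrancheSNP99.90to100.00", "chr1",
                                     100, None)

    def test_position_inside_lcr_fails(self, tmp_path):
        bed = tmp_path / "l.bed"
        bed.write_text("chr1\t99\t200\n")
        lcr = load_lcr(bed)
        assert not vf.site_prefilter("PASS", "chr1", 100, lcr)  # 0-based 99
        assert vf.site_prefilter("PASS", "chr1", 99, lcr)       # 0-based 98
        assert vf.site_prefilter("PASS", "chr2", 100, lcr)


class TestGenotypeQc:
    @pytest.mark.parametrize("c,masked", [
        (call(dp=9, gq=50), True),                   # low depth
        (call(dp=30, gq=60, ad_ref=4, ad_alt=26), True),   # AB ~0.87
        (call(dp=10, gq=20), False),                 # boundary kept (strict <)
        (call(dp=40, gq=19), True),                  # low GQ
        (call(zyg="hom_alt", dp=40, gq=90, ad_ref=0, ad_alt=40), False),
        (call(ad_ref=32, ad_alt=8), False),          # AB exactly 0.2 kept
        (call(ad_ref=8, ad_alt=32), False),          # AB exactly 0.8 kept
        (call(ad_ref=33, ad_alt=7), True),           # AB 0.175 < 0.2
        (call(ad_ref=0, ad_alt=0), True),            # het with no depth support
    ])
    def test_masking_rules(self, c, masked):
        out = vf.genotype_qc(c)
        assert (out.zygosity == "missing") == masked

    zyg_st = st.sampled_from(["hom_ref", "het", "hom_alt", "hemi", "missing"])

    @given(zyg_st, st.integers(0, 120), st.integers(0, 99),
           st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, zyg, dp, gq, ar, aa):
        c = vf.GenotypeCall("s", zyg, dp, gq, ar, aa)
        once = vf.genotype_qc(c)
        assert vf.genotype_qc(once) == once

    @given(zyg_st, st.integers(0, 120), st.integers(0, 99),
           st.integers(0, 80), st.integers(0, 80), st.integers(0, 30))
    @settings(max_examples=200, deadline=None)
    def test_raising_dp_min_never_unmasks(self, zyg, dp, gq, ar, aa, extra):
        c = vf.GenotypeCall("s", zyg, dp, gq, ar, aa)
        lo = vf.genotype_qc(c, vf.QcThresholds(dp_min=10))
        hi = vf.genotype_qc(c, vf.QcThresholds(dp_min=10 + extra))
        if lo.zygosity == "missing":
            assert hi.zygosity == "missing"


class TestCohortAf:
    def test_singleton_het_prints_like_reference_table(self):
        calls = [call(zyg="hom_ref", sample=f"s{i}") for i in range(6214)]
        calls.append(call(zyg="het", sample="carrier"))
        af = vf.cohort_af(calls)
        assert af == pytest.approx(1 / (2 * 6215))
        assert vf.format_maf(af) == "8.05e-05"

    def test_singleton_hom_prints_like_reference_table(self):
        calls = [call(zyg="hom_ref", sample=f"s{i}") for i in range(6214)]
        calls.append(call(zyg="hom_alt", sample="carrier"))
        assert vf.format_maf(vf.cohort_af(calls)) == "1.61e-04"

    def test_all_hom_ref_zero(self):
        assert vf.cohort_af([call(zyg="hom_ref")] * 5) == 0.0

    def test_all_missing_undefined(self):
        assert vf.cohort_af([call(zyg="missing")] * 3) is None

    def test_masked_calls_leave_allele_number(self):
        calls = [call(zyg="hom_ref", sample=f"s{i}") for i in range(3)]
        calls.append(call(zyg="missing", sample="m"))
        calls.append(call(zyg="het", sample="h"))
        assert vf.cohort_af(calls) == pytest.approx(1 / 8)

    @given(st.integers(1, 500))
    @settings(max_examples=30, deadline=None)
    def test_singleton_het_is_1_over_2n(self, n):
        calls = [call(zyg="hom_ref", sample=f"s{i}") for i in range(n - 1)]
        calls.append(call(zyg="het", sample="c"))
        assert vf.cohort_af(calls) == pytest.approx(1 / (2 * n))

    def test_x_males_contribute_one_allele(self):
        male = {"m1": True, "m2": True, "f1": False}
        calls = [call(zyg="hemi", sample="m1"),
                 call(zyg="hom_ref", sample="m2"),
                 call(zyg="het", sample="f1")]
        af = vf.cohort_af(calls, chrom="chrX", male=male)
        assert af == pytest.approx(2 / 4)   # AN = 1 + 1 + 2


def make_variant(maf_1kg=None, maf_esp=None, maf_gnomad=None, cohort=0.0001,
                 terms=("stop_gained",)):
    return vf.AnnotatedVariant("chr1", 100, "A", "T", gene="G",
                               consequence_terms=frozenset(terms),
                               maf_1kg=maf_1kg, maf_esp=maf_esp,
                               maf_gnomad=maf_gnomad, cohort_af=cohort)


class TestRarity:
    def test_all_below_threshold_kept(self):
        assert vf.rarity_filter(make_variant(0.004, None, 0.001))

    def test_any_database_above_excluded(self):
        assert not vf.rarity_filter(make_variant(None, None, 0.006))

    def test_exactly_at_threshold_kept(self):
        # exclusion applies to frequencies strictly higher than the cutoff
        assert vf.rarity_filter(make_variant(0.005, 0.005, 0.005))

    def test_cohort_af_counts(self):
        assert not vf.rarity_filter(make_variant(cohort=0.01))

    @given(st.floats(0, 0.05), st.floats(0, 0.004))
    @settings(max_examples=100, deadline=None)
    def test_lower_threshold_never_enlarges_kept_set(self, maf, delta):
        v = make_variant(maf_gnomad=maf)
        if vf.rarity_filter(v, threshold=0.005 - delta):
            assert vf.rarity_filter(v, threshold=0.005)


class TestConsequence:
    @pytest.mark.parametrize("terms,expected", [
        ({"stop_gained"}, "PTV"),
        ({"frameshift_variant"}, "PTV"),
        ({"splice_acceptor_variant"}, "PTV"),
        ({"splice_donor_variant"}, "PTV"),
        ({"start_lost"}, "PTV"),
        ({"synonymous_variant"}, "synonymous"),
        ({"missense_variant"}, "other"),
        ({"stop_gained", "synonymous_variant"}, "PTV"),  # PTV term wins
        ({"some_novel_term"}, "other"),
    ])
    def test_classes(self, terms, expected):
        assert vf.classify_consequence(terms) == expected


def oracle_inheritance(hits, mode, sex=None, xl_female_dominant=False):
    """Independent truth table: which of the (key, zygosity) hits qualify.

    Coded directly from the filtering rule: exclude 1-hit heterozygous in
    recessive contexts and homozygous in dominant contexts; hemizygous
    males qualify in X-linked genes.
    """
    out = []
    distinct = len({k for k, _ in hits})
    for key, zyg in hits:
        if mode == "AD":
            ok = zyg == "het"
        elif mode == "XL" and sex == "male":
            ok = zyg in ("hemi", "hom_alt")
        elif mode == "XL" and xl_female_dominant:
            ok = zyg in ("het", "hom_alt")
        else:  # AR, or XL female under the recessive reading
            ok = zyg == "hom_alt" or (zyg == "het" and distinct >= 2)
        if ok:
            out.append((key, zyg))
    return out


def iter_inheritance_cases(max_hits=3):
    for mode in ("AD", "AR", "XL"):
        sexes = ("male", "female") if mode == "XL" else (None,)
        for sex in sexes:
            zygs = ("hemi", "hom_alt") if (mode == "XL" and sex == "male") \
                else ("het", "hom_alt")
            for n in range(1, max_hits + 1):
                for combo in itertools.product(zygs, repeat=n):
                    hits = [(f"v{i}", z) for i, z in enumerate(combo)]
                    yield mode, sex, hits


class TestInheritance:
    def test_single_het_in_ar_gene_excluded(self):
        assert vf.inheritance_filter([("v1", "het")], "AR") == []

    def test_hom_in_ad_gene_excluded(self):
        assert vf.inheritance_filter([("v1", "hom_alt")], "AD") == []

    def test_two_distinct_het_in_ar_gene_qualify(self):
        hits = [("v1", "het"), ("v2", "het")]
        assert vf.inheritance_filter(hits, "AR") == hits

    def test_same_variant_twice_is_one_hit(self):
        hits = [("v1", "het"), ("v1", "het")]
        assert vf.inheritance_filter(hits, "AR") == []

    def test_xl_male_hemi_qualifies(self):
        assert vf.inheritance_filter([("v1", "hemi")], "XL", sex="male") == \
            [("v1", "hemi")]

    def test_xl_female_follows_recessive_rule(self):
        assert vf.inheritance_filter([("v1", "het")], "XL", sex="female") == []
        assert vf.inheritance_filter([("v1", "hom_alt")], "XL", sex="female") \
            == [("v1", "hom_alt")]

    def test_xl_female_dominant_gene(self):
        assert vf.inheritance_filter([("v1", "het")], "XL", sex="female",
                                     xl_female_dominant=True) == [("v1", "het")]

    def test_unknown_mode_rejected(self):
        with pytest.raises(Exception):
            vf.inheritance_filter([("v1", "het")], "MT")

    def test_exhaustive_truth_table(self):
        """All (mode, sex, zygosity multiset) combinations with <= 3 hits."""
        n_cases = 0
        for mode, sex, hits in iter_inheritance_cases():
            got = vf.inheritance_filter(hits, mode, sex=sex)
            want = oracle_inheritance(hits, mode, sex=sex)
            assert got == want, (mode, sex, hits)
            n_cases += 1
        assert n_cases > 50


class TestKnownVariants:
    def test_exact_match(self):
        known = {"chr1:100:A:T"}
        assert vf.known_variant_match(make_variant(), known)

    def test_different_alt_no_match(self):
        assert not vf.known_variant_match("chr1:100:A:G", {"chr1:100:A:T"})

    def test_empty_list_never_matches(self):
        assert not vf.known_variant_match(make_variant(), set())

    def test_duplicate_keys_rejected(self, tmp_path):
        path = tmp_path / "known.tsv"
        path.write_text("chrom\tpos\tref\talt\tsource_label\n"
                        "chr1\t100\tA\tT\tx\nchr1\t100\tA\tT\ty\n")
        with pytest.raises(Exception, match="duplicate"):
            vf.load_known_variants(path)


class TestFilterCommutation:
    def test_stage_order_does_not_change_survivors(self, tmp_path):
        """Site, rarity and consequence predicates are pure per-variant
        filters, so any application order keeps the same set."""
        rng = np.random.default_rng(5)
        bed = tmp_path / "l.bed"
        bed.write_text("chr1\t1000\t2000\n")
        lcr = load_lcr(bed)
        pool = []
        for i in range(200):
            v = vf.AnnotatedVariant(
                "chr1", int(rng.integers(1, 3000)), "A", "T", gene="G",
                consequence_terms=frozenset(
                    {str(rng.choice(["stop_gained", "missense_variant",
                                     "synonymous_variant"]))}),
                maf_gnomad=(None if rng.random() < 0.5
                            else float(rng.uniform(0, 0.02))),
                cohort_af=float(rng.uniform(0, 0.01)))
            status = "PASS" if rng.random() < 0.7 else "lowqual"
            pool.append((v, status))

        preds = {
            "site": lambda v, s: vf.site_prefilter(s, v.chrom, v.pos, lcr),
            "rare": lambda v, s: vf.rarity_filter(v),
            "cons": lambda v, s: v.consequence_class == "PTV",
        }
        results = []
        for order in itertools.permutations(preds):
            kept = pool
            for name in order:
                kept = [(v, s) for v, s in kept if preds[name](v, s)]
            results.append({v.key for v, _ in kept})
        assert all(r == results[0] for r in results)
        assert 0 < len(results[0]) < len(pool)
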