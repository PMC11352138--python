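"""Allele database: loading, HGVS handling, and variant-set matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhdtype.alleles import (
    AlleleDatabaseError,
    Category,
    Confidence,
    HgvsSyntaxError,
    StructuralClass,
    Variant,
    Zygosity,
    hgvs_format,
    hgvs_parse,
    load_allele_db,
    match_variants,
)

TABLE_ALLELES = [
    "RHD*01", "RHD*01N.01", "RHD*01W.1", "RHD*01W.2", "RHD*01W.3",
    "RHD*01W.5", "RHD*07.01", "RHD*04.03", "RHD*01EL.01", "RHD*19",
    "RHD*25", "RHD*11",
]


class TestLoad:
    def test_default_db_contains_panel_alleles(self, db):
        for name in TABLE_ALLELES:
            assert name in db

    def test_weak_d_type_1_definition(self, db):
        a = db["RHD*01W.1"]
        assert a.defining_variants == {Variant(809, "T", "G")}
        assert a.category is Category.WEAK_D
        assert a.phenotype_label == "weak D type 1"
        assert a.rs_ids[Variant(809, "T", "G")] == "rs121912763"

    def test_reference_allele_has_no_variants(self, db):
        a = db["RHD*01"]
        assert a.defining_variants == frozenset()
        assert a.category is Category.NORMAL

    def test_deletion_and_hybrid_structure(self, db):
        assert db["RHD*01N.01"].structural_class is StructuralClass.GENE_ABSENT
        hybrid = db["RHD*04.03"]
        assert hybrid.structural_class is StructuralClass.EXON_DROPOUT
        assert hybrid.dropped_exons == {6, 7, 8, 9}

    def test_synonymous_del_allele_is_annotation_only(self, db):
        a = db["RHD*01EL.01"]
        assert a.defining_variants == {Variant(1227, "G", "A")}
        assert a.category is Category.DEL

    def test_duplicate_allele_rejected(self):
        rows = [
            {"allele_name": "X*1", "variants": "c.10A>G", "structural_class": "FULL_GENE",
             "category": "weak D", "phenotype_label": "x"},
        ] * 2
        with pytest.raises(AlleleDatabaseError, match="duplicate"):
            load_allele_db(rows)

    def test_out_of_range_variant_rejected_with_index(self):
        rows = [
            {"allele_name": "X*1", "variants": "c.1300A>G", "structural_class": "FULL_GENE",
             "category": "weak D", "phenotype_label": "x"},
        ]
        with pytest.raises(AlleleDatabaseError, match="record 0"):
            load_allele_db(rows)


class TestHgvs:
    @pytest.mark.parametrize(
        "variant,expected",
        [
            (Variant(809, "T", "G"), "NM_016124.6:c.809T>G"),
            (Variant(8, "C", "G"), "NM_016124.6:c.8C>G"),
            (Variant(1063, "G", "A"), "NM_016124.6:c.1063G>A"),
        ],
    )
    def test_format(self, variant, expected):
        assert hgvs_format(variant) == expected

    def test_parse(self):
        assert hgvs_parse("NM_016124.6:c.8C>G") == Variant(8, "C", "G")
        assert hgvs_parse("c.446C>A") == Variant(446, "C", "A")

    @pytest.mark.parametrize("bad", ["NM_016124.6:c.809del", "c.8_9insT", "c.100dupA"])
    def test_non_substitution_rejected(self, bad):
        with pytest.raises(HgvsSyntaxError):
            hgvs_parse(bad)

    @settings(derandomize=True, max_examples=100)
    @given(
        pos=st.integers(1, 1254),
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
    )
    def test_round_trip(self, pos, ref, alt):
        if ref == alt:
            return
        v = Variant(pos, ref, alt)
        assert hgvs_parse(hgvs_format(v)) == v

    def test_invalid_variant_fields(self):
        with pytest.raises(ValueError):
            Variant(0, "A", "G")
        with pytest.raises(ValueError):
            Variant(10, "A", "A")
        with pytest.raises(ValueError):
            Variant(10, "N", "G")


class TestMatchVariants:
    def test_lone_het_variant_in_trans_to_reference(self, db):
        call = match_variants([(Variant(1063, "G", "A"), Zygosity.HET)], db)
        assert call.allele_pair == ("RHD*25", "RHD*01")
        assert call.confidence_note is Confidence.HET_PHASE_ASSUMED

    def test_empty_set_is_reference_unresolved(self, db):
        call = match_variants([], db)
        assert call.allele_pair == ("RHD*01", "unresolved")

    def test_hom_single_variant(self, db):
        call = match_variants([(Variant(809, "T", "G"), Zygosity.HOM)], db)
        assert call.allele_pair == ("RHD*01W.1", "unresolved")
        assert call.confidence_note is Confidence.EXACT_MATCH

    def test_unknown_combination_is_novel_not_error(self, db):
        observed = [
            (Variant(809, "T", "G"), Zygosity.HOM),
            (Variant(1154, "G", "C"), Zygosity.HOM),
        ]
        call = match_variants(observed, db)
        assert call.confidence_note is Confidence.NOVEL_CANDIDATE
        assert set(v for v, _ in call.unmatched) == {v for v, _ in observed}

    def test_multi_het_is_phase_unknown_novel(self, db):
        observed = [
            (Variant(809, "T", "G"), Zygosity.HET),
            (Variant(1063, "G", "A"), Zygosity.HET),
        ]
        call = match_variants(observed, db)
        assert call.confidence_note is Confidence.NOVEL_CANDIDATE
        assert call.phase_unknown

    def test_order_independence(self, db):
        observed = [
            (Variant(809, "T", "G"), Zygosity.HOM),
            (Variant(1154, "G", "C"), Zygosity.HOM),
        ]
        assert match_variants(observed, db) == match_variants(observed[::-1], db)

    @pytest.mark.parametrize(
        "allele", ["RHD*01W.1", "RHD*01W.2", "RHD*01W.3", "RHD*01W.5",
                   "RHD*07.01", "RHD*01EL.01", "RHD*19", "RHD*25", "RHD*11"]
    )
    def test_every_snp_allele_resolvable_hom_and_het(self, db, allele):
        (v,) = db[allele].defining_variants
        hom = match_variants([(v, Zygosity.HOM)], db)
        assert hom.allele_pair[0] == allele
        het = match_variants([(v, Zygosity.HET)], db)
        assert het.allele_pair == (allele, "RHD*01")
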