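"""Allele-specific PCR, melt-curve synthesis/classification, and the
exon amplification screen."""

import numpy as np
import pytest

from rhdtype.primers import revcomp
from rhdtype.simulate import make_sample
from rhdtype.ssp import (
    AssayConfigError,
    classify_melt,
    estimate_tm,
    find_amplicon,
    run_ssp_assay,
    synthesize_melt_curve,
    validate_standards,
)

from conftest import brute_force_amplicon, random_primer


def _assay(assays, name):
    return next(a for a in assays if a.assay_name == name)


class TestFindAmplicon:
    def test_three_prime_discrimination(self, model, db, ssp_assays):
        w1 = _assay(ssp_assays, "RHD*01W.1")
        carrier = make_sample("RHD*01W.1", "RHD*01W.1", model, db)
        normal = make_sample("RHD*01", "RHD*01", model, db)
        assert find_amplicon(carrier.haplotypes[0].sequence, *w1.target_pair) is not None
        assert find_amplicon(normal.haplotypes[0].sequence, *w1.target_pair) is None

    def test_absent_template(self, ssp_assays):
        w1 = _assay(ssp_assays, "RHD*01W.1")
        assert find_amplicon(None, *w1.target_pair) is None
        assert find_amplicon("", *w1.target_pair) is None

    def test_m13_tail_excluded_from_matching_but_in_product(self, model, exon_assays):
        ea = exon_assays[0]  # exon 1, tailed forward primer
        product = find_amplicon(model.genomic_sequence, ea.fwd, ea.rev)
        assert product is not None
        assert product.startswith("CAGGAAACAGCTATGAC")
        assert product[len(ea.fwd.tail):].startswith(ea.fwd.core)

    def test_max_len_respected(self, model, exon_assays):
        ea = exon_assays[0]
        assert find_amplicon(model.genomic_sequence, ea.fwd, ea.rev, max_len=50) is None

    def test_agrees_with_exhaustive_scan_on_random_templates(self):
        rng = np.random.default_rng(2024)
        agreements = 0
        for trial in range(100):
            fwd = random_primer(rng, int(rng.integers(16, 26)), "f")
            rev = random_primer(rng, int(rng.integers(16, 26)), "r")
            template = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
            if trial % 2 == 0:
                # embed a genuine site pair so positives are exercised
                a = int(rng.integers(0, 800))
                b = int(rng.integers(a + len(fwd.core), 1800))
                template = (
                    template[:a] + fwd.core
                    + template[a + len(fwd.core): b]
                    + revcomp(rev.core) + template[b + len(rev.core):]
                )
            got = find_amplicon(template, fwd, rev)
            expected = brute_force_amplicon(template, fwd, rev)
            assert got == expected
            agreements += 1
        assert agreements == 100

    def test_mismatch_budget_agrees_with_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            fwd = random_primer(rng, 18, "f")
            rev = random_primer(rng, 18, "r")
            template = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
            core = list(fwd.core)
            core[3] = "ACGT"[(("ACGT".index(core[3])) + 1) % 4]  # one 5' mismatch
            template = template[:50] + "".join(core) + template[50 + 18: 300] + revcomp(rev.core) + template[300 + 18:]
            for budget in (0, 1):
                assert find_amplicon(template, fwd, rev, mismatch_budget=budget) == \
                    brute_force_amplicon(template, fwd, rev, budget=budget)


class TestMeltCurve:
    def test_single_peak_at_assigned_tm(self):
        curve = synthesize_melt_curve([("ACGT" * 30, 83.0, 1.0)])
        assert len(curve.peaks) == 1
        assert curve.peak_tms[0] == pytest.approx(83.0, abs=0.1)

    def test_two_products_well_separated(self):
        curve = synthesize_melt_curve([("A" * 100, 78.0, 1.0), ("G" * 100, 83.0, 0.6)])
        assert len(curve.peaks) == 2

    def test_empty_product_list_is_flat(self):
        curve = synthesize_melt_curve([])
        assert curve.peaks == ()
        assert np.all(curve.signal == 0)

    def test_classification_with_published_standards(self):
        standards = {"RHD*01W.1": 83.0, "control": 80.7}
        curve = synthesize_melt_curve([("x" * 50, 83.0, 1.0), ("y" * 50, 80.7, 0.6)])
        assert sorted(classify_melt(curve, standards)) == ["RHD*01W.1", "control"]
        curve = synthesize_melt_curve([("y" * 50, 80.7, 0.6)])
        assert classify_melt(curve, standards) == ["control"]

    def test_unmatched_peak_labelled_unclassified(self):
        standards = {"RHD*01W.1": 83.0, "control": 80.7}
        curve = synthesize_melt_curve([("z" * 50, 77.0, 1.0)])
        assert classify_melt(curve, standards) == ["unclassified_peak"]

    def test_ambiguous_standards_rejected_at_configuration(self):
        with pytest.raises(AssayConfigError):
            validate_standards({"a": 80.0, "b": 81.5}, tolerance=1.0)

    def test_round_trip_label_recovery(self):
        # classify(synthesize(...)) recovers generating labels whenever
        # standards are spaced more than twice the tolerance apart
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            tms = np.sort(71 + rng.random(n) * 22)
            while np.any(np.diff(tms) <= 2.5):
                tms = np.sort(71 + rng.random(n) * 22)
            standards = {f"s{i}": round(float(t), 1) for i, t in enumerate(tms)}
            chosen = [lab for lab in standards if rng.random() < 0.6]
            curve = synthesize_melt_curve([("x", standards[lab], 1.0) for lab in chosen])
            got = classify_melt(curve, standards, tolerance=1.0)
            assert sorted(got) == sorted(chosen)


class TestSspAssay:
    def test_positive_call_with_genotype_label(self, model, db, ssp_assays):
        w3 = _assay(ssp_assays, "RHD*01W.3")
        sample = make_sample("RHD*01W.3", "RHD*01W.3", model, db)
        r = run_ssp_assay(sample, w3)
        assert r.call == "POSITIVE"
        assert r.genotype_label == "RHD*01W.3"

    def test_negative_call_shows_control_peak(self, model, db, ssp_assays):
        w2 = _assay(ssp_assays, "RHD*01W.2")
        sample = make_sample("RHD*01", "RHD*01", model, db)
        r = run_ssp_assay(sample, w2)
        assert r.call == "NEGATIVE"
        assert r.genotype_label == "non-RHD*01W.2"
        assert r.observed_tms[0] == pytest.approx(86.0, abs=0.1)

    def test_positive_iff_truth_carries_defining_variant(self, panel, model, db, ssp_assays):
        # SSP correctness over the full panel x all four assays, checked
        # against direct truth lookup
        for sample in panel:
            carried = set()
            for name in sample.truth_allele_pair:
                carried |= db[name].defining_variants
            for assay in ssp_assays:
                target_vars = db[assay.target_allele].defining_variants
                expected = "POSITIVE" if target_vars <= carried and target_vars else "NEGATIVE"
                r = run_ssp_assay(sample, assay)
                assert r.call == expected, (sample.sample_id, assay.assay_name)

    def test_template_bearing_sample_never_invalid(self, panel, ssp_assays):
        for sample in panel:
            for assay in ssp_assays:
                assert run_ssp_assay(sample, assay).call != "INVALID"

    def test_control_linkage_per_assay(self, ssp_assays):
        tms = {a.assay_name: a.control_tm for a in ssp_assays}
        assert tms["RHD*01W.2"] == 86.0
        assert tms["RHD*01W.1"] == tms["RHD*01W.3"] == tms["RHD*07.01"] == 80.7


class TestExonScreen:
    def test_full_gene_all_present(self, panel, model, exon_assays):
        from rhdtype.ssp import amplify_exons

        ref_sample = next(s for s in panel if s.sample_id == "2019-31")
        assert amplify_exons(ref_sample, exon_assays).present == set(range(1, 11))

    def test_deletion_all_absent(self, panel, exon_assays):
        from rhdtype.ssp import amplify_exons

        dele = next(s for s in panel if s.sample_id == "2020-31")
        assert amplify_exons(dele, exon_assays).present == frozenset()

    def test_hybrid_profile_is_complement_of_dropout(self, panel, db, exon_assays):
        from rhdtype.ssp import amplify_exons

        hybrid = next(s for s in panel if s.sample_id == "2019-33")
        profile = amplify_exons(hybrid, exon_assays)
        assert profile.present == {1, 2, 3, 4, 5, 10}
        assert profile.absent == db["RHD*04.03"].dropped_exons

    def test_every_panel_profile_matches_structure(self, panel, db, exon_assays):
        from rhdtype.alleles import StructuralClass
        from rhdtype.ssp import amplify_exons

        for sample in panel:
            profile = amplify_exons(sample, exon_assays)
            classes = {db[n].structural_class for n in sample.truth_allele_pair}
            if classes == {StructuralClass.GENE_ABSENT}:
                assert profile.all_absent
            elif StructuralClass.EXON_DROPOUT in classes:
                dropped = set().union(*(db[n].dropped_exons for n in sample.truth_allele_pair))
                assert profile.absent == dropped
            else:
                assert profile.all_present, sample.sample_id


class TestEstimateTm:
    def test_gc_monotonicity_at_fixed_length(self):
        low = "AT" * 30
        high = "GC" * 30
        assert estimate_tm(high) > estimate_tm(low)

    def test_length_effect_nonnegative(self):
        amp = "ACGTGGCTAGCTAGGCTAAC" * 3
        assert estimate_tm(amp + amp) >= estimate_tm(amp)

    def test_matches_independent_nearest_neighbor_sum(self):
        # independent oracle: hand-summed unified nearest-neighbor
        # enthalpies/entropies with the same salt correction
        from Bio.SeqUtils.MeltingTemp import DNA_NN3
        import math

        seq = "AGCGTACCGGTTAGCAT"
        dh, ds = DNA_NN3["init"][0], DNA_NN3["init"][1]
        for key in ("init_A/T",):
            for end in (seq[0], seq[-1]):
                if end in "AT":
                    dh += DNA_NN3[key][0]
                    ds += DNA_NN3[key][1]
        for key in ("init_G/C",):
            for end in (seq[0], seq[-1]):
                if end in "GC":
                    dh += DNA_NN3[key][0]
                    ds += DNA_NN3[key][1]
        comp = str.maketrans("ACGT", "TGCA")
        for i in range(len(seq) - 1):
            pair = seq[i : i + 2]
            key = pair[0] + pair[1] + "/" + pair.translate(comp)[0] + pair.translate(comp)[1]
            if key not in DNA_NN3:
                rc = pair.translate(comp)[::-1]
                key = rc[0] + rc[1] + "/" + rc.translate(comp)[0] + rc.translate(comp)[1]
            dh += DNA_NN3[key][0]
            ds += DNA_NN3[key][1]
        # salt correction 5 (SantaLucia 1998) on entropy, 50 mM Na+;
        # effective duplex concentration 25 - 25/2 nM for a non-self-
        # complementary oligo with both strands supplied equally
        ds_corr = ds + 0.368 * (len(seq) - 1) * math.log(0.05)
        k = (25 - 25 / 2.0) * 1e-9
        tm = (1000 * dh) / (ds_corr + 1.987 * math.log(k)) - 273.15
        assert estimate_tm(seq) == pytest.approx(tm, abs=0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_tm("")
        with pytest.raises(ValueError):
            estimate_tm("ACGTN")
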