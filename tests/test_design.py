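import re

import numpy as np
import pytest

from promdissect import (
    ExpectedFeature,
    FeatureHit,
    SequenceRecord,
    compose_promoter,
    knockout,
    randomize_positions,
    split_promoter,
    symmetrize_fnr,
    verify_design,
)
from promdissect.catalog import (
    CRITICAL_OFFSETS,
    MINUS10_CONSENSUS,
    MINUS35_CONSENSUS,
    fnr_matrix,
)
from promdissect.design import DesignPlan, apply_edits
from promdissect.features import best_pwm_score, find_hits, scan_pwm
from promdissect.simulate import generate_background

FNR_THRESHOLD = 10 * np.log2(0.91 / 0.25) - 1e-9  # perfect half-sites


def fnr_def(catalogue):
    return next(f for f in catalogue if f.feature_id == "FNR")


def basal_def(catalogue):
    return next(f for f in catalogue if f.feature_id == "BasalP")


@pytest.fixture()
def template(rng):
    rec = generate_background(100, 0.55, rng)
    return SequenceRecord("tmpl", rec.sequence, "designed")


class TestSplitPromoter:
    def test_partition_property(self, rng):
        rec = SequenceRecord("P0", "".join(rng.choice(list("ACGT"), size=300)))
        frags = split_promoter(rec, [])
        assert "".join(f.sequence for f in frags) == rec.sequence
        assert all(50 <= f.length <= 100 for f in frags[:-1])
        assert frags[0].id == "P0_1" and frags[-1].id == f"P0_{len(frags)}"

    def test_cut_avoids_bisecting_hit(self, rng):
        rec = SequenceRecord("P0", "".join(rng.choice(list("ACGT"), size=200)))
        hit = FeatureHit("FNR", "P0", 95, 109, "+", 1.0)
        frags = split_promoter(rec, [hit])
        boundaries = np.cumsum([f.length for f in frags])[:-1]
        assert all(not (95 < b < 109) for b in boundaries)

    def test_modules_stay_within_single_fragments(self, rng, catalogue):
        # implant three separated FNR sites, split, re-scan the fragments
        seq = list("".join(rng.choice(list("ACGT"), size=400)))
        positions = [40, 180, 330]
        for pos in positions:
            seq[pos : pos + 14] = list("TTGATCATGATCAA")
        rec = SequenceRecord("P0", "".join(seq))
        hits = scan_pwm(rec.sequence, fnr_matrix(), FNR_THRESHOLD, "P0")
        frags = split_promoter(rec, hits)
        refound = sum(
            len([h for h in scan_pwm(f.sequence, fnr_matrix(), FNR_THRESHOLD) if h.strand == "+"])
            for f in frags
        )
        assert refound == len(positions)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            split_promoter(SequenceRecord("x", "ACGT"), [])


class TestKnockout:
    @pytest.fixture()
    def fnr_record(self, template):
        seq = template.sequence[:40] + "TTGATCATGATCAA" + template.sequence[54:]
        return SequenceRecord("rec", seq, "designed")

    def test_empty_offsets_identity(self, fnr_record):
        hit = FeatureHit("FNR", "rec", 40, 54, "+", 1.0)
        plan = knockout(fnr_record, hit, [], seed=1)
        assert plan.product.sequence == fnr_record.sequence
        assert plan.edits == []

    def test_knockout_abolishes_hit_at_locus(self, fnr_record, catalogue):
        hit = FeatureHit("FNR", "rec", 40, 54, "+", 1.0)
        plan = knockout(fnr_record, hit, CRITICAL_OFFSETS["FNR"], seed=2,
                        feature=fnr_def(catalogue), threshold=FNR_THRESHOLD)
        report = verify_design(plan)
        assert report["passed"]
        hits = find_hits(plan.product, fnr_def(catalogue), FNR_THRESHOLD)
        assert not any(h.start < 54 and 40 < h.end for h in hits)

    def test_never_alters_bases_outside_hit(self, fnr_record):
        hit = FeatureHit("FNR", "rec", 40, 54, "+", 1.0)
        plan = knockout(fnr_record, hit, CRITICAL_OFFSETS["FNR"], seed=3)
        assert plan.product.sequence[:40] == fnr_record.sequence[:40]
        assert plan.product.sequence[54:] == fnr_record.sequence[54:]

    def test_gc_alphabet_for_basal_knockout(self, fnr_record):
        hit = FeatureHit("BasalP", "rec", 40, 46, "+", 1.0)
        plan = knockout(fnr_record, hit, list(range(6)), seed=4,
                        replacement_alphabet="GC")
        changed = plan.product.sequence[40:46]
        assert all(b in "GC" for b in changed)

    def test_offset_outside_hit_rejected(self, fnr_record):
        hit = FeatureHit("FNR", "rec", 40, 54, "+", 1.0)
        with pytest.raises(ValueError, match="outside"):
            knockout(fnr_record, hit, [20], seed=0)

    def test_repeated_seeded_knockouts_all_drop_below_threshold(self, catalogue, rng):
        # 100 independent knockouts of a consensus implant: the re-scan score
        # must fall below the detection threshold every time
        feature = fnr_def(catalogue)
        failures = 0
        for s in range(100):
            bg = generate_background(80, 0.5, 1000 + s).sequence
            seq = bg[:30] + "TTGATCATGATCAA" + bg[44:]
            rec = SequenceRecord(f"r{s}", seq, "designed")
            hit = FeatureHit("FNR", rec.id, 30, 44, "+", 1.0)
            plan = knockout(rec, hit, CRITICAL_OFFSETS["FNR"], seed=s,
                            feature=feature, threshold=FNR_THRESHOLD)
            hits = find_hits(plan.product, feature, FNR_THRESHOLD)
            if any(h.start < 44 and 30 < h.end for h in hits):
                failures += 1
        assert failures == 0


class TestRandomize:
    def test_empty_positions_identity(self, template):
        plan = randomize_positions(template, [], seed=1)
        assert plan.product.sequence == template.sequence

    def test_only_listed_positions_change(self, template):
        plan = randomize_positions(template, [5, 10, 20], seed=2)
        diffs = [i for i, (a, b) in enumerate(zip(template.sequence,
                                                  plan.product.sequence)) if a != b]
        assert diffs == [5, 10, 20]

    def test_preserved_feature_redetected(self, rng, catalogue):
        bg = generate_background(120, 0.5, rng).sequence
        seq = bg[:50] + "TTGATCATGATCAA" + bg[64:]
        rec = SequenceRecord("r", seq, "designed")
        preserve = [ExpectedFeature(fnr_def(catalogue), FNR_THRESHOLD, True, (50, 64))]
        spacer_positions = [55, 56, 57, 58]  # the N4 core, non-critical
        plan = randomize_positions(rec, spacer_positions, seed=5, preserve=preserve)
        hits = find_hits(plan.product, fnr_def(catalogue), FNR_THRESHOLD)
        assert any(h.start < 64 and 50 < h.end for h in hits)

    def test_critical_position_clash_rejected(self, rng, catalogue):
        bg = generate_background(120, 0.5, rng).sequence
        seq = bg[:50] + "TTGATCATGATCAA" + bg[64:]
        rec = SequenceRecord("r", seq, "designed")
        preserve = [ExpectedFeature(fnr_def(catalogue), FNR_THRESHOLD, True, (50, 64))]
        with pytest.raises(ValueError, match="critical"):
            randomize_positions(rec, [51], seed=0, preserve=preserve)


class TestSymmetrize:
    def test_already_palindromic_site_unchanged(self, p23):
        # the printed promoter's site TTGAT-CATG-ATCAA: ATCAA is already the
        # reverse complement of TTGAT
        rec = SequenceRecord("P2_3", p23, "designed")
        hit = FeatureHit("FNR", "P2_3", 31, 45, "+", 1.0)
        plan = symmetrize_fnr(rec, hit)
        assert plan.edits == []
        assert plan.product.sequence == p23

    def test_asymmetric_site_gains_score(self, rng):
        bg = generate_background(60, 0.5, rng).sequence
        site = "TTGAT" + "CATG" + "GTCAA"  # second half one base off
        seq = bg[:20] + site + bg[34:]
        rec = SequenceRecord("r", seq, "designed")
        plan = symmetrize_fnr(rec, FeatureHit("FNR", "r", 20, 34, "+", 1.0))
        assert len(plan.edits) == 1
        before = best_pwm_score(site, fnr_matrix(), "forward")
        after = best_pwm_score(plan.product.sequence[20:34], fnr_matrix(), "forward")
        assert after > before

    def test_wrong_width_rejected(self, p23):
        rec = SequenceRecord("r", p23, "designed")
        with pytest.raises(ValueError, match="14"):
            symmetrize_fnr(rec, FeatureHit("FNR", "r", 0, 10, "+", 1.0))


class TestCompose:
    def test_empty_parts_identity(self, template):
        plan = compose_promoter(template, [], seed=1)
        assert plan.product.sequence == template.sequence

    def test_implants_redetected(self, template, catalogue):
        spacer = 17
        parts = [
            ("TTGATCATGATCAA", 5),
            (MINUS35_CONSENSUS, 30),
            (MINUS10_CONSENSUS, 30 + 6 + spacer),
        ]
        expected = [
            ExpectedFeature(fnr_def(catalogue), FNR_THRESHOLD, True),
            ExpectedFeature(basal_def(catalogue), 10.0, True),
        ]
        plan = compose_promoter(template, parts, seed=2, expected_features=expected)
        report = verify_design(plan, tss=30 + 6 + spacer + 6 + 6)
        assert report["passed"]
        assert "tss_melting_at_fraction" in report

    def test_overlapping_parts_rejected(self, template):
        with pytest.raises(ValueError, match="overlap"):
            compose_promoter(template, [("AAAA", 10), ("TTTT", 12)])

    def test_at_enrichment_reaches_target_outside_parts(self, template):
        plan = compose_promoter(template, [("TTGATCATGATCAA", 40)],
                                at_enrich=(47, 20, 0.7), seed=3)
        window = plan.product.sequence[27:67]
        from promdissect import at_fraction

        assert at_fraction(window) >= 0.7
        assert plan.product.sequence[40:54] == "TTGATCATGATCAA"

    def test_printed_promoter_architecture_reconstructed(self, p23, catalogue):
        # implant the printed promoter's FNR site at 31 and the AATAAAC
        # initiation motif at 83 into a GC-rich template: the product carries
        # TTGAT-N4-ATCAA at [31,45) and AATAAAC, matching the printed layout
        template = SequenceRecord("tmpl", generate_background(97, 0.55, 7).sequence,
                                  "designed")
        plan = compose_promoter(template, [(p23[31:45], 31), ("AATAAAC", 83)], seed=4)
        product = plan.product.sequence
        assert [m.start() for m in re.finditer(r"(?=TTGAT....ATCAA)", product)] == [31]
        assert product[83:90] == "AATAAAC"

    def test_hundred_seeded_compositions_redetect_both_implants(self, catalogue):
        fnr, basal = fnr_def(catalogue), basal_def(catalogue)
        failures = 0
        for s in range(100):
            template = SequenceRecord(
                "t", generate_background(100, 0.55, 2000 + s).sequence, "designed"
            )
            parts = [("TTGATCATGATCAA", 3),
                     (MINUS35_CONSENSUS, 25),
                     (MINUS10_CONSENSUS, 48)]
            expected = [ExpectedFeature(fnr, FNR_THRESHOLD, True),
                        ExpectedFeature(basal, 10.0, True)]
            plan = compose_promoter(template, parts, seed=s,
                                    expected_features=expected)
            if not verify_design(plan)["passed"]:
                failures += 1
        assert failures == 0


class TestDesignPlan:
    def test_serialization_round_trip(self, template):
        plan = compose_promoter(template, [("TTGATCATGATCAA", 10)], seed=1)
        back = DesignPlan.from_json(plan.to_json())
        assert back.product.sequence == plan.product.sequence
        assert back.edits == plan.edits

    def test_edits_reproduce_product(self, template):
        plan = compose_promoter(template, [("AAAA", 10), ("TTTT", 50)], seed=1)
        assert apply_edits(template.sequence, plan.edits) == plan.product.sequence

    def test_failed_expectation_names_feature(self, template, catalogue):
        plan = compose_promoter(
            template, [],
            expected_features=[ExpectedFeature(fnr_def(catalogue), FNR_THRESHOLD, True)],
        )
        report = verify_design(plan)
        assert not report["passed"]
        assert report["checks"][0]["feature_id"] == "FNR"

    def test_empty_expectations_vacuous_pass(self, template):
        assert verify_design(compose_promoter(template, []))["passed"]
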