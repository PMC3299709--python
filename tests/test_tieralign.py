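"""Tiered alignment: mode thresholds, mapping quality, classification and
the read-set partition invariant."""

import numpy as np
import pytest

from somaclone._seq import mutate_substitutions, random_seq, revcomp
from somaclone.repeatmask import Masker
from somaclone.synthdata import ReadProfile, simulate_reads
from somaclone.tieralign import (AlignmentRecord, Rejection, TieredAligner,
                                 classify_unaligned, mapq_score)


@pytest.fixture(scope="module")
def flat_ref():
    """Unique sequence plus an exact two-copy duplication."""
    r = np.random.default_rng(606)
    u = random_seq(r, 30_000)
    dup = random_seq(r, 1_500)
    return {"chr1": u[:12_000] + dup + u[12_000:24_000] + dup + u[24_000:]}


@pytest.fixture(scope="module")
def flat_aligner(flat_ref):
    return TieredAligner(flat_ref, None)


class TestStrictMode:
    def test_exact_substring_accepted(self, flat_ref, flat_aligner):
        seq = flat_ref["chr1"][3_000:3_355]
        rec = flat_aligner.align_single_read("r", seq, "STRICT")
        assert isinstance(rec, AlignmentRecord)
        assert rec.identity == 1.0
        assert rec.step == 1
        assert rec.ref_start == 3_000
        assert rec.mapq == 90
        assert rec.n_candidate_loci == 1

    def test_reverse_strand_recovered(self, flat_ref, flat_aligner):
        seq = revcomp(flat_ref["chr1"][5_000:5_300])
        rec = flat_aligner.align_single_read("r", seq, "STRICT")
        assert isinstance(rec, AlignmentRecord)
        assert rec.strand == "-"
        assert rec.ref_start == 5_000

    def test_identity_boundary_strict_vs_relaxed(self, flat_ref, flat_aligner, rng):
        """~6% divergence fails the 95% strict floor but passes relaxed."""
        base = flat_ref["chr1"][8_000:8_100]
        b = list(base)
        for i in range(0, 60, 10):  # exactly 6 mismatches in 100 bp
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        seq = "".join(b)
        assert isinstance(flat_aligner.align_single_read("r", seq, "STRICT"),
                         Rejection)
        rec = flat_aligner.align_single_read("r", seq, "RELAXED")
        assert isinstance(rec, AlignmentRecord)
        assert rec.step == 3

    def test_two_copy_duplication_multi_locus(self, flat_ref, flat_aligner):
        seq = flat_ref["chr1"][12_100:12_400]  # inside the duplicated block
        rej = flat_aligner.align_single_read("r", seq, "STRICT")
        assert isinstance(rej, Rejection)
        assert rej.reason == "MULTI_LOCUS"

    def test_foreign_read_no_hit(self, flat_aligner, rng):
        rej = flat_aligner.align_single_read("r", random_seq(rng, 300),
                                             "STRICT")
        assert isinstance(rej, Rejection)
        assert rej.reason == "NO_HIT"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            TieredAligner({}, None)


class TestMaskedMode:
    def test_junction_read_aligned_by_flank(self, lib4, rng):
        fam = lib4.get("Gret1")
        u = random_seq(rng, 20_000)
        ref = {"c": u}
        al = TieredAligner(ref, lib4)
        flank = u[7_000:7_200]
        read = flank + fam.ltr_seq[:155]
        rec = al.align_single_read("r", read, "MASKED")
        assert isinstance(rec, AlignmentRecord)
        assert rec.step == 2
        assert rec.te_family == "Gret1"
        assert rec.junction == 7_200
        assert rec.junction_side == "R"
        assert rec.masked_bases >= 120

    def test_too_masked_rejected(self, lib4, rng):
        fam = lib4.get("Gret1")
        ref = {"c": random_seq(rng, 20_000)}
        al = TieredAligner(ref, lib4)
        read = ref["c"][100:200] + fam.ltr_seq + fam.internal_seq[:100]
        rej = al.align_single_read("r", read, "MASKED")
        assert isinstance(rej, Rejection)
        assert rej.reason == "TOO_MASKED"


class TestMapq:
    def test_no_second_candidate_caps_at_90(self):
        assert mapq_score(350, None, 355) == 90

    def test_tie_scores_zero(self):
        assert mapq_score(350, 350, 355) == 0

    def test_monotone_in_margin(self):
        qs = [mapq_score(355, 355 - gap, 355) for gap in range(0, 400, 10)]
        assert qs == sorted(qs)
        assert qs[-1] == 90

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            mapq_score(10, 20, 100)


class TestClassifyUnaligned:
    def test_short_read_low_quality(self, rng):
        seq = random_seq(rng, 80)
        assert classify_unaligned(seq, "I" * 80, None, {}, {}, False) \
            == "LOW_QUALITY"

    def test_low_mean_quality(self, rng):
        seq = random_seq(rng, 150)
        assert classify_unaligned(seq, chr(33 + 10) * 150, None, {}, {},
                                  False) == "LOW_QUALITY"

    def test_fully_masked_repeat(self, lib4, rng):
        masker = Masker(lib4)
        seq = lib4.get("Gypsy19").ltr_seq[:400]
        m = masker.mask(seq)
        assert classify_unaligned(seq, "I" * 400, m, {}, {}, False) == "REPEAT"

    def test_organelle_read_with_errors(self, rng):
        org = {"chloroplast": random_seq(rng, 20_000)}
        seq = mutate_substitutions(rng, org["chloroplast"][500:855], 0.02)
        assert classify_unaligned(seq, "I" * 355, None, org, {}, False) \
            == "CYTOPLASMIC"

    def test_organelle_read_minus_strand(self, rng):
        org = {"mito": random_seq(rng, 20_000)}
        seq = revcomp(org["mito"][1_000:1_355])
        assert classify_unaligned(seq, "I" * 355, None, org, {}, False) \
            == "CYTOPLASMIC"

    def test_paralog_priority_after_repeat(self, lib4, rng):
        masker = Masker(lib4)
        seq = lib4.get("Gypsy19").ltr_seq[:400]
        m = masker.mask(seq)
        assert classify_unaligned(seq, "I" * 400, m, {}, {}, True) == "REPEAT"

    def test_unknown_fallback(self, rng):
        seq = random_seq(rng, 300)
        assert classify_unaligned(seq, "I" * 300, None, {}, {}, False) \
            == "UNKNOWN"


class TestTieredPartition:
    def test_every_read_exactly_once(self, pair_sim):
        res = pair_sim["results"][0]
        reads = pair_sim["readsets"][0]
        aligned_ids = {r.read_id for r in res.records}
        class_ids = [c.read_id for c in res.classifications]
        assert len(class_ids) == len(set(class_ids)) == len(reads)
        aligned_classes = {c.read_id for c in res.classifications
                           if c.category.startswith("ALIGNED")}
        assert aligned_classes == aligned_ids

    def test_percentages_sum_to_100(self, pair_sim):
        for res in pair_sim["results"]:
            assert sum(res.summary.percentages().values()) \
                == pytest.approx(100.0, abs=0.05)

    def test_clean_genomic_reads_mostly_step1(self, pair_sim):
        res = pair_sim["results"][0]
        reads = pair_sim["readsets"][0]
        anc = pair_sim["ancestor"]
        rep = [(r.chrom, r.start, r.end) for r in anc.repeats]
        cat = {c.read_id: c.category for c in res.classifications}
        n = ok = 0
        for rid in reads.ids[:4000]:
            p = reads.provenance[rid]
            if p.category != "genomic":
                continue
            # restrict to reads from unambiguous territory
            clone = pair_sim["clones"][0]
            apos = clone.to_ancestor(p.chrom, p.start)
            if any(c == p.chrom and s - 400 < apos < e + 400
                   for c, s, e in rep):
                continue
            if any(c == p.chrom and (s - 400 < apos < s + dl + 400
                                     or d - 400 < apos < d + dl + 400)
                   for c, s, _c2, d, dl in anc.duplications):
                continue
            # positions inside an inserted element project up to the
            # insert's length past the insertion point
            ledger = pair_sim["ledgers"][0]
            if any(e.type == "TE_INS" and e.chrom == p.chrom
                   and -400 < apos - e.pos < len(e.detail["seq"]) + 400
                   for e in ledger.entries):
                continue
            n += 1
            ok += cat[rid] == "ALIGNED_STEP1"
        assert n > 200
        assert ok / n >= 0.99

    def test_placement_accuracy(self, pair_sim):
        """Error-free unique-region reads align within 2 bp of their origin."""
        res = pair_sim["results"][0]
        reads = pair_sim["readsets"][0]
        clone = pair_sim["clones"][0]
        n = ok = 0
        for rec in res.records:
            if rec.step != 1:
                continue
            p = reads.provenance[rec.read_id]
            if p.category not in ("genomic", "duplicate"):
                continue
            true_anc = clone.to_ancestor(p.chrom, p.start)
            n += 1
            ok += (rec.chrom == p.chrom
                   and abs(rec.ref_start - true_anc) <= 2)
        assert n > 1000
        assert ok / n >= 0.95

    def test_spiked_categories_recovered(self, pair_sim):
        res = pair_sim["results"][0]
        reads = pair_sim["readsets"][0]
        cat = {c.read_id: c.category for c in res.classifications}
        org_ids = [rid for rid, p in reads.provenance.items()
                   if p.category == "organelle"]
        assert len(org_ids) > 50
        hit = sum(cat[r] == "CYTOPLASMIC" for r in org_ids)
        assert hit / len(org_ids) >= 0.95
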