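"""Calling gates on constructed pileups and records, plus integration
against the simulation ledger."""

import numpy as np
import pytest

from somaclone._seq import random_seq
from somaclone.covstats import RegionSet
from somaclone.evaluate import recovery_metrics
from somaclone.polycall import (INDEL, SNP, TE_INSERTION, annotate_and_rates,
                                build_pileup, call_indels, call_pair,
                                call_snps, call_te_insertions,
                                cluster_junctions, PolymorphismCall)
from somaclone.synthdata import Gene
from somaclone.tieralign import AlignmentRecord


def rec(chrom, start, seq, cigar, read_id="r", step=1, mapq=90,
        junction=None, side=None, family=None):
    from somaclone._seq import cigar_identity
    return AlignmentRecord(read_id=read_id, chrom=chrom, ref_start=start,
                           strand="+", cigar=cigar,
                           identity=cigar_identity(cigar), step=step,
                           mapq=mapq, n_candidate_loci=1, read_len=len(seq),
                           q_start=0, q_end=len(seq), seq=seq,
                           junction=junction, junction_side=side,
                           te_family=family)


@pytest.fixture()
def flat_ref(rng):
    return {"c": random_seq(rng, 2_000)}


def stack(ref, start, length, n, read_id_prefix="r", mutate=None, step=1,
          mapq=90):
    """n identical full-match reads; `mutate` = (offset, alt) applies a
    substitution at ref offset `start+offset` in every read."""
    out = []
    base = ref["c"][start:start + length]
    for i in range(n):
        seq = base
        cigar = f"{length}="
        if mutate is not None:
            off, alt = mutate
            seq = base[:off] + alt + base[off + 1:]
            cigar = f"{off}=1X{length - off - 1}="
        out.append(rec("c", start, seq, cigar, f"{read_id_prefix}{i}",
                       step=step, mapq=mapq))
    return out


ALL = RegionSet({"c": [(0, 2_000)]})


class TestCallSnps:
    def test_minor_allele_at_threshold_called(self, flat_ref):
        # clone A: 6 reference reads; clone B: 4 alt + 2 ref (MAF 1/3)
        a = build_pileup("A", stack(flat_ref, 100, 300, 6), flat_ref)
        ref_base = flat_ref["c"][250]
        alt = "T" if ref_base != "T" else "G"
        recs = (stack(flat_ref, 100, 300, 4, "alt", mutate=(150, alt))
                + stack(flat_ref, 100, 300, 2, "wt"))
        b = build_pileup("B", recs, flat_ref)
        calls = call_snps(a, b, ALL)
        assert len(calls) == 1
        assert calls[0].pos == 250
        assert calls[0].carrier == "B"

    def test_below_frequency_not_called(self, flat_ref):
        a = build_pileup("A", stack(flat_ref, 100, 300, 6), flat_ref)
        ref_base = flat_ref["c"][250]
        alt = "T" if ref_base != "T" else "G"
        recs = (stack(flat_ref, 100, 300, 1, "alt", mutate=(150, alt))
                + stack(flat_ref, 100, 300, 5, "wt"))
        b = build_pileup("B", recs, flat_ref)
        assert call_snps(a, b, ALL) == []

    def test_depth_gate(self, flat_ref):
        ref_base = flat_ref["c"][250]
        alt = "T" if ref_base != "T" else "G"
        a = build_pileup("A", stack(flat_ref, 100, 300, 5), flat_ref)  # 5x
        b = build_pileup("B", stack(flat_ref, 100, 300, 6, "m",
                                    mutate=(150, alt)), flat_ref)
        assert call_snps(a, b, ALL) == []

    def test_quality_gate(self, flat_ref):
        ref_base = flat_ref["c"][250]
        alt = "T" if ref_base != "T" else "G"
        a = build_pileup("A", stack(flat_ref, 100, 300, 6), flat_ref)
        b = build_pileup("B", stack(flat_ref, 100, 300, 6, "m",
                                    mutate=(150, alt), mapq=60), flat_ref)
        assert call_snps(a, b, ALL) == []

    def test_outside_shared_not_called(self, flat_ref):
        ref_base = flat_ref["c"][250]
        alt = "T" if ref_base != "T" else "G"
        a = build_pileup("A", stack(flat_ref, 100, 300, 6), flat_ref)
        b = build_pileup("B", stack(flat_ref, 100, 300, 6, "m",
                                    mutate=(150, alt)), flat_ref)
        assert call_snps(a, b, RegionSet({"c": [(500, 900)]})) == []

    def test_terminal_mismatches_not_evidence(self, flat_ref):
        # alt base 5 bp from the read end is inside the terminal margin
        a = build_pileup("A", stack(flat_ref, 100, 300, 6), flat_ref)
        ref_base = flat_ref["c"][105]
        alt = "T" if ref_base != "T" else "G"
        b = build_pileup("B", stack(flat_ref, 100, 300, 6, "m",
                                    mutate=(5, alt)), flat_ref)
        assert call_snps(a, b, ALL) == []


class TestCallIndels:
    def make_del_reads(self, ref, n, step=1, pos=250, dlen=3, start=100,
                       length=300):
        """Reads spanning a deletion of ref[pos:pos+dlen]."""
        out = []
        left = pos - start
        for i in range(n):
            seq = ref["c"][start:pos] + ref["c"][pos + dlen:start + length + dlen]
            cigar = f"{left}={dlen}D{length - left}="
            out.append(rec("c", start, seq, cigar, f"d{step}_{i}", step=step))
        return out

    def test_mid_read_deletion_called(self, flat_ref):
        a = build_pileup("A", self.make_del_reads(flat_ref, 3)
                         + stack(flat_ref, 100, 300, 3, "wt"), flat_ref)
        b = build_pileup("B", stack(flat_ref, 100, 300, 6, "o"), flat_ref)
        calls = call_indels(a, b, ALL)
        assert len(calls) == 1
        assert calls[0].carrier == "A"
        assert calls[0].detail.startswith("-")

    def test_step3_evidence_excluded(self, flat_ref):
        a = build_pileup("A", self.make_del_reads(flat_ref, 6, step=3),
                         flat_ref)
        b = build_pileup("B", stack(flat_ref, 100, 300, 6, "o"), flat_ref)
        assert call_indels(a, b, ALL) == []

    def test_terminal_indel_evidence_discarded(self, flat_ref):
        # deletion 5 bp from the read start: all evidence inside the margin
        a = build_pileup("A", self.make_del_reads(flat_ref, 6, pos=105),
                         flat_ref)
        b = build_pileup("B", stack(flat_ref, 100, 300, 6, "o"), flat_ref)
        assert call_indels(a, b, ALL) == []

    def test_homopolymer_flagged(self, rng):
        ref = {"c": random_seq(rng, 400) + "A" * 8 + random_seq(rng, 400)}
        pos, dlen, start, length = 403, 2, 150, 500
        reads = []
        for i in range(4):
            seq = ref["c"][start:pos] + ref["c"][pos + dlen:start + length + dlen]
            reads.append(rec("c", start, seq,
                             f"{pos - start}={dlen}D{length - (pos - start)}=",
                             f"h{i}"))
        a = build_pileup("A", reads + stack({"c": ref["c"]}, start, length, 2,
                                            "wt"), ref)
        b = build_pileup("B", stack({"c": ref["c"]}, start, length, 6, "o"),
                         ref)
        calls = call_indels(a, b, RegionSet({"c": [(0, len(ref["c"]))]}))
        assert len(calls) == 1
        assert calls[0].low_confidence


class TestCallTeInsertions:
    def make_junction(self, ref, n, pos, read_id_prefix, family="Gret1",
                      mapq=90):
        out = []
        for i in range(n):
            seq = ref["c"][pos - 200:pos]
            out.append(rec("c", pos - 200, seq, "200=",
                           f"{read_id_prefix}{i}", step=2, mapq=mapq,
                           junction=pos, side="R", family=family))
        return out

    def test_polymorphic_insertion_called(self, flat_ref):
        carrier = (self.make_junction(flat_ref, 4, 800, "j")
                   + stack(flat_ref, 700, 300, 6, "spanA"))
        other = stack(flat_ref, 700, 300, 6, "spanB")
        pa = build_pileup("A", carrier, flat_ref)
        pb = build_pileup("B", other, flat_ref)
        calls = call_te_insertions(carrier, pa, other, pb)
        assert len(calls) == 1
        assert calls[0].carrier == "A"
        assert abs(calls[0].pos - 800) <= 15
        assert calls[0].te_family == "Gret1"

    def test_ancestral_boundary_not_called(self, flat_ref):
        carrier = (self.make_junction(flat_ref, 4, 800, "ja")
                   + stack(flat_ref, 700, 300, 6, "sa"))
        other = (self.make_junction(flat_ref, 3, 803, "jb")
                 + stack(flat_ref, 700, 300, 6, "sb"))
        pa = build_pileup("A", carrier, flat_ref)
        pb = build_pileup("B", other, flat_ref)
        assert call_te_insertions(carrier, pa, other, pb) == []

    def test_other_clone_needs_coverage(self, flat_ref):
        carrier = (self.make_junction(flat_ref, 4, 800, "j")
                   + stack(flat_ref, 700, 300, 6, "spanA"))
        other = stack(flat_ref, 700, 300, 3, "spanB")  # only 3x
        pa = build_pileup("A", carrier, flat_ref)
        pb = build_pileup("B", other, flat_ref)
        assert call_te_insertions(carrier, pa, other, pb) == []

    def test_junction_fraction_gate(self, flat_ref):
        carrier = (self.make_junction(flat_ref, 1, 800, "j")
                   + stack(flat_ref, 700, 300, 12, "spanA"))
        other = stack(flat_ref, 700, 300, 6, "spanB")
        pa = build_pileup("A", carrier, flat_ref)
        pb = build_pileup("B", other, flat_ref)
        assert call_te_insertions(carrier, pa, other, pb) == []
        assert len(call_te_insertions(carrier, pa, other, pb,
                                      apply_frac=False)) == 1

    def test_cluster_radius(self, flat_ref):
        recs = (self.make_junction(flat_ref, 2, 800, "a")
                + self.make_junction(flat_ref, 2, 810, "b"))
        clusters = cluster_junctions(recs)
        assert len(clusters) == 1
        assert clusters[0].n_reads == 4


class TestRatesAndSymmetry:
    def test_rate_arithmetic(self):
        calls = [PolymorphismCall(SNP, "c", i * 100, "A", "B", "A", "x",
                                  6, 6, 90) for i in range(7)]
        rep = annotate_and_rates(calls, [], RegionSet({"c": [(0, 2_000_000)]}),
                                 ("A", "B"))
        assert rep.rates_per_mb[SNP] == pytest.approx(3.5)
        assert rep.counts[INDEL] == 0

    def test_gene_overlap(self):
        genes = [Gene("g1", "c", 100, 500, ((120, 300),))]
        calls = [PolymorphismCall(SNP, "c", 150, "A", "B", "A", "x", 6, 6, 90),
                 PolymorphismCall(SNP, "c", 700, "A", "B", "A", "x", 6, 6, 90)]
        rep = annotate_and_rates(calls, genes,
                                 RegionSet({"c": [(0, 1_000_000)]}), ("A", "B"))
        assert calls[0].in_gene and calls[0].gene_id == "g1"
        assert not calls[1].in_gene
        assert rep.in_gene_counts[SNP] == 1

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            annotate_and_rates([], [], RegionSet({}), ("A", "B"))

    def test_pair_symmetry(self, pair_sim):
        """Swapping the clone order changes labels, not sites."""
        anc = pair_sim["ancestor"]
        ra, rb = (r.records for r in pair_sim["results"])
        ab, _, _, _ = call_pair(ra, rb, anc.chromosomes, "A", "B")
        ba, _, _, _ = call_pair(rb, ra, anc.chromosomes, "B", "A")
        assert {(c.type, c.chrom, c.pos) for c in ab} \
            == {(c.type, c.chrom, c.pos) for c in ba}
        carriers_ab = {(c.chrom, c.pos): c.carrier for c in ab}
        carriers_ba = {(c.chrom, c.pos): c.carrier for c in ba}
        assert carriers_ab == carriers_ba

    def test_ledger_recovery_unit_scale(self, pair_sim):
        anc = pair_sim["ancestor"]
        calls, shared, _, _ = call_pair(
            pair_sim["results"][0].records, pair_sim["results"][1].records,
            anc.chromosomes, "A", "B")
        m = recovery_metrics(pair_sim["ledgers"], calls, shared)
        assert m[SNP].precision == 1.0 or np.isnan(m[SNP].precision)
        assert m[INDEL].precision == 1.0 or np.isnan(m[INDEL].precision)
        assert m[TE_INSERTION].recall >= 0.85
        assert m[TE_INSERTION].precision >= 0.95

    def test_no_call_outside_shared(self, pair_sim):
        anc = pair_sim["ancestor"]
        calls, shared, _, _ = call_pair(
            pair_sim["results"][0].records, pair_sim["results"][1].records,
            anc.chromosomes, "A", "B")
        for c in calls:
            if c.type == TE_INSERTION:
                assert any(shared.contains(c.chrom, p)
                           for p in range(c.pos - 15, c.pos + 16))
            else:
                assert shared.contains(c.chrom, c.pos) \
                    or shared.contains(c.chrom, c.pos + 1)

    def test_no_ssr_calls(self, pair_sim):
        """No simple-sequence-repeat mutation model, so no SSR-type calls."""
        anc = pair_sim["ancestor"]
        calls, _, _, _ = call_pair(
            pair_sim["results"][0].records, pair_sim["results"][1].records,
            anc.chromosomes, "A", "B")
        assert all(c.type in (SNP, INDEL, TE_INSERTION) for c in calls)
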