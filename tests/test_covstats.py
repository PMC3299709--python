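"""Coverage profiles, region algebra against brute-force oracles, and the
composition/correlation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from somaclone._seq import random_seq
from somaclone.covstats import (DepthProfile, RegionSet, composition_stats,
                                depth_profile, regions_at_depth,
                                sequence_composition, shared_regions,
                                window_correlations)
from somaclone.tieralign import AlignmentRecord


def rec(chrom, start, length, read_id="r", dup=False, seq=None):
    return AlignmentRecord(read_id=read_id, chrom=chrom, ref_start=start,
                           strand="+", cigar=f"{length}=", identity=1.0,
                           step=1, mapq=90, n_candidate_loci=1,
                           read_len=length, q_start=0, q_end=length,
                           seq=seq or "A" * length, is_duplicate=dup)


class TestDepthProfile:
    def test_tiling_reads_stack(self):
        ref = {"c": "A" * 2_000}
        records = [rec("c", 500, 355, f"r{i}") for i in range(6)]
        prof = depth_profile(records, ref)
        assert (prof.depth["c"][500:855] == 6).all()
        assert prof.depth["c"][499] == 0
        assert prof.depth["c"][855] == 0

    def test_zero_records(self):
        prof = depth_profile([], {"c": "A" * 100})
        assert (prof.depth["c"] == 0).all()

    def test_duplicates_counted_once(self):
        ref = {"c": "A" * 1_000}
        records = [rec("c", 0, 100, "a"), rec("c", 0, 100, "b", dup=True)]
        prof = depth_profile(records, ref)
        assert prof.depth["c"][50] == 1

    def test_conservation(self):
        ref = {"c": "A" * 5_000}
        rng = np.random.default_rng(1)
        records = [rec("c", int(rng.integers(0, 4_600)), 300, f"r{i}")
                   for i in range(50)]
        prof = depth_profile(records, ref)
        assert prof.total_aligned_bases == 50 * 300

    def test_out_of_bounds_named(self):
        with pytest.raises(ValueError, match="rbad"):
            depth_profile([rec("c", 900, 200, "rbad")], {"c": "A" * 1_000})

    def test_uniform_placement_poisson(self):
        """Depth under uniform placement follows Poisson(total/length)."""
        L, n, rl = 1_000_000, 10_000, 100
        rng = np.random.default_rng(7)
        records = [rec("c", int(s), rl, f"r{i}")
                   for i, s in enumerate(rng.integers(0, L - rl, size=n))]
        prof = depth_profile(records, {"c": "A" * L})
        # sample bases one read-length apart: no read can cover two of
        # them, so the sampled depths are independent Poisson draws
        d = prof.depth["c"][rl: L - rl: rl]
        lam = n * rl / L
        kmax = 5
        obs = np.bincount(np.minimum(d, kmax), minlength=kmax + 1)
        pk = stats.poisson.pmf(np.arange(kmax), lam)
        probs = np.append(pk, 1 - pk.sum())
        chi2, p = stats.chisquare(obs, probs * obs.sum(), ddof=0)
        assert p > 0.01


class TestRegionAlgebra:
    def test_uniform_block(self):
        prof = DepthProfile({"c": np.full(1_000, 6, dtype=np.int32)})
        rs = regions_at_depth(prof, 6)
        assert rs.regions["c"] == [(0, 1_000)]
        assert regions_at_depth(prof, 7).regions["c"] == []

    def test_nesting_and_monotonicity(self):
        rng = np.random.default_rng(3)
        prof = DepthProfile({"c": rng.poisson(4, size=5_000).astype(np.int32)})
        spans = []
        prev = None
        for k in range(1, 9):
            rs = regions_at_depth(prof, k)
            spans.append(rs.span)
            if prev is not None:
                mask_prev = prev.mask_array("c", 5_000)
                mask_now = rs.mask_array("c", 5_000)
                assert not (mask_now & ~mask_prev).any()  # nested
            prev = rs
        assert spans == sorted(spans, reverse=True)

    def test_invalid_k(self):
        prof = DepthProfile({"c": np.zeros(10, dtype=np.int32)})
        with pytest.raises(ValueError):
            regions_at_depth(prof, 0)

    def test_shared_identity_and_disjoint(self):
        a = RegionSet({"c": [(0, 100), (200, 300)]})
        assert shared_regions(a, a).regions["c"] == a.regions["c"]
        b = RegionSet({"c": [(100, 200)]})
        assert shared_regions(a, b).regions["c"] == []

    def test_shared_matches_boolean_oracle(self):
        """Interval intersection equals per-base boolean AND on random
        fixtures (commutativity included)."""
        rng = np.random.default_rng(11)
        L = 2_000
        for _ in range(100):
            def random_set():
                ivs = []
                for _ in range(rng.integers(1, 12)):
                    s = int(rng.integers(0, L - 1))
                    e = int(rng.integers(s + 1, min(L, s + 300) + 1))
                    ivs.append((s, e))
                return RegionSet({"c": ivs})
            a, b = random_set(), random_set()
            got = shared_regions(a, b)
            swapped = shared_regions(b, a)
            oracle = a.mask_array("c", L) & b.mask_array("c", L)
            assert (got.mask_array("c", L) == oracle).all()
            assert got.regions == swapped.regions
            assert got.span <= min(a.span, b.span)


class TestComposition:
    def test_hand_counts(self):
        gc, cpg, cng = sequence_composition(["GCGC"])
        assert gc == 100.0
        assert cpg == pytest.approx(100.0 / 3)

    def test_direct_count_oracle(self, rng):
        reads = [random_seq(rng, int(rng.integers(20, 80)))
                 for _ in range(10)]
        gc, cpg, cng = sequence_composition(reads)
        bases = sum(len(s) for s in reads)
        gc_o = 100 * sum(s.count("G") + s.count("C") for s in reads) / bases
        cpg_o = 100 * sum(s.count("CG") for s in reads) / (bases - 10)
        cng_o = 100 * sum(sum(1 for i in range(len(s) - 2)
                              if s[i] == "C" and s[i + 2] == "G")
                          for s in reads) / (bases - 20)
        assert gc == pytest.approx(gc_o)
        assert cpg == pytest.approx(cpg_o)
        assert cng == pytest.approx(cng_o)

    def test_reads_reflect_reference_gc(self, rng):
        ref = {"c": random_seq(rng, 60_000, gc=0.40)}
        records = []
        for i in range(800):
            s = int(rng.integers(0, 59_700))
            records.append(rec("c", s, 300, f"r{i}", seq=ref["c"][s:s + 300]))
        rep = composition_stats(records, ref, [])
        ref_gc = 100 * (ref["c"].count("G") + ref["c"].count("C")) / 60_000
        assert rep.gc_pct == pytest.approx(ref_gc, abs=0.5)

    def test_exon_overlap_fraction(self, pair_sim):
        anc = pair_sim["ancestor"]
        res = pair_sim["results"][0]
        rep = composition_stats(res.records, anc.chromosomes, anc.genes)
        # aligned reads avoid repeats, so their exon share is mildly
        # enriched relative to the genomic exon fraction
        assert 4.0 < rep.exon_pct < 15.0


class TestCorrelations:
    def test_constructed_negative(self, rng):
        """Reads placed only outside clustered repeats give negative r."""
        L = 2_000_000
        rep = RegionSet({"c": [(i, i + 50_000) for i in
                               range(0, L, 400_000)]})
        mask = rep.mask_array("c", L)
        records = []
        i = 0
        while len(records) < 3_000:
            s = int(rng.integers(0, L - 300))
            if not mask[s:s + 300].any():
                records.append(rec("c", s, 300, f"r{i}"))
                i += 1
        corr = window_correlations(records, rep, {"c": L}, window=50_000)
        assert corr.repeat_r < -0.5
        assert corr.repeat_p < 0.01

    def test_no_signal_when_uniform(self, rng):
        L = 4_000_000
        rep = RegionSet({"c": [(int(s), int(s) + 500) for s in
                               rng.integers(0, L - 500, size=2_000)]})
        records = [rec("c", int(s), 300, f"r{i}") for i, s in
                   enumerate(rng.integers(0, L - 300, size=4_000))]
        corr = window_correlations(records, rep, {"c": L}, window=20_000)
        assert corr.n_windows == 200
        assert abs(corr.repeat_r) < 0.1

    def test_window_floor(self):
        with pytest.raises(ValueError):
            window_correlations([], RegionSet({}), {"c": 100_000}, window=5_000)


_interval = st.tuples(st.integers(0, 490), st.integers(1, 200)) \
    .map(lambda t: (t[0], min(500, t[0] + t[1])))
_interval_set = st.lists(_interval, min_size=0, max_size=10)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(a=_interval_set, b=_interval_set)
def test_region_algebra_properties(a, b):
    """Intersection is commutative, idempotent and equals the per-base
    boolean AND on arbitrary interval sets."""
    ra, rb = RegionSet({"c": list(a)}), RegionSet({"c": list(b)})
    got = shared_regions(ra, rb)
    assert got.regions == shared_regions(rb, ra).regions
    assert (got.mask_array("c", 500)
            == (ra.mask_array("c", 500) & rb.mask_array("c", 500))).all()
    assert shared_regions(ra, ra).regions == ra.regions
    assert got.span <= min(ra.span, rb.span)
    for ivs in got.regions.values():  # output is sorted, disjoint, merged
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 < s2
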