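"""Pairwise clone comparison: SNP, indel and TE-insertion calling.

All calls are rule-gated rather than probabilistic: a site is callable only
inside the pair's shared >= 6x region (at least six independent reads in
*each* clone), an allele exists in a clone only if its within-clone
frequency is >= 0.3, and supporting evidence must carry an alignment
quality score above 60.  Indel evidence additionally must come from
step-1/step-2 reads and sit >= 20 bp away from the read ends (relaxed-gap
step-3 alignments and read termini are the classic sources of false
indels).  Reads composed of a unique flank plus a masked mobile-element
segment ("TE evidence" reads, placed at step 2) contribute junction
evidence: a cluster of junction reads present in one clone, against clean
spanning coverage in the other, is a TE insertion polymorphism.

Indel calls sitting in a reference homopolymer run >= 6 bp are flagged
low-confidence (pyrosequencing's characteristic artefact) but not removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import cigar_stats
from .covstats import DepthProfile, RegionSet, depth_profile
from .synthdata import Gene, RepeatLibrary
from .tieralign import AlignmentRecord

__all__ = ["Pileup", "PolymorphismCall", "build_pileup", "call_snps",
           "call_indels", "call_te_insertions", "annotate_and_rates",
           "RatesReport", "JunctionCluster", "cluster_junctions"]

SNP, INDEL, TE_INSERTION = "SNP", "INDEL", "TE_INSERTION"


@dataclass
class Pileup:
    """Sparse per-site allele evidence over a reference, for one clone."""

    clone_id: str
    reference: dict[str, str]
    depth: DepthProfile
    # (chrom, pos) -> {alt_base: [count, max_mapq, n_gated]}
    snp_ev: dict = field(default_factory=dict)
    # (chrom, pos) -> {inserted_seq: [count, max_mapq, n_gated]}
    ins_ev: dict = field(default_factory=dict)
    # (chrom, pos) -> {deleted_seq: [count, max_mapq, n_gated]}
    del_ev: dict = field(default_factory=dict)

    def depth_at(self, chrom: str, pos: int) -> int:
        d = self.depth.depth[chrom]
        if not 0 <= pos < len(d):
            return 0
        return int(d[pos])

    def ref_base(self, chrom: str, pos: int) -> str:
        return self.reference[chrom][pos]

    def allele_set(self, chrom: str, pos: int, maf: float = 0.3) -> set[str]:
        """Bases present at >= maf frequency among independent reads.

        Alternative alleles are counted from curated evidence only
        (mismatches away from read ends on otherwise-clean reads); the
        reference allele is what remains of the depth."""
        d = self.depth_at(chrom, pos)
        if d == 0:
            return set()
        ev = self.snp_ev.get((chrom, pos), {})
        alt_total = sum(v[0] for v in ev.values())
        alleles = {b for b, v in ev.items() if v[2] / d >= maf}
        if (d - alt_total) / d >= maf:
            alleles.add(self.ref_base(chrom, pos))
        return alleles


def _left_normalize(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Shift an indel allele to its leftmost equivalent placement."""
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def build_pileup(clone_id: str, records: list[AlignmentRecord],
                 reference: dict[str, str], end_margin: int = 20,
                 indel_max_step: int = 2,
                 snp_min_identity: float = 0.99,
                 min_mapq: int = 0) -> Pileup:
    """Accumulate allele evidence from step-tagged alignment records.

    Indel evidence is counted as "gated" (usable for calling) only when the
    record's step is <= ``indel_max_step`` and the indel lies >=
    ``end_margin`` bp from both ends of the aligned portion of the read.
    Substitution evidence is gated by the same terminal-distance rule and
    by requiring the supporting read to be otherwise clean (overall
    alignment identity >= ``snp_min_identity``): relaxed-gap alignments of
    junction-straddling reads, and repeat-copy reads mis-placed onto a
    lone related copy, otherwise deposit coordinated runs of false
    mismatches — exactly the artefacts the original study removed by
    eye-balling each locus.

    ``min_mapq`` drops records at or below the given mapping quality from
    the pileup altogether (evidence *and* depth).  Building the calling
    pileup at the calling quality floor makes the depth gate and the
    quality gate agree: territory covered only by ambiguous, quality-capped
    reads (the interior of near-identical repeat copies) never reaches
    callable depth instead of appearing callable and then yielding nothing."""
    if min_mapq > 0:
        records = [r for r in records if r.mapq > min_mapq]
    prof = depth_profile(records, reference)
    pile = Pileup(clone_id, reference, prof)
    for r in records:
        if r.is_duplicate:
            continue
        ref = reference[r.chrom]
        rp, qp = r.ref_start, 0
        n = 0
        L = len(r.seq)
        # cleanliness of the read apart from its indels: a read carrying a
        # genuine indel still matches everywhere else, whereas misplaced or
        # junction-straddling reads are peppered with substitutions
        m_, x_, _, _ = cigar_stats(r.cigar)
        clean = (m_ / (m_ + x_) if m_ + x_ else 0.0) >= snp_min_identity
        for ch in r.cigar:
            if ch.isdigit():
                n = n * 10 + ord(ch) - 48
                continue
            if ch == "=":
                rp += n
                qp += n
            elif ch == "X":
                for i in range(n):
                    key = (r.chrom, rp + i)
                    end_dist = min(qp + i, L - (qp + i + 1))
                    gated = clean and end_dist >= end_margin
                    ev = pile.snp_ev.setdefault(key, {})
                    slot = ev.setdefault(r.seq[qp + i], [0, 0, 0])
                    slot[0] += 1
                    if gated:
                        slot[1] = max(slot[1], r.mapq)
                        slot[2] += 1
                rp += n
                qp += n
            elif ch == "I":
                seq = r.seq[qp: qp + n]
                pos, seq = _left_normalize(ref, rp, seq)
                end_dist = min(qp, L - (qp + n))
                gated = (clean and r.step <= indel_max_step
                         and end_dist >= end_margin)
                ev = pile.ins_ev.setdefault((r.chrom, pos), {})
                slot = ev.setdefault(seq, [0, 0, 0])
                slot[0] += 1
                slot[1] = max(slot[1], r.mapq)
                slot[2] += int(gated)
                qp += n
            elif ch == "D":
                seq = ref[rp: rp + n]
                pos, seq = _left_normalize(ref, rp, seq)
                end_dist = min(qp, L - qp)
                gated = (clean and r.step <= indel_max_step
                         and end_dist >= end_margin)
                ev = pile.del_ev.setdefault((r.chrom, pos), {})
                slot = ev.setdefault(seq, [0, 0, 0])
                slot[0] += 1
                slot[1] = max(slot[1], r.mapq)
                slot[2] += int(gated)
                rp += n
            n = 0
    return pile


@dataclass
class PolymorphismCall:
    type: str
    chrom: str
    pos: int  # 0-based; +1 when written out
    clone_a: str
    clone_b: str
    carrier: str  # clone carrying the non-shared allele/insertion
    detail: str
    depth_a: int
    depth_b: int
    quality: int
    te_family: str | None = None
    in_gene: bool = False
    gene_id: str | None = None
    low_confidence: bool = False

    @property
    def site(self) -> tuple[str, str, int]:
        return (self.type, self.chrom, self.pos)


def _in_homopolymer(ref: str, pos: int, min_run: int = 6) -> bool:
    s = max(0, pos - min_run)
    e = min(len(ref), pos + min_run + 1)
    run, prev = 1, None
    for i in range(s, e):
        if ref[i] == prev:
            run += 1
            if run >= min_run and s + 1 <= pos <= i + 1:
                return True
        else:
            run, prev = 1, ref[i]
    return run >= min_run


def call_snps(pile_a: Pileup, pile_b: Pileup, shared: RegionSet,
              min_depth: int = 6, maf: float = 0.3,
              min_qual: int = 60) -> list[PolymorphismCall]:
    """SNPs between two clones inside the shared high-coverage regions.

    A site is polymorphic when the two clones' allele sets (alleles at
    within-clone frequency >= ``maf``) differ, both depths reach
    ``min_depth`` and the supporting evidence quality exceeds ``min_qual``."""
    calls = []
    sites = set(pile_a.snp_ev) | set(pile_b.snp_ev)
    for chrom, pos in sorted(sites):
        if not shared.contains(chrom, pos):
            continue
        da, db = pile_a.depth_at(chrom, pos), pile_b.depth_at(chrom, pos)
        if da < min_depth or db < min_depth:
            continue
        sa = pile_a.allele_set(chrom, pos, maf)
        sb = pile_b.allele_set(chrom, pos, maf)
        if not sa or not sb or sa == sb:
            continue
        qual = 0
        for pile in (pile_a, pile_b):
            for b, v in pile.snp_ev.get((chrom, pos), {}).items():
                qual = max(qual, v[1])
        if qual <= min_qual:
            continue
        ref = pile_a.ref_base(chrom, pos)
        carrier = pile_a.clone_id if sa - {ref} else pile_b.clone_id
        calls.append(PolymorphismCall(
            SNP, chrom, pos, pile_a.clone_id, pile_b.clone_id, carrier,
            detail=f"{ref}>{'/'.join(sorted((sa | sb) - {ref}))}"
                   f" [{pile_a.clone_id}:{''.join(sorted(sa))}"
                   f" {pile_b.clone_id}:{''.join(sorted(sb))}]",
            depth_a=da, depth_b=db, quality=qual))
    return calls


def _indel_alleles(pile: Pileup, kind: str, chrom: str, pos: int,
                   maf: float) -> dict[str, int]:
    """Indel alleles present at >= maf gated frequency; value = max mapq."""
    ev = (pile.ins_ev if kind == "ins" else pile.del_ev).get((chrom, pos), {})
    d = pile.depth_at(chrom, pos)
    if d == 0:
        return {}
    return {seq: v[1] for seq, v in ev.items() if v[2] / d >= maf}


def call_indels(pile_a: Pileup, pile_b: Pileup, shared: RegionSet,
                min_depth: int = 6, maf: float = 0.3,
                min_qual: int = 60) -> list[PolymorphismCall]:
    """Indel polymorphisms, counting only mid-read step-1/2 evidence.

    The depth/shared gates are evaluated over the two bases flanking the
    left-normalised coordinate: normalisation can shift an event one base
    left of the position where coverage is measured."""
    calls = []
    keys = (set(pile_a.ins_ev) | set(pile_b.ins_ev)
            | set(pile_a.del_ev) | set(pile_b.del_ev))
    for chrom, pos in sorted(keys):
        if not (shared.contains(chrom, pos) or shared.contains(chrom, pos + 1)):
            continue
        da = max(pile_a.depth_at(chrom, pos), pile_a.depth_at(chrom, pos + 1))
        db = max(pile_b.depth_at(chrom, pos), pile_b.depth_at(chrom, pos + 1))
        if da < min_depth or db < min_depth:
            continue
        for kind, sign in (("ins", "+"), ("del", "-")):
            aa = _indel_alleles(pile_a, kind, chrom, pos, maf)
            ab = _indel_alleles(pile_b, kind, chrom, pos, maf)
            for seq in set(aa) ^ set(ab):
                qual = max(aa.get(seq, 0), ab.get(seq, 0))
                if qual <= min_qual:
                    continue
                carrier = pile_a.clone_id if seq in aa else pile_b.clone_id
                ref = pile_a.reference[chrom]
                calls.append(PolymorphismCall(
                    INDEL, chrom, pos, pile_a.clone_id, pile_b.clone_id,
                    carrier, detail=f"{sign}{seq}", depth_a=da, depth_b=db,
                    quality=qual,
                    low_confidence=_in_homopolymer(ref, pos)))
    return calls


# ---------------------------------------------------------------------------
# TE insertions
# ---------------------------------------------------------------------------

@dataclass
class JunctionCluster:
    chrom: str
    pos: int  # median junction coordinate
    n_reads: int
    family: str
    max_mapq: int
    positions: list[int]


def cluster_junctions(records: list[AlignmentRecord],
                      radius: int = 15) -> list[JunctionCluster]:
    """Group step-2 junction evidence into candidate insertion sites."""
    ev = [(r.chrom, r.junction, r.te_family or "?", r.mapq)
          for r in records
          if r.junction is not None and not r.is_duplicate]
    ev.sort(key=lambda t: (t[0], t[1]))
    clusters: list[JunctionCluster] = []
    cur: list[tuple[str, int, str, int]] = []
    for item in ev:
        if cur and (item[0] != cur[-1][0] or item[1] - cur[-1][1] > radius):
            clusters.append(_finish_cluster(cur))
            cur = []
        cur.append(item)
    if cur:
        clusters.append(_finish_cluster(cur))
    return clusters


def _finish_cluster(items) -> JunctionCluster:
    pos = sorted(t[1] for t in items)
    fams: dict[str, int] = {}
    for t in items:
        fams[t[2]] = fams.get(t[2], 0) + 1
    fam = max(fams, key=fams.get)
    return JunctionCluster(items[0][0], pos[len(pos) // 2], len(items), fam,
                           max(t[3] for t in items), pos)


def _span_depth(pile: Pileup, chrom: str, pos: int) -> int:
    d = pile.depth.depth[chrom]
    lo = max(pos - 1, 0)
    hi = min(pos, len(d) - 1)
    return int(max(d[lo], d[hi]))


def _interior_depth(records: list[AlignmentRecord],
                    reference: dict[str, str], margin: int = 16
                    ) -> dict[str, np.ndarray]:
    """Depth counting only read interiors (``margin`` bp trimmed per end).

    A read whose alignment merely *ends* at a position does not span it;
    interior depth distinguishes true continuous coverage from stacks of
    alignments that all break at the same boundary."""
    diffs = {c: np.zeros(len(s) + 1, dtype=np.int32)
             for c, s in reference.items()}
    for r in records:
        if r.is_duplicate:
            continue
        s = r.ref_start + margin
        e = r.ref_end - margin
        if e > s:
            diffs[r.chrom][s] += 1
            diffs[r.chrom][e] -= 1
    return {c: np.cumsum(d[:-1]).astype(np.int32) for c, d in diffs.items()}


def call_te_insertions(records_a: list[AlignmentRecord], pile_a: Pileup,
                       records_b: list[AlignmentRecord], pile_b: Pileup,
                       library: RepeatLibrary | None = None,
                       radius: int = 15, min_depth: int = 6,
                       junction_frac: float = 0.3, apply_frac: bool = True,
                       min_qual: int = 60,
                       shared: RegionSet | None = None) -> list[PolymorphismCall]:
    """TE insertion polymorphisms from masked-read junction evidence.

    A cluster of junction reads in one clone is emitted as an insertion
    when (i) it accounts for >= ``junction_frac`` of that clone's
    site-spanning independent reads, (ii) the other clone covers the site
    *continuously* — >= ``min_depth`` reads whose alignments pass through
    the site interior, not merely end there — with no junction reads of
    its own within ``radius``, and (iii) the best junction-read alignment
    quality exceeds ``min_qual``.  Sites where both clones' alignments
    break are ancestral element boundaries, not polymorphisms.

    When ``shared`` is given, a site is only emitted if the shared
    high-coverage territory comes within ``radius`` of the cluster
    position: coverage dips by construction at an insertion junction, so
    the gate is applied at cluster rather than single-base resolution."""
    del library  # family already attached to the junction evidence
    clus_a = cluster_junctions(records_a, radius)
    clus_b = cluster_junctions(records_b, radius)
    interior_a = _interior_depth(records_a, pile_a.reference)
    interior_b = _interior_depth(records_b, pile_b.reference)
    calls = []
    for carrier_clusters, other_clusters, carrier_pile, other_pile, other_int in (
            (clus_a, clus_b, pile_a, pile_b, interior_b),
            (clus_b, clus_a, pile_b, pile_a, interior_a)):
        for cl in carrier_clusters:
            if cl.max_mapq <= min_qual:
                continue
            if shared is not None and not any(
                    shared.contains(cl.chrom, p)
                    for p in range(cl.pos - radius, cl.pos + radius + 1)):
                continue
            span_c = _span_depth(carrier_pile, cl.chrom, cl.pos)
            d_int = other_int[cl.chrom]
            span_o = int(d_int[min(max(cl.pos, 0), len(d_int) - 1)])
            if span_c < min_depth or span_o < min_depth:
                continue
            if apply_frac and cl.n_reads / max(span_c, cl.n_reads) < junction_frac:
                continue
            if any(o.chrom == cl.chrom and abs(o.pos - cl.pos) <= 2 * radius
                   for o in other_clusters):
                continue
            calls.append(PolymorphismCall(
                TE_INSERTION, cl.chrom, cl.pos, pile_a.clone_id,
                pile_b.clone_id, carrier_pile.clone_id,
                detail=f"{cl.family} junction x{cl.n_reads}",
                depth_a=_span_depth(pile_a, cl.chrom, cl.pos),
                depth_b=_span_depth(pile_b, cl.chrom, cl.pos),
                quality=cl.max_mapq, te_family=cl.family))
    calls.sort(key=lambda c: (c.chrom, c.pos))
    # flank-trim jitter can split one insertion into two nearby clusters;
    # collapse same-carrier same-family calls within 2*radius
    merged: list[PolymorphismCall] = []
    for c in calls:
        if (merged and merged[-1].chrom == c.chrom
                and merged[-1].carrier == c.carrier
                and merged[-1].te_family == c.te_family
                and c.pos - merged[-1].pos <= 2 * radius):
            continue
        merged.append(c)
    return merged


def call_pair(records_a: list[AlignmentRecord], records_b: list[AlignmentRecord],
              reference: dict[str, str], clone_a: str, clone_b: str,
              min_depth: int = 6, maf: float = 0.3, min_qual: int = 60,
              te_radius: int = 15
              ) -> tuple[list[PolymorphismCall], RegionSet, Pileup, Pileup]:
    """Full pairwise comparison: pileups, shared territory, all three callers.

    Pileups (and hence the shared >= 6x territory) are built from
    quality-eligible reads only, so the depth and quality gates describe
    the same territory."""
    from .covstats import regions_at_depth, shared_regions
    pile_a = build_pileup(clone_a, records_a, reference, min_mapq=min_qual)
    pile_b = build_pileup(clone_b, records_b, reference, min_mapq=min_qual)
    shared = shared_regions(regions_at_depth(pile_a.depth, min_depth),
                            regions_at_depth(pile_b.depth, min_depth))
    calls = call_snps(pile_a, pile_b, shared, min_depth, maf, min_qual)
    calls += call_indels(pile_a, pile_b, shared, min_depth, maf, min_qual)
    calls += call_te_insertions(records_a, pile_a, records_b, pile_b,
                                radius=te_radius, min_depth=min_depth,
                                junction_frac=maf, min_qual=min_qual,
                                shared=shared)
    return calls, shared, pile_a, pile_b


# ---------------------------------------------------------------------------
# Annotation and rates
# ---------------------------------------------------------------------------

@dataclass
class RatesReport:
    pair: tuple[str, str]
    shared_mb: float
    counts: dict[str, int]
    rates_per_mb: dict[str, float]
    in_gene_counts: dict[str, int]
    in_gene_rates_per_mb: dict[str, float]
    site_map: list[tuple[str, int, str, str]]  # chrom, pos1, type, carrier

    @property
    def total_sites(self) -> int:
        return sum(self.counts.values())


def annotate_and_rates(calls: list[PolymorphismCall], genes: list[Gene],
                       shared: RegionSet,
                       pair: tuple[str, str]) -> RatesReport:
    """Attach gene overlap to calls and compute per-Mb rates."""
    mb = shared.span / 1e6
    if mb <= 0:
        raise ValueError("shared region span must be positive")
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.start)
    starts = {c: np.array([g.start for g in gl]) for c, gl in by_chrom.items()}

    counts = {SNP: 0, INDEL: 0, TE_INSERTION: 0}
    gene_counts = {SNP: 0, INDEL: 0, TE_INSERTION: 0}
    site_map = []
    for c in calls:
        counts[c.type] = counts.get(c.type, 0) + 1
        gl = by_chrom.get(c.chrom, [])
        if gl is not None and len(gl):
            i = int(np.searchsorted(starts[c.chrom], c.pos, side="right")) - 1
            for g in gl[max(i - 1, 0): i + 1]:
                if g.start <= c.pos < g.end:
                    c.in_gene, c.gene_id = True, g.gene_id
                    gene_counts[c.type] = gene_counts.get(c.type, 0) + 1
                    break
        site_map.append((c.chrom, c.pos + 1, c.type, c.carrier))
    return RatesReport(
        pair=pair, shared_mb=mb, counts=counts,
        rates_per_mb={k: v / mb for k, v in counts.items()},
        in_gene_counts=gene_counts,
        in_gene_rates_per_mb={k: v / mb for k, v in gene_counts.items()},
        site_map=site_map)
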