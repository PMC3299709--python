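"""Depth profiles, coverage-tier regions and composition/correlation reports.

Coverage is counted in *independent* reads: exact duplicates (same sequence
placed at the same position, the signature of emulsion-PCR artefacts) are
collapsed before counting.  Polymorphism calling is restricted to regions
where both clones of a pair reach at least 6 independent reads per base, so
:func:`regions_at_depth` / :func:`shared_regions` are the gatekeepers of the
whole comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import cigar_ops
from .synthdata import AncestralGenome, Gene
from .tieralign import AlignmentRecord

__all__ = ["DepthProfile", "RegionSet", "depth_profile", "regions_at_depth",
           "shared_regions", "intersect_many", "composition_stats",
           "window_correlations", "CompositionReport", "CorrelationReport"]


@dataclass
class DepthProfile:
    """Per-base counts of independent aligned reads, one array per chromosome."""

    depth: dict[str, np.ndarray]

    @property
    def total_aligned_bases(self) -> int:
        return int(sum(int(d.sum()) for d in self.depth.values()))

    def covered_bp(self, k: int = 1) -> int:
        return int(sum(int((d >= k).sum()) for d in self.depth.values()))


@dataclass
class RegionSet:
    """Sorted, disjoint, merged intervals per chromosome (0-based half-open)."""

    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, ivs in self.regions.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if e <= s:
                    continue
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self.regions[chrom] = merged

    @property
    def span(self) -> int:
        return sum(e - s for ivs in self.regions.values() for s, e in ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.regions.get(chrom)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def mask_array(self, chrom: str, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=bool)
        for s, e in self.regions.get(chrom, []):
            out[s:e] = True
        return out


def depth_profile(records: list[AlignmentRecord],
                  reference: dict[str, str]) -> DepthProfile:
    """Per-base independent-read depth from alignment records.

    Records flagged as duplicates (identical sequence and placement) are
    counted once; a record extending past its chromosome end raises."""
    diffs = {c: np.zeros(len(s) + 1, dtype=np.int32)
             for c, s in reference.items()}
    for r in records:
        if r.is_duplicate:
            continue
        if r.chrom not in diffs:
            raise ValueError(f"record {r.read_id}: unknown chromosome {r.chrom}")
        end = r.ref_end
        if end > len(reference[r.chrom]):
            raise ValueError(
                f"record {r.read_id} extends past end of {r.chrom} "
                f"({end} > {len(reference[r.chrom])})")
        diffs[r.chrom][r.ref_start] += 1
        diffs[r.chrom][end] -= 1
    return DepthProfile({c: np.cumsum(d[:-1]).astype(np.int32)
                         for c, d in diffs.items()})


def regions_at_depth(profile: DepthProfile, k: int) -> RegionSet:
    """Maximal runs with depth >= k.  Nested: span(k+1) is inside span(k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, d in profile.depth.items():
        above = d >= k
        if not above.any():
            out[chrom] = []
            continue
        edges = np.diff(above.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(d))
        out[chrom] = list(zip(map(int, starts), map(int, ends)))
    return RegionSet(out)


def shared_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Interval intersection of two region sets (commutative)."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in set(a.regions) | set(b.regions):
        ia, ib = a.regions.get(chrom, []), b.regions.get(chrom, [])
        res, i, j = [], 0, 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if s < e:
                res.append((s, e))
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
        out[chrom] = res
    return RegionSet(out)


def intersect_many(sets: list[RegionSet]) -> RegionSet:
    """n-way intersection (all samples must cover a base)."""
    if not sets:
        return RegionSet({})
    acc = sets[0]
    for s in sets[1:]:
        acc = shared_regions(acc, s)
    return acc


# ---------------------------------------------------------------------------
# Composition and correlation reports
# ---------------------------------------------------------------------------

@dataclass
class CompositionReport:
    """GC/CpG/CnG and exon content of the aligned read sequences (percent)."""

    gc_pct: float
    cpg_pct: float
    cng_pct: float
    exon_pct: float
    n_reads: int
    n_bases: int

    def rows(self):
        yield ("% GC in aligned sequences", round(self.gc_pct, 1))
        yield ("% CpG in aligned sequences", round(self.cpg_pct, 1))
        yield ("% CnG in aligned sequences", round(self.cng_pct, 1))
        yield ("% Exons", round(self.exon_pct, 1))


def sequence_composition(seqs: list[str]) -> tuple[float, float, float]:
    """(GC, CpG, CnG) percentages over a set of sequences.

    CpG counts "CG" dinucleotides over all dinucleotide positions, CnG
    counts "C?G" trinucleotides over all trinucleotide positions."""
    bases = sum(len(s) for s in seqs)
    n = len(seqs)
    gc = sum(s.count("G") + s.count("C") for s in seqs)
    cpg = sum(s.count("CG") for s in seqs)
    cng = 0
    for s in seqs:
        b = np.frombuffer(s.encode(), dtype=np.uint8)
        if len(b) >= 3:
            cng += int(np.count_nonzero((b[:-2] == ord("C")) & (b[2:] == ord("G"))))
    dinuc = max(bases - n, 1)
    trinuc = max(bases - 2 * n, 1)
    return (100.0 * gc / max(bases, 1), 100.0 * cpg / dinuc, 100.0 * cng / trinuc)


def _exon_mask(genes: list[Gene], reference: dict[str, str]) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(len(s), dtype=bool) for c, s in reference.items()}
    for g in genes:
        for s, e in g.exons:
            masks[g.chrom][s:e] = True
    return masks


def composition_stats(records: list[AlignmentRecord], reference: dict[str, str],
                      genes: list[Gene]) -> CompositionReport:
    """Composition of aligned reads and their exon overlap.

    Exon content is the fraction of aligned read bases that fall inside
    annotated exon intervals (interval arithmetic on the alignments; the
    identity condition is inherited from alignment acceptance itself)."""
    seqs = [r.seq for r in records if not r.is_duplicate]
    gc, cpg, cng = sequence_composition(seqs)
    emask = _exon_mask(genes, reference)
    exon_bases = 0
    total = 0
    for r in records:
        if r.is_duplicate:
            continue
        span = r.ref_end - r.ref_start
        total += span
        exon_bases += int(emask[r.chrom][r.ref_start:r.ref_end].sum())
    return CompositionReport(gc, cpg, cng,
                             100.0 * exon_bases / max(total, 1),
                             len(seqs), sum(len(s) for s in seqs))


def reference_composition(genome: AncestralGenome) -> CompositionReport:
    """The same statistics computed over the reference itself."""
    seqs = list(genome.chromosomes.values())
    gc, cpg, cng = sequence_composition(seqs)
    return CompositionReport(gc, cpg, cng, 100.0 * genome.exon_fraction(),
                             len(seqs), genome.total_len())


@dataclass
class CorrelationReport:
    """Read-placement structure statistics.

    ``repeat_r``/``repeat_p``: Pearson correlation between per-window
    aligned-read counts and per-window repeat-annotated bases (expected
    strongly negative when repeat-dense regions exclude unique alignment).
    ``length_r2``: coefficient of determination between per-chromosome
    aligned bases and chromosome length (expected high when reads sample
    chromosomes proportionally)."""

    repeat_r: float
    repeat_p: float
    length_r2: float
    window: int
    n_windows: int


def window_correlations(records: list[AlignmentRecord],
                        repeat_regions: RegionSet,
                        chrom_lengths: dict[str, int],
                        window: int = 100_000) -> CorrelationReport:
    if window < 10_000:
        raise ValueError("window must be >= 10 kb")
    counts: list[float] = []
    repeat_bp: list[float] = []
    per_chrom_bases = {c: 0 for c in chrom_lengths}
    per_chrom_counts: dict[str, np.ndarray] = {}
    for c, L in chrom_lengths.items():
        per_chrom_counts[c] = np.zeros(max(1, int(np.ceil(L / window))), dtype=float)
    for r in records:
        if r.is_duplicate:
            continue
        per_chrom_bases[r.chrom] += r.ref_end - r.ref_start
        mid = (r.ref_start + r.ref_end) // 2
        per_chrom_counts[r.chrom][min(mid // window,
                                      len(per_chrom_counts[r.chrom]) - 1)] += 1
    for c, L in chrom_lengths.items():
        rep = repeat_regions.mask_array(c, L)
        nb = len(per_chrom_counts[c])
        for w in range(nb):
            counts.append(per_chrom_counts[c][w])
            repeat_bp.append(float(rep[w * window: min((w + 1) * window, L)].sum()))
    counts_a, rep_a = np.asarray(counts), np.asarray(repeat_bp)
    if len(counts_a) >= 3 and counts_a.std() > 0 and rep_a.std() > 0:
        r, p = stats.pearsonr(counts_a, rep_a)
    else:
        r, p = float("nan"), float("nan")
    lens = np.array([chrom_lengths[c] for c in chrom_lengths], dtype=float)
    bases = np.array([per_chrom_bases[c] for c in chrom_lengths], dtype=float)
    if len(lens) >= 3 and lens.std() > 0:
        lr = stats.linregress(lens, bases)
        r2 = float(lr.rvalue ** 2)
    else:
        r2 = float("nan")
    return CorrelationReport(float(r), float(p), r2, window, len(counts_a))
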