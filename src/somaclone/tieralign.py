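"""Three-step tiered read alignment with full read classification.

Every read that passes the length/quality floor (>= 100 bp, mean quality
>= Q20) is tried against the reference in three successively more permissive
modes:

* ``STRICT``  — seed-and-extend (13-mer seeds sampled every 24 bp of the
  read against a dense reference index) on both strands, accepted only at
  a single locus with >= 95% alignment identity;
* ``MASKED``  — the read is repeat-masked; if >= 150 contiguous unmasked
  bases remain, that unique flank is aligned under STRICT rules (this is the
  step that places reads spanning a repeat/unique junction);
* ``RELAXED`` — gap-tolerant alignment with the gap penalty at its minimum
  (unit-cost edits), accepted at >= 90% identity at a single locus.

Reads rejected by all three steps are classified, in priority order, as
LOW_QUALITY, REPEAT (>= 90% of bases repeat-masked), PARALOG (equally good
hits at more than one locus), CYTOPLASMIC (>= 90% identity to an organelle
reference), CONTAMINANT (>= 90% identity to a foreign-organism reference) or
UNKNOWN.  Aligned and unaligned categories partition the read set, mirroring
a run-summary table of percentages.

Mapping quality follows a phred-style 0-90 scale driven by the score margin
between the best and second-best locus: ``Q = min(90, round(90 * (best -
second) / read_length))``, with 90 for a hit with no competing locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from skbio import DNA
from skbio.alignment import pair_align

from ._seq import (KmerIndex, cigar_identity, cigar_ops, kmer_codes_at,
                   revcomp)
from .repeatmask import (MOSTLY_UNIQUE, OTHER, REPEAT_READ, TE_EVIDENCE,
                         Masker, MaskResult, masked_composition)
from .synthdata import ReadSet, RepeatLibrary

__all__ = [
    "AlignmentRecord", "ReadClassification", "Rejection", "TieredAligner",
    "Table1Summary", "align_single_read", "mapq_score", "run_tiered_alignment",
    "classify_unaligned",
]

STRICT, MASKED, RELAXED = "STRICT", "MASKED", "RELAXED"

# rejection reasons
MULTI_LOCUS = "MULTI_LOCUS"
NO_HIT = "NO_HIT"
TOO_MASKED = "TOO_MASKED"

# unaligned categories (aligned reads are ALIGNED_STEP<n>)
LOW_QUALITY = "LOW_QUALITY"
REPEAT = "REPEAT"
PARALOG = "PARALOG"
CYTOPLASMIC = "CYTOPLASMIC"
CONTAMINANT = "CONTAMINANT"
UNKNOWN = "UNKNOWN"


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    ref_start: int  # 0-based on the reference chromosome
    strand: str
    cigar: str  # extended cigar over the *aligned portion* of the read
    identity: float
    step: int  # 1=STRICT, 2=MASKED, 3=RELAXED
    mapq: int
    n_candidate_loci: int
    read_len: int
    # portion of the read that was aligned (read coordinates, fwd orientation)
    q_start: int = 0
    q_end: int = 0
    # step-2 metadata: masked interval on the read and the best family hit
    masked_bases: int = 0
    te_family: str | None = None
    # reference coordinate of the unique/masked junction and its side
    junction: int | None = None
    junction_side: str | None = None  # 'L': TE is left of flank, 'R': right
    seq: str = ""  # read sequence (fwd orientation as aligned)
    is_duplicate: bool = False

    @property
    def ref_end(self) -> int:
        span = sum(n for n, op in cigar_ops(self.cigar) if op in "=XD")
        return self.ref_start + span


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # MULTI_LOCUS | NO_HIT | TOO_MASKED | LOW_QUALITY


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    category: str


@dataclass
class Table1Summary:
    """Percentages of reads per alignment step / unaligned category."""

    n_reads: int
    counts: dict[str, int]

    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n_reads for k, v in self.counts.items()}

    def aligned_pct(self) -> float:
        return sum(p for k, p in self.percentages().items()
                   if k.startswith("ALIGNED"))

    def unaligned_pct(self) -> float:
        return 100.0 - self.aligned_pct()


def mapq_score(best_score: float, second_score: float | None,
               read_len: int) -> int:
    """Phred-style mapping quality on a 0-90 scale.

    ``best_score``/``second_score`` are alignment scores in base units
    (matches minus penalties); a read with no second candidate locus gets
    the cap of 90.
    """
    if second_score is None:
        return 90
    if best_score < second_score:
        raise ValueError("best_score must be >= second_score")
    return min(90, int(round(90.0 * (best_score - second_score) / read_len)))


class TieredAligner:
    """Seed-and-extend aligner over one reference genome."""

    def __init__(self, reference: dict[str, str], library: RepeatLibrary | None,
                 k: int = 13, step: int = 1, seed_spacing: int = 24,
                 strict_identity: float = 0.95, relaxed_identity: float = 0.90,
                 margin_frac: float = 0.07, min_flank: int = 150,
                 max_candidates: int = 6, max_loci: int = 24,
                 masker: Masker | None = None):
        if not reference or all(len(s) == 0 for s in reference.values()):
            raise ValueError("reference is empty")
        self.reference = reference
        self.index = KmerIndex(reference, k=k, step=step)
        self.k = k
        self.seed_spacing = seed_spacing
        self.strict_identity = strict_identity
        self.relaxed_identity = relaxed_identity
        self.margin_frac = margin_frac
        self.min_flank = min_flank
        self.max_candidates = max_candidates
        self.max_loci = max_loci
        self.masker = masker or (Masker(library) if library and len(library) else None)
        self._ref_b = self.index.seq  # concatenated reference
        # the strict and relaxed tiers search identical loci for the same
        # read; memoise the last search so the relaxed retry is free
        self._memo_seq: str | None = None
        self._memo_hit = None

    # ------------------------------------------------------------------
    def _candidate_diags(self, seq: str
                         ) -> tuple[list[tuple[int, int]], int, bool]:
        """Diagonal clusters (votes, global_diag) for one strand.

        Returns the clusters sorted by decreasing votes, the number of
        clusters found, and a repetitiveness flag: true when most seeds
        were capped (the read lives inside a high-copy cohort) or when
        many distinct loci collect multiple seed votes."""
        L = len(seq)
        offs = np.arange(0, max(L - self.k, 0) + 1, self.seed_spacing, dtype=np.int64)
        if len(offs) == 0:
            return [], 0, False
        codes = kmer_codes_at(seq, self.k, offs)
        gpos, qoff, n_capped = self.index.lookup(codes, offs,
                                                 max_hits_per_seed=96)
        capped = n_capped >= max(2, len(offs) // 2)
        if len(gpos) == 0:
            return [], 0, capped
        diag = np.sort(gpos - qoff)
        # cluster diagonals closer than the index step + indel slack
        brk = np.nonzero(np.diff(diag) > self.index.step + 12)[0] + 1
        starts = np.concatenate(([0], brk))
        ends = np.concatenate((brk, [len(diag)]))
        votes = ends - starts
        n_clusters = len(starts)
        n_strong = int((votes >= 2).sum())
        if capped or n_strong > self.max_loci:
            return [], n_clusters, True
        order = np.argsort(-votes, kind="stable")
        clusters = [(int(votes[i]), int(diag[starts[i]])) for i in order]
        return clusters, n_clusters, False

    def _verify(self, seq: str, gdiag: int):
        """Edlib alignment of the read against the window at a diagonal.

        Returns (score, window_start, window_end); score = read_len - 2*dist
        so that one substitution costs two match units."""
        L = len(seq)
        ws = max(0, gdiag - 40)
        we = min(len(self._ref_b), gdiag + L + 40)
        if we - ws < min(L // 2, 50):
            return None
        res = edlib.align(seq, self._ref_b[ws:we], mode="HW", task="distance")
        if res["editDistance"] < 0:
            return None
        return (L - 2 * res["editDistance"], ws, we)

    def _best_locus(self, seq: str):
        """Best and runner-up locus over both strands.

        Candidate diagonal clusters closer than half a read length on the
        same strand are treated as one locus (their verification windows
        overlap), so the runner-up really is a distinct genomic placement.

        Returns (strand, score, second_score, window_start, window_end,
        n_candidates) or None if nothing seeds."""
        if seq == self._memo_seq:
            return self._memo_hit
        cands = []
        n_loci = 0
        L = len(seq)
        repetitive = False
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            clusters, n, rep = self._candidate_diags(s)
            n_loci += n
            repetitive = repetitive or rep
            for votes, gdiag in clusters[: self.max_candidates]:
                cands.append((votes, strand, gdiag))
        if repetitive:
            self._memo_seq, self._memo_hit = seq, "REPETITIVE"
            return "REPETITIVE"
        if not cands:
            self._memo_seq, self._memo_hit = seq, None
            return None
        cands.sort(reverse=True)
        distinct = []
        for votes, strand, gdiag in cands:
            if any(st == strand and abs(gd - gdiag) < max(60, L // 2)
                   for _, st, gd in distinct):
                continue
            distinct.append((votes, strand, gdiag))
            if len(distinct) >= 2 * self.max_candidates:
                break
        scored = []
        rc = revcomp(seq)
        for k, (votes, strand, gdiag) in enumerate(distinct):
            s = seq if strand == "+" else rc
            v = self._verify(s, gdiag)
            if v is not None:
                scored.append((v[0], strand, gdiag, v[1], v[2]))
            # once several placements tie within the margin the read is
            # multi-locus whatever the rest scores; stop burning alignments
            if k >= 3 and len(scored) >= 2:
                sc = sorted((t[0] for t in scored), reverse=True)
                if sc[1] >= sc[0] - self.margin_frac * L:
                    break
        if not scored:
            self._memo_seq, self._memo_hit = seq, None
            return None
        scored.sort(key=lambda t: -t[0])
        best = scored[0]
        second = scored[1][0] if len(scored) > 1 else None
        hit = (best[1], best[0], second, best[3], best[4], n_loci)
        self._memo_seq, self._memo_hit = seq, hit
        return hit

    # ------------------------------------------------------------------
    def _attempt(self, read_id: str, seq: str, mode: str,
                 min_identity: float) -> AlignmentRecord | Rejection:
        L = len(seq)
        hit = self._best_locus(seq)
        if hit is None:
            return Rejection(read_id, NO_HIT)
        if hit == "REPETITIVE":
            return Rejection(read_id, MULTI_LOCUS)
        strand, score, second, ws, we, n_loci = hit
        # the best candidate must itself be a plausible placement before
        # ambiguity is even considered: two equally bad chance hits are a
        # non-alignment, not a paralog
        est_identity = (L + score) / (2 * L)  # exact for gapless placements
        if est_identity < min_identity - 0.02:
            return Rejection(read_id, NO_HIT)
        # unique-locus requirement: runner-up must trail by the margin
        if second is not None and second >= score - self.margin_frac * L:
            return Rejection(read_id, MULTI_LOCUS)
        s = seq if strand == "+" else revcomp(seq)
        window = self._ref_b[ws:we]
        if score == L:  # perfect hit: no need for a traceback
            loc0 = window.find(s)
            cigar = f"{L}="
        else:
            path = edlib.align(s, window, mode="HW", task="path")
            cigar = path["cigar"]
            loc0, loc1 = path["locations"][0]
            n_indel_ops = sum(1 for _, op in cigar_ops(cigar) if op in "ID")
            if n_indel_ops >= 2:
                # edlib's unit-cost paths scatter a multi-base indel into
                # co-optimal fragments; an affine-gap realignment restores
                # the contiguous (canonical) gap evidence extraction expects
                cigar = _affine_cigar(s, window[loc0: loc1 + 1])
        ident = cigar_identity(cigar)
        if ident < min_identity:
            return Rejection(read_id, NO_HIT)
        gstart = ws + loc0
        chrom, local = self.index.locate(gstart)
        mapq = mapq_score(score, second, L)
        return AlignmentRecord(
            read_id=read_id, chrom=chrom, ref_start=local, strand=strand,
            cigar=cigar, identity=ident, step={STRICT: 1, MASKED: 2, RELAXED: 3}[mode],
            mapq=mapq, n_candidate_loci=1, read_len=L, q_start=0, q_end=L,
            seq=s)

    def align_single_read(self, read_id: str, seq: str, mode: str
                          ) -> AlignmentRecord | Rejection:
        """Align one read in the given mode; see the module docstring."""
        if mode == STRICT:
            return self._attempt(read_id, seq, mode, self.strict_identity)
        if mode == RELAXED:
            return self._attempt(read_id, seq, mode, self.relaxed_identity)
        if mode != MASKED:
            raise ValueError(f"unknown mode {mode!r}")
        if self.masker is None:
            return Rejection(read_id, NO_HIT)
        mask = self.masker.mask(seq)
        return self._masked_attempt(read_id, seq, mask)

    def _masked_attempt(self, read_id: str, seq: str, mask: MaskResult
                        ) -> AlignmentRecord | Rejection:
        """Align the longest unmasked flank; record the junction point."""
        if not mask.intervals:
            return Rejection(read_id, NO_HIT)  # nothing masked: STRICT already failed
        # longest unmasked run
        runs, prev = [], 0
        for s, e in mask.intervals:
            if s > prev:
                runs.append((prev, s))
            prev = e
        if prev < len(seq):
            runs.append((prev, len(seq)))
        if not runs:
            return Rejection(read_id, TOO_MASKED)
        fs, fe = max(runs, key=lambda r: r[1] - r[0])
        if fe - fs < self.min_flank:
            return Rejection(read_id, TOO_MASKED)
        flank = seq[fs:fe]
        rec = self._attempt(read_id, flank, MASKED, self.strict_identity)
        if isinstance(rec, Rejection):
            return rec
        # junction: reference coordinate where the masked segment abuts the
        # aligned flank.  'L' = element on the left of the flank in reference
        # orientation, 'R' = on the right.
        left_masked = fs > 0
        right_masked = fe < len(seq)
        side = None
        if rec.strand == "+":
            if right_masked:
                side, jpos = "R", rec.ref_end
            elif left_masked:
                side, jpos = "L", rec.ref_start
        else:
            if right_masked:
                side, jpos = "L", rec.ref_start
            elif left_masked:
                side, jpos = "R", rec.ref_end
        rec.q_start, rec.q_end = fs, fe
        rec.read_len = len(seq)
        rec.masked_bases = mask.n_masked
        rec.te_family = mask.best_family
        if side is not None:
            rec.junction = jpos
            rec.junction_side = side
        return rec


def _affine_cigar(query: str, target: str) -> str:
    """Extended =/X/I/D cigar (SAM query-first convention) of an affine-gap
    global alignment of two sequences."""
    res = pair_align(DNA(query), DNA(target), mode="global",
                     sub_score=(1.0, -2.0), gap_cost=(4.0, 1.0),
                     free_ends=False)
    aq, at = res.paths[0].to_aligned((DNA(query), DNA(target)))
    parts: list[str] = []
    n, cur = 0, ""
    for cq, ct in zip(aq, at):
        if cq == "-":
            op = "D"
        elif ct == "-":
            op = "I"
        elif cq == ct:
            op = "="
        else:
            op = "X"
        if op == cur:
            n += 1
        else:
            if cur:
                parts.append(f"{n}{cur}")
            cur, n = op, 1
    if cur:
        parts.append(f"{n}{cur}")
    return "".join(parts)


@dataclass
class TieredResult:
    records: list[AlignmentRecord]
    classifications: list[ReadClassification]
    summary: Table1Summary
    masks: dict[str, MaskResult] = field(default_factory=dict)


def _mean_quality(qual: str) -> float:
    b = np.frombuffer(qual.encode(), dtype=np.uint8)
    return float(b.mean()) - 33.0


def _identity_to_refs(seq: str, refs: dict[str, str]) -> float:
    best = 0.0
    for rseq in refs.values():
        res = edlib.align(seq, rseq, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = max(best, 1.0 - res["editDistance"] / len(seq))
    return best


class _ForeignScreen:
    """k-mer prefilter + edlib identity against organelle/contaminant refs."""

    def __init__(self, refs: dict[str, str], k: int = 13):
        self.refs = refs
        self.index = KmerIndex(refs, k=k, step=1) if refs else None
        self.k = k

    def identity(self, seq: str) -> float:
        if not self.refs:
            return 0.0
        offs = np.arange(0, max(len(seq) - self.k, 0) + 1, 31, dtype=np.int64)
        if len(offs):
            for s in (seq, revcomp(seq)):
                if self.index.n_hits(kmer_codes_at(s, self.k, offs)).sum() >= 2:
                    break
            else:
                return 0.0  # no shared seeds: identity cannot reach 90%
        return max(_identity_to_refs(seq, self.refs),
                   _identity_to_refs(revcomp(seq), self.refs))


def classify_unaligned(seq: str, qual: str, mask: MaskResult | None,
                       organelles: "dict[str, str] | _ForeignScreen",
                       contaminants: "dict[str, str] | _ForeignScreen",
                       was_multi_locus: bool, min_len: int = 100,
                       min_qual: float = 20.0, repeat_frac: float = 0.90,
                       foreign_identity: float = 0.90) -> str:
    """Category of a read rejected by all three alignment steps.

    Priority: LOW_QUALITY > REPEAT > PARALOG > CYTOPLASMIC > CONTAMINANT >
    UNKNOWN (quality/length is checked first, as the aligner's own input
    filter would).  Identity to organelle/contaminant references is checked
    on both strands."""
    if len(seq) < min_len or _mean_quality(qual) < min_qual:
        return LOW_QUALITY
    if mask is not None and mask.length and \
            mask.n_masked >= repeat_frac * mask.length:
        return REPEAT
    if was_multi_locus:
        return PARALOG
    org = organelles if isinstance(organelles, _ForeignScreen) \
        else _ForeignScreen(organelles)
    con = contaminants if isinstance(contaminants, _ForeignScreen) \
        else _ForeignScreen(contaminants)
    if org.identity(seq) >= foreign_identity:
        return CYTOPLASMIC
    if con.identity(seq) >= foreign_identity:
        return CONTAMINANT
    return UNKNOWN


def run_tiered_alignment(reads: ReadSet, reference: dict[str, str],
                         library: RepeatLibrary | None,
                         organelles: dict[str, str] | None = None,
                         contaminants: dict[str, str] | None = None,
                         aligner: TieredAligner | None = None,
                         progress: bool = False) -> TieredResult:
    """Run the full three-step alignment and classify every read.

    Returns alignment records (step-tagged), one classification per read
    (aligned or otherwise) and a percentage summary whose categories
    partition the read set.
    """
    al = aligner or TieredAligner(reference, library)
    organelles = _ForeignScreen(organelles or {})
    contaminants = _ForeignScreen(contaminants or {})
    records: list[AlignmentRecord] = []
    classes: list[ReadClassification] = []
    masks: dict[str, MaskResult] = {}
    counts: dict[str, int] = {}
    seen: set = set()

    def bump(cat: str):
        counts[cat] = counts.get(cat, 0) + 1

    for i, (rid, seq, qual) in enumerate(reads):
        if len(seq) < 100 or _mean_quality(qual) < 20.0:
            classes.append(ReadClassification(rid, LOW_QUALITY))
            bump(LOW_QUALITY)
            continue
        r1 = al.align_single_read(rid, seq, STRICT)
        if isinstance(r1, AlignmentRecord):
            key = (r1.chrom, r1.ref_start, r1.strand, hash(r1.seq))
            r1.is_duplicate = key in seen
            seen.add(key)
            records.append(r1)
            classes.append(ReadClassification(rid, "ALIGNED_STEP1"))
            bump("ALIGNED_STEP1")
            continue
        multi = r1.reason == MULTI_LOCUS
        mask = al.masker.mask(seq) if al.masker is not None else None
        if mask is not None:
            masks[rid] = mask
        r2 = (al._masked_attempt(rid, seq, mask)
              if mask is not None else Rejection(rid, NO_HIT))
        if isinstance(r2, AlignmentRecord):
            key = (r2.chrom, r2.ref_start, r2.strand, hash(seq))
            r2.is_duplicate = key in seen
            seen.add(key)
            records.append(r2)
            classes.append(ReadClassification(rid, "ALIGNED_STEP2"))
            bump("ALIGNED_STEP2")
            continue
        multi = multi or r2.reason == MULTI_LOCUS
        # a read that is mostly repeat will never place uniquely; skip the
        # relaxed attempt for those (they are classified REPEAT below)
        r3: AlignmentRecord | Rejection
        if mask is not None and mask.n_masked >= 0.9 * mask.length:
            r3 = Rejection(rid, TOO_MASKED)
        else:
            r3 = al.align_single_read(rid, seq, RELAXED)
        if isinstance(r3, AlignmentRecord):
            key = (r3.chrom, r3.ref_start, r3.strand, hash(r3.seq))
            r3.is_duplicate = key in seen
            seen.add(key)
            records.append(r3)
            classes.append(ReadClassification(rid, "ALIGNED_STEP3"))
            bump("ALIGNED_STEP3")
            continue
        multi = multi or r3.reason == MULTI_LOCUS
        cat = classify_unaligned(seq, qual, mask, organelles, contaminants,
                                 was_multi_locus=multi)
        classes.append(ReadClassification(rid, cat))
        bump(cat)

    summary = Table1Summary(len(reads.ids), counts)
    return TieredResult(records, classes, summary, masks)


def align_single_read(read_id: str, seq: str, reference: dict[str, str],
                      mode: str = STRICT, library: RepeatLibrary | None = None,
                      **kw) -> AlignmentRecord | Rejection:
    """Convenience one-shot wrapper around :class:`TieredAligner`."""
    al = TieredAligner(reference, library, **kw)
    return al.align_single_read(read_id, seq, mode)
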