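"""Library-driven repeat masking of reads and genome windows.

A read is screened against every sequence in the TE library (LTR forms and
internal regions).  Any stretch locally matching a library sequence at
>= 75% identity over >= 50 bp (defaults, configurable; the sensitivity of a
RepeatMasker-style screen, which recognises old copies that have drifted
20%+ from their family consensus) is masked; the masked/unmasked balance
then classifies the read:

* ``TE_EVIDENCE``   — >= 150 unmasked and >= 100 masked bases: the unmasked
  flank can be placed uniquely on the reference while the masked part names
  the element, which is exactly the evidence used for TE-insertion calling;
* ``REPEAT_READ``   — >= 90% of the read masked: uninformative repeat copy;
* ``MOSTLY_UNIQUE`` — < 50 masked bases;
* ``OTHER``         — everything else.

Matching is seed-and-verify: shared 11-mers vote for (library sequence,
diagonal) candidates, which are verified by gapless maximal-scoring-segment
extension along the diagonal (element copies diverge by substitutions;
occasional read indels split a hit into adjacent diagonals, which the merge
step reunites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import KmerIndex, kmer_codes, revcomp
from .synthdata import RepeatLibrary

__all__ = ["MaskResult", "Masker", "mask_sequence", "masked_composition",
           "hard_mask", "soft_mask"]

TE_EVIDENCE = "TE_EVIDENCE"
REPEAT_READ = "REPEAT_READ"
MOSTLY_UNIQUE = "MOSTLY_UNIQUE"
OTHER = "OTHER"


@dataclass
class MaskResult:
    """Masked intervals (0-based half-open, disjoint, sorted) on one read."""

    length: int
    intervals: list[tuple[int, int]]
    family_hits: list[tuple[str, float]]  # per-interval best family, identity

    @property
    def n_masked(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def n_unmasked(self) -> int:
        return self.length - self.n_masked

    @property
    def best_family(self) -> str | None:
        if not self.family_hits:
            return None
        return max(self.family_hits, key=lambda h: h[1])[0]


def masked_composition(mask: MaskResult, te_min_unmasked: int = 150,
                       te_min_masked: int = 100, repeat_frac: float = 0.90,
                       unique_max_masked: int = 50) -> str:
    """Classify a read from its masked/unmasked composition (ordered rules)."""
    if mask.n_unmasked >= te_min_unmasked and mask.n_masked >= te_min_masked:
        return TE_EVIDENCE
    if mask.length and mask.n_masked >= repeat_frac * mask.length:
        return REPEAT_READ
    if mask.n_masked < unique_max_masked:
        return MOSTLY_UNIQUE
    return OTHER


def hard_mask(seq: str, intervals: list[tuple[int, int]]) -> str:
    b = list(seq)
    for s, e in intervals:
        b[s:e] = "N" * (e - s)
    return "".join(b)


def soft_mask(seq: str, intervals: list[tuple[int, int]]) -> str:
    b = list(seq)
    for s, e in intervals:
        b[s:e] = seq[s:e].lower()
    return "".join(b)


class Masker:
    """Reusable masking engine for a TE library (or any named sequences).

    Accepts either a :class:`RepeatLibrary` or a plain ``{name: sequence}``
    mapping (e.g. straight from a repeat FASTA); family attribution uses
    the part of the name before the first '/'."""

    def __init__(self, library: "RepeatLibrary | dict[str, str]", k: int = 11,
                 min_len: int = 50, min_identity: float = 0.75,
                 mismatch_penalty: float | None = None):
        self.library = library
        self.k = k
        self.min_len = min_len
        self.min_identity = min_identity
        # break-even penalty: a stretch at exactly min_identity scores zero,
        # so extension stops where identity falls below the floor
        self.mismatch_penalty = (mismatch_penalty if mismatch_penalty is not None
                                 else min_identity / (1.0 - min_identity))
        if isinstance(library, dict):
            seqs = dict(library)
        else:
            seqs = library.mask_sequences() if len(library) else {}
        self.index = KmerIndex(seqs, k=k, step=1) if seqs else None
        self._target = (np.frombuffer(self.index.seq.encode(), dtype=np.uint8)
                        if self.index else np.empty(0, dtype=np.uint8))
        # map a global index position to the family name it belongs to
        self._seq_families = ([name.split("/", 1)[0] for name in self.index.names]
                              if self.index else [])

    # -- internals ---------------------------------------------------------

    def _segments_on_diag(self, rb: np.ndarray, rs: int, re: int, diag: int):
        """Maximal-scoring gapless stretches of read[rs:re] vs target on a
        diagonal; returns (read_start, read_end, identity) tuples."""
        ts, te = rs + diag, re + diag
        if ts < 0:
            rs -= ts
            ts = 0
        if te > len(self._target):
            re -= te - len(self._target)
            te = len(self._target)
        if re - rs < self.min_len:
            return []
        eq = (rb[rs:re] == self._target[ts:te])
        score = np.where(eq, 1.0, -self.mismatch_penalty)
        out = []
        self._kadane(score, eq, 0, len(score), rs, out)
        return out

    def _kadane(self, score, eq, lo, hi, off, out):
        """Best-scoring segment in score[lo:hi], widened to the longest
        stretch still meeting the identity floor; recurse on the flanks.

        The maximum-score core alone under-reports: a stretch whose tails
        run at, say, 75% identity still satisfies an 80% floor overall when
        pooled with its high-identity core."""
        if hi - lo < self.min_len:
            return
        pref = np.concatenate(([0.0], np.cumsum(score[lo:hi])))
        run_min = np.minimum.accumulate(pref)
        gains = pref - run_min
        j = int(np.argmax(gains))
        if gains[j] <= 0:
            return
        i = int(np.argmin(pref[:j + 1]))
        s, e = lo + i, lo + j
        # widen while the whole segment keeps the identity floor; the
        # added block must itself look like diverged homology (>= 12 bp at
        # >= 65% identity), which random flanking sequence (25% expected)
        # essentially never does
        cum = np.concatenate(([0], np.cumsum(eq)))
        floor = self.min_identity
        e2 = e
        cand = np.arange(e + 12, hi + 1)
        if len(cand):
            ok = (eq[cand - 1]
                  & ((cum[cand] - cum[s]) >= floor * (cand - s))
                  & ((cum[cand] - cum[e]) >= 0.65 * (cand - e)))
            hits = np.nonzero(ok)[0]
            if len(hits):
                e2 = int(cand[hits[-1]])
        s2 = s
        cand = np.arange(lo, max(s - 12, lo - 1) + 1)
        if len(cand):
            ok = (eq[cand]
                  & ((cum[e2] - cum[cand]) >= floor * (e2 - cand))
                  & ((cum[s] - cum[cand]) >= 0.65 * (s - cand)))
            hits = np.nonzero(ok)[0]
            if len(hits):
                s2 = int(cand[hits[0]])
        s, e = s2, e2
        # trim to match boundaries
        while s < e and not eq[s]:
            s += 1
        while e > s and not eq[e - 1]:
            e -= 1
        n = e - s
        if n >= self.min_len:
            ident = float(np.count_nonzero(eq[s:e])) / n
            if ident >= self.min_identity:
                out.append((off + s, off + e, ident))
        self._kadane(score, eq, lo, s, off, out)
        self._kadane(score, eq, e, hi, off, out)

    def _hits_one_strand(self, seq: str):
        k = self.k
        if len(seq) < k:
            return []
        codes = kmer_codes(seq, k)
        offs = np.arange(len(codes), dtype=np.int64)
        # ignore seeds containing non-ACGT symbols (hard-masked input)
        valid_base = np.frombuffer(seq.encode(), dtype=np.uint8)
        ok = np.isin(valid_base, np.frombuffer(b"ACGT", dtype=np.uint8))
        ok_kmer = (np.convolve(ok.astype(int), np.ones(k, dtype=int), "valid") == k)
        codes, offs = codes[ok_kmer], offs[ok_kmer]
        if len(codes) == 0:
            return []
        gpos, qoff, _capped = self.index.lookup(codes, offs, max_hits_per_seed=400)
        if len(gpos) == 0:
            return []
        diag = gpos - qoff
        # group by (target sequence, diagonal band)
        seq_idx = np.searchsorted(self.index.starts, gpos, side="right") - 1
        order = np.lexsort((diag, seq_idx))
        diag, qoff, seq_idx = diag[order], qoff[order], seq_idx[order]
        new_group = np.concatenate(([True], (np.diff(seq_idx) != 0)
                                    | (np.diff(diag) > 6)))
        brk = np.nonzero(new_group)[0]
        g_starts = brk
        g_ends = np.concatenate((brk[1:], [len(diag)]))
        sizes = g_ends - g_starts
        # groups are contiguous slices (hits sorted by sequence, diagonal);
        # verify the best-seeded ones first and cap the work per read
        order = np.argsort(-sizes, kind="stable")[:48]
        rb = np.frombuffer(seq.encode(), dtype=np.uint8)
        hits = []
        for gi in order:
            a, b = int(g_starts[gi]), int(g_ends[gi])
            if b - a < 2 and self.min_len >= 2 * self.k:
                continue
            q = qoff[a:b]
            d = int(np.median(diag[a:b]))
            # widen beyond the seed span: a sparse seed cluster can sit
            # inside a maskable stretch much longer than itself
            pad = self.min_len + 10
            rs = max(0, int(q.min()) - pad)
            re = min(len(seq), int(q.max()) + self.k + pad)
            if re - rs < self.min_len:
                continue
            fam = self._seq_families[int(seq_idx[a])]
            for s, e, ident in self._segments_on_diag(rb, rs, re, d):
                hits.append((s, e, fam, ident))
        return hits

    # -- public ------------------------------------------------------------

    def mask(self, seq: str) -> MaskResult:
        """Mask every library match >= min_len at >= min_identity."""
        if not seq:
            raise ValueError("cannot mask an empty sequence")
        useq = seq.upper()
        if self.index is None:
            import warnings
            warnings.warn("masking with an empty repeat library: nothing masked")
            return MaskResult(len(seq), [], [])
        hits = list(self._hits_one_strand(useq))
        L = len(seq)
        for s, e, fam, ident in self._hits_one_strand(revcomp(useq)):
            hits.append((L - e, L - s, fam, ident))
        if not hits:
            return MaskResult(L, [], [])
        hits.sort()
        merged: list[list] = []
        for s, e, fam, ident in hits:
            if merged and s <= merged[-1][1]:
                if ident > merged[-1][3]:
                    merged[-1][2], merged[-1][3] = fam, ident
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e, fam, ident])
        return MaskResult(L, [(s, e) for s, e, _, _ in merged],
                          [(fam, ident) for _, _, fam, ident in merged])


def mask_sequence(seq: str, library: RepeatLibrary | Masker, **kw) -> MaskResult:
    """One-shot masking; pass a :class:`Masker` to reuse the seed index."""
    masker = library if isinstance(library, Masker) else Masker(library, **kw)
    return masker.mask(seq)
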