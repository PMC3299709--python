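"""Low-level nucleotide utilities shared across the package.

Sequences are plain Python ``str`` over the alphabet ``ACGT`` (soft-masked
intermediates may contain lowercase, hard-masked aligner input may contain
``N``).  Coordinates are 0-based half-open everywhere in memory; file writers
convert to the 1-based conventions of GFF3/VCF-style outputs.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# byte value -> 2-bit code; anything outside ACGT maps to 0 (callers must
# avoid indexing masked sequence)
_CODE = np.zeros(256, dtype=np.int64)
_CODE[ord("A")] = 0
_CODE[ord("C")] = 1
_CODE[ord("G")] = 2
_CODE[ord("T")] = 3

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """2-bit integer codes (A=0, C=1, G=2, T=3) for a sequence."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer of ``seq`` (length ``len(seq)-k+1``)."""
    b = seq_to_codes(seq)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = np.zeros(n, dtype=np.int64)
    for j in range(k):
        c = c * 4 + b[j : j + n]
    return c


class KmerIndex:
    """Sorted k-mer lookup table over a set of named sequences.

    Positions are global offsets into the concatenation of the sequences;
    :meth:`locate` converts a global offset back to ``(name, local_offset)``.
    k-mers spanning a boundary between two sequences are excluded.
    """

    def __init__(self, seqs: dict[str, str], k: int = 13, step: int = 1):
        self.k = k
        self.step = step
        self.names: list[str] = list(seqs)
        self.starts = np.zeros(len(self.names) + 1, dtype=np.int64)
        parts = []
        for i, name in enumerate(self.names):
            parts.append(seqs[name])
            self.starts[i + 1] = self.starts[i] + len(seqs[name])
        self.seq = "".join(parts)

        codes_parts, pos_parts = [], []
        for i, name in enumerate(self.names):
            s = seqs[name]
            if len(s) < k:
                continue
            c = kmer_codes(s, k)[::step]
            p = np.arange(0, len(s) - k + 1, step, dtype=np.int64) + self.starts[i]
            codes_parts.append(c)
            pos_parts.append(p)
        if codes_parts:
            codes = np.concatenate(codes_parts)
            pos = np.concatenate(pos_parts)
            order = np.argsort(codes, kind="stable")
            codes, pos = codes[order], pos[order]
            # 4^k codes and genome offsets fit int32 for k <= 15 and
            # references below 2 Gb; halving the width speeds up the
            # binary searches considerably
            if k <= 15:
                codes = codes.astype(np.int32)
            if self.starts[-1] < 2**31:
                pos = pos.astype(np.int32)
            self._codes = codes
            self._pos = pos
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)

    @property
    def total_len(self) -> int:
        return int(self.starts[-1])

    def locate(self, gpos: int) -> tuple[str, int]:
        """Map a global offset to (sequence name, local offset)."""
        i = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        return self.names[i], int(gpos - self.starts[i])

    def lookup(self, query_codes: np.ndarray, query_offsets: np.ndarray,
               max_hits_per_seed: int = 64
               ) -> tuple[np.ndarray, np.ndarray, int]:
        """Seed matches: (global positions, query offsets, n_capped_seeds).

        Seeds whose k-mer occurs more than ``max_hits_per_seed`` times are
        dropped (they carry no locating information inside high-copy
        repeats); the count of such seeds is returned so callers can
        recognise reads that live in repetitive territory.
        """
        q = query_codes.astype(self._codes.dtype, copy=False)
        lo = np.searchsorted(self._codes, q, side="left")
        hi = np.searchsorted(self._codes, q, side="right")
        counts = hi - lo
        n_capped = int((counts > max_hits_per_seed).sum())
        keep = (counts > 0) & (counts <= max_hits_per_seed)
        lo, counts = lo[keep], counts[keep]
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64),
                    np.empty(0, dtype=np.int64), n_capped)
        # grouped arange: positions _pos[lo_i : lo_i + counts_i] concatenated
        cum = np.cumsum(counts) - counts
        idx = (np.arange(total, dtype=np.int64)
               - np.repeat(cum, counts) + np.repeat(lo, counts))
        qoff = np.repeat(query_offsets[keep], counts)
        return self._pos[idx].astype(np.int64), qoff, n_capped

    def n_hits(self, query_codes: np.ndarray) -> np.ndarray:
        """Occurrence count in the index for each query k-mer code."""
        q = query_codes.astype(self._codes.dtype, copy=False)
        lo = np.searchsorted(self._codes, q, side="left")
        hi = np.searchsorted(self._codes, q, side="right")
        return hi - lo


def kmer_codes_at(seq: str, k: int, offsets: np.ndarray) -> np.ndarray:
    """k-mer codes at selected offsets only (cheaper than all positions)."""
    b = seq_to_codes(seq)
    idx = offsets[:, None] + np.arange(k)
    window = b[idx]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return window @ powers


def cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions_bp, deletions_bp) of an =/X/I/D cigar."""
    m = x = ins = dele = 0
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            if ch == "=":
                m += n
            elif ch == "X":
                x += n
            elif ch == "I":
                ins += n
            elif ch == "D":
                dele += n
            n = 0
    return m, x, ins, dele


def cigar_identity(cigar: str) -> float:
    """Matches over alignment columns for an extended (=/X/I/D) cigar."""
    m, x, i, d = cigar_stats(cigar)
    cols = m + x + i + d
    return m / cols if cols else 0.0


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    """Parse a cigar string into (length, op) tuples."""
    ops = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            ops.append((n, ch))
            n = 0
    return ops


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.345) -> str:
    """Random nucleotide string with the given expected GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def mutate_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Copy of ``seq`` with point substitutions at the given per-base rate."""
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(b)) < rate)[0]
    for i in hits:
        cur = chr(b[i])
        b[i] = ord(rng.choice([c for c in BASES if c != cur]))
    return b.tobytes().decode("ascii")
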