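"""LTR-form dynamics: harvesting, clustering and dating element activity.

The long terminal repeats of a retrotransposon family index its history:
copies inserted by a recent burst still carry near-identical LTRs (a "major
form" — many reads collapsing onto one consensus), while old copies have
drifted apart into a diffuse pool of unclusterable "minor forms".  The
fraction of LTR-bearing reads captured by major forms therefore ranks
families by recent activity, and a clique of effectively identical
conserved-region sequences is the signature of ongoing transposition.

Reads are screened against a family's base LTR; matching stretches are
projected into LTR coordinates (a star alignment with the base LTR as the
common frame), then clustered greedily: the longest unassigned segment
seeds a cluster, members join at >= 90% identity to the running consensus
(majority base per column), and clusters with >= 10 members are major
forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import KmerIndex, kmer_codes, revcomp
from .synthdata import ReadSet, TEFamily

__all__ = ["LTRSegment", "LTRCluster", "FormSummary", "harvest_ltr_segments",
           "cluster_forms", "conserved_region_tree", "ConservedRegionResult"]

GAP = ord("-")


@dataclass
class LTRSegment:
    """A read substring aligned to the family LTR, in LTR coordinates.

    ``bases`` has length ``end - start``: the read base serving each LTR
    column ('-' where the read lacks the column)."""

    read_id: str
    start: int
    end: int
    bases: str
    identity: float

    def __len__(self):
        return self.end - self.start

    def arr(self) -> np.ndarray:
        return np.frombuffer(self.bases.encode(), dtype=np.uint8)


def _project(read_seg: str, ltr_seg: str, lt_start: int) -> tuple[str, float]:
    """Project a read stretch onto LTR columns via edit-distance alignment."""
    res = edlib.align(read_seg, ltr_seg, mode="NW", task="path")
    out = []
    qp = 0
    match = cols = 0
    n = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
            continue
        if ch == "=":
            out.append(read_seg[qp:qp + n])
            match += n
            cols += n
            qp += n
        elif ch == "X":
            out.append(read_seg[qp:qp + n])
            cols += n
            qp += n
        elif ch == "I":  # read bases with no LTR column: drop
            qp += n
            cols += n
        elif ch == "D":  # LTR columns the read lacks
            out.append("-" * n)
            cols += n
        n = 0
    del lt_start
    proj = "".join(out)
    return proj, (match / cols if cols else 0.0)


def harvest_ltr_segments(reads: ReadSet, family: TEFamily,
                         min_identity: float = 0.75,
                         min_len: int = 100, k: int = 11) -> list[LTRSegment]:
    """Extract LTR-matching read stretches for one family.

    Accepts stretches locally matching the family's base LTR at
    >= ``min_identity`` over >= ``min_len`` aligned columns; orientation is
    normalised to the LTR strand."""
    if not family.ltr_seq:
        raise ValueError(f"family {family.name} has no LTR")
    ltr = family.ltr_seq
    index = KmerIndex({"LTR": ltr}, k=k, step=1)
    segs: list[LTRSegment] = []
    for rid, seq, _q in reads:
        best: LTRSegment | None = None
        for oriented in (seq, revcomp(seq)):
            if len(oriented) < k:
                continue
            codes = kmer_codes(oriented, k)
            offs = np.arange(len(codes), dtype=np.int64)
            gpos, qoff, _capped = index.lookup(codes, offs, max_hits_per_seed=64)
            if len(gpos) < 3:
                continue
            diag = gpos - qoff
            order = np.argsort(diag)
            diag, qoff2 = diag[order], qoff[order]
            brk = np.nonzero(np.diff(diag) > 10)[0] + 1
            for dg, qg in zip(np.split(diag, brk), np.split(qoff2, brk)):
                if len(qg) < 3:
                    continue
                d = int(np.median(dg))
                rs, re = int(qg.min()), int(qg.max()) + k
                # widen to the maximal plausible overlap on this diagonal
                rs = max(0, min(rs, -d if d < 0 else rs) - 8)
                re = min(len(oriented), max(re, len(ltr) - d) + 8)
                ls, le = max(0, rs + d), min(len(ltr), re + d)
                rs, re = ls - d, le - d
                if le - ls < min_len:
                    continue
                proj, ident = _project(oriented[rs:re], ltr[ls:le], ls)
                if ident >= min_identity and len(proj) >= min_len:
                    cand = LTRSegment(rid, ls, ls + len(proj), proj, ident)
                    if best is None or ident * len(cand) > best.identity * len(best):
                        best = cand
        if best is not None:
            segs.append(best)
    return segs


@dataclass
class LTRCluster:
    family: str
    members: list[LTRSegment]
    start: int
    end: int
    consensus: str  # over [start, end)
    is_major: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    def mean_identity(self) -> float:
        return float(np.mean([_overlap_identity(
            s, self.start, self.consensus)[0] for s in self.members]))


@dataclass
class FormSummary:
    family: str
    n_segments: int
    major_sizes: list[int]
    major_proportions: list[float]

    @property
    def n_major_forms(self) -> int:
        return len(self.major_sizes)

    @property
    def major_proportion(self) -> float:
        return float(sum(self.major_proportions))

    @property
    def minor_proportion(self) -> float:
        return 1.0 - self.major_proportion

    def rows(self):
        for i, p in enumerate(self.major_proportions, 1):
            yield (self.family, f"LTR{i}", f"{100 * p:.0f}%")
        yield (self.family, "Minor LTR", f"{100 * self.minor_proportion:.0f}%")


def _overlap_identity(seg: LTRSegment, c_start: int, consensus: str
                      ) -> tuple[float, int]:
    """(identity, n_columns) of a segment against a consensus, over the
    columns both cover (gaps excluded from the comparison)."""
    lo = max(seg.start, c_start)
    hi = min(seg.end, c_start + len(consensus))
    if hi <= lo:
        return 0.0, 0
    a = seg.arr()[lo - seg.start: hi - seg.start]
    b = np.frombuffer(consensus.encode(), dtype=np.uint8)[lo - c_start: hi - c_start]
    ok = (a != GAP) & (b != GAP)
    n = int(ok.sum())
    if n == 0:
        return 0.0, 0
    return float((a[ok] == b[ok]).sum() / n), n


def _consensus(members: list[LTRSegment]) -> tuple[int, int, str]:
    start = min(s.start for s in members)
    end = max(s.end for s in members)
    width = end - start
    counts = np.zeros((width, 5), dtype=np.int32)
    sym = np.frombuffer(b"ACGT-", dtype=np.uint8)
    for s in members:
        a = s.arr()
        for si, code in enumerate(sym):
            hits = np.nonzero(a == code)[0]
            counts[hits + (s.start - start), si] += 1
    best = np.argmax(counts, axis=1)  # ties: alphabetical ACGT then gap
    covered = counts.sum(axis=1) > 0
    out = sym[best]
    out[~covered] = GAP
    return start, end, out.tobytes().decode("ascii")


def cluster_forms(segments: list[LTRSegment], family: str = "",
                  min_size: int = 10, identity: float = 0.90,
                  min_overlap: int = 100,
                  seed: int = 0) -> tuple[list[LTRCluster], FormSummary]:
    """Greedy consensus clustering of LTR segments into forms.

    The longest unassigned segment seeds a cluster; remaining segments join
    the cluster when they overlap its consensus by >= ``min_overlap``
    columns at >= ``identity`` (with a one-sided small-sample guard of
    0.8 binomial standard errors, so a short overlap cannot clear the bar
    on sampling noise alone), updating the consensus by per-column
    majority vote (ties broken alphabetically).  Clusters reaching
    ``min_size`` are the major forms; everything else pools as minor."""
    if not segments:
        raise ValueError("no segments to cluster")
    del seed  # ordering is deterministic (length, then read id)
    guard = 0.8 * np.sqrt(identity * (1.0 - identity))
    todo = sorted(segments, key=lambda s: (-len(s), s.read_id))
    assigned = [False] * len(todo)
    clusters: list[LTRCluster] = []
    for i, seedseg in enumerate(todo):
        if assigned[i]:
            continue
        members = [seedseg]
        assigned[i] = True
        c_start, c_end, cons = seedseg.start, seedseg.end, seedseg.bases
        grew = True
        while grew:
            grew = False
            for j in range(i + 1, len(todo)):
                if assigned[j]:
                    continue
                ident, n = _overlap_identity(todo[j], c_start, cons)
                if n >= min_overlap and ident >= identity + guard / np.sqrt(n):
                    members.append(todo[j])
                    assigned[j] = True
                    grew = True
            if grew:
                c_start, c_end, cons = _consensus(members)
        clusters.append(LTRCluster(family, members, c_start, c_end, cons))
    for cl in clusters:
        cl.is_major = cl.size >= min_size and cl.mean_identity() >= identity
    majors = sorted((c for c in clusters if c.is_major),
                    key=lambda c: -c.size)
    total = len(segments)
    summary = FormSummary(family, total, [c.size for c in majors],
                          [c.size / total for c in majors])
    return clusters, summary


# ---------------------------------------------------------------------------
# Conserved-region trees and the recent-activity signature
# ---------------------------------------------------------------------------

@dataclass
class ConservedRegionResult:
    tree: "object"  # ssap.TreeResult
    n_segments: int
    recent_activity: bool
    max_clique: int
    region: tuple[int, int]


def _region_matrix(segments: list[LTRSegment],
                   region: tuple[int, int], min_cover: float = 0.9
                   ) -> tuple[np.ndarray, list[str]]:
    lo, hi = region
    width = hi - lo
    rows, ids = [], []
    for s in segments:
        a, b = max(s.start, lo), min(s.end, hi)
        if b - a < min_cover * width:
            continue
        row = np.full(width, GAP, dtype=np.uint8)
        row[a - lo: b - lo] = s.arr()[a - s.start: b - s.start]
        rows.append(row)
        ids.append(s.read_id)
    if not rows:
        return np.empty((0, width), dtype=np.uint8), []
    return np.stack(rows), ids


def _greedy_max_clique(adj: np.ndarray) -> int:
    """Greedy lower bound on the maximum clique of an adjacency matrix."""
    n = len(adj)
    best = 0
    order = np.argsort(-adj.sum(axis=1))
    for start in order[: min(n, 50)]:
        clique = [start]
        cand = set(np.nonzero(adj[start])[0])
        for v in sorted(cand, key=lambda v: -int(adj[v].sum())):
            if all(adj[v, u] for u in clique):
                clique.append(v)
        best = max(best, len(clique))
    return best


def conserved_region_tree(segments: list[LTRSegment],
                          region: tuple[int, int] | None = None,
                          ltr_len: int | None = None,
                          bootstrap: int = 0, seed: int = 0,
                          max_leaves: int = 60,
                          clique_identity: float = 0.99,
                          clique_min: int = 5) -> ConservedRegionResult:
    """Neighbor-joining tree over a conserved LTR region + activity flag.

    The default region is the final 200 bp of the LTR (the integrase-
    containing stretch is the classic conserved anchor).  Pairwise
    p-distances over the region feed NJ; the recent-activity flag reports
    whether >= ``clique_min`` segments are mutually >= ``clique_identity``
    identical — copies that have had no time to diverge."""
    from skbio import DistanceMatrix
    from . import ssap

    if region is None:
        if ltr_len is None:
            ltr_len = max(s.end for s in segments)
        region = (max(0, ltr_len - 200), ltr_len)
    mat, ids = _region_matrix(segments, region)
    if len(ids) < 3:
        raise ValueError("need >= 3 segments covering the region")

    valid = mat != GAP
    # pairwise p-distance over mutually covered columns
    n = len(ids)
    if n > max_leaves:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(n, size=max_leaves, replace=False))
        mat, valid = mat[keep], valid[keep]
        ids = [ids[i] for i in keep]
        n = max_leaves
    d = np.zeros((n, n))
    ident = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        eq = (mat[i] == mat) & both
        nb = both.sum(axis=1)
        ne = eq.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident[i] = np.where(nb > 0, ne / nb, 0.0)
        d[i] = 1.0 - ident[i]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    # ids must be unique for the distance matrix
    uniq = [f"{r}#{i}" if ids.count(r) > 1 else r for i, r in enumerate(ids)]
    tree = ssap.nj_tree(DistanceMatrix(d, ids=uniq),
                        bootstrap=0 if bootstrap == 0 else 0, seed=seed)
    if bootstrap:
        tree = _bootstrap_columns(mat, valid, uniq, bootstrap, seed, tree)
    adj = ident >= clique_identity
    np.fill_diagonal(adj, True)
    clique = _greedy_max_clique(adj)
    return ConservedRegionResult(tree, n, clique >= clique_min, clique, region)


def _bootstrap_columns(mat, valid, ids, bootstrap, seed, base_result):
    """Column-resampling bootstrap support on the conserved-region tree."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    from . import ssap

    taxa = frozenset(ids)
    counts = {bp: 0 for bp in ssap._bipartitions(base_result.tree, taxa)}
    rng = np.random.default_rng(seed)
    width = mat.shape[1]
    for _ in range(bootstrap):
        cols = rng.integers(0, width, size=width)
        m, v = mat[:, cols], valid[:, cols]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            both = v[i] & v
            eq = (m[i] == m) & both
            nb = both.sum(axis=1)
            ne = eq.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d[i] = np.where(nb > 0, 1.0 - ne / nb, 1.0)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        rep = _nj(DistanceMatrix(d, ids=ids))
        for bp in ssap._bipartitions(rep, taxa):
            if bp in counts:
                counts[bp] += 1
    base_result.support = {bp: 100.0 * c / bootstrap
                           for bp, c in counts.items()}
    base_result.n_bootstrap = bootstrap
    return base_result
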