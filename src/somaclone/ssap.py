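"""In-silico S-SAP: band profiles, Nei-Li distances, neighbor-joining trees.

Sequence-specific amplified polymorphism (S-SAP) fingerprints the insertion
sites of a mobile element: PCR runs from a primer anchored at the element's
LTR end out into the flanking DNA, up to an adapter ligated at the nearest
restriction site.  Each insertion locus therefore yields a band whose length
is the primer-to-site distance; clones differing by an insertion differ by a
band.  We emulate this on clone genome sequences directly: every genomic
occurrence of the primer is extended to the nearest downstream enzyme motif
and the fragment length is scored if it falls in the gel's resolvable range.

Band presence/absence matrices feed the classic marker workflow: Nei-Li
(fragment-sharing) distance, neighbor joining for the topology, and a
nonparametric bootstrap over band columns for edge support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from ._seq import revcomp
from .synthdata import CloneGenome, TEFamily

__all__ = ["Band", "BandMatrix", "insilico_ssap", "band_matrix",
           "nei_li_distance", "nei_li_matrix", "nj_tree", "default_primer",
           "bootstrap_support", "TreeResult"]

# MseI-like four-cutter: the frequent-cutter partner of classic S-SAP/AFLP
# digests.  A six-cutter alone leaves most insertion loci without a site
# inside the resolvable fragment range, defeating the fingerprint.
DEFAULT_ENZYME = "TTAA"


def default_primer(family: TEFamily, length: int = 20) -> str:
    """Primer anchored at the 3' end of the family's base LTR.

    The terminal LTR stretch is the region conserved across insertion loci
    (every full-length copy carries it), so a primer there amplifies the
    largest number of loci."""
    if not family.ltr_seq:
        raise ValueError(f"family {family.name} has no LTR to anchor a primer")
    if length > len(family.ltr_seq):
        raise ValueError("primer longer than the LTR")
    return family.ltr_seq[-length:]


@dataclass(frozen=True)
class Band:
    element: str
    length_bin: int  # fragment length quantised to the gel resolution

    def __str__(self):
        return f"{self.element}:{self.length_bin}"


def insilico_ssap(genome: CloneGenome | dict[str, str], element: TEFamily,
                  primer: str | None = None,
                  enzyme_site: str = DEFAULT_ENZYME,
                  size_range: tuple[int, int] = (50, 1000),
                  bin_bp: int = 4) -> set[Band]:
    """Band set of one clone for one element.

    For every occurrence of ``primer`` (either strand), the distance from
    the primer's 3' end to the start of the nearest downstream
    ``enzyme_site`` is a band if it lies within ``size_range``.  Fragment
    lengths are binned at ``bin_bp`` (~±2 bp), emulating gel resolution.
    """
    if primer is None:
        primer = default_primer(element)
    if len(enzyme_site) < 4:
        raise ValueError("enzyme motif must be >= 4 bp")
    if element.ltr_seq and primer not in element.ltr_seq \
            and primer not in revcomp(element.ltr_seq):
        raise ValueError("primer does not occur in the element LTR")
    chroms = genome.chromosomes if isinstance(genome, CloneGenome) else genome
    lo, hi = size_range
    bands: set[Band] = set()
    for seq in chroms.values():
        for strand_seq in (seq, revcomp(seq)):
            start = 0
            while True:
                i = strand_seq.find(primer, start)
                if i < 0:
                    break
                start = i + 1
                p3 = i + len(primer)  # primer 3' end
                j = strand_seq.find(enzyme_site, p3, p3 + hi + len(enzyme_site))
                if j < 0:
                    continue
                frag = j - p3
                if lo <= frag <= hi:
                    bands.add(Band(element.name, int(round(frag / bin_bp))))
    return bands


@dataclass
class BandMatrix:
    """Samples x bands binary presence/absence matrix."""

    df: pd.DataFrame  # index: samples, columns: band labels, values 0/1

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def n_bands(self) -> int:
        return self.df.shape[1]

    @property
    def n_polymorphic(self) -> int:
        col = self.df.sum(axis=0)
        return int(((col > 0) & (col < len(self.df))).sum())

    @property
    def pct_polymorphic(self) -> float:
        return 100.0 * self.n_polymorphic / self.n_bands if self.n_bands else 0.0

    def row(self, sample: str) -> np.ndarray:
        return self.df.loc[sample].to_numpy()

    def patterns_unique(self) -> bool:
        return len(set(map(tuple, self.df.to_numpy()))) == len(self.df)


def band_matrix(band_sets: dict[str, set[Band]]) -> BandMatrix:
    """Assemble per-sample band sets into a presence/absence matrix."""
    if len(band_sets) < 2:
        raise ValueError("need at least two samples")
    all_bands = sorted({b for s in band_sets.values() for b in s},
                       key=lambda b: (b.element, b.length_bin))
    data = {str(b): [int(b in band_sets[s]) for s in band_sets]
            for b in all_bands}
    df = pd.DataFrame(data, index=list(band_sets), dtype=np.int8)
    return BandMatrix(df)


def nei_li_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Nei-Li fragment-sharing distance between two 0/1 band rows.

    D = 1 - 2*n_xy / (n_x + n_y), where n_xy is the number of shared
    bands and n_x, n_y the band counts of each sample."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("band rows differ in length")
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 or ny == 0:
        raise ValueError("Nei-Li distance undefined for a sample with no bands")
    nxy = int((x & y).sum())
    return 1.0 - 2.0 * nxy / (nx + ny)


def nei_li_matrix(bm: BandMatrix) -> DistanceMatrix:
    m = bm.df.to_numpy(dtype=bool)
    n = len(bm.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_li_distance(m[i], m[j])
    return DistanceMatrix(d, ids=bm.samples)


@dataclass
class TreeResult:
    tree: TreeNode
    support: dict[frozenset, float] = field(default_factory=dict)
    n_bootstrap: int = 0

    def newick(self) -> str:
        return str(self.tree).strip()


def _canonical_side(side: frozenset, taxa: frozenset) -> frozenset:
    """Deterministic representative of a bipartition (smaller side; ties
    broken by sorted taxon names)."""
    other = taxa - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return frozenset(min(tuple(sorted(side)), tuple(sorted(other))))


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions in canonical form."""
    out = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(_canonical_side(side, taxa))
    return out


def nj_tree(dm: DistanceMatrix, bootstrap: int = 0,
            seed: int = 0, bm: BandMatrix | None = None) -> TreeResult:
    """Neighbor-joining tree, optionally with band-resampling bootstrap.

    Support for each internal edge is the percentage of bootstrap
    replicates (band columns resampled with replacement, distances and
    topology recomputed) containing the same bipartition.  Negative branch
    lengths are clamped to zero by the NJ implementation."""
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    tree = nj(dm)
    result = TreeResult(tree, {}, bootstrap)
    if bootstrap > 0:
        if bm is None:
            raise ValueError("bootstrap requires the band matrix")
        taxa = frozenset(dm.ids)
        counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(tree, taxa)}
        rng = np.random.default_rng(seed)
        ncol = bm.df.shape[1]
        mat = bm.df.to_numpy(dtype=bool)
        for _ in range(bootstrap):
            cols = rng.integers(0, ncol, size=ncol)
            sub = mat[:, cols]
            n = len(bm.samples)
            d = np.zeros((n, n))
            ok = True
            for i in range(n):
                for j in range(i + 1, n):
                    ni, njj = sub[i].sum(), sub[j].sum()
                    if ni == 0 or njj == 0:
                        ok = False
                        break
                    nij = (sub[i] & sub[j]).sum()
                    d[i, j] = d[j, i] = 1.0 - 2.0 * nij / (ni + njj)
                if not ok:
                    break
            if not ok:
                continue
            rep = nj(DistanceMatrix(d, ids=bm.samples))
            for bp in _bipartitions(rep, taxa):
                if bp in counts:
                    counts[bp] += 1
        result.support = {bp: 100.0 * c / bootstrap for bp, c in counts.items()}
        # annotate internal nodes for newick output
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            key = _canonical_side(side, taxa)
            if key in result.support:
                node.name = f"{result.support[key]:.0f}"
    return result
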