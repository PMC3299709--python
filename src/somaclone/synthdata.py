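"""Synthetic inputs for the clone-comparison pipeline.

This module fabricates everything the analysis consumes — a transposable
element (TE) library, a repeat-rich ancestral reference with gene annotation,
clone genomes derived from the ancestor by somatic mutation, 454-style reads
and "in-silico sheared" assembly fragments — together with a mutation ledger
that records the exact ground truth, so that every downstream stage can be
validated against a known answer.

The defaults mirror the observed biology of vegetatively propagated grapevine
clones: somatic divergence of roughly 1.6 SNPs, 5.1 indels and 35.2 new TE
insertions per Mb, reads averaging 355 bp whose quality decays along the
read, ~0.58% emulsion-PCR duplicates, ~3.8% organelle reads and trace
contamination.  The clone model is haploid: somatic changes are then
unambiguous allele-set differences, which is how the calls are compared.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, mutate_substitutions, random_seq, revcomp

__all__ = [
    "LTRVariant",
    "TEFamily",
    "RepeatLibrary",
    "Gene",
    "RepeatCopy",
    "AncestralGenome",
    "LedgerEntry",
    "MutationLedger",
    "CloneGenome",
    "ReadProfile",
    "Provenance",
    "ReadSet",
    "apply_ledger",
    "build_te_library",
    "build_te_population_genome",
    "build_ancestral_genome",
    "derive_clone",
    "simulate_reads",
    "shear_assembly",
]


# ---------------------------------------------------------------------------
# TE library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LTRVariant:
    """A subfamily form of a family's long terminal repeat.

    ``weight`` is the fraction of genomic copies carrying this form;
    ``copy_divergence`` is the additional per-base substitution divergence
    accumulated independently by each genomic copy of the form (0 for a
    recently amplified, still-identical subfamily).
    """

    name: str
    seq: str
    weight: float
    copy_divergence: float = 0.0


@dataclass(frozen=True)
class TEFamily:
    """A named mobile-element family.

    Class I elements (Gypsy/Copia LTR retrotransposons, LINEs and
    Caulimoviridae-like elements) carry ``ltr_seq``; class II DNA transposons
    have only ``internal_seq``.  ``tsd_len`` is the target-site duplication
    created on insertion.  ``subfamily_variants`` lists the major LTR forms;
    the residual weight ``1 - sum(weights)`` is the diffuse pool of old,
    mutually divergent copies ("minor forms").
    """

    name: str
    te_class: str
    superfamily: str
    ltr_seq: str
    internal_seq: str
    tsd_len: int
    subfamily_variants: tuple[LTRVariant, ...] = ()
    minor_divergence: tuple[float, float] = (0.17, 0.22)
    # relative copy abundance in the reference repeat landscape (LINEs
    # dominate real plant genomes) and the share of ancestral copies that
    # belong to a young, near-identical cohort (ambiguous to an aligner)
    abundance: float = 1.0
    young_frac: float = 0.0
    young_divergence: float = 0.008

    def __post_init__(self):
        if self.te_class not in ("I", "II"):
            raise ValueError(f"te_class must be 'I' or 'II', got {self.te_class!r}")
        if self.ltr_seq and not 100 <= len(self.ltr_seq) <= 1000:
            raise ValueError("LTR length must be in [100, 1000]")
        if len(self.internal_seq) < 500:
            raise ValueError("internal sequence must be >= 500 bp")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.major_weight > 1.0 + 1e-9:
            raise ValueError("subfamily variant weights exceed 1")

    @property
    def major_weight(self) -> float:
        return float(sum(v.weight for v in self.subfamily_variants))

    @property
    def minor_weight(self) -> float:
        """Weight of the diffuse minor-form pool (normalised complement)."""
        return max(0.0, 1.0 - self.major_weight)

    @property
    def dominant_variant(self) -> LTRVariant | None:
        return self.subfamily_variants[0] if self.subfamily_variants else None

    def make_copy(self, rng: np.random.Generator,
                  variant: LTRVariant | None = None,
                  prefer_dominant: float = 0.0,
                  fresh: bool = False,
                  force_minor: bool = False) -> tuple[str, str, str]:
        """Materialise one genomic copy of the element.

        Returns ``(sequence, variant_name, strand)``; strand is drawn
        uniformly.  With probability ``prefer_dominant`` the dominant
        subfamily variant is used regardless of the weights (new somatic
        insertions come overwhelmingly from the currently active form).
        ``fresh`` marks a new somatic insertion: it is a near-identical copy
        of its source element (~1% divergence), whereas non-fresh copies
        drawn from the minor pool model old insertions that have
        accumulated 12-20% private divergence since they jumped.
        """
        if variant is None and not force_minor:
            variant = self._draw_variant(rng, prefer_dominant)
        if variant is not None:
            base, div, vname = variant.seq, variant.copy_divergence, variant.name
        elif not fresh and not force_minor and rng.random() < self.young_frac:
            base, div, vname = self.ltr_seq, self.young_divergence, "young"
        else:
            div = 0.01 if fresh else float(rng.uniform(*self.minor_divergence))
            base, vname = self.ltr_seq, "minor"
        internal = mutate_substitutions(rng, self.internal_seq, div)
        if base:
            # post-insertion substitutions hit the two LTR ends independently
            ltr5 = mutate_substitutions(rng, base, div)
            ltr3 = mutate_substitutions(rng, base, div)
            seq = ltr5 + internal + ltr3
        else:
            seq = internal
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        return seq, vname, strand

    def _draw_variant(self, rng: np.random.Generator,
                      prefer_dominant: float) -> LTRVariant | None:
        if self.subfamily_variants and rng.random() < prefer_dominant:
            return self.dominant_variant
        u = rng.random()
        acc = 0.0
        for v in self.subfamily_variants:
            acc += v.weight
            if u < acc:
                return v
        return None


@dataclass
class RepeatLibrary:
    """The set of known mobile-element families used for masking and calling."""

    families: list[TEFamily]

    def __post_init__(self):
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names in library")

    def __iter__(self):
        return iter(self.families)

    def __len__(self):
        return len(self.families)

    def get(self, name: str) -> TEFamily:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)

    def mask_sequences(self) -> dict[str, str]:
        """Named sequences to screen against (LTR forms and internal regions)."""
        out: dict[str, str] = {}
        for f in self.families:
            if f.ltr_seq:
                out[f"{f.name}/LTR"] = f.ltr_seq
                for v in f.subfamily_variants:
                    out[f"{f.name}/LTR:{v.name}"] = v.seq
            out[f"{f.name}/INT"] = f.internal_seq
        return out


def _variants(rng: np.random.Generator, base: str, spec: list[tuple[float, float, float]]
              ) -> tuple[LTRVariant, ...]:
    """Major LTR forms derived from a base LTR.

    ``spec`` rows are (weight, divergence_from_base, copy_divergence).
    Divergences are chosen so that distinct forms stay below the 90%
    clustering identity while remaining detectable against the base.
    """
    out = []
    for i, (w, d, cd) in enumerate(spec, start=1):
        seq = mutate_substitutions(rng, base, d) if d else base
        out.append(LTRVariant(name=f"LTR{i}", seq=seq, weight=w, copy_divergence=cd))
    return tuple(out)


def build_te_library(n_families: int, seed: int) -> RepeatLibrary:
    """Build a mobile-element library of ``n_families`` families.

    With ``n_families >= 4`` the first four are the focal grapevine-like
    elements: a Gret1-like Gypsy element with four major LTR forms (weights
    0.25/0.18/0.05/0.03, the first recently amplified and still identical
    between copies), a Copia10-like element (0.19/0.07/0.07/0.03), a
    Gypsy19-like element (one form, 0.10) and a Cauliv1-like
    Caulimoviridae element (one form, 0.07); the rest of each family's copy
    mass is a diffuse pool of old divergent copies.  Additional families
    alternate LINE-like class I and MITE-like class II elements.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    fams: list[TEFamily] = []

    # Divergence geometry: non-dominant forms sit 15% from the base LTR
    # (detectable at the 75% harvest floor, separable at the 90% clustering
    # bar) and, being independent draws, ~26% from each other; the diffuse
    # minor pool sits further out still (17-22% per copy).
    # Variant copy divergence 0.015 makes same-form ancestral copies ~3%
    # apart pairwise: close enough that an aligner cannot place their reads
    # uniquely, yet far enough that they never look recently amplified
    # (pairwise identity stays below the 0.99 activity bar).  Only the
    # Gret1-like dominant form is a truly identical (active) cohort.
    focal = [
        # name, superfamily, ltr_len, int_len, tsd, abundance,
        #   variant spec (weight, div_from_base, copy_div)
        ("Gret1", "Gypsy", 420, 2600, 5, 0.05,
         [(0.25, 0.00, 0.000), (0.18, 0.15, 0.015),
          (0.05, 0.15, 0.015), (0.03, 0.15, 0.015)]),
        ("Copia10", "Copia", 300, 2200, 5, 0.10,
         [(0.19, 0.00, 0.015), (0.07, 0.15, 0.015),
          (0.07, 0.15, 0.015), (0.03, 0.15, 0.015)]),
        ("Gypsy19", "Gypsy", 500, 2800, 5, 0.10,
         [(0.10, 0.00, 0.015)]),
        ("Cauliv1", "Caulimoviridae", 220, 2000, 5, 0.05,
         [(0.07, 0.00, 0.015)]),
    ]
    n_focal = min(n_families, 4) if n_families >= 4 else 0
    for name, sup, ltr_len, int_len, tsd, ab, vspec in focal[:n_focal]:
        base = random_seq(rng, ltr_len)
        fams.append(TEFamily(
            name=name, te_class="I", superfamily=sup, ltr_seq=base,
            internal_seq=random_seq(rng, int_len), tsd_len=tsd,
            subfamily_variants=_variants(rng, base, vspec),
            abundance=ab))

    i = len(fams)
    while len(fams) < n_families:
        i += 1
        if i % 3 == 0:
            fams.append(TEFamily(
                name=f"DTX{i}", te_class="II", superfamily="Mutator",
                ltr_seq="", internal_seq=random_seq(rng, 900),
                tsd_len=int(rng.integers(2, 9)),
                abundance=0.15, young_frac=0.5))
        elif i % 3 == 1:
            base = random_seq(rng, int(rng.integers(150, 600)))
            fams.append(TEFamily(
                name=f"RLX{i}", te_class="I",
                superfamily="Gypsy" if i % 2 else "Copia",
                ltr_seq=base, internal_seq=random_seq(rng, 1800),
                tsd_len=5, abundance=0.10, young_frac=0.3,
                subfamily_variants=_variants(
                    rng, base, [(float(rng.uniform(0.05, 0.3)), 0.0, 0.015)])))
        else:
            # LINE retrotransposons dominate the repeat landscape and carry
            # large young cohorts, as in real plant genomes
            fams.append(TEFamily(
                name=f"LINE{i}", te_class="I", superfamily="LINE",
                ltr_seq="", internal_seq=random_seq(rng, 2400),
                tsd_len=int(rng.integers(5, 16)),
                abundance=0.55, young_frac=0.8))
    return RepeatLibrary(fams[:n_families])


# ---------------------------------------------------------------------------
# Ancestral genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    exons: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class RepeatCopy:
    chrom: str
    start: int
    end: int
    family: str
    variant: str
    strand: str


@dataclass
class AncestralGenome:
    """The reference against which all clones are compared."""

    chromosomes: dict[str, str]
    genes: list[Gene]
    repeats: list[RepeatCopy]
    organelles: dict[str, str] = field(default_factory=dict)
    contaminants: dict[str, str] = field(default_factory=dict)
    # segmental duplications (paralogous regions): list of
    # (chrom_src, start_src, chrom_dst, start_dst, length)
    duplications: list[tuple[str, int, str, int, int]] = field(
        default_factory=list)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def total_len(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def exon_fraction(self) -> float:
        ex = sum(e - s for g in self.genes for (s, e) in g.exons)
        return ex / self.total_len()

    def repeat_fraction(self) -> float:
        rep = sum(r.end - r.start for r in self.repeats)
        return rep / self.total_len()


def _place_genes(rng, chrom, length, occupied, target_exon_bp):
    """Gene models (with exons) in repeat-free space until the exon target."""
    genes, exon_bp, attempts = [], 0, 0
    gi = 0
    while exon_bp < target_exon_bp and attempts < 20000:
        attempts += 1
        n_ex = int(rng.integers(2, 7))
        ex_lens = rng.integers(150, 400, size=n_ex)
        introns = rng.integers(200, 800, size=n_ex - 1)
        glen = int(ex_lens.sum() + introns.sum())
        if glen >= length:
            continue
        start = int(rng.integers(0, length - glen))
        end = start + glen
        if any(s < end and start < e for (s, e) in occupied):
            continue
        exons, pos = [], start
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += int(introns[j])
        gi += 1
        genes.append(Gene(f"{chrom}.g{gi}", chrom, start, end, tuple(exons)))
        occupied.append((start, end))
        exon_bp += int(ex_lens.sum())
    return genes


def build_ancestral_genome(n_chrom: int, chrom_len: int, repeat_fraction: float,
                           library: RepeatLibrary, seed: int,
                           exon_fraction: float = 0.069,
                           gc: float = 0.33,
                           dup_fraction: float = 0.08,
                           dup_divergence: float = 0.02) -> AncestralGenome:
    """Construct a repeat-rich ancestral reference.

    Chromosome lengths taper from ``chrom_len`` down to 60% of it so that
    per-chromosome aligned-base totals can be regressed on length.  Each
    chromosome carries one dense central repeat block (a centromere
    stand-in) plus dispersed TE copies — drawn by family abundance — up to
    ``repeat_fraction`` of bases, segmental duplications over
    ``dup_fraction`` of bases (paralogous regions, ~``dup_divergence``
    apart, the legacy of ancient polyploidy), and gene models with exons
    summing to ``exon_fraction`` of bases placed outside repeats.
    """
    if not 0 <= repeat_fraction <= 0.6:
        raise ValueError("repeat_fraction must be in [0, 0.6]")
    rng = np.random.default_rng(seed)
    chroms: dict[str, str] = {}
    genes: list[Gene] = []
    repeats: list[RepeatCopy] = []
    duplications: list[tuple[str, int, str, int, int]] = []

    fam_p = np.array([f.abundance for f in library.families], dtype=float)
    fam_p = fam_p / fam_p.sum()

    def draw_family():
        return library.families[int(rng.choice(len(fam_p), p=fam_p))]

    for ci in range(n_chrom):
        frac = 1.0 if n_chrom == 1 else 1.0 - 0.4 * ci / (n_chrom - 1)
        length = int(round(chrom_len * frac))
        name = f"chr{ci + 1}"
        seq = np.frombuffer(random_seq(rng, length, gc).encode(), dtype=np.uint8).copy()
        occupied: list[tuple[int, int]] = []
        rep_target = int(repeat_fraction * length)
        rep_bp = 0

        if rep_target > 0:
            # centromere stand-in: back-to-back copies over ~1/3 of the target
            cen_span = min(rep_target // 3, length // 10)
            cen_start = int(length * 0.5 - cen_span // 2)
            pos = cen_start
            while pos - cen_start < cen_span:
                fam = draw_family()
                copy, vname, strand = fam.make_copy(rng)
                end = min(pos + len(copy), length)
                seq[pos:end] = np.frombuffer(copy[: end - pos].encode(), dtype=np.uint8)
                repeats.append(RepeatCopy(name, pos, end, fam.name, vname, strand))
                rep_bp += end - pos
                pos = end
            occupied.append((cen_start, pos))

            attempts = 0
            while rep_bp < rep_target and attempts < 50000:
                attempts += 1
                fam = draw_family()
                copy, vname, strand = fam.make_copy(rng)
                if len(copy) >= length:
                    continue
                start = int(rng.integers(0, length - len(copy)))
                end = start + len(copy)
                if any(s < end and start < e for (s, e) in occupied):
                    continue
                seq[start:end] = np.frombuffer(copy.encode(), dtype=np.uint8)
                repeats.append(RepeatCopy(name, start, end, fam.name, vname, strand))
                occupied.append((start, end))
                rep_bp += len(copy)

        # segmental duplications: copy a background stretch elsewhere with
        # a little divergence -- reads in either copy become paralogous
        dup_target = int(dup_fraction * length)
        dup_bp = 0
        attempts = 0
        while dup_bp < dup_target and attempts < 20000:
            attempts += 1
            dlen = int(rng.integers(4000, 12000))
            if 2 * dlen >= length:
                break
            src = int(rng.integers(0, length - dlen))
            dst = int(rng.integers(0, length - dlen))
            s_iv, d_iv = (src, src + dlen), (dst, dst + dlen)
            if (abs(src - dst) < dlen
                    or any(s < s_iv[1] and s_iv[0] < e for (s, e) in occupied)
                    or any(s < d_iv[1] and d_iv[0] < e for (s, e) in occupied)):
                continue
            stretch = seq[src:src + dlen].tobytes().decode("ascii")
            mutated = mutate_substitutions(rng, stretch, dup_divergence)
            seq[dst:dst + dlen] = np.frombuffer(mutated.encode(), dtype=np.uint8)
            occupied.extend([s_iv, d_iv])
            duplications.append((name, src, name, dst, dlen))
            dup_bp += 2 * dlen

        genes.extend(_place_genes(rng, name, length, occupied,
                                  int(exon_fraction * length)))
        chroms[name] = seq.tobytes().decode("ascii")

    organelles = {
        "chloroplast": random_seq(rng, 20000, gc=0.37),
        "mitochondrion": random_seq(rng, 30000, gc=0.45),
    }
    contaminants = {
        "Scerevisiae_frag": random_seq(rng, 15000, gc=0.38),
        "Ecoli_frag": random_seq(rng, 15000, gc=0.50),
    }
    return AncestralGenome(chroms, genes,
                           sorted(repeats, key=lambda r: (r.chrom, r.start)),
                           organelles, contaminants, duplications)


def build_te_population_genome(family: TEFamily, n_copies: int, seed: int,
                               spacer_len: int = 300
                               ) -> tuple[dict[str, str], dict[str, int]]:
    """A genome fragment holding ``n_copies`` of one family's element.

    Copies are drawn by the family's subfamily-variant weights (the rest
    from the diffuse minor pool) and separated by random spacers; used to
    study the family's LTR-form structure at a chosen copy number.
    Returns the sequence (one contig) and the per-variant copy counts."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    # deterministic allocation: the variant weights are the study condition,
    # not something to re-draw per run
    alloc: list[LTRVariant | None] = []
    for v in family.subfamily_variants:
        alloc.extend([v] * int(round(v.weight * n_copies)))
    alloc.extend([None] * max(0, n_copies - len(alloc)))
    parts, counts = [], {}
    for variant in alloc[:n_copies]:
        copy, vname, _strand = family.make_copy(rng, variant=variant,
                                                force_minor=variant is None)
        counts[vname] = counts.get(vname, 0) + 1
        parts.append(copy)
        parts.append(random_seq(rng, spacer_len))
    return {f"{family.name}_pop": "".join(parts)}, counts


# ---------------------------------------------------------------------------
# Clone derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LedgerEntry:
    clone_id: str
    type: str  # SNP | INDEL | TE_INS
    chrom: str
    pos: int  # 0-based position on the *ancestor*
    detail: dict = field(compare=False, hash=False, default_factory=dict)


@dataclass
class MutationLedger:
    """Ground truth of every somatic mutation applied to a clone."""

    entries: list[LedgerEntry]

    def by_type(self, t: str) -> list[LedgerEntry]:
        return [e for e in self.entries if e.type == t]

    def to_rows(self):
        for e in sorted(self.entries, key=lambda e: (e.chrom, e.pos)):
            yield (e.clone_id, e.type, e.chrom, e.pos + 1,
                   e.detail.get("summary", ""))


@dataclass
class CloneGenome:
    """A clone's genome plus the piecewise map back to ancestor coordinates."""

    clone_id: str
    chromosomes: dict[str, str]
    organelles: dict[str, str] = field(default_factory=dict)
    contaminants: dict[str, str] = field(default_factory=dict)
    # per chromosome: sorted clone-coordinate breakpoints and the ancestor
    # offset (anc = clone + offset) valid from that breakpoint on
    _maps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_ancestor(self, chrom: str, clone_pos: int) -> int:
        """Ancestor coordinate of a clone position (nearest left anchor
        inside inserted material)."""
        if chrom not in self._maps:
            return clone_pos
        breaks, offs = self._maps[chrom]
        i = int(np.searchsorted(breaks, clone_pos, side="right")) - 1
        return clone_pos + int(offs[i])

    def total_len(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


def derive_clone(ancestor: AncestralGenome, snp_rate: float, indel_rate: float,
                 te_rate: float, library: RepeatLibrary, seed: int,
                 clone_id: str | None = None,
                 tsd: bool = True) -> tuple[CloneGenome, MutationLedger]:
    """Mutate the ancestor into a clone at the given per-Mb rates.

    Counts per chromosome are Poisson with mean ``rate * length / 1e6``;
    positions are uniform with a 10-bp separation floor so every event is
    recoverable independently.  TE insertions copy a library family (biased
    towards its dominant, currently active subfamily form), are inserted in
    random orientation and create a target-site duplication.
    """
    for r in (snp_rate, indel_rate, te_rate):
        if r < 0:
            raise ValueError("mutation rates must be >= 0")
    rng = np.random.default_rng(seed)
    clone_id = clone_id or f"clone{seed}"
    entries: list[LedgerEntry] = []

    for chrom, seq in ancestor.chromosomes.items():
        L = len(seq)
        mb = L / 1e6
        n_snp = rng.poisson(snp_rate * mb)
        n_ind = rng.poisson(indel_rate * mb)
        n_te = rng.poisson(te_rate * mb)
        taken: list[int] = []

        def draw_pos(margin: int = 20) -> int | None:
            for _ in range(200):
                p = int(rng.integers(margin, L - margin))
                if all(abs(p - q) >= 10 for q in taken):
                    taken.append(p)
                    return p
            return None

        for _ in range(n_snp):
            p = draw_pos()
            if p is None:
                continue
            ref = seq[p]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            entries.append(LedgerEntry(clone_id, "SNP", chrom, p,
                                       {"ref": ref, "alt": alt,
                                        "summary": f"{ref}>{alt}"}))
        for _ in range(n_ind):
            p = draw_pos()
            if p is None:
                continue
            ilen = int(rng.integers(1, 11))
            if rng.random() < 0.5:
                ins = random_seq(rng, ilen)
                entries.append(LedgerEntry(clone_id, "INDEL", chrom, p,
                                           {"ins": ins, "summary": f"+{ins}"}))
            else:
                entries.append(LedgerEntry(clone_id, "INDEL", chrom, p,
                                           {"del": seq[p:p + ilen],
                                            "summary": f"-{ilen}"}))
        for _ in range(n_te):
            p = draw_pos(margin=50)
            if p is None:
                continue
            fam = library.families[int(rng.integers(len(library.families)))]
            copy, vname, strand = fam.make_copy(rng, prefer_dominant=0.8,
                                                fresh=True)
            t = fam.tsd_len if tsd else 0
            entries.append(LedgerEntry(clone_id, "TE_INS", chrom, p,
                                       {"family": fam.name, "variant": vname,
                                        "strand": strand, "seq": copy, "tsd": t,
                                        "summary": f"{fam.name}:{vname}:{strand}"}))

    clone_chroms: dict[str, str] = {}
    maps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, seq in ancestor.chromosomes.items():
        evs = sorted((e for e in entries if e.chrom == chrom), key=lambda e: e.pos)
        parts: list[str] = []
        breaks, offs = [0], [0]
        prev = 0
        shift = 0  # clone = anc + shift so far
        for e in evs:
            p = e.pos
            if e.type == "SNP":
                parts.append(seq[prev:p])
                parts.append(e.detail["alt"])
                prev = p + 1
            elif e.type == "INDEL":
                if "ins" in e.detail:
                    ins = e.detail["ins"]
                    parts.append(seq[prev:p])
                    parts.append(ins)
                    prev = p
                    shift += len(ins)
                    breaks.append(p + shift)
                    offs.append(-shift)
                else:
                    dl = len(e.detail["del"])
                    parts.append(seq[prev:p])
                    prev = p + dl
                    shift -= dl
                    breaks.append(p + dl + shift)
                    offs.append(-shift)
            else:  # TE_INS with TSD duplication
                t = e.detail["tsd"]
                te = e.detail["seq"]
                parts.append(seq[prev:p + t])
                parts.append(te)
                prev = p
                shift += len(te) + t
                breaks.append(p + shift)
                offs.append(-shift)
        parts.append(seq[prev:])
        clone_chroms[chrom] = "".join(parts)
        maps[chrom] = (np.asarray(breaks, dtype=np.int64),
                       np.asarray(offs, dtype=np.int64))

    clone = CloneGenome(clone_id, clone_chroms,
                        organelles=ancestor.organelles,
                        contaminants=ancestor.contaminants,
                        _maps=maps)
    return clone, MutationLedger(entries)


def apply_ledger(ancestor: AncestralGenome, ledger: MutationLedger,
                 clone_id: str) -> dict[str, str]:
    """Re-apply a ledger to the ancestor (round-trip check helper)."""
    entries = [e for e in ledger.entries if e.clone_id == clone_id]
    out = {}
    for chrom, seq in ancestor.chromosomes.items():
        evs = sorted((e for e in entries if e.chrom == chrom), key=lambda e: e.pos)
        parts, prev = [], 0
        for e in evs:
            p = e.pos
            if e.type == "SNP":
                parts += [seq[prev:p], e.detail["alt"]]
                prev = p + 1
            elif e.type == "INDEL":
                if "ins" in e.detail:
                    parts += [seq[prev:p], e.detail["ins"]]
                    prev = p
                else:
                    parts.append(seq[prev:p])
                    prev = p + len(e.detail["del"])
            else:
                t = e.detail["tsd"]
                parts += [seq[prev:p + t], e.detail["seq"]]
                prev = p
        parts.append(seq[prev:])
        out[chrom] = "".join(parts)
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadProfile:
    """454 GS-FLX-like run profile.

    Lengths are Normal(mean, sd) truncated to [min, max]; quality decays
    linearly from ``q_start`` to ``q_end`` along the read (the defaults give
    a run-mean quality of ~30); substitutions
    occur at the per-base Phred rate 10^(-Q/10); homopolymer runs >= 3 bp
    gain or lose one base with probability ``homopolymer_rate`` per run;
    ``duplicate_frac`` of reads are exact emulsion-PCR duplicates;
    organelle and foreign-organism reads are spiked at the given fractions.
    """

    mean_len: float = 355.0
    sd_len: float = 60.0
    min_len: int = 60
    max_len: int = 700
    q_start: int = 36
    q_end: int = 24
    substitution_errors: bool = True
    homopolymer_rate: float = 0.02
    duplicate_frac: float = 0.0058
    organelle_frac: float = 0.038
    contaminant_frac: float = 1.3e-4

    def __post_init__(self):
        for name in ("homopolymer_rate", "duplicate_frac",
                     "organelle_frac", "contaminant_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def error_free(cls, **kw) -> "ReadProfile":
        """Clean reads: no errors, no duplicates, no spiked sequences."""
        base = dict(substitution_errors=False, homopolymer_rate=0.0,
                    duplicate_frac=0.0, organelle_frac=0.0,
                    contaminant_frac=0.0)
        base.update(kw)
        return cls(**base)


@dataclass(frozen=True)
class Provenance:
    clone_id: str
    chrom: str
    start: int  # on the clone genome (or organelle/contaminant sequence)
    strand: str
    category: str  # genomic | organelle | contaminant | duplicate


@dataclass
class ReadSet:
    """A set of reads with per-read true provenance."""

    ids: list[str]
    seqs: list[str]
    quals: list[str]
    provenance: dict[str, Provenance]

    def __len__(self):
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs, self.quals))

    def mean_length(self) -> float:
        return float(np.mean([len(s) for s in self.seqs]))

    def mean_quality(self) -> float:
        tot = sum(sum(q.encode()) - 33 * len(q) for q in self.quals)
        n = sum(len(q) for q in self.quals)
        return tot / n

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.provenance.values():
            out[p.category] = out.get(p.category, 0) + 1
        return out


def _qual_string(L: int, q_start: int, q_end: int, cache: dict) -> str:
    if L not in cache:
        q = np.rint(np.linspace(q_start, q_end, max(L, 2))[:L]).astype(int)
        cache[L] = "".join(chr(int(v) + 33) for v in np.clip(q, 2, 41))
    return cache[L]


def _apply_substitutions(rng, seq: str, qual: str) -> str:
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33
    p = 10 ** (-q / 10)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if len(hits) == 0:
        return seq
    b = list(seq)
    for i in hits:
        b[i] = BASES[(BASES.index(b[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(b)


def _apply_homopolymer_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    change = np.nonzero(np.diff(b) != 0)[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(b)]))
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= 3]
    if not runs:
        return seq
    edits = []
    for s, e in runs:
        if rng.random() < rate:
            edits.append((s, e, +1 if rng.random() < 0.5 else -1))
    if not edits:
        return seq
    out, prev = [], 0
    for s, e, d in edits:
        out.append(seq[prev:e + (d if d < 0 else 0)])
        if d > 0:
            out.append(seq[s])
        prev = e
    out.append(seq[prev:])
    return "".join(out)


def simulate_reads(genome: CloneGenome, n_reads: int, seed: int,
                   profile: ReadProfile | None = None) -> ReadSet:
    """Simulate a 454-like run from a clone genome.

    Reads are drawn uniformly from the genome (both strands), organelle and
    contaminant reads are spiked at the profile fractions, and a fraction of
    reads are exact duplicates of earlier reads (emulsion-PCR artefacts).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    profile = profile or ReadProfile()
    rng = np.random.default_rng(seed)

    chroms = list(genome.chromosomes)
    clens = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    cprob = clens / clens.sum()
    qcache: dict[int, str] = {}

    def pool(d: dict[str, str]):
        names = list(d)
        lens = np.array([len(d[n]) for n in names], dtype=float)
        return names, lens / lens.sum() if lens.sum() else lens

    org_names, org_prob = pool(genome.organelles) if genome.organelles else ([], None)
    con_names, con_prob = pool(genome.contaminants) if genome.contaminants else ([], None)

    lengths = rng.normal(profile.mean_len, profile.sd_len, size=n_reads)
    lengths = np.clip(np.rint(lengths), profile.min_len, profile.max_len).astype(int)
    u_cat = rng.random(n_reads)
    u_dup = rng.random(n_reads)

    ids, seqs, quals = [], [], []
    prov: dict[str, Provenance] = {}
    noisy = profile.substitution_errors or profile.homopolymer_rate > 0

    for i in range(n_reads):
        rid = f"{genome.clone_id}.r{i:07d}"
        if i > 0 and u_dup[i] < profile.duplicate_frac:
            j = int(rng.integers(0, i))
            src = prov[ids[j]]
            ids.append(rid)
            seqs.append(seqs[j])
            quals.append(quals[j])
            prov[rid] = Provenance(src.clone_id, src.chrom, src.start,
                                   src.strand, "duplicate")
            continue
        L = int(lengths[i])
        if org_names and u_cat[i] < profile.organelle_frac:
            src_pool, name_list, p, cat = genome.organelles, org_names, org_prob, "organelle"
        elif con_names and u_cat[i] < profile.organelle_frac + profile.contaminant_frac:
            src_pool, name_list, p, cat = genome.contaminants, con_names, con_prob, "contaminant"
        else:
            src_pool, name_list, p, cat = genome.chromosomes, chroms, cprob, "genomic"
        ci = int(rng.choice(len(name_list), p=p))
        cname = name_list[ci]
        src = src_pool[cname]
        if L >= len(src):
            L = len(src)
            start = 0
        else:
            start = int(rng.integers(0, len(src) - L + 1))
        seq = src[start:start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        qual = _qual_string(len(seq), profile.q_start, profile.q_end, qcache)
        if noisy:
            if profile.substitution_errors:
                seq = _apply_substitutions(rng, seq, qual)
            seq = _apply_homopolymer_errors(rng, seq, profile.homopolymer_rate)
            if len(seq) != len(qual):
                qual = _qual_string(len(seq), profile.q_start, profile.q_end, qcache)
        ids.append(rid)
        seqs.append(seq)
        quals.append(qual)
        prov[rid] = Provenance(genome.clone_id, cname, start, strand, cat)

    return ReadSet(ids, seqs, quals, prov)


def shear_assembly(assembly: dict[str, str], fragment_len: int = 1000,
                   seed: int = 0, min_keep: int = 100,
                   sample_id: str = "assembly") -> ReadSet:
    """Tile assembly contigs into fixed-length optimal-quality fragments.

    Contigs are cut into non-overlapping ``fragment_len`` pieces; a final
    piece shorter than ``min_keep`` is dropped.  All bases get the maximum
    quality symbol, emulating an assembly treated as if it were perfectly
    base-called read data.  ``seed`` is accepted for interface symmetry; the
    operation is deterministic.
    """
    if fragment_len < 100:
        raise ValueError("fragment_len must be >= 100")
    del seed
    ids, seqs, quals = [], [], []
    prov: dict[str, Provenance] = {}
    qmax = chr(41 + 33)
    i = 0
    for name, seq in assembly.items():
        for start in range(0, len(seq), fragment_len):
            frag = seq[start:start + fragment_len]
            if len(frag) < min_keep:
                continue
            rid = f"{sample_id}.f{i:07d}"
            i += 1
            ids.append(rid)
            seqs.append(frag)
            quals.append(qmax * len(frag))
            prov[rid] = Provenance(sample_id, name, start, "+", "genomic")
    if not ids:
        import warnings
        warnings.warn("shear_assembly: no fragments produced (empty assembly?)")
    return ReadSet(ids, seqs, quals, prov)
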