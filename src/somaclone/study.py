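"""Canonical study conditions and headline measurements.

These functions bundle the package's standard experiments — the 10-Mb
two-clone comparison, the per-family LTR-form populations, the multi-clone
S-SAP fingerprint panel and the replicate rate-calibration — so that the
reproduction script and the test suite measure exactly the same thing.
Every quantity returned is computed from a fresh simulation at call time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .covstats import RegionSet, window_correlations
from .evaluate import RecoveryMetrics, recovery_metrics
from .ltrdyn import cluster_forms, conserved_region_tree, harvest_ltr_segments
from .polycall import INDEL, SNP, TE_INSERTION, annotate_and_rates, call_pair
from .ssap import band_matrix, insilico_ssap, nei_li_matrix, nj_tree
from .synthdata import (CloneGenome, ReadProfile, build_ancestral_genome,
                        build_te_library, build_te_population_genome,
                        derive_clone, simulate_reads)
from .tieralign import TieredAligner, run_tiered_alignment

#: somatic divergence rates of the default study, events per Mb
DEFAULT_RATES = (1.6, 5.1, 35.2)


@dataclass
class ClonePairStudy:
    genome_mb: float
    n_reads_per_clone: int
    classification_pct: dict[str, dict[str, float]]  # per clone
    classification_pct_sum: float
    repeat_plus_paralog_pct: float
    shared_mb: float
    shared_pct_of_genome: float
    recovery: dict[str, RecoveryMetrics]
    measured_rates_per_mb: dict[str, float]
    repeat_corr_r: float
    repeat_corr_p: float
    chrom_length_r2: float
    total_calls: int


def clone_pair_study(seed: int, total_mb: float = 10.0, coverage: float = 12.0,
                     repeat_fraction: float = 0.30, n_chrom: int = 4,
                     rates: tuple[float, float, float] = DEFAULT_RATES,
                     corr_window: int = 50_000) -> ClonePairStudy:
    """The central experiment: two clones of a repeat-rich ancestor,
    clean reads deep enough for >=6x over more than half the genome,
    full tiered alignment, pairwise calling and ledger scoring.

    ``total_mb`` is split over ``n_chrom`` chromosomes tapering to 60% of
    the longest, so chromosome-length regressions are meaningful."""
    taper = np.linspace(1.0, 0.6, n_chrom)
    chrom_len = int(round(total_mb * 1e6 / taper.sum()))
    library = build_te_library(6, seed=seed)
    ancestor = build_ancestral_genome(n_chrom, chrom_len, repeat_fraction,
                                      library, seed=seed + 1)
    genome = ancestor.total_len()
    n_reads = int(genome * coverage / 355)
    aligner = TieredAligner(ancestor.chromosomes, library)

    ledgers, results = [], []
    for i, cid in enumerate(("A", "B")):
        clone, ledger = derive_clone(ancestor, *rates, library,
                                     seed=seed + 10 + i, clone_id=cid)
        reads = simulate_reads(clone, n_reads, seed=seed + 100 + i,
                               profile=ReadProfile.error_free())
        res = run_tiered_alignment(reads, ancestor.chromosomes, library,
                                   ancestor.organelles, ancestor.contaminants,
                                   aligner=aligner)
        ledgers.append(ledger)
        results.append(res)

    pct = {cid: res.summary.percentages()
           for cid, res in zip(("A", "B"), results)}
    pct_sum = sum(pct["A"].values())
    rp = np.mean([p.get("REPEAT", 0) + p.get("PARALOG", 0)
                  for p in pct.values()])

    calls, shared, _, _ = call_pair(results[0].records, results[1].records,
                                    ancestor.chromosomes, "A", "B")
    rec = recovery_metrics(ledgers, calls, shared)
    rates_rep = annotate_and_rates(calls, ancestor.genes, shared, ("A", "B"))

    rep_regions = RegionSet({c: [(r.start, r.end) for r in ancestor.repeats
                                 if r.chrom == c]
                             for c in ancestor.chromosomes})
    corr = window_correlations(results[0].records, rep_regions,
                               ancestor.chrom_lengths(), window=corr_window)

    return ClonePairStudy(
        genome_mb=genome / 1e6,
        n_reads_per_clone=n_reads,
        classification_pct=pct,
        classification_pct_sum=pct_sum,
        repeat_plus_paralog_pct=float(rp),
        shared_mb=shared.span / 1e6,
        shared_pct_of_genome=100.0 * shared.span / genome,
        recovery=rec,
        measured_rates_per_mb=rates_rep.rates_per_mb,
        repeat_corr_r=corr.repeat_r,
        repeat_corr_p=corr.repeat_p,
        chrom_length_r2=corr.length_r2,
        total_calls=len(calls),
    )


@dataclass
class LTRFormStudy:
    family: str
    n_segments: int
    n_major_forms: int
    major_pct: float
    minor_pct: float
    major_form_pcts: list[float]
    recent_activity: bool
    max_clique: int


def ltr_form_study(seed: int, n_copies: int = 500,
                   coverage: float = 0.75,
                   families: tuple[str, ...] = ("Gret1", "Copia10",
                                                "Gypsy19", "Cauliv1")
                   ) -> dict[str, LTRFormStudy]:
    """Per-family LTR-form landscape at the family's copy weights."""
    library = build_te_library(4, seed=7)
    out = {}
    for fname in families:
        fam = library.get(fname)
        chroms, _counts = build_te_population_genome(fam, n_copies,
                                                     seed=seed)
        pop = CloneGenome("pop", chroms)
        n = max(100, int(sum(map(len, chroms.values())) * coverage / 355))
        reads = simulate_reads(pop, n, seed=seed + 1,
                               profile=ReadProfile.error_free())
        segs = harvest_ltr_segments(reads, fam)
        _clusters, summary = cluster_forms(segs, family=fname)
        cr = conserved_region_tree(segs, ltr_len=len(fam.ltr_seq), seed=seed)
        out[fname] = LTRFormStudy(
            family=fname, n_segments=len(segs),
            n_major_forms=summary.n_major_forms,
            major_pct=100.0 * summary.major_proportion,
            minor_pct=100.0 * summary.minor_proportion,
            major_form_pcts=[100.0 * p for p in summary.major_proportions],
            recent_activity=cr.recent_activity,
            max_clique=cr.max_clique)
    return out


@dataclass
class SSAPStudy:
    n_clones: int
    n_clones_with_private_insertion: int
    all_informative_patterns_unique: bool
    n_bands: int
    pct_polymorphic: float
    mean_pairwise_distance: float
    max_bootstrap_support: float


def ssap_pattern_study(seed: int, n_clones: int = 8,
                       genome_kb: int = 400,
                       bootstrap: int = 200) -> SSAPStudy:
    """Multi-clone S-SAP fingerprint panel on clone genome sequences.

    Each clone derives independently from one ancestor at the default
    rates; banding uses the four focal LTR families.  The headline check:
    clones that carry at least one private insertion of a banding-capable
    form have pairwise-distinct fingerprints."""
    library = build_te_library(4, seed=7)
    ancestor = build_ancestral_genome(2, genome_kb * 1000 // 2, 0.15,
                                      library, seed=seed + 1)
    fams = [f for f in library if f.ltr_seq]
    band_sets, informative = {}, []
    for i in range(n_clones):
        cid = f"PN{i + 1:02d}"
        clone, ledger = derive_clone(ancestor, *DEFAULT_RATES, library,
                                     seed=seed + 20 + i, clone_id=cid)
        bands = set()
        for fam in fams:
            bands |= insilico_ssap(clone, fam)
        band_sets[cid] = bands
        # banding-capable private insertion: dominant form of an LTR family
        has_banding_ins = any(
            e.type == "TE_INS" and e.detail.get("variant") == "LTR1"
            for e in ledger.entries)
        if has_banding_ins:
            informative.append(cid)
    bm = band_matrix(band_sets)
    rows = {cid: tuple(bm.row(cid)) for cid in informative}
    unique = len(set(rows.values())) == len(rows)
    dm = nei_li_matrix(bm)
    tree = nj_tree(dm, bootstrap=bootstrap, seed=seed, bm=bm)
    support = max(tree.support.values()) if tree.support else float("nan")
    n = len(bm.samples)
    mean_d = float(np.sum(dm.data) / (n * (n - 1)))
    return SSAPStudy(
        n_clones=n_clones,
        n_clones_with_private_insertion=len(informative),
        all_informative_patterns_unique=unique,
        n_bands=bm.n_bands,
        pct_polymorphic=bm.pct_polymorphic,
        mean_pairwise_distance=mean_d,
        max_bootstrap_support=support)


@dataclass
class RateCalibration:
    n_replicates: int
    simulated: dict[str, float]
    mean_measured: dict[str, float]
    se_measured: dict[str, float]

    def within(self, n_se: float = 3.0) -> bool:
        return all(abs(self.mean_measured[t] - self.simulated[t])
                   <= n_se * max(self.se_measured[t], 1e-9)
                   for t in self.simulated)


def rate_calibration(seed: int, n_replicates: int = 20,
                     chrom_len: int = 150_000, coverage: float = 10.0,
                     rates: tuple[float, float, float] = DEFAULT_RATES
                     ) -> RateCalibration:
    """Replicate clone pairs scoring the per-Mb rate estimator.

    Each replicate simulates a fresh small ancestor and clone pair, runs
    the full pipeline and measures calls per shared Mb; the estimator is
    unbiased when the replicate mean matches the simulated rates."""
    per_rep = {SNP: [], INDEL: [], TE_INSERTION: []}
    for r in range(n_replicates):
        library = build_te_library(6, seed=seed + r)
        ancestor = build_ancestral_genome(2, chrom_len, 0.12, library,
                                          seed=seed + 1000 + r,
                                          dup_fraction=0.03)
        n_reads = int(ancestor.total_len() * coverage / 355)
        results = []
        ledgers = []
        aligner = TieredAligner(ancestor.chromosomes, library)
        for i, cid in enumerate(("A", "B")):
            clone, ledger = derive_clone(ancestor, *rates, library,
                                         seed=seed + 10 + 2 * r + i,
                                         clone_id=cid)
            reads = simulate_reads(clone, n_reads,
                                   seed=seed + 100 + 2 * r + i,
                                   profile=ReadProfile.error_free())
            res = run_tiered_alignment(reads, ancestor.chromosomes, library,
                                       aligner=aligner)
            results.append(res)
            ledgers.append(ledger)
        calls, shared, _, _ = call_pair(results[0].records,
                                        results[1].records,
                                        ancestor.chromosomes, "A", "B")
        mb = shared.span / 1e6
        if mb <= 0:
            continue
        for t in per_rep:
            per_rep[t].append(sum(c.type == t for c in calls) / mb)
    # both clones mutate independently, so a pair accumulates 2x each rate
    simulated = {SNP: 2 * rates[0], INDEL: 2 * rates[1],
                 TE_INSERTION: 2 * rates[2]}
    mean = {t: float(np.mean(v)) for t, v in per_rep.items()}
    se = {t: float(np.std(v, ddof=1) / np.sqrt(len(v)))
          for t, v in per_rep.items()}
    return RateCalibration(len(per_rep[SNP]), simulated, mean, se)


# ---------------------------------------------------------------------------
# Desk-scale arithmetic over printed run summaries
# ---------------------------------------------------------------------------

def total_aligned_pct(step_pcts: dict[str, float]) -> float:
    """Total aligned percentage from per-step alignment percentages."""
    return float(sum(step_pcts.values()))


def major_form_total_pct(form_pcts: list[float]) -> float:
    """Summed share of the major LTR forms (percent of harvested LTRs)."""
    return float(sum(form_pcts))


def minor_form_pct(form_pcts: list[float]) -> float:
    """Minor-form share as the complement of the major forms."""
    return 100.0 - major_form_total_pct(form_pcts)


def mean_read_length(run_lengths: list[float]) -> float:
    """Mean read length across sequencing runs."""
    return float(np.mean(run_lengths))


def summary_asdict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return d
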