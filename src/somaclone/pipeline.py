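"""End-to-end orchestration: simulate -> mask/align -> coverage -> call ->
S-SAP -> LTR dynamics, with manifests and report tables.

A run is driven by a :class:`RunConfig` (YAML-loadable, every parameter has
a default, unknown keys are rejected).  All artefacts are plain text
(FASTA/FASTQ/GFF3/BED/TSV/JSON) and a fixed seed reproduces every file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .covstats import (composition_stats, depth_profile, reference_composition,
                       regions_at_depth, RegionSet, shared_regions,
                       window_correlations)
from .evaluate import recovery_metrics
from .ltrdyn import cluster_forms, conserved_region_tree, harvest_ltr_segments
from .polycall import annotate_and_rates, call_pair
from .repeatmask import Masker
from .ssap import band_matrix, insilico_ssap, nei_li_matrix, nj_tree
from .synthdata import (build_ancestral_genome, build_te_library,
                        build_te_population_genome, CloneGenome, derive_clone,
                        ReadProfile, simulate_reads)
from .tieralign import TieredAligner, run_tiered_alignment

log = logging.getLogger("somaclone")


@dataclass
class RunConfig:
    """All knobs of a synthetic end-to-end run."""

    outdir: str = "somaclone_run"
    seed: int = 1
    # genome
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    repeat_fraction: float = 0.15
    n_te_families: int = 6
    # clones
    clone_ids: list[str] = field(default_factory=lambda: ["PN-A", "PN-B"])
    snp_per_mb: float = 1.6
    indel_per_mb: float = 5.1
    te_per_mb: float = 35.2
    # reads
    coverage: float = 10.0
    error_free_reads: bool = True
    # calling
    min_depth: int = 6
    maf: float = 0.3
    min_qual: int = 60
    # statistics / outputs
    corr_window: int = 50_000
    write_depth_bedgraph: bool = False
    # ssap / ltr
    ssap_enzyme: str = "TTAA"
    ssap_bootstrap: int = 200
    ltr_copies: int = 500
    ltr_coverage: float = 0.75

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if len(self.clone_ids) < 2:
            raise ValueError("need at least two clones")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class RunReport:
    table1: pd.DataFrame  # read classification percentages per clone
    table2: pd.DataFrame  # coverage tiers per clone + common regions
    table3: pd.DataFrame  # composition per clone + reference
    table4: pd.DataFrame  # LTR form summary per family
    pair_counts: pd.DataFrame  # polymorphism counts per pair and type
    rates: pd.DataFrame  # per-Mb rates per pair
    extras: dict = field(default_factory=dict)

    @property
    def total_polymorphic_sites(self) -> int:
        return int(self.pair_counts[["SNP", "INDEL", "TE_INSERTION"]]
                   .to_numpy().sum())

    @property
    def n_ssr_calls(self) -> int:
        return int(self.pair_counts.get("SSR", pd.Series(dtype=int)).sum())


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic analysis described by ``config``."""
    config.validate()
    t_start = time.time()
    out = sio.ensure_dir(config.outdir)
    rng = np.random.default_rng(config.seed)
    stage_times = {}

    def stage(name):
        stage_times[name] = time.time() - t_start
        log.info("stage %s at +%.1fs", name, stage_times[name])

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    library = build_te_library(config.n_te_families, seed=config.seed)
    ancestor = build_ancestral_genome(config.n_chrom, config.chrom_len,
                                      config.repeat_fraction, library,
                                      seed=config.seed + 1)
    sio.write_fasta(out / "reference.fa", ancestor.chromosomes)
    sio.write_fasta(out / "te_library.fa", library.mask_sequences())
    sio.write_gff3(out / "genes.gff3", ancestor)
    sio.write_repeat_bed(out / "repeats.bed", ancestor)

    profile = (ReadProfile.error_free() if config.error_free_reads
               else ReadProfile())
    n_reads = int(ancestor.total_len() * config.coverage / profile.mean_len)
    clones, ledgers, readsets = [], [], []
    for i, cid in enumerate(config.clone_ids):
        clone, ledger = derive_clone(
            ancestor, config.snp_per_mb, config.indel_per_mb,
            config.te_per_mb, library, seed=config.seed + 10 + i,
            clone_id=cid)
        reads = simulate_reads(clone, n_reads,
                               seed=config.seed + 100 + i, profile=profile)
        clones.append(clone)
        ledgers.append(ledger)
        readsets.append(reads)
        sio.write_ledger(out / f"{cid}.ledger.tsv", ledger)
        sio.write_fastq(out / f"{cid}.reads.fastq", reads)

    # --- mask + align -----------------------------------------------------
    stage("align")
    aligner = TieredAligner(ancestor.chromosomes, library)
    results = []
    t1_rows = {}
    for cid, reads in zip(config.clone_ids, readsets):
        res = run_tiered_alignment(reads, ancestor.chromosomes, library,
                                   ancestor.organelles, ancestor.contaminants,
                                   aligner=aligner)
        results.append(res)
        t1_rows[cid] = res.summary.percentages()
        sio.write_tsv(out / f"{cid}.aln.tsv",
                      ((r.read_id, r.chrom, r.ref_start + 1, r.strand,
                        r.cigar, r.mapq, r.step, r.masked_bases,
                        r.te_family or ".") for r in res.records),
                      header=["read", "chrom", "pos1", "strand", "cigar",
                              "mapq", "step", "masked", "family"])
    cats = sorted({k for row in t1_rows.values() for k in row})
    table1 = pd.DataFrame({cid: {c: row.get(c, 0.0) for c in cats}
                           for cid, row in t1_rows.items()}).round(2)

    # --- coverage ---------------------------------------------------------
    stage("coverage")
    profiles = [depth_profile([r for r in res.records], ancestor.chromosomes)
                for res in results]
    if config.write_depth_bedgraph:
        for cid, prof in zip(config.clone_ids, profiles):
            sio.write_bedgraph(out / f"{cid}.depth.bedgraph", prof.depth)
    tiers = range(1, config.min_depth + 1)
    t2 = {}
    for cid, prof in zip(config.clone_ids, profiles):
        t2[cid] = {f">={k}x": regions_at_depth(prof, k).span / 1e6
                   for k in tiers}
    common = {}
    for k in tiers:
        sets = [regions_at_depth(p, k) for p in profiles]
        acc = sets[0]
        for s in sets[1:]:
            acc = shared_regions(acc, s)
        common[f">={k}x"] = acc.span / 1e6
    t2["common"] = common
    table2 = pd.DataFrame(t2).round(3)

    t3 = {}
    for cid, res in zip(config.clone_ids, results):
        comp = composition_stats(res.records, ancestor.chromosomes,
                                 ancestor.genes)
        t3[cid] = dict(comp.rows())
    t3["reference"] = dict(reference_composition(ancestor).rows())
    table3 = pd.DataFrame(t3)

    rep_regions = RegionSet({c: [(r.start, r.end) for r in ancestor.repeats
                                 if r.chrom == c]
                             for c in ancestor.chromosomes})
    corr = window_correlations(results[0].records, rep_regions,
                               ancestor.chrom_lengths(),
                               window=config.corr_window)

    # --- polymorphism calling per pair -----------------------------------
    stage("call")
    pair_rows, rate_rows, all_metrics = [], [], {}
    for i in range(len(clones)):
        for j in range(i + 1, len(clones)):
            a, b = config.clone_ids[i], config.clone_ids[j]
            calls, shared, _, _ = call_pair(
                results[i].records, results[j].records, ancestor.chromosomes,
                a, b, min_depth=config.min_depth, maf=config.maf,
                min_qual=config.min_qual)
            rep = annotate_and_rates(calls, ancestor.genes, shared, (a, b))
            pair_rows.append({"pair": f"{a}x{b}", **rep.counts,
                              "shared_mb": round(rep.shared_mb, 3)})
            rate_rows.append({"pair": f"{a}x{b}",
                              **{k: round(v, 2)
                                 for k, v in rep.rates_per_mb.items()}})
            sio.write_tsv(out / f"calls.{a}x{b}.tsv",
                          ((c.type, c.chrom, c.pos + 1, c.carrier, c.detail,
                            c.depth_a, c.depth_b, c.quality,
                            c.gene_id or ".",
                            "LOWCONF" if c.low_confidence else ".")
                           for c in calls),
                          header=["type", "chrom", "pos1", "carrier",
                                  "detail", "depth_a", "depth_b", "qual",
                                  "gene", "flag"])
            all_metrics[f"{a}x{b}"] = recovery_metrics(
                [ledgers[i], ledgers[j]], calls, shared)
    pair_counts = pd.DataFrame(pair_rows).set_index("pair")
    rates = pd.DataFrame(rate_rows).set_index("pair")

    # --- S-SAP ------------------------------------------------------------
    stage("ssap")
    ltr_fams = [f for f in library if f.ltr_seq][:4]
    band_sets = {}
    for cid, clone in zip(config.clone_ids, clones):
        bands = set()
        for fam in ltr_fams:
            bands |= insilico_ssap(clone, fam, enzyme_site=config.ssap_enzyme)
        band_sets[cid] = bands
    bm = band_matrix(band_sets)
    bm.df.to_csv(out / "ssap_bands.tsv", sep="\t")
    tree = None
    if len(config.clone_ids) >= 3:
        dm = nei_li_matrix(bm)
        tree = nj_tree(dm, bootstrap=config.ssap_bootstrap,
                       seed=config.seed, bm=bm)
        (out / "ssap_tree.nwk").write_text(tree.newick() + "\n")

    # --- LTR dynamics -----------------------------------------------------
    stage("ltr")
    t4_rows = []
    activity = {}
    for fam in ltr_fams:
        chroms, _counts = build_te_population_genome(
            fam, config.ltr_copies, seed=config.seed + 7)
        pop = CloneGenome("pop", chroms)
        n = max(100, int(sum(map(len, chroms.values()))
                         * config.ltr_coverage / profile.mean_len))
        reads = simulate_reads(pop, n, seed=config.seed + 8,
                               profile=ReadProfile.error_free())
        segs = harvest_ltr_segments(reads, fam)
        if not segs:
            continue
        _clusters, summary = cluster_forms(segs, family=fam.name)
        cr = conserved_region_tree(segs, ltr_len=len(fam.ltr_seq),
                                   seed=config.seed)
        activity[fam.name] = cr.recent_activity
        row = {"family": fam.name, "n_major": summary.n_major_forms,
               "major_pct": round(100 * summary.major_proportion, 1),
               "minor_pct": round(100 * summary.minor_proportion, 1),
               "recent_activity": cr.recent_activity}
        for k, p in enumerate(summary.major_proportions[:4], 1):
            row[f"LTR{k}_pct"] = round(100 * p, 1)
        t4_rows.append(row)
    table4 = pd.DataFrame(t4_rows).set_index("family") if t4_rows \
        else pd.DataFrame()

    # --- report + manifest ------------------------------------------------
    stage("report")
    report = RunReport(table1, table2, table3, table4, pair_counts, rates,
                       extras={"window_correlation": dataclasses.asdict(corr),
                               "recovery": {
                                   p: {t: {"recall": m.recall,
                                           "precision": m.precision}
                                       for t, m in mm.items()}
                                   for p, mm in all_metrics.items()},
                               "ssap_pct_polymorphic": bm.pct_polymorphic,
                               "ssap_patterns_unique": bm.patterns_unique(),
                               "activity": activity})
    for name, df in (("table1", table1), ("table2", table2),
                     ("table3", table3), ("table4", table4),
                     ("pair_counts", pair_counts), ("rates", rates)):
        df.to_csv(out / f"report_{name}.tsv", sep="\t")
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "files": {p.name: _sha(p) for p in sorted(out.iterdir())
                  if p.is_file() and not p.name.startswith("manifest")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    del rng
    return report


def make_report(pair_counts: pd.DataFrame,
                shared_mb: "pd.Series | None" = None) -> dict:
    """Aggregate per-pair call counts into the headline summary.

    ``pair_counts`` must have one row per clone pair with columns per call
    type (``SNP``/``INDEL``/``TE_INSERTION``, optionally ``SSR``).  Returns
    totals, per-Mb rates (if ``shared_mb`` is given) and the SSR flag
    (expected zero: simple-sequence-repeat slippage is not part of the
    somatic mutation model)."""
    types = [c for c in ("SSR", "SNP", "INDEL", "TE_INSERTION")
             if c in pair_counts.columns]
    totals = {t: int(pair_counts[t].sum()) for t in types}
    out = {"counts": totals,
           "total_sites": int(sum(totals.values())),
           "n_ssr": int(totals.get("SSR", 0))}
    if shared_mb is not None:
        rates = {t: (pair_counts[t] / shared_mb).mean() for t in types}
        out["mean_rate_per_mb"] = {t: float(r) for t, r in rates.items()}
        out["sd_rate_per_mb"] = {
            t: float((pair_counts[t] / shared_mb).std(ddof=1))
            for t in types}
    return out
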