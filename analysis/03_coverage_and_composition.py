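#!/usr/bin/env python
"""Step 3 — coverage tiers, shared regions, composition and correlations.

From the saved alignments: per-clone coverage at 1-6x, the territory every
clone covers at each tier, GC/CpG/CnG/exon composition of aligned reads,
and the two placement-structure statistics (repeat-window depletion and
the chromosome-length regression).
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "cfg", Path(__file__).with_name("00_config.py"))
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from somaclone import io as sio
from somaclone.covstats import (RegionSet, composition_stats, depth_profile,
                                reference_composition, regions_at_depth,
                                shared_regions, window_correlations)
from somaclone.synthdata import build_ancestral_genome, build_te_library


def main():
    data = cfg.DATA
    ref = sio.read_fasta(data / "reference.fa")
    lib = build_te_library(6, seed=cfg.SEED)
    anc = build_ancestral_genome(cfg.N_CHROM, cfg.CHROM_LEN,
                                 cfg.REPEAT_FRACTION, lib, seed=cfg.SEED + 1)
    records = {cid: sio.read_alignments(data / f"{cid}.aln.tsv")
               for cid in cfg.CLONES}
    profiles = {cid: depth_profile(r, ref) for cid, r in records.items()}

    tiers = {}
    for cid, prof in profiles.items():
        tiers[cid] = {f">={k}x": regions_at_depth(prof, k).span / 1e6
                      for k in range(1, 7)}
    common = {}
    for k in range(1, 7):
        acc = None
        for prof in profiles.values():
            rs = regions_at_depth(prof, k)
            acc = rs if acc is None else shared_regions(acc, rs)
        common[f">={k}x"] = acc.span / 1e6
    tiers["common"] = common
    t2 = pd.DataFrame(tiers).round(3)
    t2.to_csv(cfg.RESULTS / "03_coverage_tiers_mb.tsv", sep="\t")
    print("Coverage (Mb) by minimum depth:")
    print(t2)

    comp = {cid: dict(composition_stats(r, ref, anc.genes).rows())
            for cid, r in records.items()}
    comp["reference"] = dict(reference_composition(anc).rows())
    t3 = pd.DataFrame(comp)
    t3.to_csv(cfg.RESULTS / "03_composition.tsv", sep="\t")
    print("\nComposition of aligned reads vs reference:")
    print(t3)

    rep_regions = RegionSet({c: [(r.start, r.end) for r in anc.repeats
                                 if r.chrom == c] for c in ref})
    corr = window_correlations(records[cfg.CLONES[0]], rep_regions,
                               {c: len(s) for c, s in ref.items()},
                               window=50_000)
    pd.DataFrame([{"repeat_r": corr.repeat_r, "repeat_p": corr.repeat_p,
                   "length_r2": corr.length_r2,
                   "n_windows": corr.n_windows}]) \
        .to_csv(cfg.RESULTS / "03_correlations.tsv", sep="\t", index=False)
    print(f"\nRepeat-window correlation r={corr.repeat_r:.3f} "
          f"(p={corr.repeat_p:.2e}); chromosome-length R2="
          f"{corr.length_r2:.3f}")


if __name__ == "__main__":
    sys.exit(main())
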