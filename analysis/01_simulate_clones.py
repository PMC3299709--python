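#!/usr/bin/env python
"""Step 1 — fabricate the study inputs.

Builds the mobile-element library, a repeat-rich ancestral reference with
gene annotation, three somatically diverged clones (with their ground-truth
mutation ledgers) and a clean 454-style run per clone.  Everything lands
under results/data/.
"""

import importlib.util
import sys
import time
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "cfg", Path(__file__).with_name("00_config.py"))
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from somaclone import io as sio
from somaclone.synthdata import (ReadProfile, build_ancestral_genome,
                                 build_te_library, derive_clone,
                                 simulate_reads)


def main():
    t0 = time.time()
    out = sio.ensure_dir(cfg.DATA)
    lib = build_te_library(6, seed=cfg.SEED)
    anc = build_ancestral_genome(cfg.N_CHROM, cfg.CHROM_LEN,
                                 cfg.REPEAT_FRACTION, lib,
                                 seed=cfg.SEED + 1)
    sio.write_fasta(out / "reference.fa", anc.chromosomes)
    sio.write_fasta(out / "te_library.fa", lib.mask_sequences())
    sio.write_fasta(out / "organelles.fa", anc.organelles)
    sio.write_fasta(out / "contaminants.fa", anc.contaminants)
    sio.write_gff3(out / "genes.gff3", anc)
    sio.write_repeat_bed(out / "repeats.bed", anc)

    n_reads = int(anc.total_len() * cfg.COVERAGE / 355)
    for i, cid in enumerate(cfg.CLONES):
        clone, ledger = derive_clone(anc, *cfg.RATES, lib,
                                     seed=cfg.SEED + 10 + i, clone_id=cid)
        reads = simulate_reads(clone, n_reads, seed=cfg.SEED + 100 + i,
                               profile=ReadProfile.error_free())
        sio.write_ledger(out / f"{cid}.ledger.tsv", ledger)
        sio.write_fastq(out / f"{cid}.reads.fastq", reads)
        n_events = len(ledger.entries)
        print(f"{cid}: {n_reads} reads, {n_events} true somatic events "
              f"(ledger written)")
    print(f"Reference: {anc.total_len() / 1e6:.2f} Mb, "
          f"{anc.repeat_fraction() * 100:.1f}% repeat, "
          f"{anc.exon_fraction() * 100:.1f}% exon, "
          f"{len(anc.duplications)} segmental duplications "
          f"[{time.time() - t0:.0f}s]")


if __name__ == "__main__":
    sys.exit(main())
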