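"""Readers and writers for the standard formats the pipeline exchanges.

In-memory coordinates are 0-based half-open; GFF3 and the ledger TSV use
1-based inclusive coordinates, BED/BEDGraph stay 0-based half-open, FASTQ
qualities are Sanger Phred+33.  FASTA/FASTQ parsing goes through Biopython;
the writers are plain text emitters.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .synthdata import (AncestralGenome, MutationLedger, Provenance, ReadSet)


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: ReadSet) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> ReadSet:
    ids, seqs, quals = [], [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        quals.append("".join(chr(q + 33) for q in
                             rec.letter_annotations["phred_quality"]))
    prov = {i: Provenance("?", "?", -1, "?", "unknown") for i in ids}
    return ReadSet(ids, seqs, quals, prov)


def write_gff3(path, genome: AncestralGenome) -> None:
    """Gene/exon annotation, 1-based inclusive per the GFF3 spec."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in genome.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(f"{g.chrom}\tsomaclone\tgene\t{g.start + 1}\t{g.end}\t.\t+\t."
                     f"\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsomaclone\texon\t{s + 1}\t{e}\t.\t+\t."
                         f"\tID={g.gene_id}.e{i};Parent={g.gene_id}\n")


def write_repeat_bed(path, genome: AncestralGenome) -> None:
    with open(path, "w") as fh:
        for r in genome.repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}:{r.variant}"
                     f"\t0\t{r.strand}\n")


def write_ledger(path, ledger: MutationLedger) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\ttype\tchrom\tpos1\tdetail\n")
        for row in ledger.to_rows():
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(path, depth_by_chrom: dict) -> None:
    """Per-base depth as BEDGraph (0-based half-open, runs collapsed)."""
    import numpy as np
    with open(path, "w") as fh:
        for chrom, d in depth_by_chrom.items():
            if len(d) == 0:
                continue
            change = np.nonzero(np.diff(d))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                v = int(d[s])
                if v:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_bed(path, regions_by_chrom: dict[str, list[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in regions_by_chrom.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_tsv(path, rows, header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


ALN_COLUMNS = ["read_id", "chrom", "pos1", "strand", "cigar", "mapq", "step",
               "identity", "masked", "family", "junction1", "side", "dup",
               "seq"]


def write_alignments(path, records) -> None:
    """Full-fidelity TSV of alignment records (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ALN_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(map(str, (
                r.read_id, r.chrom, r.ref_start + 1, r.strand, r.cigar,
                r.mapq, r.step, f"{r.identity:.5f}", r.masked_bases,
                r.te_family or ".",
                r.junction + 1 if r.junction is not None else ".",
                r.junction_side or ".", int(r.is_duplicate), r.seq))) + "\n")


def read_alignments(path) -> list:
    """Reload alignment records written by :func:`write_alignments`."""
    from .tieralign import AlignmentRecord
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == ALN_COLUMNS, "unexpected alignment file schema"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(AlignmentRecord(
                read_id=f[0], chrom=f[1], ref_start=int(f[2]) - 1,
                strand=f[3], cigar=f[4], mapq=int(f[5]), step=int(f[6]),
                identity=float(f[7]), n_candidate_loci=1,
                read_len=len(f[13]), q_start=0, q_end=len(f[13]),
                masked_bases=int(f[8]),
                te_family=None if f[9] == "." else f[9],
                junction=None if f[10] == "." else int(f[10]) - 1,
                junction_side=None if f[11] == "." else f[11],
                is_duplicate=bool(int(f[12])), seq=f[13]))
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
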