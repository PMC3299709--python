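"""Shared settings for the numbered analysis steps.

A deliberately small instance of the study (1.6 Mb over two chromosomes,
three clones, clean 10x reads) so that the whole sequence of scripts runs
in a few minutes; the acceptance script runs the full-size version.
"""

from pathlib import Path

SEED = 20120312
N_CHROM = 2
CHROM_LEN = 1_000_000  # tapering chromosomes: 1.0 Mb + 0.6 Mb
REPEAT_FRACTION = 0.30
CLONES = ["PN-A", "PN-B", "PN-C"]
COVERAGE = 10.0
RATES = (1.6, 5.1, 35.2)  # SNPs, indels, TE insertions per Mb per clone

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
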