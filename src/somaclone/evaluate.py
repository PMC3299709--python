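"""Ground-truth evaluation of calls against the simulation ledger.

Only usable on synthetic data, where the mutation ledger records every
somatic event.  Recall/precision are computed inside the pair's shared
high-coverage regions — the only territory where the caller is allowed to
call — and TE-insertion matching allows the positional jitter created by
target-site duplications and junction-read clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .covstats import RegionSet
from .polycall import INDEL, SNP, TE_INSERTION, PolymorphismCall
from .synthdata import MutationLedger

__all__ = ["RecoveryMetrics", "recovery_metrics"]

_LEDGER_TYPE = {"SNP": SNP, "INDEL": INDEL, "TE_INS": TE_INSERTION}


@dataclass
class RecoveryMetrics:
    type: str
    n_true: int  # ledger events inside the shared (callable) regions
    n_called: int
    n_matched: int  # callable events that were recovered
    n_family_correct: int = 0
    n_true_pos: int = 0  # calls matching any ledger event at all

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return self.n_true_pos / self.n_called if self.n_called else float("nan")

    @property
    def family_accuracy(self) -> float:
        return (self.n_family_correct / self.n_true_pos
                if self.n_true_pos else float("nan"))


def recovery_metrics(ledgers: list[MutationLedger], calls: list[PolymorphismCall],
                     shared: RegionSet, te_radius: int = 25,
                     point_radius: int = 1,
                     indel_radius: int = 12) -> dict[str, RecoveryMetrics]:
    """Compare calls for one clone pair against the clones' ledgers.

    A ledger event is eligible when its ancestor position lies inside the
    shared region set.  SNP matches must agree within ``point_radius``;
    indels within ``indel_radius`` (a multi-base indel has equivalent
    placements across its repeat context and calls are left-normalised,
    whereas the ledger records the simulated breakpoint); TE insertions
    within ``te_radius`` (target-site duplication plus junction-cluster
    jitter)."""
    truth: dict[str, list] = {SNP: [], INDEL: [], TE_INSERTION: []}
    eligible: dict[str, set[int]] = {SNP: set(), INDEL: set(),
                                     TE_INSERTION: set()}
    for ledger in ledgers:
        for e in ledger.entries:
            t = _LEDGER_TYPE[e.type]
            truth[t].append(e)
            if shared.contains(e.chrom, e.pos):
                eligible[t].add(len(truth[t]) - 1)

    out: dict[str, RecoveryMetrics] = {}
    for t, radius in ((SNP, point_radius), (INDEL, indel_radius),
                      (TE_INSERTION, te_radius)):
        tcalls = [c for c in calls if c.type == t]
        matched: set[int] = set()
        n_true_pos = 0
        n_family = 0
        for c in tcalls:
            best = None
            for i, e in enumerate(truth[t]):
                if i in matched or e.chrom != c.chrom:
                    continue
                d = abs(e.pos - c.pos)
                if d <= radius and (best is None or d < best[0]):
                    best = (d, i, e)
            if best is not None:
                matched.add(best[1])
                n_true_pos += 1
                if t == TE_INSERTION and c.te_family is not None:
                    if c.te_family == best[2].detail.get("family"):
                        n_family += 1
        # recall over events inside the callable territory; precision over
        # all calls (a call matching a true event just outside the shared
        # set is still a correct discovery, not a false positive)
        n_recalled = len(matched & eligible[t])
        out[t] = RecoveryMetrics(t, len(eligible[t]), len(tcalls), n_recalled,
                                 n_family, n_true_pos)
    return out
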