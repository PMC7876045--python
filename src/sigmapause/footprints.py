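"""Protected-fragment length distributions and translocation-state fractions.

Length bins follow the in-vivo footprint calibration: 16-17 nt post-
translocated, 18 nt pre-translocated, >18 nt backtracked.  Fragments under
16 nt arise from pausing too close to the promoter for the nuclease to read
out the register and are binned as indeterminate, never backtrack-classified.
Bin edges are configuration, not constants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .track_io import ReadRecord

STATE_NAMES = ("indeterminate", "post", "pre", "backtracked")


@dataclass(frozen=True)
class StateBins:
    """Translocation-state bin edges over fragment length (nt)."""

    post: tuple[int, int] = (16, 17)  # inclusive
    pre: tuple[int, int] = (18, 18)

    def state_of(self, length: int) -> str:
        if length < self.post[0]:
            return "indeterminate"
        if self.post[0] <= length <= self.post[1]:
            return "post"
        if self.pre[0] <= length <= self.pre[1]:
            return "pre"
        return "backtracked"


@dataclass
class FootprintDistribution:
    histogram: dict[int, int]
    mean_length: float | None
    fractions: dict[str, float] = field(default_factory=dict)
    total: int = 0

    def ratio_of_reads(self) -> dict[int, float]:
        """Per-length fraction of all reads (the plotted 'ratio of reads')."""
        if self.total == 0:
            return {}
        return {l: n / self.total for l, n in sorted(self.histogram.items())}


def state_fractions(
    histogram: Mapping[int, int], bins: StateBins = StateBins()
) -> FootprintDistribution:
    """Summarise a length histogram into state fractions.

    An empty histogram yields an explicit empty result (total 0, no
    fractions, undefined mean) rather than NaNs.
    """
    hist = {int(l): int(n) for l, n in histogram.items() if n > 0}
    total = sum(hist.values())
    if total == 0:
        return FootprintDistribution(histogram={}, mean_length=None, fractions={}, total=0)
    for length in hist:
        if length < 1:
            raise ValueError(f"invalid fragment length {length}")
    tallies = dict.fromkeys(STATE_NAMES, 0)
    for length, n in hist.items():
        tallies[bins.state_of(length)] += n
    mean = sum(l * n for l, n in hist.items()) / total
    fractions = {s: tallies[s] / total for s in STATE_NAMES}
    return FootprintDistribution(
        histogram=dict(sorted(hist.items())),
        mean_length=mean,
        fractions=fractions,
        total=total,
    )


def length_distribution(
    reads: Iterable[ReadRecord],
    groups: Mapping[tuple[str, int, str], str] | None = None,
    bins: StateBins = StateBins(),
) -> FootprintDistribution | dict[str, FootprintDistribution]:
    """Length histogram(s) of reads, optionally stratified by pause group.

    ``groups`` maps (contig, 3'-end position, strand) to a group label, as
    produced from pause annotations; reads whose 3' end carries no label go
    into an "unassigned" stratum.  Without ``groups`` a single pooled
    distribution is returned.
    """
    if groups is None:
        hist = Counter(r.length for r in reads)
        return state_fractions(hist, bins)
    strata: dict[str, Counter] = {}
    for r in reads:
        label = groups.get((r.contig, r.three_prime_end, r.strand), "unassigned")
        strata.setdefault(label, Counter())[r.length] += 1
    return {label: state_fractions(h, bins) for label, h in sorted(strata.items())}


def groups_from_annotations(annotations: Sequence) -> dict[tuple[str, int, str], str]:
    """Pause-group lookup keyed by 3'-end coordinate, for stratification."""
    return {
        (a.pause.contig, a.pause.position, a.pause.strand): a.group
        for a in annotations
    }
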