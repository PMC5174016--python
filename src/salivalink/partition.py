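"""Host / microbiota read partitioning by paired mapping quality.

Whole-ecosystem (total saliva DNA) shotgun libraries mix host and
microbial reads.  After alignment against the host genome, a read pair
is labelled host-originating when BOTH mates' mapping qualities exceed
a threshold (default 100, strict inequality); every other pair is
considered microbiota-originating.  Pairs with an unmapped mate carry
MAPQ 0 for that mate and therefore fail the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "ReadPairAlignment",
    "PartitionResult",
    "RecoveryReport",
    "partition_read_pairs",
    "recovery_report",
]

HOST_LABEL = "host"


@dataclass(frozen=True)
class ReadPairAlignment:
    """Mapping evidence for one read pair against the host genome.

    ``mapq1``/``mapq2`` are the Phred-scaled mapping qualities of the
    two mates; a missing (unmapped) mate is encoded as 0.  ``target``
    optionally records the microbial genome the pair mapped to.
    """

    read_id: str
    mapq1: int
    mapq2: int
    target: str | None = None

    def __post_init__(self) -> None:
        if self.mapq1 < 0 or self.mapq2 < 0:
            raise ValueError(f"read {self.read_id}: negative MAPQ")


@dataclass(frozen=True)
class PartitionResult:
    host_ids: frozenset[str]
    microbial_ids: frozenset[str]
    host_fraction: float | None  # None for empty input
    microbial_fraction: float | None

    @property
    def n_pairs(self) -> int:
        return len(self.host_ids) + len(self.microbial_ids)


def partition_read_pairs(
    pairs: Sequence[ReadPairAlignment], threshold: int = 100
) -> PartitionResult:
    """Split pairs into host vs microbiota sets.

    A pair is host iff min(mapq1, mapq2) > threshold (strict: a MAPQ
    equal to the threshold does not qualify).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    seen: set[str] = set()
    host: set[str] = set()
    microbial: set[str] = set()
    for p in pairs:
        if p.read_id in seen:
            raise ValueError(f"duplicate read id: {p.read_id}")
        seen.add(p.read_id)
        if min(p.mapq1, p.mapq2) > threshold:
            host.add(p.read_id)
        else:
            microbial.add(p.read_id)
    n = len(seen)
    hf = len(host) / n if n else None
    mf = len(microbial) / n if n else None
    return PartitionResult(frozenset(host), frozenset(microbial), hf, mf)


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion counts of host labelling against simulation truth."""

    tp: int  # truth host, called host
    fp: int  # truth microbial, called host
    fn: int  # truth host, called microbial
    tn: int  # truth microbial, called microbial
    error_rate: float | None  # None for empty input

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def recovery_report(result: PartitionResult, truth: Mapping[str, str]) -> RecoveryReport:
    """Score a partition against per-read truth labels (host | genome id)."""
    tp = fp = fn = tn = 0
    for rid in result.host_ids:
        if rid not in truth:
            raise KeyError(f"read id missing from truth: {rid}")
        if truth[rid] == HOST_LABEL:
            tp += 1
        else:
            fp += 1
    for rid in result.microbial_ids:
        if rid not in truth:
            raise KeyError(f"read id missing from truth: {rid}")
        if truth[rid] == HOST_LABEL:
            fn += 1
        else:
            tn += 1
    n = tp + fp + fn + tn
    err = (fp + fn) / n if n else None
    return RecoveryReport(tp, fp, fn, tn, err)
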