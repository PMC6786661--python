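"""Mutation-cluster calling.

The procedure has three stages, applied per sample:

1. *Complex collapsing* — runs of mutations with consecutive distances
   < 10 bp are treated as one event (they may derive from a single lesion)
   and carry weight 1 in the statistic.
2. *Candidate grouping* — maximal chains of events whose consecutive
   nearest-edge distances are <= 10 kb (and >= 10 bp by construction, since
   anything closer was collapsed).
3. *Significance* — for a group of ``k`` events spanning ``x`` bases, the
   probability of seeing ``k - 1`` mutations within ``x - 1`` or fewer bases
   under a uniform per-base mutation probability ``pi`` (total collapsed
   mutations of the sample divided by total genome bases) is the
   negative-binomial tail

       p = sum_{j=0}^{x-k} C(k+j-2, j) (1-pi)^j pi^(k-1)

   Groups with ``p <= 1e-4`` are called bona fide clusters.

Grouping is single-pass maximal chaining: a non-significant group is not
recursively subdivided in search of significant sub-groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import GenomeModel, MutationRecord

logger = logging.getLogger(__name__)

#: Consecutive mutations closer than this are one complex event.
DEFAULT_MAX_GAP = 10
#: Maximal chaining distance between events within a candidate group.
DEFAULT_MAX_DISTANCE = 10_000
#: P-value at or below which a group is a bona fide cluster.
DEFAULT_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class CollapsedEvent:
    """One mutation, or one complex event (members < 10 bp apart), weight 1."""

    members: tuple[MutationRecord, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty event")

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        return self.members[-1].pos

    @property
    def k_weight(self) -> int:
        return 1

    @property
    def n_raw(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CandidateGroup:
    """A maximal chain of events with consecutive distances <= max_distance."""

    events: tuple[CollapsedEvent, ...]
    p_value: float | None = None

    @property
    def k(self) -> int:
        return len(self.events)

    @property
    def x(self) -> int:
        """Bases spanned, first event start to last event end, inclusive."""
        return self.events[-1].end - self.events[0].start + 1

    @property
    def testable(self) -> bool:
        return self.k >= 2

    @property
    def mutations(self) -> tuple[MutationRecord, ...]:
        return tuple(m for ev in self.events for m in ev.members)


@dataclass(frozen=True)
class Cluster:
    """A significant group: the footprint of one hypermutable ssDNA tract."""

    sample_id: str
    chrom: str
    events: tuple[CollapsedEvent, ...]
    k: int
    x: int
    p_value: float
    selected: bool = False
    cluster_id: str = ""

    @property
    def mutations(self) -> tuple[MutationRecord, ...]:
        return tuple(m for ev in self.events for m in ev.members)

    @property
    def start(self) -> int:
        return self.events[0].start

    @property
    def end(self) -> int:
        return self.events[-1].end

    @property
    def length(self) -> int:
        """Distance between the bordering mutations (the ssDNA length proxy)."""
        return self.end - self.start

    @property
    def n_mutations(self) -> int:
        """Raw mutation count, complexes expanded."""
        return sum(ev.n_raw for ev in self.events)


def collapse_complexes(
    records: Sequence[MutationRecord], max_gap: int = DEFAULT_MAX_GAP
) -> list[CollapsedEvent]:
    """Collapse maximal chains with consecutive distances < ``max_gap``.

    ``records`` must be one sample/chromosome, sorted by position.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if not records:
        return []
    for a, b in zip(records, records[1:]):
        if b.pos < a.pos:
            raise ValueError("records must be sorted by position")
        if b.pos == a.pos:
            raise ValueError(f"duplicate position {a.chrom}:{a.pos}")
    events: list[CollapsedEvent] = []
    chain: list[MutationRecord] = [records[0]]
    for rec in records[1:]:
        if rec.pos - chain[-1].pos < max_gap:
            chain.append(rec)
        else:
            events.append(CollapsedEvent(tuple(chain)))
            chain = [rec]
    events.append(CollapsedEvent(tuple(chain)))
    return events


def group_candidates(
    events: Sequence[CollapsedEvent], max_distance: int = DEFAULT_MAX_DISTANCE
) -> list[CandidateGroup]:
    """Chain events whose nearest-edge distance is <= ``max_distance``.

    Singleton groups are retained but flagged untestable.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    if not events:
        return []
    groups: list[CandidateGroup] = []
    chain: list[CollapsedEvent] = [events[0]]
    for ev in events[1:]:
        if ev.start - chain[-1].end <= max_distance:
            chain.append(ev)
        else:
            groups.append(CandidateGroup(tuple(chain)))
            chain = [ev]
    groups.append(CandidateGroup(tuple(chain)))
    return groups


def cluster_pvalue(k: int, x: int, pi: float) -> float:
    """Negative-binomial cluster P-value.

    Probability of observing ``k - 1`` mutations in ``x - 1`` or fewer bases
    when each base mutates independently with probability ``pi``:

        p = sum_{j=0}^{x-k} C(k+j-2, j) (1-pi)^j pi^(k-1)

    Computed in log space (stable for k up to thousands). For ``k == 2``
    the sum is geometric and the closed form ``1 - (1-pi)**(x-1)`` is used.
    """
    if not (0.0 < pi < 1.0):
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if x < k:
        raise ValueError(f"x must be >= k, got x={x}, k={k}")
    if k == 2:
        # geometric sum: pi * sum_{j=0}^{x-2} (1-pi)^j = 1 - (1-pi)^(x-1)
        return -math.expm1((x - 1) * math.log1p(-pi))
    j = np.arange(0, x - k + 1)
    log_terms = (
        (k - 1) * math.log(pi)
        + gammaln(k + j - 1)
        - gammaln(j + 1)
        - gammaln(k - 1)
        + j * math.log1p(-pi)
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def sample_pi(records: Sequence[MutationRecord], genome: GenomeModel, max_gap: int = DEFAULT_MAX_GAP) -> float:
    """Genome-wide mutation probability: collapsed events / total bases.

    Complexes count once, consistent with how ``k`` counts them.
    """
    by_chrom: dict[str, list[MutationRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    n_events = sum(len(collapse_complexes(recs, max_gap)) for recs in by_chrom.values())
    return n_events / genome.total_bases


def detect_clusters(
    records: Sequence[MutationRecord],
    genome: GenomeModel,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    reporter: tuple[str, int, int] | None = None,
) -> list[Cluster]:
    """Call bona fide clusters in a (possibly multi-sample) catalog.

    ``pi`` is computed per sample over the whole genome at the model's
    ploidy. Clusters overlapping the ``reporter`` interval (chrom, start,
    end; 1-based closed) are flagged ``selected``.
    """
    by_sample: dict[str, dict[str, list[MutationRecord]]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, {}).setdefault(rec.chrom, []).append(rec)
    clusters: list[Cluster] = []
    for sample_id in sorted(by_sample):
        chroms = by_sample[sample_id]
        pi = sample_pi([r for recs in chroms.values() for r in recs], genome, max_gap)
        if pi <= 0:
            logger.info("sample %s has no mutations; skipping", sample_id)
            continue
        n_cluster = 0
        for chrom in sorted(chroms, key=genome.chrom_rank):
            recs = sorted(chroms[chrom], key=lambda r: r.pos)
            events = collapse_complexes(recs, max_gap)
            for group in group_candidates(events, max_distance):
                if not group.testable:
                    continue
                p = cluster_pvalue(group.k, group.x, pi)
                if p <= p_threshold:
                    n_cluster += 1
                    sel = False
                    if reporter is not None:
                        rchrom, rstart, rend = reporter
                        sel = (
                            chrom == rchrom
                            and group.events[0].start <= rend
                            and group.events[-1].end >= rstart
                        )
                    clusters.append(
                        Cluster(
                            sample_id=sample_id,
                            chrom=chrom,
                            events=group.events,
                            k=group.k,
                            x=group.x,
                            p_value=p,
                            selected=sel,
                            cluster_id=f"{sample_id}:{n_cluster}",
                        )
                    )
    return clusters


def scattered_mutations(
    records: Sequence[MutationRecord], clusters: Sequence[Cluster]
) -> list[MutationRecord]:
    """Mutations that belong to no cluster (the complement partition)."""
    keys = {(m.sample_id, m.chrom, m.pos) for cl in clusters for m in cl.mutations}
    return [r for r in records if (r.sample_id, r.chrom, r.pos) not in keys]


def clusters_to_frame(clusters: Sequence[Cluster]) -> "pd.DataFrame":
    """Detail table of cluster calls (one row per cluster)."""
    import pandas as pd

    rows = []
    for cl in clusters:
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "sample_id": cl.sample_id,
                "chrom": cl.chrom,
                "start": cl.start,
                "end": cl.end,
                "cluster_length": cl.length,
                "n_events": cl.k,
                "n_mutations": cl.n_mutations,
                "span_x": cl.x,
                "p_value": cl.p_value,
                "selected": cl.selected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "sample_id",
            "chrom",
            "start",
            "end",
            "cluster_length",
            "n_events",
            "n_mutations",
            "span_x",
            "p_value",
            "selected",
        ],
    )


def clusters_to_bed(clusters: Sequence[Cluster], path) -> None:
    """Write clusters as BED (0-based half-open; score = -log10 p)."""
    with open(path, "w") as fh:
        for cl in clusters:
            score = min(1000, int(round(-math.log10(max(cl.p_value, 1e-300)))))
            fh.write(f"{cl.chrom}\t{cl.start - 1}\t{cl.end}\t{cl.cluster_id}\t{score}\t.\n")
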