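"""Shared fixtures: small in-memory genomes and cluster builders."""

from __future__ import annotations

import numpy as np
import pytest

from hyperclust.detect import Cluster, CollapsedEvent
from hyperclust.io import GenomeModel, MutationRecord
from hyperclust.simulate import random_genome

PAIRED = {"C": "T", "G": "A", "A": "G", "T": "C"}  # ref -> an arbitrary alt


@pytest.fixture(scope="session")
def yeast_genome() -> GenomeModel:
    """Random 12.07 Mb, 16-chromosome, GC-0.38 haploid genome."""
    return random_genome(seed=7)


@pytest.fixture()
def lengths_only_genome() -> GenomeModel:
    """A 12.07 Mb single-chromosome genome without sequence (detection only)."""
    return GenomeModel({"chr1": 12_070_000})


def build_cluster(
    pattern: str,
    positions: list[int] | None = None,
    sample_id: str = "s1",
    chrom: str = "chr1",
    p_value: float = 1e-6,
    selected: bool = False,
    cluster_id: str = "s1:1",
) -> Cluster:
    """A cluster with the given top-strand ref pattern at given positions."""
    if positions is None:
        positions = [1000 + 500 * i for i in range(len(pattern))]
    assert len(positions) == len(pattern)
    events = tuple(
        CollapsedEvent((MutationRecord(sample_id, chrom, pos, ref, PAIRED[ref]),))
        for pos, ref in zip(positions, pattern)
    )
    return Cluster(
        sample_id=sample_id,
        chrom=chrom,
        events=events,
        k=len(events),
        x=positions[-1] - positions[0] + 1,
        p_value=p_value,
        selected=selected,
        cluster_id=cluster_id,
    )


@pytest.fixture()
def make_cluster():
    return build_cluster


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_920)
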