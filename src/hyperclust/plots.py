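"""Basic report figures (rainfall and cluster-length plots).

Matplotlib is imported lazily so the analysis modules carry no plotting
dependency at import time.
"""

from __future__ import annotations

from typing import Sequence

from .detect import Cluster
from .io import GenomeModel, MutationRecord


def rainfall_plot(records: Sequence[MutationRecord], genome: GenomeModel, ax=None):
    """Inter-mutation distance vs genome position, log-y (rainfall plot).

    Clusters appear as dips of closely spaced points.
    """
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offsets = {}
    running = 0
    for name in genome.chrom_names:
        offsets[name] = running
        running += genome.chrom_lengths[name]
    pos = np.array(
        sorted(offsets[r.chrom] + r.pos for r in records), dtype=float
    )
    if len(pos) > 1:
        ax.scatter(pos[1:], np.diff(pos), s=4, alpha=0.6)
        ax.set_yscale("log")
    for name in genome.chrom_names[1:]:
        ax.axvline(offsets[name], color="0.85", lw=0.5, zorder=0)
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("distance to previous SNV (bp)")
    return ax


def cluster_length_hist(clusters: Sequence[Cluster], ax=None, bins: int = 30):
    """Histogram of cluster lengths (log-x)."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots()
    lengths = [cl.length for cl in clusters if cl.length > 0]
    if lengths:
        ax.hist(lengths, bins=np.logspace(np.log10(min(lengths)), np.log10(max(lengths)), bins))
        ax.set_xscale("log")
    ax.set_xlabel("cluster length (bp)")
    ax.set_ylabel("clusters")
    return ax
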