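"""Strand-coordination taxonomy of CG clusters.

A cluster's mutations are read 5'->3' on the top (Watson) strand and reduced
to the string of their reference alleles. Clusters containing any mutated A
or T are set aside as ``non_CG``; CG clusters with fewer than four mutations
are below the size filter (the single-switch definition itself needs a
>=2 C-run next to a >=2 G-run, so ">3 mutations" is read as >=4). The
remaining clusters partition by the run structure of their C/G string:

* one run                      -> C-coordinated or G-coordinated
* two runs, one of length 1    -> coordinated with a terminal
  noncoordinated base (the singleton may sit at either end)
* two runs, both length >= 2   -> CG single-switch (5'C-3'G or 5'G-3'C)
* three or more runs           -> CG multiple-switch

A contiguous ssDNA tract exposes only one strand, so fully coordinated
clusters mark unidirectional resection or BIR tails, while a single C->G
switch (top strand, 5'->3') is the signature of bidirectional resection
around a double-strand break.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import Cluster

DEFAULT_MIN_MUTATIONS = 4


class ClusterType(str, Enum):
    C_COORDINATED = "C_coordinated"
    G_COORDINATED = "G_coordinated"
    C_COORDINATED_TERMINAL_G = "C_coordinated_terminal_G"
    G_COORDINATED_TERMINAL_C = "G_coordinated_terminal_C"
    CG_SINGLE_SWITCH_5PC = "CG_single_switch_5pC"
    CG_SINGLE_SWITCH_5PG = "CG_single_switch_5pG"
    CG_MULTIPLE_SWITCH = "CG_multiple_switch"
    NON_CG = "non_CG"
    BELOW_SIZE_FILTER = "below_size_filter"


#: The four classes displayed in distribution panels; everything else is
#: excluded from their denominator.
DISPLAY_CLASS = {
    ClusterType.C_COORDINATED: "coordinated",
    ClusterType.G_COORDINATED: "coordinated",
    ClusterType.C_COORDINATED_TERMINAL_G: "coordinated_terminal",
    ClusterType.G_COORDINATED_TERMINAL_C: "coordinated_terminal",
    ClusterType.CG_SINGLE_SWITCH_5PC: "single_switch",
    ClusterType.CG_SINGLE_SWITCH_5PG: "single_switch",
    ClusterType.CG_MULTIPLE_SWITCH: "multiple_switch",
}

SINGLE_SWITCH_TYPES = frozenset(
    {ClusterType.CG_SINGLE_SWITCH_5PC, ClusterType.CG_SINGLE_SWITCH_5PG}
)
TERMINAL_TYPES = frozenset(
    {ClusterType.C_COORDINATED_TERMINAL_G, ClusterType.G_COORDINATED_TERMINAL_C}
)


def mutation_pattern(cluster: Cluster) -> str:
    """Reference alleles of the cluster's mutations in positional order.

    Complex events contribute every member allele, expanded in place.
    """
    return "".join(m.ref for m in cluster.mutations)


def _runs(pattern: str) -> list[tuple[str, int]]:
    return [(base, sum(1 for _ in grp)) for base, grp in itertools.groupby(pattern)]


def classify_pattern(pattern: str, min_mutations: int = DEFAULT_MIN_MUTATIONS) -> ClusterType:
    """Classify a top-strand ref-allele string (see module docstring)."""
    if not pattern:
        raise ValueError("empty cluster pattern")
    if any(base not in "CG" for base in pattern):
        return ClusterType.NON_CG
    if len(pattern) < min_mutations:
        return ClusterType.BELOW_SIZE_FILTER
    runs = _runs(pattern)
    if len(runs) == 1:
        return ClusterType.C_COORDINATED if runs[0][0] == "C" else ClusterType.G_COORDINATED
    if len(runs) == 2:
        (b1, n1), (b2, n2) = runs
        if n1 >= 2 and n2 >= 2:
            return (
                ClusterType.CG_SINGLE_SWITCH_5PC if b1 == "C" else ClusterType.CG_SINGLE_SWITCH_5PG
            )
        # exactly one singleton run, necessarily terminal
        coordinated = b1 if n1 >= 2 else b2
        return (
            ClusterType.C_COORDINATED_TERMINAL_G
            if coordinated == "C"
            else ClusterType.G_COORDINATED_TERMINAL_C
        )
    return ClusterType.CG_MULTIPLE_SWITCH


def classify_cluster(cluster: Cluster, min_mutations: int = DEFAULT_MIN_MUTATIONS) -> ClusterType:
    return classify_pattern(mutation_pattern(cluster), min_mutations)


def classification_frame(
    clusters: Sequence[Cluster],
    strata: Mapping[str, str] | None = None,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> pd.DataFrame:
    """Per-cluster table: type, display class, pattern, geometry columns.

    ``strata`` maps sample_id to a stratum label (e.g. strain or colony
    type); unmapped samples fall in stratum ``"all"``.
    """
    rows = []
    for cl in clusters:
        ctype = classify_cluster(cl, min_mutations)
        geom = switch_geometry(cl) if ctype in SINGLE_SWITCH_TYPES else None
        term = _terminal_distances(cl) if ctype in TERMINAL_TYPES else None
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "sample_id": cl.sample_id,
                "stratum": (strata or {}).get(cl.sample_id, "all"),
                "chrom": cl.chrom,
                "start": cl.start,
                "end": cl.end,
                "cluster_length": cl.length,
                "n_mutations": cl.n_mutations,
                "selected": cl.selected,
                "pattern": mutation_pattern(cl),
                "cluster_type": ctype.value,
                "display_class": DISPLAY_CLASS.get(ctype, ""),
                "left_arm_bp": geom.left_arm_bp if geom else np.nan,
                "right_arm_bp": geom.right_arm_bp if geom else np.nan,
                "dist_terminal_nonmatched": term[0] if term else np.nan,
                "dist_terminal_matched": term[1] if term else np.nan,
            }
        )
    return pd.DataFrame(rows)


def type_distribution(
    clusters: Sequence[Cluster],
    strata: Mapping[str, str] | None = None,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> pd.DataFrame:
    """Counts and fractions of the four displayed classes per stratum.

    Fractions sum to 1 within a stratum over displayed classes only;
    ``non_CG`` and ``below_size_filter`` clusters are excluded from the
    denominator (but reported in the count columns).
    """
    classes = ["coordinated", "coordinated_terminal", "single_switch", "multiple_switch"]
    frame = classification_frame(clusters, strata, min_mutations)
    rows = []
    strat_labels = sorted(frame["stratum"].unique()) if len(frame) else []
    for stratum in strat_labels:
        sub = frame[frame["stratum"] == stratum]
        displayed = sub[sub["display_class"] != ""]
        denom = len(displayed)
        for cls in classes:
            n = int((displayed["display_class"] == cls).sum())
            rows.append(
                {
                    "stratum": stratum,
                    "display_class": cls,
                    "count": n,
                    "fraction": (n / denom) if denom else np.nan,
                    "n_cg_clusters": denom,
                    "n_non_cg": int((sub["cluster_type"] == ClusterType.NON_CG.value).sum()),
                    "n_below_size": int(
                        (sub["cluster_type"] == ClusterType.BELOW_SIZE_FILTER.value).sum()
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "display_class",
            "count",
            "fraction",
            "n_cg_clusters",
            "n_non_cg",
            "n_below_size",
        ],
    )


def switch_direction_summary(
    clusters: Sequence[Cluster], min_mutations: int = DEFAULT_MIN_MUTATIONS
) -> pd.Series:
    """Fractions of single-switch clusters with 5'C-3'G vs 5'G-3'C polarity."""
    n_5pc = n_5pg = 0
    for cl in clusters:
        ctype = classify_cluster(cl, min_mutations)
        if ctype is ClusterType.CG_SINGLE_SWITCH_5PC:
            n_5pc += 1
        elif ctype is ClusterType.CG_SINGLE_SWITCH_5PG:
            n_5pg += 1
    total = n_5pc + n_5pg
    return pd.Series(
        {
            "n_single_switch": total,
            "n_5pC_3pG": n_5pc,
            "n_5pG_3pC": n_5pg,
            "frac_5pC_3pG": n_5pc / total if total else np.nan,
            "frac_5pG_3pC": n_5pg / total if total else np.nan,
        }
    )


@dataclass(frozen=True)
class SwitchGeometry:
    """Arm spans of a single-switch cluster around its switch point."""

    left_arm_bp: int
    right_arm_bp: int
    switch_point: float

    @property
    def log_ratio(self) -> float:
        return math.log(self.left_arm_bp / self.right_arm_bp)


def switch_geometry(cluster: Cluster, min_mutations: int = DEFAULT_MIN_MUTATIONS) -> SwitchGeometry:
    """Arm lengths of a single-switch cluster.

    Each arm spans from its outermost to its innermost mutation; the switch
    point is midway between the innermost mutations of the two runs.
    """
    ctype = classify_cluster(cluster, min_mutations)
    if ctype not in SINGLE_SWITCH_TYPES:
        raise ValueError(f"not a single-switch cluster: {ctype.value}")
    pattern = mutation_pattern(cluster)
    positions = [m.pos for m in cluster.mutations]
    split = next(i for i in range(1, len(pattern)) if pattern[i] != pattern[0])
    left = positions[:split]
    right = positions[split:]
    return SwitchGeometry(
        left_arm_bp=left[-1] - left[0],
        right_arm_bp=right[-1] - right[0],
        switch_point=(left[-1] + right[0]) / 2,
    )


def _terminal_distances(cluster: Cluster) -> tuple[int, int]:
    """(nonmatched, matched) neighbour distances for a terminal-type cluster."""
    positions = [m.pos for m in cluster.mutations]
    pattern = mutation_pattern(cluster)
    runs = _runs(pattern)
    if runs[0][1] == 1:  # singleton at the 5' end
        nonmatched = positions[1] - positions[0]
        matched = positions[-1] - positions[-2]
    else:  # singleton at the 3' end
        nonmatched = positions[-1] - positions[-2]
        matched = positions[1] - positions[0]
    return nonmatched, matched


def terminal_distance_analysis(
    clusters: Iterable[Cluster], min_mutations: int = DEFAULT_MIN_MUTATIONS
) -> tuple[pd.DataFrame, "stats._mannwhitneyu.MannwhitneyuResult | None"]:
    """Neighbour distances of terminal noncoordinated vs coordinated mutations.

    For each coordinated-with-terminal cluster, the *nonmatched* distance is
    from the singleton noncoordinated terminal mutation to its nearest
    neighbour, the *matched* distance from the opposite-end coordinated
    terminal mutation to its neighbour. A systematically larger nonmatched
    distance indicates random colocalization rather than a strand switch.
    Returns the per-cluster table and a two-sided rank-sum comparison
    (``None`` when either list is empty).
    """
    rows = []
    for cl in clusters:
        ctype = classify_cluster(cl, min_mutations)
        if ctype not in TERMINAL_TYPES:
            raise ValueError(f"cluster {cl.cluster_id}: not a terminal-type cluster ({ctype.value})")
        nonmatched, matched = _terminal_distances(cl)
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "sample_id": cl.sample_id,
                "cluster_type": ctype.value,
                "dist_terminal_nonmatched": nonmatched,
                "dist_terminal_matched": matched,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "sample_id",
            "cluster_type",
            "dist_terminal_nonmatched",
            "dist_terminal_matched",
        ],
    )
    if len(table) == 0:
        return table, None
    test = stats.mannwhitneyu(
        table["dist_terminal_nonmatched"],
        table["dist_terminal_matched"],
        alternative="two-sided",
    )
    return table, test


def arm_ratio_variance(
    clusters: Sequence[Cluster],
    strata: Mapping[str, str] | None = None,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dispersion of log(left arm / right arm) of single-switch clusters.

    Symmetric bidirectional resection gives log-ratios near 0 with low
    variance; asymmetric resection inflates the variance. Returns the
    per-cluster log-ratio table and pairwise Brown-Forsythe (median-centred
    Levene) comparisons between strata.
    """
    rows = []
    for cl in clusters:
        if classify_cluster(cl, min_mutations) not in SINGLE_SWITCH_TYPES:
            continue
        geom = switch_geometry(cl, min_mutations)
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "sample_id": cl.sample_id,
                "stratum": (strata or {}).get(cl.sample_id, "all"),
                "left_arm_bp": geom.left_arm_bp,
                "right_arm_bp": geom.right_arm_bp,
                "log_ratio": geom.log_ratio,
            }
        )
    table = pd.DataFrame(
        rows, columns=["cluster_id", "sample_id", "stratum", "left_arm_bp", "right_arm_bp", "log_ratio"]
    )
    comparisons = []
    labels = sorted(table["stratum"].unique()) if len(table) else []
    for a, b in itertools.combinations(labels, 2):
        xs = table.loc[table["stratum"] == a, "log_ratio"]
        ys = table.loc[table["stratum"] == b, "log_ratio"]
        if len(xs) < 2 or len(ys) < 2:
            continue
        res = stats.levene(xs, ys, center="median")
        comparisons.append(
            {
                "stratum_a": a,
                "stratum_b": b,
                "var_a": float(np.var(xs, ddof=1)),
                "var_b": float(np.var(ys, ddof=1)),
                "levene_stat": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return table, pd.DataFrame(
        comparisons, columns=["stratum_a", "stratum_b", "var_a", "var_b", "levene_stat", "p_value"]
    )
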